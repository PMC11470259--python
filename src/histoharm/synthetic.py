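"""Synthetic cohort generator with a location-scale batch-effect model.

Patch values for slide j of site i follow, per feature g,

    Y = alpha_g + shift_g(class(j)) + gamma_ig + delta_ig * eps,
    eps ~ N(0, sigma_g^2),

with gamma_ig drawn once per (site, feature) from N(mu_i, tau_i^2) and
delta_ig^2 drawn once per (site, feature) from InverseGamma(lambda_i, theta_i).
Class labels per slide are sampled with site-conditional probabilities that
interpolate between uniform (rho=0) and a fixed site->class map (rho=1).
Ground truth (effects, labels, signal features, artifact masks) is retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bags import MISSING, Cohort, PatchBag

__all__ = [
    "AttributeSpec",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_cohort",
    "inject_artifact_regions",
]


@dataclass
class AttributeSpec:
    """One categorical slide attribute.

    ``class_shifts`` is a (n_classes, D) array of additive per-feature mean
    shifts (non-zero only on the attribute's signal features).  ``rho`` dials
    site-label confounding: 0 = independent of site, 1 = fully determined by
    the fixed site->class map ``class = site_index mod n_classes``.
    ``missing_rate`` marks a random fraction of slides as missing.
    """

    name: str
    n_classes: int
    class_shifts: np.ndarray
    rho: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        self.class_shifts = np.atleast_2d(np.asarray(self.class_shifts, dtype=np.float64))
        if self.n_classes < 2:
            raise ValueError(f"attribute {self.name!r}: need >= 2 classes")
        if self.class_shifts.shape[0] != self.n_classes:
            raise ValueError(f"attribute {self.name!r}: one shift row per class required")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError(f"attribute {self.name!r}: rho must be in [0, 1]")
        if not np.all(np.isfinite(self.class_shifts)):
            raise ValueError(f"attribute {self.name!r}: non-finite shifts")

    @property
    def signal_features(self) -> np.ndarray:
        return np.flatnonzero(np.any(self.class_shifts != 0.0, axis=0))


@dataclass
class SimulationConfig:
    n_sites: int
    slides_per_site: int
    patches_per_slide: int | tuple[int, int]
    n_features: int
    grand_mean: np.ndarray | float = 0.0
    noise_scale: np.ndarray | float = 1.0
    additive_prior: list[tuple[float, float]] | tuple[float, float] = (0.0, 1.0)
    multiplicative_prior: list[tuple[float, float]] | tuple[float, float] = (4.0, 3.0)
    attributes: list[AttributeSpec] = field(default_factory=list)
    artifact_fraction: float = 0.0
    artifact_shift: np.ndarray | float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        D = self.n_features
        if D < 2:
            raise ValueError("n_features must be >= 2")
        if self.n_sites < 1 or self.slides_per_site < 1:
            raise ValueError("need at least one site and one slide per site")
        self.grand_mean = np.broadcast_to(
            np.asarray(self.grand_mean, dtype=np.float64), (D,)
        ).copy()
        self.noise_scale = np.broadcast_to(
            np.asarray(self.noise_scale, dtype=np.float64), (D,)
        ).copy()
        if np.any(self.noise_scale <= 0) or not np.all(np.isfinite(self.noise_scale)):
            raise ValueError("noise_scale must be positive and finite")
        if not np.all(np.isfinite(self.grand_mean)):
            raise ValueError("grand_mean must be finite")
        self.additive_prior = self._per_site(self.additive_prior)
        self.multiplicative_prior = self._per_site(self.multiplicative_prior)
        for mu, tau2 in self.additive_prior:
            if tau2 < 0 or not (math.isfinite(mu) and math.isfinite(tau2)):
                raise ValueError("additive prior needs finite mu and tau^2 >= 0")
        for lam, theta in self.multiplicative_prior:
            # lambda > 2 keeps the prior variance of delta^2 finite; theta = 0
            # is the documented degenerate escape hatch (delta^2 fixed at 1).
            if theta == 0.0:
                continue
            if lam <= 2 or theta < 0:
                raise ValueError("inverse-gamma prior needs lambda > 2, theta >= 0")
        if isinstance(self.patches_per_slide, (tuple, list)):
            lo, hi = self.patches_per_slide
            if lo < 1 or hi < lo:
                raise ValueError("invalid patches_per_slide range")
        elif self.patches_per_slide < 1:
            raise ValueError("patches_per_slide must be >= 1")
        if not (0.0 <= self.artifact_fraction <= 1.0):
            raise ValueError("artifact_fraction must be in [0, 1]")
        self.artifact_shift = np.broadcast_to(
            np.asarray(self.artifact_shift, dtype=np.float64), (D,)
        ).copy()
        if not np.all(np.isfinite(self.artifact_shift)):
            raise ValueError("artifact_shift must be finite")
        for spec in self.attributes:
            if spec.class_shifts.shape[1] != D:
                raise ValueError(f"attribute {spec.name!r}: shift vectors must have length D")
            if spec.rho > 0 and self.n_sites < 2:
                raise ValueError("site confounding (rho > 0) requires >= 2 sites")

    def _per_site(self, prior):
        # a (a, b) scalar pair is shared by all sites; otherwise one pair per site
        if isinstance(prior, tuple) or (
            len(prior) == 2 and np.isscalar(prior[0]) and np.isscalar(prior[1])
        ):
            return [tuple(prior)] * self.n_sites
        prior = [tuple(p) for p in prior]
        if len(prior) != self.n_sites:
            raise ValueError("per-site prior list must have n_sites entries")
        return prior


@dataclass
class SimulationTruth:
    """Ground truth retained alongside a simulated cohort."""

    gamma_true: np.ndarray          # (n_sites, D)
    delta2_true: np.ndarray         # (n_sites, D)
    slide_site: dict[str, str]
    slide_attribute_labels: pd.DataFrame
    signal_features: dict[str, np.ndarray]
    artifact_mask: dict[str, np.ndarray]

    def copy(self) -> "SimulationTruth":
        return SimulationTruth(
            gamma_true=self.gamma_true.copy(),
            delta2_true=self.delta2_true.copy(),
            slide_site=dict(self.slide_site),
            slide_attribute_labels=self.slide_attribute_labels.copy(),
            signal_features={k: v.copy() for k, v in self.signal_features.items()},
            artifact_mask={k: v.copy() for k, v in self.artifact_mask.items()},
        )


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Split one global seed into independent per-purpose streams."""
    names = ("effects", "noise", "labels", "artifacts", "counts")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _grid_shape(n_patches: int) -> tuple[int, int]:
    rows = int(math.floor(math.sqrt(n_patches)))
    cols = int(math.ceil(n_patches / rows))
    return rows, cols


def site_name(i: int) -> str:
    return f"site{i:02d}"


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, SimulationTruth]:
    """Draw a cohort from the generative model; deterministic under ``seed``."""
    rng = _streams(config.seed)
    D = config.n_features
    B = config.n_sites

    gamma = np.empty((B, D))
    delta2 = np.empty((B, D))
    for i in range(B):
        mu, tau2 = config.additive_prior[i]
        gamma[i] = mu + math.sqrt(tau2) * rng["effects"].standard_normal(D) if tau2 > 0 else mu
        lam, theta = config.multiplicative_prior[i]
        if theta == 0.0:
            delta2[i] = 1.0
        else:
            # InverseGamma(lam, theta) = theta / Gamma(lam, 1)
            delta2[i] = theta / rng["effects"].gamma(shape=lam, scale=1.0, size=D)

    n_slides = B * config.slides_per_site
    if isinstance(config.patches_per_slide, (tuple, list)):
        lo, hi = config.patches_per_slide
        counts = rng["counts"].integers(lo, hi + 1, size=n_slides)
    else:
        counts = np.full(n_slides, config.patches_per_slide, dtype=np.int64)

    # per-attribute slide labels with site-conditional mixing
    label_cols: dict[str, list] = {spec.name: [] for spec in config.attributes}
    slide_meta: list[tuple[str, int]] = []  # (slide_id, site index)
    for i in range(B):
        for j in range(config.slides_per_site):
            slide_meta.append((f"{site_name(i)}_s{j:03d}", i))
    for spec in config.attributes:
        C = spec.n_classes
        for _, i in slide_meta:
            p = np.full(C, (1.0 - spec.rho) / C)
            p[i % C] += spec.rho
            label_cols[spec.name].append(int(rng["labels"].choice(C, p=p)))
        if spec.missing_rate > 0:
            miss = rng["labels"].random(n_slides) < spec.missing_rate
            label_cols[spec.name] = [
                None if m else v for v, m in zip(label_cols[spec.name], miss)
            ]

    bags: list[PatchBag] = []
    attr_rows: dict[str, dict] = {}
    masks: dict[str, np.ndarray] = {}
    for k, (sid, i) in enumerate(slide_meta):
        P = int(counts[k])
        shift = np.zeros(D)
        for spec in config.attributes:
            lab = label_cols[spec.name][k]
            if lab is not None:
                shift = shift + spec.class_shifts[lab]
        eps = rng["noise"].standard_normal((P, D)) * config.noise_scale
        Y = config.grand_mean + shift + gamma[i] + np.sqrt(delta2[i]) * eps
        rows, cols = _grid_shape(P)
        rc = np.arange(P)
        coords = np.column_stack([rc // cols, rc % cols])
        bags.append(PatchBag(slide_id=sid, site=site_name(i), features=Y, coords=coords))
        attr_rows[sid] = {
            spec.name: (MISSING if label_cols[spec.name][k] is None
                        else f"class{label_cols[spec.name][k]}")
            for spec in config.attributes
        }
        masks[sid] = np.zeros(P, dtype=bool)

    attributes = pd.DataFrame.from_dict(attr_rows, orient="index")
    if attributes.empty:
        attributes = pd.DataFrame(index=[b.slide_id for b in bags])
    cohort = Cohort(
        bags=bags,
        attributes=attributes,
        provenance={"seed": config.seed, "generator": "histoharm.synthetic"},
    )
    truth = SimulationTruth(
        gamma_true=gamma,
        delta2_true=delta2,
        slide_site={sid: site_name(i) for sid, i in slide_meta},
        slide_attribute_labels=attributes.copy(),
        signal_features={s.name: s.signal_features for s in config.attributes},
        artifact_mask=masks,
    )
    return cohort, truth


def inject_artifact_regions(
    cohort: Cohort, truth: SimulationTruth, config: SimulationConfig
) -> tuple[Cohort, SimulationTruth]:
    """Add ``artifact_shift`` to a contiguous patch rectangle on selected slides.

    Slides are chosen from the artifact stream of ``config.seed``; exactly
    ``round(artifact_fraction * n_slides)`` slides receive one axis-aligned
    rectangle covering roughly 4-16% of their patch grid.
    """
    if not (0.0 <= config.artifact_fraction <= 1.0):
        raise ValueError("artifact_fraction must be in [0, 1]")
    rng = _streams(config.seed)["artifacts"]
    cohort = cohort.copy()
    truth = truth.copy()
    n_hit = int(round(config.artifact_fraction * cohort.n_slides))
    if n_hit == 0:
        return cohort, truth
    hit = rng.choice(cohort.n_slides, size=n_hit, replace=False)
    for b_idx in sorted(hit):
        bag = cohort.bags[b_idx]
        if bag.coords is None:
            raise ValueError(f"slide {bag.slide_id!r}: patch grid coordinates required")
        rows = int(bag.coords[:, 0].max()) + 1
        cols = int(bag.coords[:, 1].max()) + 1
        h = max(1, int(round(rows * rng.uniform(0.2, 0.4))))
        w = max(1, int(round(cols * rng.uniform(0.2, 0.4))))
        r0 = int(rng.integers(0, rows - h + 1))
        c0 = int(rng.integers(0, cols - w + 1))
        inside = (
            (bag.coords[:, 0] >= r0) & (bag.coords[:, 0] < r0 + h)
            & (bag.coords[:, 1] >= c0) & (bag.coords[:, 1] < c0 + w)
        )
        bag.features[inside] += config.artifact_shift
        truth.artifact_mask[bag.slide_id] = inside
    return cohort, truth
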