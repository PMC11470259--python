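"""Empirical-Bayes location-scale batch correction for patch embeddings.

The model per feature g and batch i is

    Y_ijg = alpha_g + gamma_ig + delta_ig * eps_ijg,   eps ~ N(0, sigma_g^2)

with a normal prior on the additive effects gamma_ig and an inverse-gamma
prior on the squared multiplicative effects delta_ig^2, whose hyperparameters
are estimated by the method of moments across features.  The adjustment is
the fully standardized form

    Y*_ijg = sigma_g * (Z_ijg - gamma*_ig) / delta*_ig + alpha_g,
    Z_ijg = (Y_ijg - alpha_g) / sigma_g,

where (gamma*, delta*^2) are the EB-shrunk effect estimates, obtained either
from the parametric fixed point or from a non-parametric leave-one-out
posterior over the other features' estimates.

Conventions (shared with the test oracles): alpha_g is the sample-size
weighted batch-mean average; sigma_g^2 is the pooled residual variance with
an N denominator; within-batch delta^2 and all across-feature moments use
the n-1 (sample) denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bags import Cohort

__all__ = [
    "CombatModel",
    "drop_degenerate_features",
    "standardize",
    "moments_hyperpriors",
    "eb_shrink_parametric",
    "eb_shrink_nonparametric",
    "fit_transform",
    "apply_reference",
    "harmonize_cohort",
    "apply_reference_cohort",
]

PRIOR_MODES = ("parametric", "nonparametric")
CORRECTION_MODES = ("both", "additive_only", "multiplicative_only")


@dataclass
class CombatModel:
    """Every quantity fitted by :func:`fit_transform`."""

    alpha_hat: np.ndarray                 # (D,)
    sigma_hat: np.ndarray                 # (D,) pooled scale, > 0
    gamma_star: np.ndarray                # (B, D)
    delta_star2: np.ndarray               # (B, D), > 0
    hyper: dict[str, tuple[float, float, float, float]]  # site -> (gbar, t2, lam, theta)
    batch_levels: list[str]
    n_per_batch: dict[str, int]
    feature_mask: np.ndarray              # bool over original columns
    prior_mode: str = "parametric"
    correction_mode: str = "both"
    reference_batch: str | None = None
    log: list[str] = field(default_factory=list)

    def batch_index(self, label: str) -> int:
        try:
            return self.batch_levels.index(label)
        except ValueError:
            raise KeyError(f"unknown batch label {label!r}") from None


def drop_degenerate_features(cohort: Cohort) -> tuple[np.ndarray, Cohort]:
    """Drop, dataset-wide, any feature constant within at least one slide.

    Returns the boolean keep-mask over original columns and the masked cohort.
    """
    if cohort.n_slides == 0:
        raise ValueError("empty cohort")
    D = cohort.n_features
    keep = np.ones(D, dtype=bool)
    for bag in cohort.bags:
        if bag.n_patches < 2:
            raise ValueError(f"slide {bag.slide_id!r}: need >= 2 patches")
        keep &= bag.features.var(axis=0) > 0.0
    if not keep.any():
        raise ValueError("all features are degenerate (zero within-slide variance)")
    masked = cohort.with_features([b.features[:, keep] for b in cohort.bags])
    masked.provenance["feature_mask"] = keep.tolist()
    return keep, masked


def _batch_groups(batches: np.ndarray) -> tuple[list[str], list[np.ndarray]]:
    batches = np.asarray(batches, dtype=object)
    levels = list(dict.fromkeys(batches.tolist()))  # first-appearance order
    return levels, [np.flatnonzero(batches == lv) for lv in levels]


def standardize(
    X: np.ndarray, batches: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center/scale each feature by the weighted grand mean and pooled scale.

    alpha_g = sum_i (n_i/N) * mean_i(g); sigma_g^2 = (1/N) sum_ij
    (X_ijg - mean_i(g))^2.  Raises if any pooled variance is zero (degenerate
    features should have been dropped) or any batch has < 2 samples.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be an n x D matrix with D >= 1")
    if np.isnan(X).any():
        raise ValueError("X contains NaN")
    levels, groups = _batch_groups(batches)
    if len(np.asarray(batches)) != X.shape[0]:
        raise ValueError("batches length must match X rows")
    N = X.shape[0]
    alpha = np.zeros(X.shape[1])
    ss = np.zeros(X.shape[1])
    for lv, idx in zip(levels, groups):
        if idx.size < 2:
            raise ValueError(f"batch {lv!r} has fewer than 2 samples")
        m = X[idx].mean(axis=0)
        alpha += (idx.size / N) * m
        ss += ((X[idx] - m) ** 2).sum(axis=0)
    sigma2 = ss / N
    if np.any(sigma2 <= 0.0):
        bad = np.flatnonzero(sigma2 <= 0.0)
        raise ValueError(
            f"pooled variance is zero for features {bad.tolist()}; "
            "run drop_degenerate_features first"
        )
    sigma = np.sqrt(sigma2)
    Z = (X - alpha) / sigma
    return Z, alpha, sigma


def moments_hyperpriors(
    gamma_hat_i: np.ndarray, delta2_hat_i: np.ndarray
) -> tuple[float, float, float, float]:
    """Method-of-moments hyperparameters for one batch.

    Returns (gamma_bar, tau2, lambda, theta).  The inverse-gamma moments are
    inverted via lambda = (V^2 + 2 S^2) / S^2 and theta = (V^3 + V S^2) / S^2
    with V, S^2 the across-feature mean and sample variance of delta2_hat.
    S^2 = 0 yields the documented flat-prior fallback (lambda=1, theta=0),
    under which the fixed point reproduces the unshrunk (N-denominator)
    residual variance.
    """
    g = np.asarray(gamma_hat_i, dtype=np.float64)
    d2 = np.asarray(delta2_hat_i, dtype=np.float64)
    if g.size < 3 or d2.size < 3:
        raise ValueError("need D >= 3 features to estimate hyperpriors")
    gbar = float(g.mean())
    tau2 = float(g.var(ddof=1))
    V = float(d2.mean())
    S2 = float(d2.var(ddof=1))
    # exact zeros and floating-point dust both mean "no spread to fit a prior"
    if S2 <= 1e-12 * V * V:
        return gbar, tau2, 1.0, 0.0
    lam = (V * V + 2.0 * S2) / S2
    theta = (V ** 3 + V * S2) / S2
    return gbar, tau2, lam, theta


def eb_shrink_parametric(
    Z_batch: np.ndarray,
    gamma_hat_i: np.ndarray,
    delta2_hat_i: np.ndarray,
    hyper_i: tuple[float, float, float, float],
    tol: float = 1e-4,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Joint fixed-point EB update for one batch.

    Iterates
        gamma* <- (n tau2 gamma_hat + delta*^2 gbar) / (n tau2 + delta*^2)
        delta*^2 <- (theta + 0.5 sum_j (Z_jg - gamma*_g)^2) / (n/2 + lambda - 1)
    until the max absolute relative change drops below ``tol``.  Returns
    (gamma*, delta*^2, converged).
    """
    Z = np.asarray(Z_batch, dtype=np.float64)
    n = Z.shape[0]
    if n < 2:
        raise ValueError("batch needs >= 2 samples")
    gbar, tau2, lam, theta = hyper_i
    if not all(np.isfinite([gbar, tau2, lam, theta])):
        raise ValueError("non-finite hyperparameters")
    g_hat = np.asarray(gamma_hat_i, dtype=np.float64)
    g = g_hat.copy()
    d2 = np.asarray(delta2_hat_i, dtype=np.float64).copy()
    converged = False
    for _ in range(max_iter):
        # the location update always conditions on the raw gamma_hat
        g_new = (n * tau2 * g_hat + d2 * gbar) / (n * tau2 + d2)
        ss = ((Z - g_new) ** 2).sum(axis=0)
        d2_new = (theta + 0.5 * ss) / (n / 2.0 + lam - 1.0)
        change = max(
            _max_rel_change(g, g_new),
            _max_rel_change(d2, d2_new),
        )
        g, d2 = g_new, d2_new
        if change < tol:
            converged = True
            break
    if np.any(d2 <= 0) or not np.all(np.isfinite(d2)):
        raise FloatingPointError("EB iteration produced non-positive delta*^2")
    return g, d2, converged


def _max_rel_change(old: np.ndarray, new: np.ndarray) -> float:
    denom = np.maximum(np.abs(old), 1e-12)
    return float(np.max(np.abs(new - old) / denom))


def eb_shrink_nonparametric(
    Z_batch: np.ndarray,
    gamma_hat_i: np.ndarray,
    delta2_hat_i: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out Monte-Carlo posterior means for one batch.

    For feature g, every other feature g' contributes its raw estimates
    (gamma_hat_g', delta2_hat_g') weighted by the Gaussian likelihood of
    feature g's standardized data under those parameters; weights are
    normalized in log-space.  Cost is O(D^2 n).
    """
    Z = np.asarray(Z_batch, dtype=np.float64)
    g_hat = np.asarray(gamma_hat_i, dtype=np.float64)
    d2_hat = np.asarray(delta2_hat_i, dtype=np.float64)
    n, D = Z.shape
    if D < 2:
        raise ValueError("nonparametric shrinkage needs D >= 2")
    if np.any(d2_hat <= 0):
        raise ValueError("delta2_hat must be positive")
    # loglik[g, g'] = sum_j log N(Z_jg; gamma_hat_g', delta2_hat_g')
    S1 = Z.sum(axis=0)          # (D,)
    S2 = (Z ** 2).sum(axis=0)   # (D,)
    quad = (
        S2[:, None]
        - 2.0 * S1[:, None] * g_hat[None, :]
        + n * (g_hat ** 2)[None, :]
    )
    loglik = -0.5 * n * np.log(2.0 * np.pi * d2_hat)[None, :] - quad / (2.0 * d2_hat[None, :])
    np.fill_diagonal(loglik, -np.inf)  # leave-one-out
    m = loglik.max(axis=1, keepdims=True)
    if not np.all(np.isfinite(m)):
        raise FloatingPointError("degenerate non-parametric weights")
    W = np.exp(loglik - m)
    W /= W.sum(axis=1, keepdims=True)
    return W @ g_hat, W @ d2_hat


def fit_transform(
    X: np.ndarray,
    batches: np.ndarray,
    prior_mode: str = "parametric",
    correction_mode: str = "both",
    tol: float = 1e-4,
    max_iter: int = 500,
    reference_batch: str | None = None,
    allow_single_batch: bool = False,
    feature_mask: np.ndarray | None = None,
) -> tuple[CombatModel, np.ndarray]:
    """Fit the EB model on ``X`` (samples x D) and return the corrected matrix.

    ``reference_batch`` anchors standardization on one batch and returns it
    unchanged.  ``allow_single_batch`` enables the documented identity path
    for one-batch input (gamma_hat = 0, delta2_hat = 1 by construction).
    """
    if prior_mode not in PRIOR_MODES:
        raise ValueError(f"prior_mode must be one of {PRIOR_MODES}")
    if correction_mode not in CORRECTION_MODES:
        raise ValueError(f"correction_mode must be one of {CORRECTION_MODES}")
    X = np.asarray(X, dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("X contains NaN")
    levels, groups = _batch_groups(batches)
    if len(levels) < 2 and not allow_single_batch:
        raise ValueError("need >= 2 batches (or allow_single_batch=True)")
    D = X.shape[1]
    log: list[str] = []

    if reference_batch is not None:
        if reference_batch not in levels:
            raise KeyError(f"reference batch {reference_batch!r} not present")
        ref_idx = groups[levels.index(reference_batch)]
        if ref_idx.size < 2:
            raise ValueError("reference batch needs >= 2 samples")
        alpha = X[ref_idx].mean(axis=0)
        sigma2 = X[ref_idx].var(axis=0)  # N denominator
        if np.any(sigma2 <= 0):
            raise ValueError("reference batch has zero-variance features")
        sigma = np.sqrt(sigma2)
        Z = (X - alpha) / sigma
    else:
        Z, alpha, sigma = standardize(X, batches)

    B = len(levels)
    gamma_hat = np.zeros((B, D))
    delta2_hat = np.ones((B, D))
    for bi, (lv, idx) in enumerate(zip(levels, groups)):
        if idx.size < 2:
            raise ValueError(f"batch {lv!r} has fewer than 2 samples")
        gamma_hat[bi] = Z[idx].mean(axis=0)
        if B == 1:
            # identity path: population variance of Z is exactly 1
            delta2_hat[bi] = Z[idx].var(axis=0)
        else:
            delta2_hat[bi] = Z[idx].var(axis=0, ddof=1)

    gamma_star = np.zeros((B, D))
    delta_star2 = np.ones((B, D))
    hyper: dict[str, tuple[float, float, float, float]] = {}
    for bi, (lv, idx) in enumerate(zip(levels, groups)):
        if reference_batch is not None and lv == reference_batch:
            hyper[lv] = (0.0, 0.0, np.inf, np.inf)
            continue  # gamma*=0, delta*^2=1: reference is immutable
        hp = moments_hyperpriors(gamma_hat[bi], delta2_hat[bi])
        hyper[lv] = hp
        if hp[2] == 1.0 and hp[3] == 0.0:
            log.append(f"batch {lv!r}: flat delta prior fallback (S^2 = 0)")
        if prior_mode == "parametric":
            g_st, d2_st, conv = eb_shrink_parametric(
                Z[idx], gamma_hat[bi], delta2_hat[bi], hp, tol=tol, max_iter=max_iter
            )
            if not conv:
                log.append(f"batch {lv!r}: EB fixed point hit max_iter={max_iter}")
        else:
            g_st, d2_st = eb_shrink_nonparametric(Z[idx], gamma_hat[bi], delta2_hat[bi])
        gamma_star[bi] = g_st
        delta_star2[bi] = d2_st

    g_adj = gamma_star.copy()
    d2_adj = delta_star2.copy()
    if correction_mode == "additive_only":
        d2_adj[:] = 1.0
    elif correction_mode == "multiplicative_only":
        g_adj[:] = 0.0

    X_star = np.empty_like(X)
    for bi, idx in enumerate(groups):
        X_star[idx] = sigma * (Z[idx] - g_adj[bi]) / np.sqrt(d2_adj[bi]) + alpha

    model = CombatModel(
        alpha_hat=alpha,
        sigma_hat=sigma,
        gamma_star=gamma_star,
        delta_star2=delta_star2,
        hyper=hyper,
        batch_levels=levels,
        n_per_batch={lv: int(idx.size) for lv, idx in zip(levels, groups)},
        feature_mask=(np.ones(D, dtype=bool) if feature_mask is None
                      else np.asarray(feature_mask, dtype=bool)),
        prior_mode=prior_mode,
        correction_mode=correction_mode,
        reference_batch=reference_batch,
        log=log,
    )
    return model, X_star


def apply_reference(
    model_train: CombatModel,
    X_train_corrected: np.ndarray,
    X_ext: np.ndarray,
    ext_label: str = "external",
) -> np.ndarray:
    """Conform external data to an already-harmonized feature space.

    Runs a two-batch fit on [corrected training data (reference), external
    data] anchored so the reference rows pass through unchanged; only the
    external batch is EB-adjusted.  Returns the corrected external matrix.
    """
    X_ref = np.asarray(X_train_corrected, dtype=np.float64)
    X_ext = np.asarray(X_ext, dtype=np.float64)
    if X_ext.shape[0] < 2:
        raise ValueError("external batch needs >= 2 samples")
    if X_ext.shape[1] != X_ref.shape[1]:
        raise ValueError(
            "external data has a different feature count; align the feature "
            "mask from the training model first"
        )
    ref_label = "__reference__"
    if ext_label == ref_label:
        raise ValueError("reserved label")
    X = np.vstack([X_ref, X_ext])
    batches = np.array([ref_label] * X_ref.shape[0] + [ext_label] * X_ext.shape[0],
                       dtype=object)
    _, X_star = fit_transform(
        X,
        batches,
        prior_mode=model_train.prior_mode,
        correction_mode=model_train.correction_mode,
        reference_batch=ref_label,
    )
    return X_star[X_ref.shape[0]:]


def harmonize_cohort(
    cohort: Cohort,
    prior_mode: str = "parametric",
    correction_mode: str = "both",
    tol: float = 1e-4,
) -> tuple[CombatModel, Cohort]:
    """Dataset-wide fit with site as batch, patches pooled per site.

    Degenerate features are dropped first; the keep-mask is stored on the
    model and the corrected cohort so external data can be aligned.
    """
    keep, masked = drop_degenerate_features(cohort)
    X, site_per_patch, bag_idx = masked.stacked()
    model, X_star = fit_transform(
        X, site_per_patch, prior_mode=prior_mode,
        correction_mode=correction_mode, tol=tol, feature_mask=keep,
    )
    per_bag = [X_star[bag_idx == i] for i in range(masked.n_slides)]
    corrected = masked.with_features(per_bag)
    corrected.provenance["combat"] = {
        "prior_mode": prior_mode,
        "correction_mode": correction_mode,
    }
    return model, corrected


def apply_reference_cohort(
    model_train: CombatModel, corrected_train: Cohort, cohort_ext: Cohort
) -> Cohort:
    """Apply :func:`apply_reference` to every patch of an external cohort."""
    keep = model_train.feature_mask
    ext_masked = cohort_ext.with_features(
        [b.features[:, keep] for b in cohort_ext.bags]
    )
    X_ref, _, _ = corrected_train.stacked()
    X_ext, _, bag_idx = ext_masked.stacked()
    X_star = apply_reference(model_train, X_ref, X_ext)
    per_bag = [X_star[bag_idx == i] for i in range(ext_masked.n_slides)]
    out = ext_masked.with_features(per_bag)
    out.provenance["combat_reference"] = True
    return out
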