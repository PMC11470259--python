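"""Core data containers: per-slide patch-embedding bags and cohorts."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel used for missing categorical attribute values, both in memory and
#: on disk.  Never an empty string, so parsing is unambiguous.
MISSING = "__missing__"


@dataclass
class PatchBag:
    """One slide's patch embeddings plus identifying metadata.

    Parameters
    ----------
    slide_id : str
        Unique slide identifier within a cohort.
    site : str
        Categorical site label (the batch variable).
    features : ndarray of shape (P, D)
        One embedding vector per patch; must be finite.
    coords : ndarray of shape (P, 2), optional
        0-based (row, col) patch-grid positions, unique per slide.
    extractor_tag : str
        Free-text provenance tag for the feature extractor.
    """

    slide_id: str
    site: str
    features: np.ndarray
    coords: np.ndarray | None = None
    extractor_tag: str = "synthetic"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError(
                f"slide {self.slide_id!r}: features must be a non-empty P x D matrix"
            )
        if not np.all(np.isfinite(self.features)):
            raise ValueError(f"slide {self.slide_id!r}: non-finite feature values")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=np.int64)
            if self.coords.shape != (self.features.shape[0], 2):
                raise ValueError(f"slide {self.slide_id!r}: coords must be P x 2")
            uniq = {tuple(rc) for rc in self.coords}
            if len(uniq) != self.coords.shape[0]:
                raise ValueError(f"slide {self.slide_id!r}: duplicate patch coords")

    @property
    def n_patches(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def copy(self) -> "PatchBag":
        return PatchBag(
            slide_id=self.slide_id,
            site=self.site,
            features=self.features.copy(),
            coords=None if self.coords is None else self.coords.copy(),
            extractor_tag=self.extractor_tag,
        )


@dataclass
class Cohort:
    """A set of :class:`PatchBag` plus a slide-indexed categorical attribute table.

    ``attributes`` is indexed by slide_id (one row per bag, bijectively) and
    stores the :data:`MISSING` sentinel for absent values.  ``provenance``
    carries config/seed/version metadata and travels with the cohort on disk.
    """

    bags: list[PatchBag]
    attributes: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [b.slide_id for b in self.bags]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate slide_ids in cohort")
        if set(self.attributes.index) != set(ids):
            raise ValueError("attribute rows and bag slide_ids are not bijective")
        # keep the table aligned with bag order
        self.attributes = self.attributes.loc[ids].fillna(MISSING)

    @property
    def slide_ids(self) -> list[str]:
        return [b.slide_id for b in self.bags]

    @property
    def sites(self) -> np.ndarray:
        """Site label per slide, in bag order."""
        return np.array([b.site for b in self.bags], dtype=object)

    @property
    def n_slides(self) -> int:
        return len(self.bags)

    @property
    def n_features(self) -> int:
        return self.bags[0].n_features if self.bags else 0

    def bag(self, slide_id: str) -> PatchBag:
        for b in self.bags:
            if b.slide_id == slide_id:
                return b
        raise KeyError(slide_id)

    def labels(self, target: str) -> np.ndarray:
        """Per-slide labels for ``target``; ``"site"`` resolves to bag sites."""
        if target == "site":
            return self.sites
        if target not in self.attributes.columns:
            raise KeyError(f"unknown attribute {target!r}")
        return self.attributes[target].to_numpy(dtype=object)

    def stacked(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Pool patches across slides.

        Returns ``(X, patch_site, patch_slide_index)`` where X is the
        (total patches) x D matrix and the two index vectors give, per patch,
        the site label and the position of its bag in ``self.bags``.
        """
        X = np.vstack([b.features for b in self.bags])
        site = np.concatenate(
            [np.repeat(b.site, b.n_patches) for b in self.bags]
        ).astype(object)
        idx = np.concatenate(
            [np.repeat(i, b.n_patches) for i, b in enumerate(self.bags)]
        )
        return X, site, idx

    def with_features(self, per_bag: list[np.ndarray]) -> "Cohort":
        """Clone the cohort with replaced per-bag feature matrices."""
        if len(per_bag) != len(self.bags):
            raise ValueError("need one matrix per bag")
        bags = []
        for b, F in zip(self.bags, per_bag):
            nb = b.copy()
            if F.shape[0] != b.n_patches:
                raise ValueError(f"slide {b.slide_id!r}: patch count changed")
            nb.features = np.asarray(F, dtype=np.float64)
            bags.append(nb)
        return Cohort(bags=bags, attributes=self.attributes.copy(), provenance=dict(self.provenance))

    def copy(self) -> "Cohort":
        return Cohort(
            bags=[b.copy() for b in self.bags],
            attributes=self.attributes.copy(),
            provenance=dict(self.provenance),
        )
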