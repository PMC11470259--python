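"""Per-patch correction-magnitude maps rendered over the patch grid."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bags import Cohort, PatchBag

__all__ = ["CorrectionMap", "patch_distances", "normalize_within_site",
           "build_maps", "render_map"]


@dataclass
class CorrectionMap:
    slide_id: str
    site: str
    distances: np.ndarray               # (P,), >= 0
    normalized: np.ndarray | None       # (P,) in [0, 1] once normalized
    coords: np.ndarray | None           # (P, 2) grid positions

    @property
    def grid_shape(self) -> tuple[int, int]:
        if self.coords is None:
            raise ValueError(f"slide {self.slide_id!r}: no grid coordinates")
        return (int(self.coords[:, 0].max()) + 1, int(self.coords[:, 1].max()) + 1)


def patch_distances(raw_bag: PatchBag, corrected_bag: PatchBag) -> np.ndarray:
    """Euclidean distance between raw and corrected embeddings, per patch."""
    if raw_bag.slide_id != corrected_bag.slide_id:
        raise ValueError("bags refer to different slides")
    if raw_bag.features.shape != corrected_bag.features.shape:
        raise ValueError(
            f"slide {raw_bag.slide_id!r}: shape mismatch "
            f"{raw_bag.features.shape} vs {corrected_bag.features.shape} "
            "(feature masks must match)"
        )
    diff = raw_bag.features - corrected_bag.features
    return np.sqrt((diff * diff).sum(axis=1))


def normalize_within_site(maps: list[CorrectionMap]) -> list[CorrectionMap]:
    """Min-max normalize distances to [0, 1], pooling all patches of a site.

    All slides of a site share the same constants, enabling comparison within
    the site.  A site whose distances are all equal maps to 0 by convention.
    """
    if not maps:
        raise ValueError("empty map list")
    by_site: dict[str, list[CorrectionMap]] = {}
    for m in maps:
        by_site.setdefault(m.site, []).append(m)
    out = []
    for group in by_site.values():
        pooled = np.concatenate([m.distances for m in group])
        lo, hi = pooled.min(), pooled.max()
        for m in group:
            if hi > lo:
                norm = (m.distances - lo) / (hi - lo)
            else:
                norm = np.zeros_like(m.distances)
            out.append(CorrectionMap(m.slide_id, m.site, m.distances.copy(),
                                     norm, None if m.coords is None else m.coords.copy()))
    order = {m.slide_id: i for i, m in enumerate(maps)}
    return sorted(out, key=lambda m: order[m.slide_id])


def build_maps(raw: Cohort, corrected: Cohort, normalize: bool = True) -> list[CorrectionMap]:
    """Distance maps for every slide of a raw/corrected cohort pair.

    The raw cohort is masked to the corrected cohort's retained features
    (recorded in its provenance) before measuring distances.
    """
    if raw.slide_ids != corrected.slide_ids:
        raise ValueError("cohorts must contain the same slides in the same order")
    mask = corrected.provenance.get("feature_mask")
    maps = []
    for rb, cb in zip(raw.bags, corrected.bags):
        rb_use = rb
        if mask is not None and rb.n_features != cb.n_features:
            rb_use = rb.copy()
            rb_use.features = rb.features[:, np.asarray(mask, dtype=bool)]
        maps.append(CorrectionMap(rb.slide_id, rb.site,
                                  patch_distances(rb_use, cb), None,
                                  None if rb.coords is None else rb.coords.copy()))
    return normalize_within_site(maps) if normalize else maps


def render_map(cmap: CorrectionMap, path: str | None = None):
    """Rasterize a map onto its patch grid; cells without patches are NaN.

    Intensity equals the normalized distance (falls back to raw distances if
    normalization has not been applied).  If ``path`` is given a PNG heatmap
    is written there.  Returns the 2-D grid.
    """
    if cmap.coords is None:
        raise ValueError(f"slide {cmap.slide_id!r}: grid coordinates required")
    rows, cols = cmap.grid_shape
    values = cmap.normalized if cmap.normalized is not None else cmap.distances
    grid = np.full((rows, cols), np.nan)
    r, c = cmap.coords[:, 0], cmap.coords[:, 1]
    if r.min() < 0 or c.min() < 0:
        raise ValueError("negative grid coordinates")
    grid[r, c] = values
    if path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(max(2, cols / 4), max(2, rows / 4)))
        im = ax.imshow(grid, cmap="inferno", vmin=0.0,
                       vmax=max(1.0, np.nanmax(grid)), interpolation="nearest")
        ax.set_title(f"{cmap.slide_id} ({cmap.site})", fontsize=8)
        ax.axis("off")
        fig.colorbar(im, ax=ax, fraction=0.04)
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return grid
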