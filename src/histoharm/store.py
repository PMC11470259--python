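"""On-disk cohort store: TSV manifest + HDF5 matrix container.

Layout of a cohort directory::

    manifest.tsv     slide_id, site, patch_count, file, dataset, attributes...
    slides.h5        /slides/<slide_id>/features (+ coords), one group per slide
    provenance.json  config echo, seed, config hash, package version

Round trips are bitwise lossless for feature matrices and preserve attribute
missingness via the explicit sentinel.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .bags import MISSING, Cohort, PatchBag

MANIFEST = "manifest.tsv"
MATRICES = "slides.h5"
PROVENANCE = "provenance.json"
_RESERVED = {"slide_id", "site", "patch_count", "file", "dataset"}


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    bad = _RESERVED & set(cohort.attributes.columns)
    if bad:
        raise ValueError(f"attribute names collide with manifest columns: {sorted(bad)}")

    with h5py.File(path / MATRICES, "w") as h5:
        grp = h5.create_group("slides")
        for bag in cohort.bags:
            g = grp.create_group(bag.slide_id)
            g.create_dataset("features", data=bag.features)
            if bag.coords is not None:
                g.create_dataset("coords", data=bag.coords)
            g.attrs["site"] = bag.site
            g.attrs["extractor_tag"] = bag.extractor_tag

    rows = []
    for bag in cohort.bags:
        row = {
            "slide_id": bag.slide_id,
            "site": bag.site,
            "patch_count": bag.n_patches,
            "file": MATRICES,
            "dataset": f"/slides/{bag.slide_id}",
        }
        for col in cohort.attributes.columns:
            row[col] = cohort.attributes.at[bag.slide_id, col]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path / MANIFEST, sep="\t", index=False)

    prov = dict(cohort.provenance)
    prov.setdefault("version", __version__)
    prov["config_hash"] = config_hash(
        {k: v for k, v in prov.items() if k != "config_hash"}
    )
    (path / PROVENANCE).write_text(json.dumps(prov, indent=2, default=str))
    return path


def read_cohort(path: str | Path) -> Cohort:
    path = Path(path)
    manifest = pd.read_csv(path / MANIFEST, sep="\t", dtype=str,
                           keep_default_na=False)
    attr_cols = [c for c in manifest.columns if c not in _RESERVED]
    bags = []
    with h5py.File(path / MATRICES, "r") as h5:
        for _, row in manifest.iterrows():
            sid = row["slide_id"]
            key = row["dataset"]
            if key not in h5:
                raise ValueError(f"slide {sid!r}: matrix dataset {key!r} missing")
            g = h5[key]
            features = np.asarray(g["features"])
            if features.shape[0] != int(row["patch_count"]):
                raise ValueError(
                    f"slide {sid!r}: manifest patch_count {row['patch_count']} "
                    f"!= stored {features.shape[0]}"
                )
            coords = np.asarray(g["coords"]) if "coords" in g else None
            bags.append(PatchBag(slide_id=sid, site=row["site"],
                                 features=features, coords=coords,
                                 extractor_tag=str(g.attrs.get("extractor_tag", ""))))
    attributes = manifest.set_index("slide_id")[attr_cols].replace("", MISSING)
    attributes.index.name = None
    prov_file = path / PROVENANCE
    provenance = json.loads(prov_file.read_text()) if prov_file.exists() else {}
    return Cohort(bags=bags, attributes=attributes, provenance=provenance)
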