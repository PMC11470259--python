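"""Experiment orchestration: screening, cross-validation, AUROC, statistics.

The audit design: attributes are screened against site with chi-squared
tests (BH FDR, minority-class floor), A-MIL models are trained per fold under
each feature condition with a shared fold assignment, and per-fold one-vs-rest
AUROCs feed one-sided tests against chance and paired tests between
conditions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .amil import AMILConfig, predict_proba, train_amil
from .bags import MISSING, Cohort

__all__ = [
    "AttributeScreenResult", "ExperimentResult",
    "filter_sites_min_n", "screen_attributes", "make_folds", "auroc",
    "run_experiment", "t_tests", "bh_adjust", "bootstrap_ci",
    "summarize_cohort",
]


@dataclass
class AttributeScreenResult:
    attribute: str
    chi2: float
    p: float
    q: float
    minority_count: int
    included: bool


@dataclass
class ExperimentResult:
    target: str
    condition: str
    fold_aurocs: list[float]
    mean_auroc: float
    t_vs_chance: float
    p_vs_chance: float
    fold_hash: str = ""
    paired: dict = field(default_factory=dict)  # other condition -> {"t","p","q"}
    flags: list[str] = field(default_factory=list)


def filter_sites_min_n(cohort: Cohort, min_n: int = 5) -> Cohort:
    """Drop slides from sites with fewer than ``min_n`` slides."""
    sites = cohort.sites
    levels, counts = np.unique(sites, return_counts=True)
    keep_sites = set(levels[counts >= min_n])
    if len(keep_sites) < 2:
        raise ValueError("fewer than 2 sites remain after the minimum-n filter")
    bags = [b for b in cohort.bags if b.site in keep_sites]
    ids = [b.slide_id for b in bags]
    return Cohort(bags=[b.copy() for b in bags],
                  attributes=cohort.attributes.loc[ids].copy(),
                  provenance=dict(cohort.provenance))


def screen_attributes(
    attribute_table: pd.DataFrame,
    site_labels: np.ndarray,
    min_minority: int = 30,
    fdr: float = 0.05,
) -> list[AttributeScreenResult]:
    """Chi-squared screen of each attribute against site.

    Missing values are dropped pairwise; BH is applied across the screened
    family; inclusion requires q < fdr AND a minority class of at least
    ``min_minority`` (the count floor overrides significance).
    """
    site_labels = np.asarray(site_labels, dtype=object)
    rows = []
    for name in attribute_table.columns:
        vals = attribute_table[name].to_numpy(dtype=object)
        ok = vals != MISSING
        tab = pd.crosstab(pd.Series(vals[ok]), pd.Series(site_labels[ok]))
        tab = tab.loc[(tab.sum(axis=1) > 0), (tab.sum(axis=0) > 0)]
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            raise ValueError(f"attribute {name!r}: degenerate contingency table")
        chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy())
        minority = int(tab.sum(axis=1).min())
        rows.append((name, float(chi2), float(p), minority))
    qvals = bh_adjust(np.array([r[2] for r in rows]))
    return [
        AttributeScreenResult(
            attribute=name, chi2=chi2, p=p, q=float(q),
            minority_count=minority,
            included=bool(q < fdr and minority >= min_minority),
        )
        for (name, chi2, p, minority), q in zip(rows, qvals)
    ]


def make_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Stratified fold assignment (0..k-1 per sample), deterministic under seed."""
    labels = np.asarray(labels, dtype=object)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"a class has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assign = np.empty(len(labels), dtype=np.int64)
    y = pd.factorize(pd.Series(labels))[0]
    for f, (_, test) in enumerate(skf.split(np.zeros(len(labels)), y)):
        assign[test] = f
    return assign


def auroc(scores: np.ndarray, labels: np.ndarray, multiclass: str = "none") -> float:
    """Area under the ROC curve with the midrank tie convention.

    Binary: P(random positive outscores random negative), ties credited 1/2,
    computed from midranks.  ``multiclass="ovr_weighted"``: ``scores`` is an
    (n, C) probability matrix and the result is the support-weighted average
    of the one-vs-rest AUROCs.
    """
    labels = np.asarray(labels)
    if multiclass == "ovr_weighted":
        scores = np.asarray(scores, dtype=np.float64)
        levels = np.unique(labels)
        if len(levels) < 2:
            raise ValueError("need >= 2 classes")
        if scores.ndim != 2 or scores.shape[1] < len(levels):
            raise ValueError("scores must be an (n, C) matrix")
        total = 0.0
        for c_i, lv in enumerate(levels):
            pos = labels == lv
            total += pos.mean() * _binary_auroc(scores[:, c_i], pos)
        return float(total)
    if multiclass != "none":
        raise ValueError("multiclass must be 'none' or 'ovr_weighted'")
    scores = np.asarray(scores, dtype=np.float64).ravel()
    pos = np.asarray(labels).astype(bool) if labels.dtype == bool else None
    if pos is None:
        levels = np.unique(labels)
        if len(levels) != 2:
            raise ValueError("binary AUROC needs exactly 2 label values")
        pos = labels == levels[1]
    return _binary_auroc(scores, pos)


def _binary_auroc(scores: np.ndarray, pos: np.ndarray) -> float:
    n_pos = int(pos.sum())
    n_neg = int(len(pos) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: only one class present")
    r = rankdata(scores)  # midranks handle ties
    return float((r[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def t_tests(
    fold_aurocs_a: np.ndarray,
    fold_aurocs_b: np.ndarray | None = None,
    null_value: float = 0.5,
) -> tuple[float, float, str | None]:
    """One-sample (vs chance, alternative greater) or paired two-sided t-test.

    Returns (t, p, flag); zero-variance inputs are handled deterministically
    (t = +/-inf or 0) and flagged instead of propagating NaNs.
    """
    a = np.asarray(fold_aurocs_a, dtype=np.float64)
    if a.size < 2:
        raise ValueError("need >= 2 folds")
    if fold_aurocs_b is None:
        if np.allclose(a.std(ddof=1), 0.0):
            m = a.mean()
            if np.isclose(m, null_value):
                return 0.0, 1.0, "zero-variance"
            return (math_inf_sign(m - null_value), 0.0 if m > null_value else 1.0,
                    "zero-variance")
        t, p = stats.ttest_1samp(a, null_value, alternative="greater")
        return float(t), float(p), None
    b = np.asarray(fold_aurocs_b, dtype=np.float64)
    if b.shape != a.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0, "zero-variance"
        return math_inf_sign(d.mean()), 0.0, "zero-variance"
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), None


def math_inf_sign(x: float) -> float:
    return float(np.inf if x > 0 else -np.inf)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D array")
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1] and contain no NaN")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bootstrap_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 10,
    seed: int = 0,
    multiclass: str = "none",
) -> tuple[float, float, float]:
    """Percentile bootstrap CI (2.5/97.5) for AUROC over resampled slides.

    Single-class replicates are redrawn (up to a cap) rather than scored.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if len(np.unique(labels)) < 2:
        raise ValueError("cannot bootstrap a single-class sample")
    rng = np.random.default_rng(seed)
    point = auroc(scores, labels, multiclass=multiclass)
    reps = []
    attempts = 0
    while len(reps) < n_boot:
        if attempts > 1000 * n_boot:
            raise ValueError("could not draw two-class bootstrap replicates")
        attempts += 1
        idx = rng.integers(0, len(labels), size=len(labels))
        if len(np.unique(labels[idx])) < 2:
            continue
        reps.append(auroc(scores[idx], labels[idx], multiclass=multiclass))
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return point, float(lo), float(hi)


def _fold_hash(assign: np.ndarray) -> str:
    return hashlib.sha256(np.asarray(assign, dtype=np.int64).tobytes()).hexdigest()[:16]


def _amil_cfg(base: dict, input_dim: int, n_classes: int, seed: int) -> AMILConfig:
    kw = dict(base)
    kw.update(input_dim=input_dim, n_classes=n_classes, seed=seed)
    if "max_epochs" in kw and "patience" not in kw:
        kw["patience"] = min(16, kw["max_epochs"])
    return AMILConfig(**kw)


def run_experiment(
    cohorts: dict[str, Cohort],
    target: str,
    k: int = 5,
    seed: int = 0,
    amil_kwargs: dict | None = None,
) -> dict[str, ExperimentResult]:
    """Paired cross-validated audit of one target across feature conditions.

    ``cohorts`` maps condition name (e.g. ``raw``/``combat``) to a cohort with
    identical slides in identical order; one stratified fold assignment is
    shared by every condition so fold AUROCs are paired.  Slides with a
    missing target label are excluded consistently.  The held-out fold doubles
    as the early-stopping validation set (matching the source design; see
    package docs for the leakage caveat).
    """
    amil_kwargs = amil_kwargs or {}
    names = list(cohorts)
    if len(names) < 1:
        raise ValueError("need at least one condition")
    base = cohorts[names[0]]
    ids = base.slide_ids
    for nm in names[1:]:
        if cohorts[nm].slide_ids != ids:
            raise ValueError(f"condition {nm!r}: slide set/order mismatch")

    labels_all = base.labels(target)
    usable = np.flatnonzero(np.array([v != MISSING for v in labels_all]))
    labels = labels_all[usable]
    assign = make_folds(labels, k, seed)
    fh = _fold_hash(assign)
    n_classes = len(np.unique(labels))

    results: dict[str, ExperimentResult] = {}
    for nm in names:
        cohort = cohorts[nm]
        fold_scores = []
        flags: list[str] = []
        for f in range(k):
            test_loc = usable[assign == f]
            train_loc = usable[assign != f]
            cfg = _amil_cfg(amil_kwargs, cohort.n_features, n_classes,
                            seed=seed * 1000 + f)
            model = train_amil(cohort, target, train_loc, test_loc, cfg)
            sub = Cohort(
                bags=[cohort.bags[i] for i in test_loc],
                attributes=cohort.attributes.iloc[test_loc].copy(),
                provenance={},
            )
            probs = predict_proba(model, sub)
            y_test = labels_all[test_loc]
            if len(np.unique(y_test)) < 2:
                flags.append(f"fold {f}: single-class evaluation set")
                continue
            if n_classes == 2:
                pos_class = model.classes[1]
                fold_scores.append(auroc(probs[:, 1], np.array(y_test) == pos_class))
            else:
                fold_scores.append(auroc(probs, y_test, multiclass="ovr_weighted"))
        t, p, flag = t_tests(np.array(fold_scores))
        if flag:
            flags.append(f"t vs chance: {flag}")
        results[nm] = ExperimentResult(
            target=target, condition=nm, fold_aurocs=fold_scores,
            mean_auroc=float(np.mean(fold_scores)), t_vs_chance=t,
            p_vs_chance=p, fold_hash=fh, flags=flags,
        )

    # paired comparisons of every later condition against the first
    ref = results[names[0]]
    ps = []
    for nm in names[1:]:
        t, p, flag = t_tests(np.array(results[nm].fold_aurocs),
                             np.array(ref.fold_aurocs))
        results[nm].paired[names[0]] = {"t": t, "p": p}
        if flag:
            results[nm].flags.append(f"paired vs {names[0]}: {flag}")
        ps.append(p)
    if ps:
        qs = bh_adjust(np.array(ps))
        for nm, q in zip(names[1:], qs):
            results[nm].paired[names[0]]["q"] = float(q)
    return results


def summarize_cohort(attribute_table: pd.DataFrame) -> pd.DataFrame:
    """Per-attribute missingness and class counts/percentages.

    Returns one row per (attribute, class) plus a missing row per attribute,
    with percentages under both denominators: ``pct_total`` (all slides) and
    ``pct_nonmissing`` (slides with a value; the display default).  Rounded
    display columns accompany the unrounded values.
    """
    if attribute_table.empty or attribute_table.shape[1] == 0:
        raise ValueError("empty attribute table")
    n_total = len(attribute_table)
    rows = []
    for name in attribute_table.columns:
        vals = attribute_table[name].to_numpy(dtype=object)
        miss = int(np.sum(vals == MISSING))
        pct_missing = miss / n_total * 100.0
        rows.append({
            "attribute": name, "class": "(missing)", "count": miss,
            "pct_total": pct_missing, "pct_nonmissing": np.nan,
            "display_pct": round(pct_missing, 2),
        })
        present = vals[vals != MISSING]
        n_present = len(present)
        classes, counts = np.unique(present.astype(str), return_counts=True)
        for cls, cnt in zip(classes, counts):
            pct_nm = cnt / n_present * 100.0 if n_present else np.nan
            rows.append({
                "attribute": name, "class": cls, "count": int(cnt),
                "pct_total": cnt / n_total * 100.0,
                "pct_nonmissing": pct_nm,
                "display_pct": round(pct_nm, 2) if n_present else np.nan,
            })
    return pd.DataFrame(rows)
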