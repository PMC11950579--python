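"""Inter-rater reliability statistics for ordinal Pfirrmann grades.

Cohen's kappa (two raters), Fleiss' kappa (three or more raters), and
agreement-discrepancy histograms, operating on a long-format ratings table
(patient_id, level, grade, rater).  Kappas are unweighted by default; a
linearly weighted Cohen's kappa is available because Pfirrmann grades are
ordinal and adjacent-grade confusions are clinically milder.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RatingTable",
    "KappaResult",
    "cohens_kappa",
    "fleiss_kappa",
    "agreement_histogram",
    "reliability_report",
]

GRADES = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class KappaResult:
    value: float
    n_items: int
    degenerate: bool = False

    def __float__(self):
        return float(self.value)


@dataclass
class RatingTable:
    """(patient, level) x rater grid of grades 1–5; missing entries are NaN."""

    grid: pd.DataFrame  # index: MultiIndex (patient_id, level); columns: raters

    @classmethod
    def from_records(cls, df: pd.DataFrame) -> "RatingTable":
        required = {"patient_id", "level", "grade", "rater"}
        if not required <= set(df.columns):
            raise ValueError(f"ratings table needs columns {sorted(required)}")
        vals = df["grade"].dropna()
        if not vals.isin(GRADES).all():
            raise ValueError("grades must be integers in 1..5")
        grid = df.pivot_table(
            index=["patient_id", "level"], columns="rater", values="grade", aggfunc="first"
        )
        return cls(grid)

    @property
    def raters(self) -> list[str]:
        return list(self.grid.columns)

    def pair(self, rater_a: str, rater_b: str) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
        """Pairwise-complete ratings for two raters plus the kept index rows."""
        sub = self.grid[[rater_a, rater_b]].dropna()
        return sub[rater_a].to_numpy(int), sub[rater_b].to_numpy(int), sub


def cohens_kappa(a, b, weighted: bool = False) -> KappaResult:
    """Chance-corrected agreement between two raters.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement p_o and chance
    agreement p_e from the raters' marginal category frequencies.  With
    ``weighted=True`` a linear-weight version is computed instead, crediting
    near-misses proportionally to 1 - |i-j|/(k-1).
    """
    a = np.asarray(a, int)
    b = np.asarray(b, int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be equal-length 1D vectors")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 doubly-rated items")
    cats = np.union1d(a, b)
    k = cats.size
    idx = {c: i for i, c in enumerate(cats)}
    conf = np.zeros((k, k))
    for x, y in zip(a, b):
        conf[idx[x], idx[y]] += 1
    conf /= n
    pa = conf.sum(axis=1)
    pb = conf.sum(axis=0)
    if weighted:
        ij = np.arange(k)
        w = 1.0 - np.abs(ij[:, None] - ij[None, :]) / max(k - 1, 1)
    else:
        w = np.eye(k)
    p_o = float((w * conf).sum())
    p_e = float((w * np.outer(pa, pb)).sum())
    if abs(1.0 - p_e) < 1e-12:
        # both raters constant and identical: agreement is perfect but the
        # chance correction is undefined
        return KappaResult(1.0, n, degenerate=True)
    return KappaResult((p_o - p_e) / (1.0 - p_e), n)


def fleiss_kappa(ratings: np.ndarray, categories=GRADES) -> KappaResult:
    """Fleiss' kappa over an items x raters grid of category labels.

    Items with any missing rating are dropped (complete-case) with a
    warning; every retained item must have the same number of raters,
    which the grid shape guarantees.
    """
    arr = np.asarray(ratings, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("ratings must be items x raters with >= 2 raters")
    complete = ~np.isnan(arr).any(axis=1)
    if not complete.all():
        warnings.warn(
            f"dropping {int((~complete).sum())} items with missing ratings", stacklevel=2
        )
    arr = arr[complete].astype(int)
    n_items, n_raters = arr.shape
    if n_items < 2:
        raise ValueError("need at least 2 complete items")
    cats = np.asarray(categories)
    counts = np.stack([(arr == c).sum(axis=1) for c in cats], axis=1)  # items x cats
    p_cat = counts.sum(axis=0) / (n_items * n_raters)
    p_i = ((counts * (counts - 1)).sum(axis=1)) / (n_raters * (n_raters - 1))
    p_bar = float(p_i.mean())
    p_e = float((p_cat ** 2).sum())
    if abs(1.0 - p_e) < 1e-12:
        return KappaResult(1.0, n_items, degenerate=True)
    return KappaResult((p_bar - p_e) / (1.0 - p_e), n_items)


def agreement_histogram(a, b, levels=None) -> pd.DataFrame:
    """Counts of |grade difference| in {0, 1, >=2} for paired ratings.

    If ``levels`` (one label per item) is given, counts are also broken
    out per disc level; a pooled row is always included.
    """
    a = np.asarray(a, int)
    b = np.asarray(b, int)
    if a.shape != b.shape:
        raise ValueError("paired ratings must align")
    diff = np.abs(a - b)

    def row(d):
        return {"exact": int((d == 0).sum()), "single": int((d == 1).sum()),
                "two_plus": int((d >= 2).sum()), "n": int(d.size)}

    rows = {"all": row(diff)}
    if levels is not None:
        levels = np.asarray(levels)
        for lvl in pd.unique(levels):
            rows[str(lvl)] = row(diff[levels == lvl])
    return pd.DataFrame(rows).T


def reliability_report(table: RatingTable, rater_a: str, rater_b: str) -> dict:
    """Per-level and mean Cohen's kappa plus agreement histogram for a pair."""
    a, b, sub = table.pair(rater_a, rater_b)
    levels = sub.index.get_level_values("level").to_numpy()
    per_level = {}
    for lvl in pd.unique(levels):
        m = levels == lvl
        if m.sum() >= 2:
            per_level[str(lvl)] = cohens_kappa(a[m], b[m]).value
    report = {
        "per_level_kappa": per_level,
        "mean_kappa": float(np.mean(list(per_level.values()))) if per_level else np.nan,
        "overall_kappa": cohens_kappa(a, b).value,
        "histogram": agreement_histogram(a, b, levels).to_dict(),
    }
    if len(table.raters) >= 3:
        report["fleiss_kappa"] = fleiss_kappa(table.grid.to_numpy()).value
    return report
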