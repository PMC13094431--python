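"""Two-tier selection of adipose-enriched features.

Tier 1 contrasts adipose pixels against the merged non-adipose pixels with
a Welch t-test per feature within each replicate, adjusts per replicate by
Benjamini-Hochberg, and keeps features significant (q < 0.05) *and* higher
in adipose in at least one replicate — enrichment is one-directional.
Tier 2 computes the rank-based ROC AUC (adipose as positive class) per
replicate and requires AUC > 0.7 in at least half of the replicates
(ceil(n/2)).  A feature is adipose-enriched iff it passes both tiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.stats as sps

from .stats import bh_adjust

__all__ = [
    "EnrichmentResult",
    "roc_auc",
    "roc_auc_rows",
    "tier1_filter",
    "tier2_roc",
    "run_enrichment",
    "summarize_enrichment",
    "fold_change_from_printed",
]


def roc_auc(adipose, nonadipose) -> float:
    """Rank-based AUC: P(random adipose pixel outranks random non-adipose).

    Equals (pairs won + 0.5 x ties) / (n1 x n2); ties contribute half a win.
    """
    a = np.asarray(adipose, dtype=float)
    b = np.asarray(nonadipose, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = sps.rankdata(np.concatenate([a, b]))
    r1 = ranks[:a.size].sum()
    return float((r1 - a.size * (a.size + 1) / 2) / (a.size * b.size))


def roc_auc_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise AUC for feature matrices (features x pixels)."""
    n1, n2 = A.shape[1], B.shape[1]
    ranks = sps.rankdata(np.concatenate([A, B], axis=1), axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    return (r1 - n1 * (n1 + 1) / 2) / (n1 * n2)


def tier1_filter(
    matrices: list[np.ndarray],
    adipose_idx: list[np.ndarray],
    nonadipose_idx: list[np.ndarray],
    alpha: float = 0.05,
) -> dict:
    """Per-replicate Welch tests with BH adjustment and the direction rule.

    ``matrices`` holds one (features x pixels) matrix per replicate with
    aligned feature rows.  Returns per-replicate ``p`` and ``q`` arrays
    (features x replicates), the per-replicate enrichment direction, and the
    tier-1 candidate flag: q < alpha AND adipose mean > non-adipose mean in
    at least one replicate.
    """
    n_rep = len(matrices)
    n_feat = matrices[0].shape[0]
    p = np.ones((n_feat, n_rep))
    q = np.ones((n_feat, n_rep))
    up = np.zeros((n_feat, n_rep), dtype=bool)
    for r in range(n_rep):
        A = matrices[r][:, adipose_idx[r]]
        B = matrices[r][:, nonadipose_idx[r]]
        if A.shape[1] < 2 or B.shape[1] < 2:
            raise ValueError("degenerate partition: need >= 2 pixels per side")
        res = sps.ttest_ind(A, B, axis=1, equal_var=False)
        pr = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
        p[:, r] = pr
        q[:, r] = bh_adjust(pr)
        up[:, r] = A.mean(axis=1) > B.mean(axis=1)
    candidate = np.any((q < alpha) & up, axis=1)
    return {"p": p, "q": q, "direction_up": up, "candidate": candidate}


@dataclass
class EnrichmentResult:
    """Per-feature outcome of the two-tier adipose-enrichment screen."""

    mz: float
    polarity: str
    p: tuple
    q: tuple
    auc: tuple
    pass_tier1: bool
    pass_tier2: bool
    avg_intensity_adipose: float
    avg_intensity_nonadipose: float
    avg_auc: float

    @property
    def avg_fold_change(self) -> float:
        return self.avg_intensity_adipose / self.avg_intensity_nonadipose

    @property
    def enriched(self) -> bool:
        return self.pass_tier1 and self.pass_tier2


def tier2_roc(
    matrices: list[np.ndarray],
    adipose_idx: list[np.ndarray],
    nonadipose_idx: list[np.ndarray],
    tier1: dict,
    mz: np.ndarray,
    polarity: str,
    auc_threshold: float = 0.7,
    replicate_fraction: float = 0.5,
) -> list[EnrichmentResult]:
    """Per-replicate ROC AUC and the replicate-consistency rule.

    A feature passes tier 2 iff AUC > ``auc_threshold`` in at least
    ``ceil(replicate_fraction x n_replicates)`` replicates.  Summary
    intensities average the per-replicate group means.
    """
    n_rep = len(matrices)
    need = math.ceil(replicate_fraction * n_rep)
    aucs = np.stack([
        roc_auc_rows(matrices[r][:, adipose_idx[r]],
                     matrices[r][:, nonadipose_idx[r]])
        for r in range(n_rep)
    ], axis=1)  # features x replicates
    adipose_means = np.stack([
        matrices[r][:, adipose_idx[r]].mean(axis=1) for r in range(n_rep)
    ], axis=1)
    non_means = np.stack([
        matrices[r][:, nonadipose_idx[r]].mean(axis=1) for r in range(n_rep)
    ], axis=1)
    results = []
    for i in range(len(mz)):
        n_pass = int(np.sum(aucs[i] > auc_threshold))
        results.append(EnrichmentResult(
            mz=float(mz[i]),
            polarity=polarity,
            p=tuple(tier1["p"][i]),
            q=tuple(tier1["q"][i]),
            auc=tuple(aucs[i]),
            pass_tier1=bool(tier1["candidate"][i]),
            pass_tier2=n_pass >= need,
            avg_intensity_adipose=float(adipose_means[i].mean()),
            avg_intensity_nonadipose=float(non_means[i].mean()),
            avg_auc=float(aucs[i].mean()),
        ))
    return results


def run_enrichment(
    matrices: list[np.ndarray],
    adipose_idx: list[np.ndarray],
    nonadipose_idx: list[np.ndarray],
    mz: np.ndarray,
    polarity: str = "negative",
    alpha: float = 0.05,
    auc_threshold: float = 0.7,
    replicate_fraction: float = 0.5,
) -> list[EnrichmentResult]:
    """Tier 1 then tier 2 over aligned per-replicate feature matrices."""
    t1 = tier1_filter(matrices, adipose_idx, nonadipose_idx, alpha=alpha)
    return tier2_roc(matrices, adipose_idx, nonadipose_idx, t1, mz, polarity,
                     auc_threshold=auc_threshold,
                     replicate_fraction=replicate_fraction)


def summarize_enrichment(results: list[EnrichmentResult]):
    """Summary table of the enriched features, in reporting precision.

    Fold change and average AUC are rounded to two decimals, as printed in
    curated summaries.
    """
    import pandas as pd

    rows = []
    for r in results:
        if not r.enriched:
            continue
        rows.append({
            "avg_mz": round(r.mz, 4),
            "polarity": r.polarity,
            "avg_intensity_adipose": r.avg_intensity_adipose,
            "avg_intensity_nonadipose": r.avg_intensity_nonadipose,
            "avg_fold_change": round(r.avg_fold_change, 2),
            "avg_roc": round(r.avg_auc, 2),
            "n_replicates_auc_pass": int(np.sum(np.array(r.auc) > 0.7)),
        })
    return pd.DataFrame(rows)


def fold_change_from_printed(avg_adipose: float, avg_nonadipose: float) -> float:
    """Fold change recomputed from printed-precision average intensities."""
    if avg_nonadipose <= 0:
        raise ValueError("non-adipose average must be positive")
    return round(avg_adipose / avg_nonadipose, 2)
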