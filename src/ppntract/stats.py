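"""Paired nonparametric NOS statistics.

The streamline counts (NOS) of the six reconstructed bundles are compared
with two-sided Wilcoxon signed-rank tests: GPi vs GPe within hemisphere,
ipsilateral vs contralateral within hemisphere, and left vs right per bundle
family — seven paired comparisons, uncorrected at alpha = 0.05 (a Holm
adjustment is available but off by default, matching the uncorrected design).

The signed-rank test drops zero differences, midranks ties, and computes the
two-sided p either exactly (full enumeration of the 2^n sign assignments, for
n_effective <= 12) or by a normal approximation with tie-corrected variance
and a 0.5 continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .selection import BUNDLE_NAMES

__all__ = [
    "PairedTestResult",
    "wilcoxon_signed_rank",
    "summarize_nos",
    "run_nos_comparisons",
    "PAIRED_COMPARISONS",
    "holm_adjust",
]

EXACT_MAX_N = 12

#: the seven paired NOS comparisons, as (label, bundle_x, bundle_y)
PAIRED_COMPARISONS = (
    ("L_GPi_ipsi_vs_L_GPe_ipsi", "L_GPi_ipsi", "L_GPe_ipsi"),
    ("R_GPi_ipsi_vs_R_GPe_ipsi", "R_GPi_ipsi", "R_GPe_ipsi"),
    ("L_GPi_ipsi_vs_L_GPi_contra", "L_GPi_ipsi", "L_GPi_contra"),
    ("R_GPi_ipsi_vs_R_GPi_contra", "R_GPi_ipsi", "R_GPi_contra"),
    ("L_vs_R_GPi_ipsi", "L_GPi_ipsi", "R_GPi_ipsi"),
    ("L_vs_R_GPe_ipsi", "L_GPe_ipsi", "R_GPe_ipsi"),
    ("L_vs_R_GPi_contra", "L_GPi_contra", "R_GPi_contra"),
)


@dataclass
class PairedTestResult:
    name: str
    n_total: int
    n_effective: int
    statistic: float  # W = sum of ranks of positive differences
    p_two_sided: float
    method: str  # "exact" | "normal-approximation"
    significant: bool | None = None

    def flag(self, alpha: float) -> "PairedTestResult":
        self.significant = bool(self.p_two_sided < alpha)
        return self


def _exact_two_sided_p(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided p by enumerating all 2^n assignments of signs to the ranks.

    One-sided p is the smaller tail of the exact W distribution at w_obs;
    two-sided p = min(1, 2 x one-sided).
    """
    n = len(ranks)
    signs = np.array(np.meshgrid(*([[0.0, 1.0]] * n), indexing="ij"))
    w_all = np.tensordot(ranks, signs, axes=(0, 0)).ravel()
    eps = 1e-9
    p_ge = np.mean(w_all >= w_obs - eps)
    p_le = np.mean(w_all <= w_obs + eps)
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def wilcoxon_signed_rank(x, y, name: str = "") -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; absolute differences are midranked. W is
    the sum of ranks of positive differences.  Exact enumeration is used for
    n_effective <= 12, otherwise a normal approximation with tie-corrected
    variance and continuity correction.  Raises when every difference is zero
    (the test is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D samples of length >= 2")
    d = x - y
    n_total = len(d)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero; the signed-rank test is undefined")
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= EXACT_MAX_N:
        p = _exact_two_sided_p(ranks, w)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= np.sum(tie_counts**3 - tie_counts) / 48.0
        dev = w - mean
        cc = 0.5 * np.sign(dev)
        z = (dev - cc) / np.sqrt(var)
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
        method = "normal-approximation"
    return PairedTestResult(
        name=name, n_total=n_total, n_effective=n, statistic=w,
        p_two_sided=p, method=method,
    )


def summarize_nos(table: pd.DataFrame, bundles=BUNDLE_NAMES) -> pd.DataFrame:
    """Per-bundle mean and standard error (sample sd / sqrt(n)) of NOS.

    ``table`` needs columns subject_id, bundle, nos with one row per subject
    x bundle.
    """
    for col in ("subject_id", "bundle", "nos"):
        if col not in table.columns:
            raise ValueError(f"NOS table is missing column {col!r}")
    rows = []
    for b in bundles:
        sub = table.loc[table["bundle"] == b, "nos"]
        if len(sub) < 2:
            raise ValueError(f"bundle {b!r} needs at least 2 subjects, found {len(sub)}")
        rows.append(
            {
                "bundle": b,
                "n": len(sub),
                "mean": float(sub.mean()),
                "sem": float(sub.std(ddof=1) / np.sqrt(len(sub))),
            }
        )
    return pd.DataFrame(rows)


def _pivot(table: pd.DataFrame) -> pd.DataFrame:
    wide = table.pivot(index="subject_id", columns="bundle", values="nos")
    missing = [b for b in BUNDLE_NAMES if b not in wide.columns or wide[b].isna().any()]
    if missing:
        raise ValueError(f"NOS table is missing bundles or subjects for: {missing}")
    return wide.sort_index()


def run_nos_comparisons(table: pd.DataFrame, alpha: float = 0.05) -> list[PairedTestResult]:
    """The seven paired NOS comparisons, each flagged at ``alpha``."""
    wide = _pivot(table)
    results = []
    for label, bx, by in PAIRED_COMPARISONS:
        res = wilcoxon_signed_rank(wide[bx].to_numpy(), wide[by].to_numpy(), name=label)
        results.append(res.flag(alpha))
    return results


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default upstream)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj
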