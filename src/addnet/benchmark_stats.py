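"""Group comparison of degeneration vs. control runs: permutation tests,
Benjamini-Hochberg FDR, per-ROI profiles, significance time courses, ROC.

Input to the high-level routines is a tidy long-format table (one row per
run, condition, timestep, measure and band) produced by the measurement
pipeline; see :func:`collect_group_samples`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

__all__ = [
    "permutation_test",
    "fdr_bh",
    "ROCResult",
    "roc_analysis",
    "collect_group_samples",
    "timecourse_benchmark",
    "roi_profile_comparison",
    "roc_benchmark",
]

#: permutation count above which exact enumeration is abandoned
EXACT_ENUMERATION_LIMIT = 20_000

_TIE_TOL = 1e-12


def permutation_test(
    a, b, n_perm: int = 5000, seed: int | None = None
) -> float:
    """Two-sided permutation p-value for the difference of group means.

    All label reassignments are enumerated exactly when their number is at
    most 20,000; otherwise ``n_perm`` Monte-Carlo draws are used with the
    add-one correction ``p = (1 + #{|d_perm| >= |d_obs|}) / (1 + n_perm)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    na, n = len(a), len(pooled)
    # difference of means is monotone in sum(a) for fixed group sizes
    obs = abs(a.mean() - b.mean())
    total = pooled.sum()

    def diff_from_sum(sa: float) -> float:
        return sa / na - (total - sa) / (n - na)

    if comb(n, na) <= EXACT_ENUMERATION_LIMIT:
        count = 0
        n_all = 0
        for idx in combinations(range(n), na):
            sa = pooled[list(idx)].sum()
            if abs(diff_from_sum(sa)) >= obs - _TIE_TOL:
                count += 1
            n_all += 1
        return count / n_all
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        sa = pooled[perm[:na]].sum()
        if abs(diff_from_sum(sa)) >= obs - _TIE_TOL:
            count += 1
    return (1 + count) / (1 + n_perm)


def fdr_bh(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection mask at level q)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj
    return adjusted, adjusted <= q


@dataclass(frozen=True)
class ROCResult:
    """ROC summary at the maximum-accuracy operating point."""

    auc: float
    optimal_cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    orientation: str  # "ADD-high" if the positive class scores higher, else "ADD-low"


def roc_analysis(scores_pos, scores_neg, orientation: str = "auto") -> ROCResult:
    """ROC of positive-class vs. negative-class scores.

    With ``orientation='auto'`` the scale is oriented so the positive class
    has the higher group mean (recorded in the result); ``'high'``/``'low'``
    force an orientation.  AUC equals the normalized Mann-Whitney statistic
    (trapezoid over all thresholds, ties counted half).  The operating point
    maximizes accuracy; ties prefer higher sensitivity, then the lower
    threshold.  A score is called positive when it is >= the cutoff (in
    oriented scale).
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both groups must be non-empty")
    if orientation == "auto":
        flip = pos.mean() < neg.mean()
    elif orientation in ("high", "low"):
        flip = orientation == "low"
    else:
        raise ValueError("orientation must be 'auto', 'high' or 'low'")
    orientation = "ADD-low" if flip else "ADD-high"
    sgn = -1.0 if flip else 1.0
    p, g = sgn * pos, sgn * neg
    # AUC: P(pos > neg) + 0.5 P(tie)
    gt = (p[:, None] > g[None, :]).sum()
    eq = (p[:, None] == g[None, :]).sum()
    auc = (gt + 0.5 * eq) / (len(p) * len(g))
    best = None
    for cut in np.unique(np.concatenate([p, g])):
        sens = float((p >= cut).mean())
        spec = float((g < cut).mean())
        acc = ((p >= cut).sum() + (g < cut).sum()) / (len(p) + len(g))
        key = (acc, sens, -cut)
        if best is None or key > best[0]:
            best = (key, cut, sens, spec, acc)
    _, cut, sens, spec, acc = best
    return ROCResult(
        auc=float(auc),
        optimal_cutoff=float(sgn * cut),
        sensitivity=sens,
        specificity=spec,
        accuracy=float(acc),
        orientation=orientation,
    )


def collect_group_samples(rows) -> pd.DataFrame:
    """Assemble per-run samples into the long-format benchmark table.

    Each element of ``rows`` is a mapping with keys ``condition`` ("ADD" or
    "Con"), ``run_id``, ``timestep``, ``measure``, ``band``, ``whole_brain``
    and optionally ``roi_values`` (length-N array).
    """
    df = pd.DataFrame(list(rows))
    required = {"condition", "run_id", "timestep", "measure", "band", "whole_brain"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    bad = set(df["condition"].unique()) - {"ADD", "Con"}
    if bad:
        raise ValueError(f"unknown conditions: {sorted(bad)}")
    overlap = set(df.loc[df.condition == "ADD", "run_id"]) & set(
        df.loc[df.condition == "Con", "run_id"]
    )
    if overlap:
        raise ValueError(f"run ids shared between conditions: {sorted(overlap)}")
    return df


def _group_values(df: pd.DataFrame, measure: str, band: str, timestep: int):
    sel = df[(df.measure == measure) & (df.band == band) & (df.timestep == timestep)]
    a = sel.loc[sel.condition == "ADD"].sort_values("run_id")["whole_brain"].to_numpy()
    b = sel.loc[sel.condition == "Con"].sort_values("run_id")["whole_brain"].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError(
            f"missing samples for measure={measure} band={band} timestep={timestep}"
        )
    return a, b


def timecourse_benchmark(
    df: pd.DataFrame,
    measures=None,
    bands=None,
    timesteps=None,
    n_perm: int = 5000,
    q: float = 0.05,
    seed: int | None = None,
    fdr_family: str = "timesteps",
) -> pd.DataFrame:
    """Significance curves: permutation p per (measure, band, timestep) with FDR.

    BH correction is applied across timesteps within each (measure, band)
    family by default (``fdr_family='timesteps'``); ``'all'`` corrects across
    every row jointly, ``'none'`` skips correction.
    """
    if fdr_family not in ("timesteps", "all", "none"):
        raise ValueError("fdr_family must be 'timesteps', 'all' or 'none'")
    timesteps = (
        list(timesteps) if timesteps is not None else sorted(df.timestep.unique())
    )
    combos = sorted(
        {
            (m, b)
            for m, b in df.groupby(["measure", "band"]).groups
            if (measures is None or m in measures) and (bands is None or b in bands)
        }
    )
    rng = np.random.default_rng(seed)
    rows = []
    for measure, band in combos:
        for t in timesteps:
            a, b = _group_values(df, measure, band, t)
            p = permutation_test(a, b, n_perm=n_perm, seed=int(rng.integers(2**31)))
            rows.append(
                {
                    "measure": measure,
                    "band": band,
                    "timestep": t,
                    "mean_ADD": a.mean(),
                    "mean_Con": b.mean(),
                    "p_raw": p,
                }
            )
    out = pd.DataFrame(rows)
    if fdr_family == "none":
        out["p_fdr"] = out["p_raw"]
    elif fdr_family == "all":
        out["p_fdr"], _ = fdr_bh(out["p_raw"].to_numpy(), q)
    else:
        out["p_fdr"] = np.nan
        for (_, _), idx in out.groupby(["measure", "band"]).groups.items():
            adj, _ = fdr_bh(out.loc[idx, "p_raw"].to_numpy(), q)
            out.loc[idx, "p_fdr"] = adj
    out["significant"] = out["p_fdr"] <= q
    return out


def roi_profile_comparison(
    df: pd.DataFrame,
    measure: str,
    band: str,
    timestep: int,
    n_perm: int = 5000,
    q: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-ROI group means, SEMs, permutation p-values and BH-FDR across ROIs.

    Requires ``roi_values`` arrays in the table; ROI indices are 1-based in
    the output.
    """
    sel = df[(df.measure == measure) & (df.band == band) & (df.timestep == timestep)]
    if "roi_values" not in sel.columns or sel["roi_values"].isna().any():
        raise ValueError("table lacks per-ROI values")
    a = np.vstack(sel.loc[sel.condition == "ADD"].sort_values("run_id")["roi_values"])
    b = np.vstack(sel.loc[sel.condition == "Con"].sort_values("run_id")["roi_values"])
    if a.shape[1] != b.shape[1]:
        raise ValueError("ROI count differs between conditions")
    rng = np.random.default_rng(seed)
    n_roi = a.shape[1]
    pvals = np.empty(n_roi)
    for r in range(n_roi):
        pvals[r] = permutation_test(
            a[:, r], b[:, r], n_perm=n_perm, seed=int(rng.integers(2**31))
        )
    adj, reject = fdr_bh(pvals, q)
    return pd.DataFrame(
        {
            "roi": np.arange(1, n_roi + 1),
            "mean_ADD": a.mean(axis=0),
            "sem_ADD": a.std(axis=0, ddof=1) / np.sqrt(a.shape[0]),
            "mean_Con": b.mean(axis=0),
            "sem_Con": b.std(axis=0, ddof=1) / np.sqrt(b.shape[0]),
            "p_raw": pvals,
            "p_fdr": adj,
            "significant": reject,
            "direction": np.where(a.mean(axis=0) >= b.mean(axis=0), "ADD>Con", "ADD<Con"),
        }
    )


def roc_benchmark(
    df: pd.DataFrame, measure: str, band: str, timestep: int
) -> ROCResult:
    """ROC of per-run whole-brain means, ADD as the positive class."""
    a, b = _group_values(df, measure, band, timestep)
    return roc_analysis(a, b)
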