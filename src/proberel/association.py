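"""Relating probe reliability to external per-probe statistics.

Covers three analyses that share one shape — "is this external
property of a probe coupled to how reliably the probe is measured?":

* a generic correlation (Pearson or Spearman) of ICC with any
  per-probe statistic (heritability, blood–brain concordance, ...),
  with low/mid/high concordance bins mirroring the violin-plot view;
* the intersection analysis across several brain regions (probes
  concordant in *all* regions);
* TSS-linked methylation–expression correlation across shared samples,
  whose significant probe set feeds the enrichment summaries.

Bins use boundaries (0.4, 0.75] with boundary values assigned to the
lower bin, consistent with the reliability categories.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix

__all__ = [
    "associate_external",
    "concordance_bins",
    "multi_region_intersection",
    "methylation_expression_correlation",
]

BIN_EDGES = (0.4, 0.75)


def _bin_label(values: np.ndarray) -> np.ndarray:
    lo, hi = BIN_EDGES
    out = np.where(values <= lo, "low", np.where(values <= hi, "mid", "high"))
    return out


def _icc_summary(icc: np.ndarray) -> dict:
    icc = icc[np.isfinite(icc)]
    if icc.size == 0:
        return {"n": 0, "median_icc": None, "prop_above_0.75": None}
    return {
        "n": int(icc.size),
        "median_icc": float(np.median(icc)),
        "prop_above_0.75": float(np.mean(icc > 0.75)),
    }


def concordance_bins(reliability: pd.DataFrame, stat: pd.Series) -> dict:
    """Bin probes by an external statistic and summarize ICC per bin.

    Bins are low (<= 0.4), mid (0.4, 0.75] and high (> 0.75); together
    they partition every probe with a defined statistic and ICC.
    """
    shared = reliability.index.intersection(stat.index)
    icc = reliability.loc[shared, "icc"].to_numpy(dtype=float)
    s = stat.loc[shared].to_numpy(dtype=float)
    keep = np.isfinite(icc) & np.isfinite(s)
    icc, s = icc[keep], s[keep]
    labels = _bin_label(s)
    return {
        name: _icc_summary(icc[labels == name]) for name in ("low", "mid", "high")
    }


def associate_external(
    reliability: pd.DataFrame,
    stat: pd.Series,
    method: str = "pearson",
) -> dict:
    """Correlate per-probe ICC with an external per-probe statistic.

    Parameters
    ----------
    reliability
        Probe-indexed table with an ``icc`` column.
    stat
        Probe-indexed external statistic (e.g. blood–brain correlation).
    method
        ``"pearson"`` or ``"spearman"``.

    Returns
    -------
    dict with ``r``, ``p``, ``n_probes``, ``method`` and per-bin ICC
    summaries under ``bins``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    shared = reliability.index.intersection(stat.index)
    icc = reliability.loc[shared, "icc"].to_numpy(dtype=float)
    s = stat.loc[shared].to_numpy(dtype=float)
    keep = np.isfinite(icc) & np.isfinite(s)
    icc, s = icc[keep], s[keep]
    if icc.size < 3:
        raise ValueError("need at least 3 shared probes with defined values")
    out: dict = {"method": method, "n_probes": int(icc.size)}
    if np.ptp(s) == 0 or np.ptp(icc) == 0:
        out.update({"r": None, "p": None, "flag": "zero_variance"})
    else:
        fn = stats.pearsonr if method == "pearson" else stats.spearmanr
        r, p = fn(icc, s)
        out.update({"r": float(r), "p": float(p)})
    out["bins"] = concordance_bins(reliability, stat)
    return out


def multi_region_intersection(
    reliability: pd.DataFrame,
    region_stats: dict[str, pd.Series],
    high_cut: float = 0.75,
    low_cut: float = 0.4,
) -> dict:
    """Probes concordant (or discordant) in *all* regions, with ICC summaries.

    ``region_stats`` maps region name to a per-probe statistic.  A probe
    is in the all-high intersection when its statistic exceeds
    ``high_cut`` in every region, and in the all-low intersection when
    it is below ``low_cut`` in every region.  Empty intersections are
    reported as empty, not errors.
    """
    if len(region_stats) < 2:
        raise ValueError("need statistics from at least 2 regions")
    common = reliability.index
    for s in region_stats.values():
        common = common.intersection(s.index)
    high = pd.Series(True, index=common)
    low = pd.Series(True, index=common)
    for s in region_stats.values():
        v = s.loc[common].astype(float)
        high &= v > high_cut
        low &= v < low_cut
    icc = reliability.loc[common, "icc"].to_numpy(dtype=float)
    return {
        "n_regions": len(region_stats),
        "all_high": _icc_summary(icc[high.to_numpy()]),
        "all_low": _icc_summary(icc[low.to_numpy()]),
        "high_cut": high_cut,
        "low_cut": low_cut,
    }


def methylation_expression_correlation(
    beta: BetaMatrix,
    expression: pd.DataFrame,
    links: pd.DataFrame,
    alpha: float = 1e-7,
) -> pd.DataFrame:
    """Correlate TSS-linked probe methylation with gene expression.

    Parameters
    ----------
    beta
        Probes × samples β matrix.
    expression
        Expression units × samples matrix (unrestricted reals), sample
        ids matching ``beta``'s (>= 10 shared samples required).
    links
        DataFrame with columns ``probe_id, unit_id`` (many probes may
        link to one unit); duplicated links are dropped.
    alpha
        Two-sided significance threshold on the correlation p-value
        (exact t-transform with n − 2 degrees of freedom).

    Returns
    -------
    DataFrame with one row per evaluable link: ``probe_id, unit_id, r,
    p, n_samples, significant, flag``.  Links with a zero-variance probe
    or unit are retained with ``flag='zero_variance'`` and NaN r.
    """
    if not {"probe_id", "unit_id"}.issubset(links.columns):
        raise ValueError("links must have columns 'probe_id' and 'unit_id'")
    links = links[["probe_id", "unit_id"]].astype(str).drop_duplicates()
    if links.empty:
        raise ValueError("links table is empty")
    shared_samples = [s for s in beta.sample_ids if s in set(expression.columns)]
    if len(shared_samples) < 10:
        raise ValueError(
            f"need >= 10 shared samples, found {len(shared_samples)}"
        )
    b = beta.values[shared_samples]
    e = expression[shared_samples]
    usable = links[
        links["probe_id"].isin(b.index) & links["unit_id"].isin(e.index)
    ]
    if usable.empty:
        raise ValueError("no link connects a known probe to a known unit")

    bx = b.loc[usable["probe_id"]].to_numpy(dtype=float)
    ex = e.loc[usable["unit_id"]].to_numpy(dtype=float)
    n = len(shared_samples)
    bx_c = bx - bx.mean(axis=1, keepdims=True)
    ex_c = ex - ex.mean(axis=1, keepdims=True)
    sxx = (bx_c**2).sum(axis=1)
    syy = (ex_c**2).sum(axis=1)
    sxy = (bx_c * ex_c).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = sxy / np.sqrt(sxx * syy)
        # two-sided p via the exact t transform, df = n - 2
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    zero_var = (sxx == 0.0) | (syy == 0.0)
    r = np.where(zero_var, np.nan, r)
    p = np.where(zero_var, np.nan, p)
    out = pd.DataFrame(
        {
            "probe_id": usable["probe_id"].to_numpy(),
            "unit_id": usable["unit_id"].to_numpy(),
            "r": r,
            "p": p,
            "n_samples": n,
            "significant": (p < alpha) & ~zero_var,
            "flag": np.where(zero_var, "zero_variance", "ok"),
        }
    )
    return out.reset_index(drop=True)
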