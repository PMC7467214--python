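"""Rank-based probe-set enrichment against the reliability ranking.

Tests whether a probe set (mQTL probes, clock CpGs, expression-linked
probes, ...) is concentrated at the reliable end of the ICC ranking,
using the weighted Kolmogorov–Smirnov running-sum statistic of
preranked gene-set enrichment analysis:

* probes are ranked by descending statistic (ICC), ties broken by
  probe-id lexicographic order so the ranking is deterministic;
* walking down the ranking, hits increment the running sum by
  |stat|^w normalized over the in-set total, misses decrement by
  1 / (N − m);
* ES is the signed extremum of largest absolute deviation.

The null distribution permutes *set membership* — random same-size
probe sets drawn without replacement — matching the preranked
convention (no sample-level data exist for published probe lists).
NES = ES / mean(|null ES| of matching sign) and the permutation
p-value carries an add-one correction, so p ≥ 1 / (n_perm + 1).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import ProbeSet

__all__ = [
    "RankedProbeList",
    "EnrichmentResult",
    "rank_probes",
    "enrichment_score",
    "enrichment_test",
    "set_summary",
]

DEFAULT_WEIGHT = 1.0


@dataclasses.dataclass
class RankedProbeList:
    """Probe ids ordered by descending statistic with deterministic ties."""

    probe_ids: np.ndarray
    statistics: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.statistics = np.asarray(self.statistics, dtype=float)
        if self.probe_ids.shape != self.statistics.shape:
            raise ValueError("probe_ids and statistics must have equal length")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("ranked probe ids must be unique")

    def __len__(self) -> int:
        return len(self.probe_ids)


def rank_probes(reliability: pd.DataFrame, column: str = "icc") -> RankedProbeList:
    """Build the descending reliability ranking from a reliability table.

    Probes with undefined statistic are dropped; ties are broken by
    probe id (ascending) for determinism.
    """
    stat = reliability[column]
    keep = stat.notna()
    df = reliability.loc[keep, [column]].copy()
    df["_pid"] = df.index.astype(str)
    df = df.sort_values([column, "_pid"], ascending=[False, True], kind="mergesort")
    return RankedProbeList(df["_pid"].to_numpy(), df[column].to_numpy())


def _es_from_positions(
    positions: np.ndarray, abs_stats_w: np.ndarray, n: int
) -> np.ndarray:
    """Vectorized ES for one or many hit-position vectors.

    ``positions`` is (B, m), ascending 0-based ranks of the set members;
    ``abs_stats_w`` is the length-N vector |stat|^w on the full ranking.
    The running sum is piecewise linear and its extrema occur just
    before or just at each hit, so evaluating both candidates per hit
    is exhaustive.
    """
    positions = np.atleast_2d(positions)
    b, m = positions.shape
    w = abs_stats_w[positions]
    totals = w.sum(axis=1, keepdims=True)
    # all-zero in-set weights (possible with w>0 and zero stats): fall back
    # to equal weights so the statistic stays defined
    zero = totals[:, 0] == 0.0
    if np.any(zero):
        w = w.copy()
        w[zero] = 1.0
        totals = w.sum(axis=1, keepdims=True)
    phit_after = np.cumsum(w, axis=1) / totals
    phit_before = phit_after - w / totals
    j = np.arange(m)[None, :]
    pmiss = (positions - j).astype(float) / float(n - m)
    dev_after = phit_after - pmiss
    dev_before = phit_before - pmiss
    candidates = np.concatenate([dev_after, dev_before], axis=1)
    idx = np.argmax(np.abs(candidates), axis=1)
    es = candidates[np.arange(b), idx]
    return es


def enrichment_score(
    ranked: RankedProbeList,
    probe_set: ProbeSet,
    weight_exponent: float = DEFAULT_WEIGHT,
) -> tuple[float, np.ndarray]:
    """Weighted running-sum enrichment score of a probe set.

    Returns ``(ES, profile)`` where ``profile`` is the full length-N
    running-sum trajectory (useful for plots and the small-N oracle).
    """
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be >= 0")
    n = len(ranked)
    in_set = np.isin(ranked.probe_ids.astype(str), list(probe_set.probe_ids))
    m = int(in_set.sum())
    if m == 0:
        raise ValueError(
            f"probe set {probe_set.name!r} has no overlap with the ranking"
        )
    if m == n:
        raise ValueError("probe set covers the whole ranking; ES is degenerate")
    absw = np.abs(ranked.statistics) ** weight_exponent
    hit_w = np.where(in_set, absw, 0.0)
    total = hit_w.sum()
    if total == 0.0:
        hit_w = in_set.astype(float)
        total = hit_w.sum()
    phit = np.cumsum(hit_w) / total
    pmiss = np.cumsum(~in_set) / float(n - m)
    profile = phit - pmiss
    es = float(profile[np.argmax(np.abs(profile))])
    return es, profile


@dataclasses.dataclass(frozen=True)
class EnrichmentResult:
    """Permutation-based enrichment of one probe set."""

    set_name: str
    es: float
    nes: float
    p_value: float
    set_size: int
    n_permutations: int
    seed: int


def enrichment_test(
    ranked: RankedProbeList,
    probe_set: ProbeSet,
    n_permutations: int = 10_000,
    seed: int = 0,
    weight_exponent: float = DEFAULT_WEIGHT,
) -> EnrichmentResult:
    """Permutation enrichment test of a probe set against the ranking.

    Null ES values come from random same-size sets drawn without
    replacement from the ranking (set-membership permutation); the
    result is deterministic given ``seed``.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    es, _ = enrichment_score(ranked, probe_set, weight_exponent)
    n = len(ranked)
    in_set = np.isin(ranked.probe_ids.astype(str), list(probe_set.probe_ids))
    m = int(in_set.sum())
    absw = np.abs(ranked.statistics) ** weight_exponent

    rng = np.random.default_rng(seed)
    null_es = np.empty(n_permutations)
    # draw hit positions in batches: argpartition of random keys gives
    # uniform m-subsets without replacement
    batch = max(1, min(n_permutations, int(2e7 // max(n, 1))))
    done = 0
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        keys = rng.random((b, n))
        pos = np.argpartition(keys, m - 1, axis=1)[:, :m]
        pos.sort(axis=1)
        null_es[done : done + b] = _es_from_positions(pos, absw, n)
        done += b

    if es >= 0:
        p = (1.0 + np.sum(null_es >= es)) / (n_permutations + 1.0)
        same_sign = null_es[null_es > 0]
    else:
        p = (1.0 + np.sum(null_es <= es)) / (n_permutations + 1.0)
        same_sign = null_es[null_es < 0]
    denom = np.mean(np.abs(same_sign)) if same_sign.size else np.nan
    nes = float(es / denom) if denom and np.isfinite(denom) else float("nan")
    return EnrichmentResult(
        set_name=probe_set.name,
        es=float(es),
        nes=nes,
        p_value=float(p),
        set_size=m,
        n_permutations=n_permutations,
        seed=seed,
    )


def set_summary(reliability: pd.DataFrame, probe_set: ProbeSet) -> dict:
    """Distribution summary of a probe set's ICCs.

    Median, interquartile range, proportion with ICC > 0.75 and set
    size — the quantities annotated on reliability box plots.
    """
    shared = reliability.index.intersection(list(probe_set.probe_ids))
    icc = reliability.loc[shared, "icc"].to_numpy(dtype=float)
    icc = icc[np.isfinite(icc)]
    if icc.size == 0:
        raise ValueError(
            f"probe set {probe_set.name!r} has no probes with defined ICC"
        )
    q1, med, q3 = np.percentile(icc, [25, 50, 75])
    return {
        "set_name": probe_set.name,
        "n_probes": int(icc.size),
        "median_icc": float(med),
        "iqr": (float(q1), float(q3)),
        "prop_above_0.75": float(np.mean(icc > 0.75)),
    }
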