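"""Cross-study replication of EWAS hits and its link to reliability.

Given significant-probe lists with direction of effect from several
independent EWAS of the same exposure, each probe's replication tally
is the number of studies listing it with a consistent direction.  When
studies disagree, the majority direction defines consistency
(``n_consistent = max(#up, #down)``); exact ties are reported as
``tie``.  A strict alternative (``conflict_rule="zero"``) scores any
mixed-direction probe as zero.

The association with reliability is the Pearson correlation of the
tally with per-probe ICC over the union of listed probes, plus group
summaries for low- (ICC < 0.4) and high- (ICC > 0.75) reliability
probes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import StudyHitList

__all__ = ["count_replications", "replication_reliability_association"]


def count_replications(
    hit_lists: list[StudyHitList], conflict_rule: str = "majority"
) -> pd.DataFrame:
    """Per-probe consistent-direction replication tally across studies.

    Parameters
    ----------
    hit_lists
        One :class:`~proberel.io.StudyHitList` per study (>= 2 required).
    conflict_rule
        ``"majority"`` (default) scores a mixed-direction probe by its
        majority count; ``"zero"`` scores any mixed-direction probe 0.

    Returns
    -------
    DataFrame indexed by probe id with columns
    ``n_studies_listed, n_up, n_down, n_consistent, majority_direction``.
    """
    if len(hit_lists) < 2:
        raise ValueError("need hit lists from at least 2 studies")
    if conflict_rule not in ("majority", "zero"):
        raise ValueError("conflict_rule must be 'majority' or 'zero'")
    ids = [h.study_id for h in hit_lists]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate study ids in hit lists")
    rows = [
        {"probe_id": p, "direction": d}
        for h in hit_lists
        for p, d in h.entries
    ]
    long = pd.DataFrame(rows)
    counts = (
        long.pivot_table(index="probe_id", columns="direction", aggfunc="size", fill_value=0)
        .reindex(columns=["up", "down"], fill_value=0)
        .astype(int)
    )
    counts.columns = ["n_up", "n_down"]
    counts["n_studies_listed"] = counts["n_up"] + counts["n_down"]
    maj = np.where(
        counts["n_up"] > counts["n_down"],
        "up",
        np.where(counts["n_down"] > counts["n_up"], "down", "tie"),
    )
    counts["majority_direction"] = maj
    consistent = counts[["n_up", "n_down"]].max(axis=1)
    if conflict_rule == "zero":
        mixed = (counts["n_up"] > 0) & (counts["n_down"] > 0)
        consistent = consistent.where(~mixed, 0)
    counts["n_consistent"] = consistent.astype(int)
    return counts[
        ["n_studies_listed", "n_up", "n_down", "n_consistent", "majority_direction"]
    ].sort_index()


def _group_stats(values: np.ndarray) -> dict:
    if values.size == 0:
        return {"n": 0, "mean": None, "median": None, "sd": None, "flag": "empty_group"}
    return {
        "n": int(values.size),
        "mean": float(np.mean(values)),
        "median": float(np.median(values)),
        "sd": float(np.std(values, ddof=1)) if values.size > 1 else float("nan"),
    }


def replication_reliability_association(
    counts: pd.DataFrame,
    reliability: pd.DataFrame,
    low_cut: float = 0.4,
    high_cut: float = 0.75,
) -> dict:
    """Relate the replication tally to probe reliability.

    The probe universe is the union of hit lists (probes never listed
    anywhere do not enter).  Reports the Pearson correlation of
    ``n_consistent`` with ICC and replication-count summaries for the
    low- (ICC < ``low_cut``) and high- (ICC > ``high_cut``) reliability
    groups.
    """
    shared = counts.index.intersection(reliability.index)
    icc = reliability.loc[shared, "icc"].to_numpy(dtype=float)
    tally = counts.loc[shared, "n_consistent"].to_numpy(dtype=float)
    keep = np.isfinite(icc)
    icc, tally = icc[keep], tally[keep]
    if icc.size < 3:
        raise ValueError("need at least 3 shared probes with defined ICC")
    out: dict = {"n_probes": int(icc.size)}
    if np.ptp(tally) == 0 or np.ptp(icc) == 0:
        out["r"] = None
        out["p"] = None
        out["flag"] = "zero_variance"
    else:
        r, p = stats.pearsonr(tally, icc)
        out["r"] = float(r)
        out["p"] = float(p)
    out["low_group"] = _group_stats(tally[icc < low_cut])
    out["high_group"] = _group_stats(tally[icc > high_cut])
    out["low_cut"] = low_cut
    out["high_cut"] = high_cut
    return out
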