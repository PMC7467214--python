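"""Per-probe test–retest reliability of methylation β values.

The reliability metric is the intraclass correlation for a mean-rating
(k = 2), absolute-agreement, two-way random-effects model — ICC(A,k) in
the McGraw & Wong taxonomy.  For an n×2 table of repeated measurements
the two-way ANOVA mean squares are

    MSR  between-subject (row) mean square,
    MSC  between-rater   (column) mean square,
    MSE  residual mean square,

and the average-measurement, absolute-agreement coefficient is

    ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n).

Absolute agreement penalizes a systematic offset between the two
measurement occasions (MSC enters the denominator), which Pearson's r
does not; both are reported so the model choice can be audited.
Negative estimates are reported as computed — empirical per-probe ICCs
on methylation arrays genuinely extend below zero — and never clipped.

The per-probe computation is vectorized across probes; probes with
missing cells are handled via complete pairs only.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import PairedBetaMatrix

__all__ = [
    "ICCComponents",
    "icc_absolute_agreement",
    "paired_icc",
    "paired_pearson",
    "compute_pearson",
    "reliability_table",
    "summarize_reliability",
    "classify_reliability",
    "beta_to_m",
    "bonferroni_threshold",
    "FLAG_OK",
    "FLAG_INSUFFICIENT_N",
    "FLAG_DEGENERATE",
]

FLAG_OK = "ok"
FLAG_INSUFFICIENT_N = "insufficient_n"
FLAG_DEGENERATE = "degenerate"

#: reliability category boundaries (Cicchetti convention)
CATEGORY_EDGES = (0.4, 0.6, 0.75)

#: offset applied in the M-value transform, only at β exactly 0 or 1
M_VALUE_EPSILON = 1e-6


@dataclasses.dataclass(frozen=True)
class ICCComponents:
    """Two-way ANOVA decomposition backing one ICC estimate.

    ``n`` paired samples (subjects) by ``k`` = 2 raters (measurement
    occasions); the three mean squares are exposed for auditing.
    """

    n: int
    k: int
    msr: float
    msc: float
    mse: float


def _anova_arrays(x: np.ndarray, y: np.ndarray):
    """Vectorized two-way ANOVA mean squares for P probes, k = 2 raters.

    ``x``, ``y`` are (P, n) arrays of the two measurement occasions; NaN
    in either column removes that pair for that probe (complete pairs
    only).  Returns per-probe ``n, msr, msc, mse, sst``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    mask = np.isfinite(x) & np.isfinite(y)
    xm = np.where(mask, x, 0.0)
    ym = np.where(mask, y, 0.0)
    n = mask.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx = xm.sum(axis=1)
        sy = ym.sum(axis=1)
        grand = (sx + sy) / (2.0 * n)
        g = grand[:, None]
        row_mean = np.where(mask, (xm + ym) / 2.0, np.nan)
        ssr = 2.0 * np.nansum((row_mean - g) ** 2, axis=1)
        cx = sx / n
        cy = sy / n
        ssc = n * ((cx - grand) ** 2 + (cy - grand) ** 2)
        sst = np.nansum(np.where(mask, (xm - g) ** 2 + (ym - g) ** 2, 0.0), axis=1)
        sse = np.maximum(sst - ssr - ssc, 0.0)
        msr = ssr / (n - 1.0)
        msc = ssc  # df = k - 1 = 1
        mse = sse / (n - 1.0)
    return n, msr, msc, mse, sst


def paired_icc(x: np.ndarray, y: np.ndarray):
    """ICC(A, k=2) per probe for paired measurement arrays.

    Parameters
    ----------
    x, y
        (P, n) arrays (or (n,) for a single probe) of the two occasions.

    Returns
    -------
    icc : (P,) array
        NaN where flagged.
    flags : (P,) array of str
        ``ok``, ``insufficient_n`` (< 3 complete pairs) or ``degenerate``
        (zero total variance).
    components : dict of (P,) arrays
        ``n, msr, msc, mse``.
    """
    n, msr, msc, mse, sst = _anova_arrays(x, y)
    flags = np.full(n.shape, FLAG_OK, dtype=object)
    flags[n < 3] = FLAG_INSUFFICIENT_N
    rel_tol = np.maximum(sst, 1.0) * 1e-14
    degen = (n >= 3) & (sst <= rel_tol)
    flags[degen] = FLAG_DEGENERATE
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = msr + (msc - mse) / n
        icc = (msr - mse) / denom
    # algebraically denom - numerator = ((n-1)MSE + MSC)/n >= 0, so icc <= 1
    # whenever denom > 0; a nonpositive denominator (pathological
    # anti-agreement) leaves the coefficient undefined
    bad_denom = (flags == FLAG_OK) & (denom <= (msr + msc + mse) * 1e-12)
    flags[bad_denom] = FLAG_DEGENERATE
    icc = np.where(flags == FLAG_OK, icc, np.nan)
    icc = np.where(np.isfinite(icc), icc, np.nan)
    flags[(flags == FLAG_OK) & ~np.isfinite(icc)] = FLAG_DEGENERATE
    return icc, flags, {"n": n, "msr": msr, "msc": msc, "mse": mse}


def icc_absolute_agreement(values: np.ndarray) -> tuple[float, ICCComponents, str]:
    """ICC(A, k=2) for a single probe's n×2 paired values.

    Returns ``(icc, components, flag)``; ``icc`` is NaN when the flag is
    not ``ok``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != 2:
        raise ValueError("expected an n×2 matrix of paired measurements")
    icc, flags, comp = paired_icc(values[:, 0][None, :], values[:, 1][None, :])
    components = ICCComponents(
        n=int(comp["n"][0]),
        k=2,
        msr=float(comp["msr"][0]),
        msc=float(comp["msc"][0]),
        mse=float(comp["mse"][0]),
    )
    return float(icc[0]), components, str(flags[0])


def paired_pearson(x: np.ndarray, y: np.ndarray):
    """Pearson product-moment correlation per probe (complete pairs only).

    Returns ``(r, flags)``; zero variance in either column flags the
    probe ``degenerate``, < 3 complete pairs ``insufficient_n``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    mask = np.isfinite(x) & np.isfinite(y)
    xm = np.where(mask, x, 0.0)
    ym = np.where(mask, y, 0.0)
    n = mask.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = (xm.sum(axis=1) / n)[:, None]
        my = (ym.sum(axis=1) / n)[:, None]
        dx = np.where(mask, xm - mx, 0.0)
        dy = np.where(mask, ym - my, 0.0)
        sxx = (dx**2).sum(axis=1)
        syy = (dy**2).sum(axis=1)
        sxy = (dx * dy).sum(axis=1)
        r = sxy / np.sqrt(sxx * syy)
    flags = np.full(n.shape, FLAG_OK, dtype=object)
    flags[n < 3] = FLAG_INSUFFICIENT_N
    scale = np.maximum(sxx + syy, 1.0)
    flags[(n >= 3) & ((sxx <= scale * 1e-14) | (syy <= scale * 1e-14))] = FLAG_DEGENERATE
    r = np.where(flags == FLAG_OK, r, np.nan)
    return r, flags


def compute_pearson(values: np.ndarray) -> tuple[float, str]:
    """Pearson r for a single probe's n×2 paired values."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != 2:
        raise ValueError("expected an n×2 matrix of paired measurements")
    r, flags = paired_pearson(values[:, 0][None, :], values[:, 1][None, :])
    return float(r[0]), str(flags[0])


def classify_reliability(icc) -> object:
    """Map ICC to {poor, fair, good, excellent}.

    poor: icc < 0.4 (including negatives); fair: 0.4 ≤ icc < 0.6;
    good: 0.6 ≤ icc ≤ 0.75; excellent: icc > 0.75.  NaN → None.
    Accepts scalars or arrays.
    """
    scalar = np.isscalar(icc) or (isinstance(icc, np.ndarray) and icc.ndim == 0)
    arr = np.atleast_1d(np.asarray(icc, dtype=float))
    lo, mid, hi = CATEGORY_EDGES
    out = np.full(arr.shape, None, dtype=object)
    valid = np.isfinite(arr)
    out[valid & (arr < lo)] = "poor"
    out[valid & (arr >= lo) & (arr < mid)] = "fair"
    out[valid & (arr >= mid) & (arr <= hi)] = "good"
    out[valid & (arr > hi)] = "excellent"
    return out[0] if scalar else out


def reliability_table(paired: PairedBetaMatrix, transform: str = "beta") -> pd.DataFrame:
    """Per-probe reliability table for a paired β matrix.

    Parameters
    ----------
    paired
        Aligned repeat measurements of the same DNA.
    transform
        ``"beta"`` computes on β values (default); ``"m"`` applies the
        M-value transform first.

    Returns
    -------
    DataFrame
        One row per probe: ``icc, pearson_r, mean_beta, sd_beta,
        n_pairs, category, flags``.  ``mean_beta``/``sd_beta`` summarize
        the *first* (reference) matrix only.  A run summary (mean,
        median, min, max of ICC; counts per category) is attached as
        ``df.attrs["summary"]`` and also available via
        :func:`summarize_reliability`.
    """
    if transform not in ("beta", "m"):
        raise ValueError("transform must be 'beta' or 'm'")
    x = paired.first.values.to_numpy(dtype=float)
    y = paired.second.values.to_numpy(dtype=float)
    if transform == "m":
        x = beta_to_m(x)
        y = beta_to_m(y)
    icc, flags, comp = paired_icc(x, y)
    r, _rflags = paired_pearson(x, y)
    ref = paired.first.values.to_numpy(dtype=float)
    df = pd.DataFrame(
        {
            "icc": icc,
            "pearson_r": r,
            "mean_beta": np.nanmean(ref, axis=1),
            "sd_beta": np.nanstd(ref, axis=1, ddof=1),
            "n_pairs": comp["n"].astype(int),
            "category": classify_reliability(icc),
            "flags": flags,
        },
        index=pd.Index(paired.probe_ids, name="probe_id"),
    )
    df.attrs["summary"] = summarize_reliability(df)
    df.attrs["missing_data_policy"] = "complete_pairs"
    df.attrs["transform"] = transform
    return df


def summarize_reliability(table: pd.DataFrame) -> dict:
    """Summary block for a reliability table: ICC moments and category counts."""
    icc = table["icc"].to_numpy(dtype=float)
    valid = icc[np.isfinite(icc)]
    counts = table["category"].value_counts(dropna=True).to_dict()
    return {
        "n_probes": int(len(table)),
        "n_estimated": int(valid.size),
        "mean_icc": float(np.mean(valid)) if valid.size else float("nan"),
        "median_icc": float(np.median(valid)) if valid.size else float("nan"),
        "min_icc": float(np.min(valid)) if valid.size else float("nan"),
        "max_icc": float(np.max(valid)) if valid.size else float("nan"),
        "category_counts": {k: int(v) for k, v in counts.items()},
    }


def beta_to_m(beta, epsilon: float = M_VALUE_EPSILON):
    """M-value transform M = log2(β / (1 − β)).

    The offset ``epsilon`` is applied only where β is exactly 0 or 1
    (M = log2((β + ε) / (1 − β + ε)) there), leaving interior values
    untouched.  β outside [0, 1] raises.
    """
    scalar = np.isscalar(beta)
    b = np.asarray(beta, dtype=float)
    finite = np.isfinite(b)
    if np.any((b[finite] < 0) | (b[finite] > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    boundary = finite & ((b == 0.0) | (b == 1.0))
    num = np.where(boundary, b + epsilon, b)
    den = np.where(boundary, 1.0 - b + epsilon, 1.0 - b)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2(num / den)
    return float(m) if scalar else m


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise-corrected per-test significance threshold α / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
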