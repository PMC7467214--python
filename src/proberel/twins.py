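"""ACE variance decomposition from MZ/DZ twin pairs.

The classical twin design decomposes trait variance into additive
genetic (A), shared environmental (C) and non-shared environmental (E)
proportions using the assumption that additive genetic factors
correlate 1 between monozygotic co-twins and 0.5 between dizygotic
co-twins, while shared environment correlates 1 in both.

With the trait standardized to mean 0, variance 1 per probe, a twin
pair is bivariate normal with unit variances and correlation

    r_MZ = a² + c²        r_DZ = a²/2 + c²        a² + c² + e² = 1.

``fit_ace_ml`` maximizes this bivariate-normal likelihood directly
(bounded, multi-start quasi-Newton) — the same likelihood a structural
equation model of the classical design would maximize, without an SEM
toolchain.  The likelihood is written on symmetric sufficient
statistics, so swapping twin-1/twin-2 labels within any pair cannot
change the fit.  ``fit_ace_falconer`` gives the closed-form
correlation-based estimates, used as a fallback and as an independent
cross-check: a² = 2(r_MZ − r_DZ), c² = 2 r_DZ − r_MZ, e² = 1 − r_MZ.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TwinDataset",
    "ACEEstimate",
    "fit_ace_ml",
    "fit_ace_falconer",
    "ace_table",
    "ace_reliability_association",
]

_E2_MIN = 1e-6  # e² lower bound: within-pair variance implies e² > 0
_LOGLIK_TOL = 1e-8


@dataclasses.dataclass
class TwinDataset:
    """Per-probe twin-pair values.

    ``mz``/``dz`` are (n_pairs, 2) arrays of co-twin trait values.
    """

    mz: np.ndarray
    dz: np.ndarray
    probe_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float).reshape(-1, 2)
        self.dz = np.asarray(self.dz, dtype=float).reshape(-1, 2)
        if self.n_mz < 2 or self.n_dz < 2:
            raise ValueError("need at least 2 MZ and 2 DZ complete pairs")

    @property
    def n_mz(self) -> int:
        return self.mz.shape[0]

    @property
    def n_dz(self) -> int:
        return self.dz.shape[0]

    def standardized(self) -> "TwinDataset":
        """Center and scale to mean 0, variance 1 over all twin values."""
        allv = np.concatenate([self.mz.ravel(), self.dz.ravel()])
        mu, sd = allv.mean(), allv.std(ddof=0)
        if sd == 0:
            raise ValueError(f"probe {self.probe_id!r}: zero variance across twins")
        return TwinDataset((self.mz - mu) / sd, (self.dz - mu) / sd, self.probe_id)


@dataclasses.dataclass(frozen=True)
class ACEEstimate:
    """Variance proportions a², c², e² with fit metadata."""

    a2: float
    c2: float
    e2: float
    loglik: float
    converged: bool
    method: str  # "ml" | "falconer"
    boundary: bool = False

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.a2, self.c2, self.e2)


def _suffstats(pairs: np.ndarray) -> tuple[int, float, float]:
    """Symmetric sufficient statistics (n, Σ(x²+y²), Σxy) of twin pairs."""
    x, y = pairs[:, 0], pairs[:, 1]
    return pairs.shape[0], float(np.sum(x * x + y * y)), float(np.sum(x * y))


def _group_loglik(rho: float, n: int, ssq: float, sxy: float) -> float:
    """Bivariate-normal log-likelihood with unit variances, correlation rho."""
    if not -1.0 < rho < 1.0:
        return -np.inf
    om = 1.0 - rho * rho
    return (
        -n * np.log(2.0 * np.pi)
        - 0.5 * n * np.log(om)
        - (ssq - 2.0 * rho * sxy) / (2.0 * om)
    )


def _loglik(a2: float, c2: float, stats_mz, stats_dz) -> float:
    r_mz = min(a2 + c2, 1.0 - _E2_MIN)
    r_dz = min(0.5 * a2 + c2, 1.0 - _E2_MIN)
    return _group_loglik(r_mz, *stats_mz) + _group_loglik(r_dz, *stats_dz)


def fit_ace_falconer(r_mz: float, r_dz: float) -> ACEEstimate:
    """Closed-form ACE estimates from twin correlations.

    Components are truncated at zero and renormalized to sum to one;
    boundary truncation is flagged.
    """
    for name, r in (("r_mz", r_mz), ("r_dz", r_dz)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name} must lie in [-1, 1]")
    raw = np.array([2.0 * (r_mz - r_dz), 2.0 * r_dz - r_mz, 1.0 - r_mz])
    boundary = bool(np.any(raw <= 1e-12))
    clipped = np.clip(raw, 0.0, None)
    total = clipped.sum()
    if total == 0.0:  # r_mz = 1 and degenerate geometry; fall back to pure E
        props = np.array([0.0, 0.0, 1.0])
    else:
        props = clipped / total
    return ACEEstimate(
        a2=float(props[0]),
        c2=float(props[1]),
        e2=float(props[2]),
        loglik=float("nan"),
        converged=True,
        method="falconer",
        boundary=boundary,
    )


def _sample_correlations(data: TwinDataset) -> tuple[float, float]:
    def corr(pairs):
        x, y = pairs[:, 0], pairs[:, 1]
        # symmetrized (double-entered) correlation: order-invariant
        xs = np.concatenate([x, y])
        ys = np.concatenate([y, x])
        return float(np.corrcoef(xs, ys)[0, 1])

    return corr(data.mz), corr(data.dz)


def fit_ace_ml(
    data: TwinDataset,
    standardize: bool = True,
    n_starts: int = 3,
    seed: int = 0,
) -> ACEEstimate:
    """Maximum-likelihood ACE fit on (standardized) twin pairs.

    Bounded SLSQP over (a², c²) with e² = 1 − a² − c² ≥ 0, multi-start
    (``n_starts`` seeded random starts plus the Falconer point).  If the
    optimizer fails to converge from every start, the Falconer estimates
    are returned with ``converged=False``.
    """
    if standardize:
        data = data.standardized()
    stats_mz = _suffstats(data.mz)
    stats_dz = _suffstats(data.dz)

    def objective(theta):
        return -_loglik(theta[0], theta[1], stats_mz, stats_dz)

    r_mz, r_dz = _sample_correlations(data)
    falc = fit_ace_falconer(np.clip(r_mz, -1, 1), np.clip(r_dz, -1, 1))
    rng = np.random.default_rng(seed)
    starts = [np.array([falc.a2, falc.c2])]
    for _ in range(n_starts):
        s = rng.dirichlet([1.0, 1.0, 1.0])[:2]
        starts.append(s)

    constraint = {"type": "ineq", "fun": lambda t: 1.0 - _E2_MIN - t[0] - t[1]}
    best = None
    any_success = False
    for x0 in starts:
        x0 = np.clip(x0, 0.0, 1.0 - _E2_MIN)
        if x0.sum() > 1.0 - _E2_MIN:
            x0 = x0 * (1.0 - _E2_MIN) / x0.sum()
        res = optimize.minimize(
            objective,
            x0,
            method="SLSQP",
            bounds=[(0.0, 1.0), (0.0, 1.0)],
            constraints=[constraint],
            options={"ftol": _LOGLIK_TOL, "maxiter": 200},
        )
        any_success = any_success or res.success
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        ll = _loglik(falc.a2, falc.c2, stats_mz, stats_dz)
        return dataclasses.replace(falc, loglik=float(ll), converged=False)
    a2, c2 = float(best.x[0]), float(best.x[1])
    e2 = 1.0 - a2 - c2
    return ACEEstimate(
        a2=a2,
        c2=c2,
        e2=e2,
        loglik=float(-best.fun),
        converged=any_success,
        method="ml",
        boundary=bool(a2 < 1e-6 or c2 < 1e-6),
    )


def ace_table(datasets: list[TwinDataset], **fit_kwargs) -> pd.DataFrame:
    """Fit ACE per probe; one row per dataset, indexed by probe id."""
    rows = []
    for ds in datasets:
        est = fit_ace_ml(ds, **fit_kwargs)
        rows.append(
            {
                "probe_id": ds.probe_id,
                "a2": est.a2,
                "c2": est.c2,
                "e2": est.e2,
                "loglik": est.loglik,
                "converged": est.converged,
                "method": est.method,
            }
        )
    return pd.DataFrame(rows).set_index("probe_id")


def ace_reliability_association(
    ace: pd.DataFrame, reliability: pd.DataFrame
) -> dict:
    """Pearson correlations of per-probe ICC with a², c², e².

    ``ace`` and ``reliability`` are probe-indexed frames carrying columns
    ``a2, c2, e2`` and ``icc`` respectively.
    """
    shared = ace.index.intersection(reliability.index)
    icc = reliability.loc[shared, "icc"].to_numpy(dtype=float)
    keep = np.isfinite(icc)
    if keep.sum() < 3:
        raise ValueError("need at least 3 shared probes with defined ICC")
    out = {"n_probes": int(keep.sum())}
    for comp in ("a2", "c2", "e2"):
        v = ace.loc[shared, comp].to_numpy(dtype=float)[keep]
        if np.ptp(v) == 0 or np.ptp(icc[keep]) == 0:
            out[f"r_icc_{comp}"] = None
            out[f"p_icc_{comp}"] = None
            continue
        r, p = stats.pearsonr(icc[keep], v)
        out[f"r_icc_{comp}"] = float(r)
        out[f"p_icc_{comp}"] = float(p)
    return out
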