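"""Two-phase population calibration of the positivity model.

Phase 1 fits the population parameter Q on the whole training cohort with all
level multipliers at 1, by equating the cohort-average predicted probability
with the observed positive-node frequency. Phase 2 holds Q fixed and, for
each level of each declared prognostic factor, fits that level's multiplier g
on the sub-sample (stratum) of patients at that level — again by matching the
stratum's mean prediction to its observed rate. Each level is fitted
independently against the phase-1 baseline (all other multipliers at 1), so
each g measures the marginal impact of its factor level; no joint refinement
is performed and Q is not re-normalized afterwards.

Both phases reduce to a one-dimensional root find of a strictly increasing
function, solved by geometric bracket expansion followed by Brent's method.
Strata whose observed rate is exactly 0 or 1 admit no finite root and are
clamped to [G_MIN, G_MAX] with a flag; strata smaller than ``min_stratum``
are left neutral (g = 1) with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .cohort import FactorScheme, PatientRecord
from .errors import DegenerateCohortError, SolverError
from .model import CMParameters, CohortMatrix

logger = logging.getLogger(__name__)

#: Clamp bounds for strata with observed rate exactly 0 or 1.
G_MIN = 1e-6
G_MAX = 1e6

#: Absolute tolerance on the rate mismatch at the fitted root.
RATE_TOL = 1e-10

#: Strata below this size are left at g = 1 (too small to calibrate).
DEFAULT_MIN_STRATUM = 5

_MAX_ITER = 200


@dataclass
class FactorStratum:
    """The training sub-sample at one level of one prognostic factor."""

    factor: str
    level: str
    members: Sequence[PatientRecord]

    @property
    def w(self) -> int:
        return len(self.members)

    @property
    def observed_rate(self) -> float:
        if not self.members:
            raise DegenerateCohortError(f"empty stratum {self.factor}={self.level}")
        return sum(r.node_status for r in self.members) / len(self.members)


@dataclass
class StratumFit:
    factor: str
    level: str
    w: int
    observed_rate: float
    g: float
    converged: bool
    clamped: bool
    skipped: bool = False


@dataclass
class FitReport:
    """Full record of a two-phase fit: parameters plus per-stratum diagnostics."""

    params: CMParameters
    strata: list[StratumFit]
    rate_tolerance: float = RATE_TOL

    def stratum(self, factor: str, level: str) -> StratumFit:
        for s in self.strata:
            if s.factor == factor and s.level == level:
                return s
        raise KeyError((factor, level))


def _solve_increasing(f: Callable[[float], float], x0: float = 1.0) -> float:
    """Root of a strictly increasing f with f(0+) < 0, by bracket expansion + Brent.

    The bracket grows/shrinks geometrically from ``x0`` until the sign change
    is enclosed; iteration counts are bounded to keep the solver total.
    """
    lo, hi = x0, x0
    it = 0
    while f(lo) > 0:
        lo /= 8.0
        it += 1
        if it > _MAX_ITER:
            raise SolverError("failed to bracket root from below")
    while f(hi) < 0:
        hi *= 8.0
        it += 1
        if it > _MAX_ITER:
            raise SolverError("failed to bracket root from above")
    return float(brentq(f, lo, hi, xtol=1e-300, rtol=1e-15, maxiter=_MAX_ITER))


def _fit_rate_root(d_pow: np.ndarray, target: float, coef: np.ndarray | float = 1.0,
                   x0: float = 1.0) -> float:
    """Unique x > 0 with mean(1 - exp(-x * coef * d_pow)) = target."""

    def f(x: float) -> float:
        return float(np.mean(-np.expm1(-x * coef * d_pow))) - target

    root = _solve_increasing(f, x0=x0)
    if abs(f(root)) > RATE_TOL:
        raise SolverError(f"rate mismatch {f(root):.3g} exceeds tolerance at root {root:.6g}")
    return root


def fit_qn(cohort: Sequence[PatientRecord], z: float = 1.0) -> float:
    """Phase 1: population parameter Q with all multipliers at 1.

    Solves mean(1 - exp(-Q * D**z)) = observed prevalence. The left side is
    strictly increasing in Q from 0 toward 1, so the root is unique; a cohort
    with prevalence 0 or 1 has no finite root and raises.
    """
    if not cohort:
        raise DegenerateCohortError("empty cohort")
    d = np.array([r.diameter for r in cohort], dtype=float)
    y = np.array([r.node_status for r in cohort], dtype=float)
    return _fit_qn_arrays(d, y, z)


def _fit_qn_arrays(d: np.ndarray, y: np.ndarray, z: float) -> float:
    prevalence = float(np.mean(y))
    if prevalence <= 0.0 or prevalence >= 1.0:
        raise DegenerateCohortError(
            f"prevalence {prevalence} admits no finite population parameter"
        )
    d_pow = d ** z
    # a reasonable starting scale: the equal-diameter closed form
    x0 = -np.log1p(-prevalence) / float(np.mean(d_pow))
    return _fit_rate_root(d_pow, prevalence, x0=x0)


def fit_factor_parameter(stratum: FactorStratum, qn: float, z: float = 1.0) -> float:
    """Phase 2: the multiplier g of one factor level, with Q fixed.

    Solves mean over the stratum of (1 - exp(-Q * g * D**z)) = observed rate.
    Rates of exactly 0 or 1 admit no finite root and are clamped to
    ``G_MIN`` / ``G_MAX`` respectively.
    """
    d = np.array([r.diameter for r in stratum.members], dtype=float)
    rate = stratum.observed_rate
    return _fit_g_arrays(d, rate, qn, z)


def _fit_g_arrays(d: np.ndarray, rate: float, qn: float, z: float) -> float:
    if rate <= 0.0:
        return G_MIN
    if rate >= 1.0:
        return G_MAX
    return _fit_rate_root(d ** z, rate, coef=qn)


def fit_model(
    cohort: Sequence[PatientRecord],
    scheme: FactorScheme,
    z: float = 1.0,
    min_stratum: int = DEFAULT_MIN_STRATUM,
) -> FitReport:
    """Run both calibration phases over every non-unknown level of the scheme."""
    matrix = CohortMatrix(cohort, scheme)
    return fit_model_matrix(matrix, z=z, min_stratum=min_stratum)


def fit_model_matrix(
    matrix: CohortMatrix, z: float = 1.0, min_stratum: int = DEFAULT_MIN_STRATUM
) -> FitReport:
    """Array-path twin of :func:`fit_model`; used by cross-validation loops."""
    scheme = matrix.scheme
    qn = _fit_qn_arrays(matrix.diameters, matrix.labels.astype(float), z)
    g: dict[str, dict[str, float]] = {}
    strata: list[StratumFit] = []
    for factor in scheme.factors:
        g[factor] = {}
        codes = matrix.codes[factor]
        for code, level in enumerate(scheme.levels(factor)):
            mask = codes == code
            w = int(mask.sum())
            if w == 0:
                logger.warning("stratum %s=%s is empty; leaving g = 1", factor, level)
                g[factor][level] = 1.0
                strata.append(StratumFit(factor, level, 0, float("nan"), 1.0,
                                         converged=False, clamped=False, skipped=True))
                continue
            rate = float(matrix.labels[mask].mean())
            if w < min_stratum:
                logger.warning(
                    "stratum %s=%s has only %d members (< %d); leaving g = 1",
                    factor, level, w, min_stratum,
                )
                g[factor][level] = 1.0
                strata.append(StratumFit(factor, level, w, rate, 1.0,
                                         converged=False, clamped=False, skipped=True))
                continue
            val = _fit_g_arrays(matrix.diameters[mask], rate, qn, z)
            clamped = rate <= 0.0 or rate >= 1.0
            g[factor][level] = val
            strata.append(StratumFit(factor, level, w, rate, val,
                                     converged=not clamped, clamped=clamped))
    params = CMParameters(qn=qn, z=z, g=g, scheme=scheme)
    return FitReport(params=params, strata=strata)
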