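"""Synthetic cohorts emulating a clinically node-negative breast-cancer study.

The institutional cohort the model was originally calibrated on is not
publicly deposited, so this module generates stand-in cohorts: covariates are
drawn independently from the study population's published marginal
distributions (age decades, tumor-size split T1/T2/T3 ~ 75/23/2%, histology
with ~21% unknown, ER/PR/Ki67/HER2 positivity, grading with ~60% unknown),
and the sentinel-node label is drawn from the multiplicative exponential risk
model itself under known ground-truth parameters, calibrated so the expected
positive-node prevalence matches the study's ~21%.

Tumor diameter is continuous log-normal truncated to (0, 120] mm, with
location/scale solved exactly from the two category constraints
P(D <= 20) = 0.7533 and P(D <= 50) = 0.9859. Covariate independence and
missing-completely-at-random unknowns are deliberate simplifications: only
marginal fidelity to the study population is claimed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .cohort import (
    BASE_FACTORS,
    DEFAULT_AGE_BINS,
    UNKNOWN,
    FactorScheme,
    PatientRecord,
)
from .errors import ConfigurationError
from .model import CMParameters, CohortMatrix

#: Study cohort size and positive-node prevalence (208/993).
STUDY_N = 993
STUDY_PREVALENCE = 208 / 993

#: Tumor-size category shares used to pin the diameter law.
_P_T1 = 748 / 993
_P_T2 = 231 / 993

_QUAD_NODES = 256


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of one synthetic cohort.

    Categorical marginals are dicts level -> probability (summing to 1);
    ``grading`` uses raw record codes ("1", "2", "3", "unknown"). The
    outcome-generating law is ``true_params`` applied to each drawn record.
    """

    n: int
    seed: int
    age_probs: dict[str, float]
    diameter_median_mm: float
    diameter_sigma: float
    diameter_max_mm: float
    histology_probs: dict[str, float]
    er_probs: dict[str, float]
    pr_probs: dict[str, float]
    ki67_probs: dict[str, float]
    her2_probs: dict[str, float]
    grading_probs: dict[str, float]
    true_params: CMParameters

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        if not (0 < self.diameter_max_mm and self.diameter_median_mm > 0):
            raise ConfigurationError("diameter parameters must be positive")
        for name in ("age", "histology", "er", "pr", "ki67", "her2", "grading"):
            probs = getattr(self, f"{name}_probs")
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-12:
                raise ConfigurationError(f"{name} probabilities sum to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ConfigurationError(f"{name} probabilities must be non-negative")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "seed": self.seed,
            "age_probs": self.age_probs,
            "diameter_median_mm": self.diameter_median_mm,
            "diameter_sigma": self.diameter_sigma,
            "diameter_max_mm": self.diameter_max_mm,
            "histology_probs": self.histology_probs,
            "er_probs": self.er_probs,
            "pr_probs": self.pr_probs,
            "ki67_probs": self.ki67_probs,
            "her2_probs": self.her2_probs,
            "grading_probs": self.grading_probs,
            "true_params": self.true_params.to_dict(),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["true_params"] = CMParameters.from_dict(d["true_params"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _diameter_law_from_t_split() -> tuple[float, float]:
    """(mu, sigma) of ln D from P(D<=20), P(D<=50); truncation barely moves them."""
    z1 = stats.norm.ppf(_P_T1)
    z2 = stats.norm.ppf(_P_T1 + _P_T2)
    sigma = (math.log(50.0) - math.log(20.0)) / (z2 - z1)
    mu = math.log(20.0) - z1 * sigma
    return mu, sigma


#: Ground-truth level multipliers of the default generative law. Directions
#: mirror the study population's within-level positivity gradients (peak in
#: the 41-50 age band, higher risk for lobular histology and graded tumors,
#: lower for receptor-negative disease); magnitudes are a design choice.
_DEFAULT_TRUE_G: dict[str, dict[str, float]] = {
    "age": {
        "21-30": 1.0, "31-40": 1.1, "41-50": 1.4, "51-60": 1.0,
        "61-70": 0.75, "71-80": 0.65, "81-90": 0.65, ">90": 1.0,
    },
    "histology": {"ductal": 0.95, "lobular": 1.45},
    "er": {"pos": 1.05, "neg": 0.55},
    "pr": {"pos": 1.05, "neg": 0.7},
    "grading": {"G1": 1.55, "G2": 1.35, "G3": 1.3},
}

#: Table-1 marginal probabilities (printed counts / 993).
_DEFAULT_MARGINALS = {
    "age_probs": {
        "21-30": 2 / 993, "31-40": 61 / 993, "41-50": 258 / 993, "51-60": 292 / 993,
        "61-70": 239 / 993, "71-80": 126 / 993, "81-90": 14 / 993, ">90": 1 / 993,
    },
    "histology_probs": {"ductal": 718 / 993, "lobular": 64 / 993, UNKNOWN: 211 / 993},
    "er_probs": {"pos": 872 / 993, "neg": 121 / 993},
    "pr_probs": {"pos": 759 / 993, "neg": 234 / 993},
    "ki67_probs": {"pos": 329 / 993, "neg": 664 / 993},
    "her2_probs": {"pos": 117 / 993, "neg": 870 / 993, UNKNOWN: 6 / 993},
    "grading_probs": {"1": 106 / 993, "2": 176 / 993, "3": 115 / 993, UNKNOWN: 596 / 993},
}

_AGE_SAMPLE_RANGES = {
    "21-30": (21, 30), "31-40": (31, 40), "41-50": (41, 50), "51-60": (51, 60),
    "61-70": (61, 70), "71-80": (71, 80), "81-90": (81, 90), ">90": (91, 99),
}


def _factor_level_probs(config: CohortConfig, factor: str) -> dict[str, float]:
    """Marginal law of a scheme factor's levels (incl. unknown) under the config."""
    if factor == "age":
        return dict(config.age_probs)
    if factor == "grading":
        out = {}
        for code, p in config.grading_probs.items():
            out[UNKNOWN if code == UNKNOWN else f"G{code}"] = p
        return out
    return dict(getattr(config, f"{factor}_probs"))


def _diameter_quadrature(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Gauss–Legendre nodes/weights for E over the truncated log-normal D."""
    mu = math.log(config.diameter_median_mm)
    sigma = config.diameter_sigma
    f_max = stats.norm.cdf((math.log(config.diameter_max_mm) - mu) / sigma)
    x, w = np.polynomial.legendre.leggauss(_QUAD_NODES)
    u = 0.5 * f_max * (x + 1.0)  # map [-1,1] -> (0, F(max))
    d = np.exp(mu + sigma * stats.norm.ppf(u))
    return d, w * 0.5  # weights sum to 1 over the truncated law


def expected_prevalence(config: CohortConfig, params: CMParameters | None = None) -> float:
    """Exact expected positive-node rate of the generative law.

    Enumerates every combination of factor levels (covariates are independent)
    and integrates over the diameter law by quadrature.
    """
    if params is None:
        params = config.true_params
    d, w = _diameter_quadrature(config)

    # distribution of the total multiplier: product over independent factors
    mult_vals = np.array([1.0])
    mult_probs = np.array([1.0])
    for factor in params.scheme.factors:
        probs = _factor_level_probs(config, factor)
        g_vals, g_probs = [], []
        for level, p in probs.items():
            g_vals.append(1.0 if level == UNKNOWN else params.g[factor][level])
            g_probs.append(p)
        mult_vals = np.outer(mult_vals, g_vals).ravel()
        mult_probs = np.outer(mult_probs, g_probs).ravel()

    x = params.qn * np.outer(mult_vals, d ** params.z)
    probs = -np.expm1(-x)
    return float(mult_probs @ probs @ w)


def calibrate_qn(config: CohortConfig, target: float = STUDY_PREVALENCE) -> CohortConfig:
    """Rescale the ground-truth Q so the expected prevalence equals ``target``."""

    def f(qn: float) -> float:
        trial = replace(config, true_params=replace(config.true_params, qn=qn))
        return expected_prevalence(trial) - target

    lo, hi = 1e-8, 1.0
    while f(hi) < 0:
        hi *= 4
    qn = brentq(f, lo, hi, xtol=1e-14, rtol=1e-14)
    return replace(config, true_params=replace(config.true_params, qn=float(qn)))


def default_config(n: int = STUDY_N, seed: int = 0) -> CohortConfig:
    """Study-shaped defaults: published marginals, risk law calibrated to 20.95%."""
    mu, sigma = _diameter_law_from_t_split()
    scheme = FactorScheme(factors=BASE_FACTORS, age_bins=DEFAULT_AGE_BINS)
    params = CMParameters(qn=0.01, z=1.0, scheme=scheme,
                          g={f: dict(_DEFAULT_TRUE_G[f]) for f in scheme.factors})
    config = CohortConfig(
        n=n,
        seed=seed,
        diameter_median_mm=math.exp(mu),
        diameter_sigma=sigma,
        diameter_max_mm=120.0,
        true_params=params,
        **_DEFAULT_MARGINALS,
    )
    return calibrate_qn(config)


#: Published per-factor counts of the study population as
#: (record value, total patients, node-positive patients) triples.
#: Age bins are represented by a mid-bin age, tumor-size categories by a
#: mid-category diameter.
_STUDY_COUNTS: dict[str, list[tuple[object, int, int]]] = {
    "age": [(25, 2, 0), (35, 61, 14), (45, 258, 73), (55, 292, 62),
            (65, 239, 39), (75, 126, 18), (85, 14, 2), (95, 1, 0)],
    "diameter": [(10.0, 748, 130), (30.0, 231, 69), (60.0, 14, 9)],
    "histology": [("ductal", 718, 129), ("lobular", 64, 17), (UNKNOWN, 211, 62)],
    "er": [("neg", 121, 16), ("pos", 872, 192)],
    "pr": [("neg", 234, 39), ("pos", 759, 169)],
    "ki67": [("neg", 664, 132), ("pos", 329, 76)],
    "her2": [("neg", 870, 180), ("pos", 117, 26), (UNKNOWN, 6, 2)],
    "grading": [("1", 106, 32), ("2", 176, 47), ("3", 115, 30), (UNKNOWN, 596, 99)],
}


def reference_cohort() -> list[PatientRecord]:
    """Deterministic synthetic cohort reproducing the study's per-factor counts.

    Each prognostic factor's marginal distribution — level totals and
    node-positive counts — matches the published study population exactly
    (993 patients, 208 node-positive). The joint distribution is artificial:
    factor values are assigned independently within the positive and negative
    groups, so only per-factor summaries are meaningful. Ages and diameters
    are mid-bin representatives.
    """
    n_total, n_pos = STUDY_N, 208
    pos_vals: dict[str, list] = {}
    neg_vals: dict[str, list] = {}
    for factor, triples in _STUDY_COUNTS.items():
        assert sum(t for _, t, _ in triples) == n_total
        assert sum(p for _, _, p in triples) == n_pos
        pos_vals[factor] = [v for v, _, p in triples for _ in range(p)]
        neg_vals[factor] = [v for v, t, p in triples for _ in range(t - p)]
    records = []
    for group, vals, label in (("pos", pos_vals, 1), ("neg", neg_vals, 0)):
        for i in range(len(vals["age"])):
            records.append(
                PatientRecord(
                    patient_id=f"R{group}{i:04d}",
                    age=vals["age"][i],
                    diameter=vals["diameter"][i],
                    histology=vals["histology"][i],
                    er=vals["er"][i],
                    pr=vals["pr"][i],
                    ki67=vals["ki67"][i],
                    her2=vals["her2"][i],
                    grading=vals["grading"][i],
                    node_status=label,
                )
            )
    return records


def _draw_categorical(rng: np.random.Generator, probs: dict[str, float], n: int) -> np.ndarray:
    levels = list(probs)
    p = np.array([probs[k] for k in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(np.array(levels, dtype=object), size=n, p=p)


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Draw a cohort: independent covariates, outcome from the true risk law."""
    rng = np.random.default_rng(config.seed)
    n = config.n

    age_bins = _draw_categorical(rng, config.age_probs, n)
    ages = np.empty(n, dtype=int)
    for label, (lo, hi) in _AGE_SAMPLE_RANGES.items():
        mask = age_bins == label
        ages[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))

    mu = math.log(config.diameter_median_mm)
    sigma = config.diameter_sigma
    f_max = stats.norm.cdf((math.log(config.diameter_max_mm) - mu) / sigma)
    u = rng.uniform(0.0, f_max, size=n)
    diameters = np.exp(mu + sigma * stats.norm.ppf(u))

    histology = _draw_categorical(rng, config.histology_probs, n)
    er = _draw_categorical(rng, config.er_probs, n)
    pr = _draw_categorical(rng, config.pr_probs, n)
    ki67 = _draw_categorical(rng, config.ki67_probs, n)
    her2 = _draw_categorical(rng, config.her2_probs, n)
    grading = _draw_categorical(rng, config.grading_probs, n)

    records = [
        PatientRecord(
            patient_id=f"P{i:06d}",
            age=int(ages[i]),
            diameter=float(diameters[i]),
            histology=str(histology[i]),
            er=str(er[i]),
            pr=str(pr[i]),
            ki67=str(ki67[i]),
            her2=str(her2[i]),
            grading=str(grading[i]),
            node_status=0,
        )
        for i in range(n)
    ]
    probs = CohortMatrix(records, config.true_params.scheme).predict(config.true_params)
    nodes = rng.binomial(1, probs)
    return [replace(r, node_status=int(s)) for r, s in zip(records, nodes)]
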