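"""The multiplicative exponential lymph-node positivity model.

The probability that a clinically node-negative patient has a positive
sentinel lymph node is modelled as

    L = 1 - exp(-Q * g_1 * g_2 * ... * g_k * D**Z)

where D is the primary-tumor diameter in mm, Z is a fixed exponent (1 for
nodal involvement), Q is a population-level interpolation parameter, and each
g_i is the multiplier of the level the patient occupies in one declared
prognostic factor (age band, histology, ER, PR, grade, optionally HER2 and
Ki67). A factor whose value is missing contributes a neutral multiplier of 1,
so a prediction is always available.

The probability is strictly below 1 for finite parameters; inputs that would
overflow the exponent raise :class:`~slncalc.errors.ModelOverflowError`
instead of silently saturating.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort import UNKNOWN, FactorScheme, PatientRecord, map_to_levels
from .errors import ConfigurationError, ModelOverflowError

#: Exponent arguments above this would make 1-exp(-x) indistinguishable from 1.
EXP_OVERFLOW = 700.0


@dataclass(frozen=True)
class CMParameters:
    """Fitted model parameters: Q, per-(factor, level) multipliers g, exponent Z.

    ``g`` maps factor name -> {level label -> multiplier}. Every non-unknown
    level of every scheme factor must have an entry; the reserved level
    ``"unknown"`` is implicitly 1 and must not appear.
    """

    qn: float
    g: dict[str, dict[str, float]]
    scheme: FactorScheme
    z: float = 1.0

    def __post_init__(self) -> None:
        if not self.qn > 0:
            raise ConfigurationError(f"qn must be > 0, got {self.qn}")
        for factor in self.scheme.factors:
            levels = self.scheme.levels(factor)
            got = self.g.get(factor)
            if got is None or set(got) != set(levels):
                raise ConfigurationError(
                    f"g must declare exactly the levels {levels} for factor {factor!r}"
                )
            for lev, val in got.items():
                if not val > 0:
                    raise ConfigurationError(f"g[{factor!r}][{lev!r}] must be > 0, got {val}")
        extra = set(self.g) - set(self.scheme.factors)
        if extra:
            raise ConfigurationError(f"g declares factors absent from the scheme: {sorted(extra)}")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "qn": self.qn,
            "z": self.z,
            "g": {f: dict(levels) for f, levels in self.g.items()},
            "scheme": self.scheme.to_dict(),
            "scheme_fingerprint": self.scheme.fingerprint(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CMParameters":
        scheme = FactorScheme.from_dict(d["scheme"])
        fp = d.get("scheme_fingerprint")
        if fp is not None and fp != scheme.fingerprint():
            raise ConfigurationError("scheme fingerprint mismatch in parameter document")
        return cls(qn=float(d["qn"]), z=float(d["z"]),
                   g={f: {k: float(v) for k, v in levels.items()} for f, levels in d["g"].items()},
                   scheme=scheme)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CMParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


def neutral_parameters(scheme: FactorScheme, qn: float, z: float = 1.0) -> CMParameters:
    """Parameters with every multiplier at 1 (the phase-1 baseline)."""
    return CMParameters(
        qn=qn, z=z, scheme=scheme,
        g={f: {lev: 1.0 for lev in scheme.levels(f)} for f in scheme.factors},
    )


def predict_probability(params: CMParameters, record: PatientRecord) -> float:
    """Positivity probability L for one patient; always in [0, 1)."""
    levels = map_to_levels(record, params.scheme)
    prod = 1.0
    for factor in params.scheme.factors:
        lev = levels[factor]
        if lev != UNKNOWN:
            prod *= params.g[factor][lev]
    x = params.qn * prod * record.diameter ** params.z
    if x > EXP_OVERFLOW:
        raise ModelOverflowError(
            f"exponent argument {x:.3g} overflows for patient {record.patient_id!r}"
        )
    return -math.expm1(-x)


def score_cohort(
    params: CMParameters, cohort: Sequence[PatientRecord]
) -> list[tuple[str, float]]:
    """Element-wise model scores, order preserved, as (patient_id, probability)."""
    out = []
    for record in cohort:
        try:
            out.append((record.patient_id, predict_probability(params, record)))
        except (ModelOverflowError, ConfigurationError) as exc:
            raise type(exc)(f"patient {record.patient_id!r}: {exc}") from exc
    return out


# --------------------------------------------------------------------------
# Vectorized internal representation (used by fitting and cross-validation)
# --------------------------------------------------------------------------

class CohortMatrix:
    """Array view of a cohort under a scheme: diameters, labels, level codes.

    Level codes per factor index into ``scheme.levels(factor)``; the reserved
    code -1 means unknown. Construction performs the same record-to-level
    mapping the scalar path uses, so both paths agree by construction.
    """

    def __init__(self, cohort: Sequence[PatientRecord], scheme: FactorScheme):
        self.scheme = scheme
        self.n = len(cohort)
        self.patient_ids = [r.patient_id for r in cohort]
        self.diameters = np.array([r.diameter for r in cohort], dtype=float)
        self.labels = np.array([r.node_status for r in cohort], dtype=int)
        self.codes: dict[str, np.ndarray] = {}
        lookup = {
            f: {lev: i for i, lev in enumerate(scheme.levels(f))} for f in scheme.factors
        }
        mapped = [map_to_levels(r, scheme) for r in cohort]
        for f in scheme.factors:
            self.codes[f] = np.array(
                [lookup[f].get(m[f], -1) for m in mapped], dtype=int
            )

    def subset(self, idx: np.ndarray) -> "CohortMatrix":
        out = object.__new__(CohortMatrix)
        out.scheme = self.scheme
        positions = np.arange(self.n)[idx] if idx.dtype == bool else np.asarray(idx)
        out.patient_ids = [self.patient_ids[i] for i in positions]
        out.diameters = self.diameters[idx]
        out.labels = self.labels[idx]
        out.codes = {f: c[idx] for f, c in self.codes.items()}
        out.n = out.diameters.size
        return out

    def g_product(self, params: CMParameters) -> np.ndarray:
        prod = np.ones(self.n)
        for f in self.scheme.factors:
            vals = np.array([params.g[f][lev] for lev in self.scheme.levels(f)] + [1.0])
            prod *= vals[self.codes[f]]  # code -1 picks the trailing neutral 1
        return prod

    def predict(self, params: CMParameters) -> np.ndarray:
        x = params.qn * self.g_product(params) * self.diameters ** params.z
        if np.any(x > EXP_OVERFLOW):
            bad = int(np.argmax(x))
            raise ModelOverflowError(f"exponent argument {x[bad]:.3g} overflows at index {bad}")
        return -np.expm1(-x)
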