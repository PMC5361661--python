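"""Virtual patient sampling.

Inter-individual variability is multiplicative and log-normal: every
clearance and every volume of the typical parameter set is multiplied by
an independent patient-specific factor exp(eps), eps ~ Normal(-s^2/2, s^2)
with s^2 = ln(1 + CV^2), so each factor has mean exactly 1.  One CV is
shared by all clearances and one by all volumes.  Draws depend only on
(seed, n), not on the phenotype, so cohorts of different phenotypes built
from the same seed share their factors (common random numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (CLEARANCE_FIELDS, VOLUME_FIELDS, InputError,
                     NetworkParams, ParameterSet, PHENOTYPES)

__all__ = ["PopulationSpec", "Individual", "sample_population",
           "sample_factors", "population_for", "population_frame",
           "population_from_frame"]

_VARIABLE_FIELDS = CLEARANCE_FIELDS + VOLUME_FIELDS


@dataclass(frozen=True)
class PopulationSpec:
    n: int
    phenotype: str
    cv_clearance: float
    cv_volume: float
    seed: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InputError(f"population size must be >= 1, got {self.n}")
        if self.phenotype not in PHENOTYPES:
            raise InputError(f"unknown phenotype {self.phenotype!r}")
        if self.cv_clearance < 0 or self.cv_volume < 0:
            raise InputError("CVs must be non-negative")


@dataclass(frozen=True)
class Individual:
    patient_id: int
    phenotype: str
    theta: float
    params: NetworkParams


def _sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def sample_factors(n: int, cv_clearance: float, cv_volume: float,
                   seed: int) -> pd.DataFrame:
    """Per-patient multiplicative factors, one column per variable parameter.

    Mean-1 log-normal, independent across patients and parameters.  One
    child RNG stream per parameter keyed on (seed, parameter index), so
    cohorts are nested: the first m patients of a size-n cohort (m < n)
    are identical to the size-m cohort from the same seed.  Identical
    (seed, n, CVs) give bit-identical draws.
    """
    cols = {}
    for group_fields, cv in ((CLEARANCE_FIELDS, cv_clearance),
                             (VOLUME_FIELDS, cv_volume)):
        s = _sigma(cv)
        for name in group_fields:
            rng = np.random.default_rng(
                np.random.SeedSequence((seed, _VARIABLE_FIELDS.index(name))))
            cols[name] = np.exp(rng.normal(-0.5 * s * s, s, size=n))
    return pd.DataFrame(cols, index=pd.RangeIndex(n, name="patient_id"))


def sample_population(spec: PopulationSpec, typical: NetworkParams,
                      theta: float) -> list[Individual]:
    """Sample ``spec.n`` virtual patients around the typical parameters."""
    factors = sample_factors(spec.n, spec.cv_clearance, spec.cv_volume, spec.seed)
    out = []
    for pid in range(spec.n):
        row = factors.iloc[pid]
        realized = typical.scaled({f: float(row[f]) for f in _VARIABLE_FIELDS})
        out.append(Individual(pid, spec.phenotype, theta, realized))
    return out


def population_for(ps: ParameterSet, phenotype: str, n: int,
                   seed: int) -> list[Individual]:
    """Convenience: sample a cohort using a calibrated parameter set."""
    spec = PopulationSpec(n, phenotype, ps.cv_clearance, ps.cv_volume, seed)
    return sample_population(spec, ps.network, ps.activity(phenotype).theta)


def population_frame(population: list[Individual]) -> pd.DataFrame:
    """One row per patient, one column per realized parameter (audit export)."""
    rows = []
    for ind in population:
        row = {"patient_id": ind.patient_id, "phenotype": ind.phenotype,
               "theta": ind.theta}
        row.update(ind.params.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def population_from_frame(df: pd.DataFrame) -> list[Individual]:
    """Inverse of :func:`population_frame` (reproducibility audits)."""
    param_fields = [f for f in NetworkParams.__dataclass_fields__]
    missing = set(param_fields + ["patient_id", "phenotype", "theta"]) - set(df)
    if missing:
        raise InputError(f"population frame is missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        params = NetworkParams(**{f: float(row[f]) for f in param_fields})
        out.append(Individual(int(row["patient_id"]), str(row["phenotype"]),
                              float(row["theta"]), params))
    return out
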