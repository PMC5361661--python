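"""Parameter containers for the reduced tamoxifen metabolic-cascade model.

The model tracks four compounds in plasma — tamoxifen (TAM),
N-desmethyltamoxifen (NDM), 4-hydroxytamoxifen (4OH) and endoxifen (END) —
each as a single well-stirred compartment, plus first-order oral depots for
the two dosable compounds (TAM, END).  Formation pathways:

    TAM --CYP3A4--> NDM --CYP2D6--> END
    TAM --CYP2D6--> 4OH --CYP3A4--> END

CYP2D6-mediated formation clearances are scaled by a phenotype-specific
activity multiplier theta (EM reference = 1).  Every other route out of a
compartment is lumped into a non-pathway elimination clearance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

__all__ = [
    "ParameterError",
    "InputError",
    "NumericalError",
    "NetworkParams",
    "CYP2D6Activity",
    "ParameterSet",
    "PHENOTYPES",
    "CLEARANCE_FIELDS",
    "VOLUME_FIELDS",
    "load_parameter_set",
    "save_parameter_set",
    "default_parameter_set",
]

PHENOTYPES = ("EM", "IM", "PM")

PARAMS_SCHEMA_VERSION = 1


class ParameterError(ValueError):
    """A kinetic parameter violates its physical constraints."""


class InputError(ValueError):
    """Invalid user input (dose events, population spec, ...)."""


class NumericalError(RuntimeError):
    """A numerical routine failed; message carries diagnostics."""


@dataclass(frozen=True)
class NetworkParams:
    """Typical kinetic parameters of the four-compound cascade.

    Units: absorption rate constants 1/day, bioavailabilities
    dimensionless, volumes L, clearances L/day.
    """

    ka_TAM: float
    ka_END: float
    F_TAM: float
    F_END: float
    V_TAM: float
    V_NDM: float
    V_4OH: float
    V_END: float
    CLf_TAM_NDM: float   # CYP3A4
    CLf_TAM_4OH: float   # CYP2D6, theta-scaled
    CLf_NDM_END: float   # CYP2D6, theta-scaled
    CLf_4OH_END: float   # CYP3A4
    CLe_TAM: float
    CLe_NDM: float
    CLe_4OH: float
    CLe_END: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v == v) or v < 0:  # NaN or negative
                raise ParameterError(f"{f.name} must be non-negative, got {v}")
        for name in ("ka_TAM", "ka_END", "V_TAM", "V_NDM", "V_4OH", "V_END",
                     "CLe_TAM", "CLe_NDM", "CLe_4OH", "CLe_END"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        for name in ("F_TAM", "F_END"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ParameterError(f"{name} must be in (0, 1], got {v}")

    def scaled(self, factors: dict[str, float]) -> "NetworkParams":
        """Return a copy with each named field multiplied by its factor."""
        return replace(self, **{k: getattr(self, k) * f for k, f in factors.items()})

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


CLEARANCE_FIELDS = (
    "CLf_TAM_NDM", "CLf_TAM_4OH", "CLf_NDM_END", "CLf_4OH_END",
    "CLe_TAM", "CLe_NDM", "CLe_4OH", "CLe_END",
)
VOLUME_FIELDS = ("V_TAM", "V_NDM", "V_4OH", "V_END")


@dataclass(frozen=True)
class CYP2D6Activity:
    """CYP2D6 phenotype and its activity multiplier (EM reference = 1)."""

    phenotype: str
    theta: float

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ParameterError(f"unknown phenotype {self.phenotype!r}")
        if not self.theta >= 0:
            raise ParameterError(f"theta must be >= 0, got {self.theta}")
        if self.phenotype == "EM" and self.theta != 1.0:
            raise ParameterError("EM is the reference phenotype: theta must be 1")


@dataclass(frozen=True)
class ParameterSet:
    """A versioned calibrated model: typical kinetics, phenotype activity
    multipliers, and population variability magnitudes."""

    network: NetworkParams
    theta_IM: float
    theta_PM: float
    cv_clearance: float
    cv_volume: float
    version: str = "unversioned"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1.0 > self.theta_IM > self.theta_PM >= 0.0:
            raise ParameterError(
                "phenotype ordering requires 1 > theta_IM > theta_PM >= 0, got "
                f"theta_IM={self.theta_IM}, theta_PM={self.theta_PM}")
        if self.cv_clearance < 0 or self.cv_volume < 0:
            raise ParameterError("CVs must be non-negative")

    def activity(self, phenotype: str) -> CYP2D6Activity:
        theta = {"EM": 1.0, "IM": self.theta_IM, "PM": self.theta_PM}[phenotype]
        return CYP2D6Activity(phenotype, theta)

    def to_dict(self) -> dict:
        return {
            "schema_version": PARAMS_SCHEMA_VERSION,
            "version": self.version,
            "network": self.network.to_dict(),
            "theta_IM": float(self.theta_IM),
            "theta_PM": float(self.theta_PM),
            "cv_clearance": float(self.cv_clearance),
            "cv_volume": float(self.cv_volume),
            "provenance": dict(self.provenance),
        }

    def checksum(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def save_parameter_set(ps: ParameterSet, path: str | Path) -> None:
    doc = ps.to_dict()
    doc["checksum"] = ps.checksum()
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_parameter_set(path: str | Path) -> ParameterSet:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "network" not in doc:
        raise InputError(f"{path}: not a parameter-set file")
    if doc.get("schema_version") != PARAMS_SCHEMA_VERSION:
        raise InputError(f"{path}: unsupported schema_version "
                         f"{doc.get('schema_version')!r}")
    ps = ParameterSet(
        network=NetworkParams(**doc["network"]),
        theta_IM=doc["theta_IM"],
        theta_PM=doc["theta_PM"],
        cv_clearance=doc["cv_clearance"],
        cv_volume=doc["cv_volume"],
        version=doc.get("version", "unversioned"),
        provenance=doc.get("provenance", {}),
    )
    stored = doc.get("checksum")
    if stored is not None and stored != ps.checksum():
        raise InputError(f"{path}: checksum mismatch (file edited by hand?)")
    return ps


def default_parameter_set() -> ParameterSet:
    """The calibrated parameter set shipped with the package."""
    path = Path(__file__).parent / "data" / "default_params.yaml"
    return load_parameter_set(path)
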