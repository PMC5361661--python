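"""Trial arms and dose-event streams.

Twenty arms in two study groups. Group A (4 arms) compares time to
endoxifen steady state from treatment start: EM and IM strata, each with a
case arm on the 20 mg TAM + 3 mg END loading combination and a control arm
on the stratum's reference regimen (EM: 20 mg TAM; IM: 20 mg TAM + 1 mg
END). Group B (16 arms) inserts a drug holiday of 2/4/8/12 weeks after a
24-week run-in on the reference regimen, then resumes either the reference
regimen (controls) or the 20 mg TAM + 3 mg END combination (cases).

Calendar convention: day 1 is the first dose day; one instantaneous dose
per day; the run-in covers days 1..168; the first post-holiday dose falls
on day 168 + 7*holiday_weeks, so the pre-dose trough that day is sampled
exactly 7*holiday_weeks days after the last run-in dose.  Dosing continues
through day 364 + 7*holiday_weeks ("12 months of intake").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .params import InputError

__all__ = [
    "DoseEvent",
    "Protocol",
    "ArmSpec",
    "REGIMENS",
    "RUN_IN_DAYS",
    "BASE_HORIZON_DAYS",
    "build_protocol",
    "enumerate_arms",
    "protocol_frame",
]

RUN_IN_DAYS = 168          # 24 weeks on the reference regimen
BASE_HORIZON_DAYS = 364    # 12 months of dosing (52 weeks)

# the only regimens used anywhere in the trial: daily mg per compound
REGIMENS: dict[str, dict[str, float]] = {
    "20TAM": {"TAM": 20.0},
    "20TAM+1END": {"TAM": 20.0, "END": 1.0},
    "20TAM+3END": {"TAM": 20.0, "END": 3.0},
}

_REFERENCE = {"EM": "20TAM", "IM": "20TAM+1END", "PM": "20TAM+3END"}
_LOADING = "20TAM+3END"


@dataclass(frozen=True)
class DoseEvent:
    time: float        # days; dose at the daily trough-sampling reference time
    compound: str      # "TAM" or "END"
    amount: float      # mg

    def __post_init__(self) -> None:
        if self.time < 0:
            raise InputError("dose time must be >= 0")
        if not self.amount > 0:
            raise InputError("dose amount must be > 0")


@dataclass(frozen=True)
class ArmSpec:
    group: str           # "A" or "B"
    phenotype: str       # "EM" or "IM"
    role: str            # "case" or "control"
    holiday_weeks: int   # 0 for group A; 2/4/8/12 for group B
    run_in_regimen: str
    post_regimen: str

    def __post_init__(self) -> None:
        if self.group not in ("A", "B"):
            raise InputError(f"unknown group {self.group!r}")
        if self.role not in ("case", "control"):
            raise InputError(f"unknown role {self.role!r}")
        if self.group == "A" and self.holiday_weeks != 0:
            raise InputError("group A arms have no drug holiday")
        if self.group == "B" and self.holiday_weeks not in (0, 2, 4, 8, 12):
            raise InputError("group B holidays are 2, 4, 8 or 12 weeks")
        for reg in (self.run_in_regimen, self.post_regimen):
            if reg not in REGIMENS:
                raise InputError(f"unknown regimen {reg!r}")

    @property
    def arm_id(self) -> str:
        if self.group == "A":
            return f"A-{self.phenotype}-{self.role}"
        return f"B-{self.phenotype}-{self.role}-{self.holiday_weeks}wk"


@dataclass(frozen=True)
class Protocol:
    """An ordered dose-event stream with its phase boundaries."""

    arm_id: str
    events: tuple[DoseEvent, ...]
    run_in_end_day: int      # last run-in dose day (== horizon for group A)
    holiday_end_day: int     # last dose-free day; == run_in_end_day if no holiday
    horizon_day: int         # last dose day
    start_day: int = 1       # reference day for time-to-target counting
    meta: dict = field(default_factory=dict)

    def dose_days(self) -> set[int]:
        return {int(e.time) for e in self.events}


def _daily_events(regimen: str, first_day: int, last_day: int) -> list[DoseEvent]:
    out = []
    for day in range(first_day, last_day + 1):
        for compound, mg in REGIMENS[regimen].items():
            out.append(DoseEvent(float(day), compound, mg))
    return out


def build_protocol(spec: ArmSpec) -> Protocol:
    """Expand an arm spec into its daily dose-event stream."""
    if spec.group == "A" or spec.holiday_weeks == 0:
        # degenerate-holiday group B pathway collapses to continuous dosing
        horizon = BASE_HORIZON_DAYS
        if spec.group == "A":
            events = _daily_events(spec.post_regimen, 1, horizon)
        else:
            events = (_daily_events(spec.run_in_regimen, 1, RUN_IN_DAYS)
                      + _daily_events(spec.post_regimen, RUN_IN_DAYS + 1, horizon))
        return Protocol(spec.arm_id, tuple(events), run_in_end_day=RUN_IN_DAYS
                        if spec.group == "B" else horizon,
                        holiday_end_day=RUN_IN_DAYS if spec.group == "B" else horizon,
                        horizon_day=horizon, start_day=1,
                        meta={"spec": spec})
    gap = 7 * spec.holiday_weeks
    restart_day = RUN_IN_DAYS + gap            # first post-holiday dose day
    horizon = BASE_HORIZON_DAYS + gap
    events = (_daily_events(spec.run_in_regimen, 1, RUN_IN_DAYS)
              + _daily_events(spec.post_regimen, restart_day, horizon))
    return Protocol(spec.arm_id, tuple(events),
                    run_in_end_day=RUN_IN_DAYS,
                    holiday_end_day=restart_day - 1,
                    horizon_day=horizon,
                    start_day=restart_day,
                    meta={"spec": spec})


def enumerate_arms() -> list[ArmSpec]:
    """The 20 arms of the virtual trial: 4 in group A, 16 in group B."""
    arms: list[ArmSpec] = []
    for phenotype in ("EM", "IM"):
        ref = _REFERENCE[phenotype]
        arms.append(ArmSpec("A", phenotype, "case", 0, _LOADING, _LOADING))
        arms.append(ArmSpec("A", phenotype, "control", 0, ref, ref))
    for phenotype in ("EM", "IM"):
        ref = _REFERENCE[phenotype]
        for weeks in (2, 4, 8, 12):
            arms.append(ArmSpec("B", phenotype, "case", weeks, ref, _LOADING))
            arms.append(ArmSpec("B", phenotype, "control", weeks, ref, ref))
    return arms


def arm_registry() -> list[dict]:
    """JSON-ready registry of the 20 arm definitions."""
    return [{"arm_id": s.arm_id, "group": s.group, "phenotype": s.phenotype,
             "role": s.role, "holiday_weeks": s.holiday_weeks,
             "run_in_regimen": s.run_in_regimen,
             "post_regimen": s.post_regimen} for s in enumerate_arms()]


def protocol_frame(protocol: Protocol) -> pd.DataFrame:
    """Event-list export: time_day, compound, amount_mg."""
    return pd.DataFrame({
        "time_day": [e.time for e in protocol.events],
        "compound": [e.compound for e in protocol.events],
        "amount_mg": [e.amount for e in protocol.events],
    })
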