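"""Linear kinetic core: rate matrix, exact propagation, and an ODE oracle.

The cascade is a linear time-invariant system, so between dose events the
state evolves by a matrix exponential and doses superpose.  ``simulate`` is
the production path (exact propagators, cached per step length);
``ode_oracle`` re-computes the same contract by adaptive numeric
integration and exists to cross-check ``simulate``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .params import CYP2D6Activity, InputError, NetworkParams, NumericalError

__all__ = [
    "COMPOUNDS",
    "DOSABLE",
    "N_STATES",
    "STATE_LABELS",
    "build_rate_matrix",
    "simulate",
    "ode_oracle",
    "ConcTimeSeries",
]

COMPOUNDS = ("TAM", "NDM", "4OH", "END")
DOSABLE = ("TAM", "END")
# state ordering: oral depots first, then central compartments
STATE_LABELS = ("depot_TAM", "depot_END", "TAM", "NDM", "4OH", "END")
N_STATES = 6
_DEPOT_INDEX = {"TAM": 0, "END": 1}
_CENTRAL = slice(2, 6)


def build_rate_matrix(params: NetworkParams, activity: CYP2D6Activity) -> np.ndarray:
    """First-order rate matrix A (1/day) with dA/dt = A @ amounts.

    Depot -> central transfer carries the bioavailability F (the remainder
    is never absorbed); CYP2D6-mediated formation clearances are scaled by
    ``activity.theta``.
    """
    th = activity.theta
    p = params
    A = np.zeros((N_STATES, N_STATES))
    # oral depots
    A[0, 0] = -p.ka_TAM
    A[2, 0] = p.ka_TAM * p.F_TAM
    A[1, 1] = -p.ka_END
    A[5, 1] = p.ka_END * p.F_END
    # TAM central
    k_tam_ndm = p.CLf_TAM_NDM / p.V_TAM
    k_tam_4oh = th * p.CLf_TAM_4OH / p.V_TAM
    A[2, 2] = -(k_tam_ndm + k_tam_4oh + p.CLe_TAM / p.V_TAM)
    A[3, 2] = k_tam_ndm
    A[4, 2] = k_tam_4oh
    # NDM central
    k_ndm_end = th * p.CLf_NDM_END / p.V_NDM
    A[3, 3] = -(k_ndm_end + p.CLe_NDM / p.V_NDM)
    A[5, 3] = k_ndm_end
    # 4OH central
    k_4oh_end = p.CLf_4OH_END / p.V_4OH
    A[4, 4] = -(k_4oh_end + p.CLe_4OH / p.V_4OH)
    A[5, 4] = k_4oh_end
    # END central: elimination only
    A[5, 5] = -p.CLe_END / p.V_END
    return A


@dataclass(frozen=True)
class ConcTimeSeries:
    """Plasma concentrations (ug/L) of the four compounds on a time grid (days)."""

    times: np.ndarray           # (T,)
    concentrations: np.ndarray  # (T, 4) ordered as COMPOUNDS

    def __post_init__(self) -> None:
        if self.concentrations.shape != (len(self.times), len(COMPOUNDS)):
            raise InputError("concentration array shape does not match time grid")

    def compound(self, name: str) -> np.ndarray:
        return self.concentrations[:, COMPOUNDS.index(name)]

    def to_frame(self, patient_id: int | None = None) -> pd.DataFrame:
        """Tidy export: time_day, compound, concentration_ug_per_L[, patient_id]."""
        frames = pd.DataFrame({
            "time_day": np.repeat(self.times, len(COMPOUNDS)),
            "compound": list(COMPOUNDS) * len(self.times),
            "concentration_ug_per_L": self.concentrations.reshape(-1),
        })
        if patient_id is not None:
            frames["patient_id"] = patient_id
        return frames


def _central_to_conc(states: np.ndarray, params: NetworkParams) -> np.ndarray:
    vols = np.array([params.V_TAM, params.V_NDM, params.V_4OH, params.V_END])
    return states[..., _CENTRAL] * 1000.0 / vols  # mg/L -> ug/L


def _check_events(events, horizon: float) -> list:
    evts = list(events)
    times = [e.time for e in evts]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise InputError("dose events must be sorted by time")
    for e in evts:
        if e.compound not in DOSABLE:
            raise InputError(f"cannot dose compound {e.compound!r}")
        if not e.amount > 0:
            raise InputError(f"dose amount must be positive, got {e.amount}")
        if e.time < 0:
            raise InputError("dose times must be >= 0")
    if evts and evts[-1].time > horizon:
        raise InputError("horizon must cover the last dose event")
    return evts


def simulate(
    params: NetworkParams,
    activity: CYP2D6Activity,
    events: Iterable,
    horizon: float,
    sample_times: Sequence[float],
) -> ConcTimeSeries:
    """Exact concentrations under a stream of oral bolus dose events.

    Doses are instantaneous additions to the compound's depot at the event
    time; between events the state advances by ``expm(A * dt)``.  A sample
    coinciding with a dose time is taken *before* the dose (trough
    convention).
    """
    sample_times = np.asarray(sample_times, dtype=float)
    if sample_times.ndim != 1:
        raise InputError("sample_times must be one-dimensional")
    if np.any(np.diff(sample_times) < 0):
        raise InputError("sample_times must be sorted")
    if len(sample_times) and (sample_times[0] < 0 or sample_times[-1] > horizon):
        raise InputError("sample_times must lie within [0, horizon]")
    evts = _check_events(events, horizon)

    A = build_rate_matrix(params, activity)
    prop_cache: dict[float, np.ndarray] = {}

    def advance(state: np.ndarray, dt: float) -> np.ndarray:
        if dt == 0.0:
            return state
        P = prop_cache.get(dt)
        if P is None:
            P = expm(A * dt)
            prop_cache[dt] = P
        return P @ state

    out = np.empty((len(sample_times), len(COMPOUNDS)))
    state = np.zeros(N_STATES)
    t = 0.0
    ei, si = 0, 0
    # merge walk over events and samples; samples at an event time precede the dose
    while si < len(sample_times) or ei < len(evts):
        t_next_sample = sample_times[si] if si < len(sample_times) else np.inf
        t_next_event = evts[ei].time if ei < len(evts) else np.inf
        t_next = min(t_next_sample, t_next_event)
        state = advance(state, t_next - t)
        t = t_next
        while si < len(sample_times) and sample_times[si] == t:
            out[si] = _central_to_conc(state, params)
            si += 1
        while ei < len(evts) and evts[ei].time == t:
            state[_DEPOT_INDEX[evts[ei].compound]] += evts[ei].amount
            ei += 1
    return ConcTimeSeries(sample_times, out)


def ode_oracle(
    params: NetworkParams,
    activity: CYP2D6Activity,
    events: Iterable,
    horizon: float,
    sample_times: Sequence[float],
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> ConcTimeSeries:
    """Independent verification path: adaptive ODE integration with event
    restarts.  Same contract as :func:`simulate`."""
    sample_times = np.asarray(sample_times, dtype=float)
    evts = _check_events(events, horizon)
    A = build_rate_matrix(params, activity)

    breakpoints = sorted({0.0, *(e.time for e in evts), *sample_times.tolist()})
    state = np.zeros(N_STATES)
    sampled: dict[float, np.ndarray] = {}
    t_prev = 0.0
    for t in breakpoints:
        if t > t_prev:
            sol = solve_ivp(lambda _, y: A @ y, (t_prev, t), state,
                            method="LSODA", rtol=rtol, atol=atol)
            if not sol.success:
                raise NumericalError(f"ODE integration failed on [{t_prev}, {t}]: "
                                     f"{sol.message}")
            state = sol.y[:, -1]
            t_prev = t
        if t in set(sample_times.tolist()):
            sampled[t] = _central_to_conc(state, params)
        for e in evts:
            if e.time == t:
                state[_DEPOT_INDEX[e.compound]] += e.amount
    out = np.array([sampled[t] for t in sample_times])
    if len(sample_times) == 0:
        out = out.reshape(0, len(COMPOUNDS))
    return ConcTimeSeries(sample_times, out)
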