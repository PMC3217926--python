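"""Behavioral criteria and transient-response statistics.

Eight criteria summarize one parameter set's behavior, each a dimensionless
fraction of the relevant total amount, evaluated at steady state:

====  =====================================================================
c1    Dok1:integrin complex formation after ligand stimulus
c2    talin:integrin complex formation after ligand stimulus
c3    PIPKI-dependent talin membrane recruitment
      (wild-type minus PIPKI-knock-out membrane talin) / total talin
c4    talin-dependent PIPKI membrane recruitment
      (wild-type minus talin-knock-out membrane PIPKI) / total PIPKI
c5    PIPKI phosphorylation after ligand stimulus
c6    integrin phosphorylation after ligand stimulus
c7    integrin activation by outside-in signaling (open fraction)
c8    integrin activation by inside-out signaling (open fraction)
====  =====================================================================

The printed formulas in the source text are corrupted; these are
reconstructions from the verbal definitions (see docs/methods.md).

Transient responses are characterized per observable by the sensitivity
``S = |X_peak - X_GS| / max(X_GS, eps)`` (peak searched within a 1 h window
after stimulation) and the precision
``P = |X_peak - X_GS| / max(|X_ss - X_GS|, eps)``: a transient response has
high S and high P (it returns towards baseline), a sustained response has
high S and P ~ 1.  Perfect adaptation saturates at the cap 1/eps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from . import simulate as sim
from .model import ModelSpec, knockout

__all__ = [
    "EPS",
    "P_CAP",
    "PEAK_WINDOW",
    "MONITORED",
    "CriteriaVector",
    "criteria_vector",
    "sensitivity",
    "precision",
    "run_battery",
]

EPS = 1e-6          # zero guard, fraction units
P_CAP = 1e6         # precision cap (= 1/EPS), reported for perfect adaptation
PEAK_WINDOW = 3600.0  # peak-search window for S and P [s]

#: observables monitored for S/P and for ensemble convergence
MONITORED = ["openINT", "INT_P", "INT_DOK", "INT_TAL", "TAL_PM", "PIPKI_PM"]

CRITERIA_NAMES = ["c1", "c2", "c3", "c4", "c5", "c6", "c7", "c8"]


@dataclass
class CriteriaVector:
    c: np.ndarray                      # the 8 criteria
    S: dict[str, float]                # sensitivity per monitored observable
    P: dict[str, float]                # precision per monitored observable
    valid: bool = True
    parameter_id: int | str | None = None

    def as_dict(self) -> dict[str, float]:
        out = {name: float(v) for name, v in zip(CRITERIA_NAMES, self.c)}
        for name, v in self.S.items():
            out[f"S_{name}"] = float(v)
        for name, v in self.P.items():
            out[f"P_{name}"] = float(v)
        out["valid"] = bool(self.valid)
        return out


def sensitivity(
    values: np.ndarray,
    times: np.ndarray,
    gs_value: float,
    window: float = PEAK_WINDOW,
    eps: float = EPS,
) -> float:
    """Peak deviation from the ground state, relative to the ground state."""
    mask = times <= window
    seg = values[mask]
    peak = seg[np.argmax(np.abs(seg - gs_value))]
    return abs(peak - gs_value) / max(abs(gs_value), eps)


def precision(
    values: np.ndarray,
    times: np.ndarray,
    gs_value: float,
    ss_value: float,
    window: float = PEAK_WINDOW,
    eps: float = EPS,
    cap: float = P_CAP,
) -> float:
    """Peak deviation relative to the sustained steady-state deviation.

    ``P = 1`` for a perfectly sustained response; large P marks adaptation
    (the response returns to baseline); capped at ``cap``.
    """
    mask = times <= window
    seg = values[mask]
    peak = seg[np.argmax(np.abs(seg - gs_value))]
    num = abs(peak - gs_value)
    den = abs(ss_value - gs_value)
    if den < eps * max(1.0, abs(gs_value)):
        return cap if num > 0 else 1.0
    return min(num / den, cap)


@dataclass
class BatteryResult:
    """The five protocol runs behind one criteria evaluation."""

    gs: np.ndarray
    gs_obs: np.ndarray
    oi: sim.Trajectory
    io: sim.Trajectory
    oi_tal_ko: sim.Trajectory
    oi_pipki_ko: sim.Trajectory


def run_battery(
    spec: ModelSpec,
    system: sim.RateSystem,
    params: Mapping[str, float],
    W: np.ndarray | None = None,
    oi_protocol: sim.Protocol | None = None,
) -> BatteryResult:
    """GS, OI, IO plus the two knock-out OI runs (each from its own GS)."""
    if W is None:
        W = spec.observable_matrix(system.network)
    oi_protocol = oi_protocol or sim.Protocol.oi()
    gs = sim.find_ground_state(spec, system, params)
    oi = sim.run_protocol(spec, system, params, oi_protocol, gs, W)
    io = sim.run_protocol(spec, system, params, sim.Protocol.io(), gs, W)

    kos = {}
    for mol in ("TAL", "PIPKI"):
        ko_spec = knockout(spec, mol)
        ko_params = dict(params)
        ko_params.update(ko_spec.overrides)  # the zeroed total
        ko_gs = sim.find_ground_state(ko_spec, system, ko_params)
        kos[mol] = sim.run_protocol(
            ko_spec, system, ko_params, oi_protocol, ko_gs, W
        )
    return BatteryResult(
        gs=gs,
        gs_obs=W @ gs,
        oi=oi,
        io=io,
        oi_tal_ko=kos["TAL"],
        oi_pipki_ko=kos["PIPKI"],
    )


def criteria_vector(
    spec: ModelSpec,
    system: sim.RateSystem,
    params: Mapping[str, float],
    W: np.ndarray | None = None,
    oi_protocol: sim.Protocol | None = None,
    battery: BatteryResult | None = None,
    parameter_id=None,
) -> CriteriaVector:
    """The eight criteria plus S/P for one parameter set.

    Runs (or reuses) the five-protocol battery; a nonconvergent run flags the
    record invalid rather than fabricating values.
    """
    try:
        b = battery or run_battery(spec, system, params, W, oi_protocol)
    except sim.NonconvergenceError:
        return CriteriaVector(
            c=np.full(8, np.nan),
            S={m: np.nan for m in MONITORED},
            P={m: np.nan for m in MONITORED},
            valid=False,
            parameter_id=parameter_id,
        )
    names = spec.observable_names

    def tot(sym: str) -> float:
        return max(float(params[sym]), EPS)

    def frac(traj: sim.Trajectory, obs: str, total_sym: str) -> float:
        if float(params[total_sym]) <= 0:
            return 0.0
        return traj.steady(obs) / tot(total_sym)

    c = np.empty(8)
    c[0] = frac(b.oi, "INT_DOK", "INT_tot")
    c[1] = frac(b.oi, "INT_TAL", "INT_tot")
    if float(params["TAL_tot"]) <= 0:
        c[2] = 0.0
    else:
        c[2] = (b.oi.steady("TAL_PM") - b.oi_pipki_ko.steady("TAL_PM")) / tot("TAL_tot")
    if float(params["PIPKI_tot"]) <= 0:
        c[3] = 0.0
    else:
        c[3] = (b.oi.steady("PIPKI_PM") - b.oi_tal_ko.steady("PIPKI_PM")) / tot("PIPKI_tot")
    c[4] = frac(b.oi, "PIPKI_P", "PIPKI_tot")
    c[5] = frac(b.oi, "INT_P", "INT_tot")
    c[6] = frac(b.oi, "openINT", "INT_tot")
    c[7] = frac(b.io, "openINT", "INT_tot")

    S, P = {}, {}
    for m in MONITORED:
        i = names.index(m)
        gs_v = float(b.gs_obs[i])
        ss_v = float(b.oi.steady_observables[i])
        S[m] = sensitivity(b.oi.observables[:, i], b.oi.times, gs_v)
        P[m] = precision(b.oi.observables[:, i], b.oi.times, gs_v, ss_v)
    return CriteriaVector(c=c, S=S, P=P, valid=True, parameter_id=parameter_id)
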