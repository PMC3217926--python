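"""Mass-action ODE compilation and simulation protocols.

The state vector holds species *amounts* expressed on the cytoplasmic
concentration scale (uM referred to the cytoplasmic volume, V_CP = 1).
First-order reactions and translocations act on amounts directly, so mass is
conserved exactly; a bimolecular encounter in compartment ``c`` is scaled by
``1/V_c`` relative to that common amount unit, which is what makes membrane
confinement (V_PM << V_CP) concentrate reactants.  For a mixed-compartment
encounter (extracellular ligand meeting a membrane receptor) the collision
happens in the bulk phase, i.e. the largest participating volume.

Protocols
---------
GS   ground state: no ligand, no cross-talk Src activation (k7b = 0);
     the steady state reached from the free-molecule initial condition.
OI   outside-in: ground state plus a bolus of ligand at t = 0.
IO   inside-out: ground state plus cross-talk Src activation (k7b = k7),
     no ligand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import sympy
from scipy.integrate import odeint

from .engine import ReactionNetwork

__all__ = [
    "Protocol",
    "RateSystem",
    "Trajectory",
    "NonconvergenceError",
    "compile_odes",
    "find_ground_state",
    "run_protocol",
]

# default numerical settings; see docs/methods.md
RTOL = 1e-8
ATOL = 1e-10
SS_ATOL_REL = 1e-9          # steady state when ||dy/dt||_inf < SS_ATOL_REL * max(y)
SS_MAX_HORIZON = 360_000.0  # 100 h cap for steady-state search [s]
DEFAULT_HORIZON = 36_000.0  # 10 h observation window [s]
GRID_POINTS = 200


class NonconvergenceError(RuntimeError):
    def __init__(self, residual: float, horizon: float, context: str = ""):
        self.residual = residual
        self.horizon = horizon
        super().__init__(
            f"no steady state within {horizon:.3g} s "
            f"(residual {residual:.3g}){': ' + context if context else ''}"
        )


# ---------------------------------------------------------------------------
# numba-accelerated kernels (pure-numpy fallback if numba is unavailable)
# ---------------------------------------------------------------------------

def _rhs_py(y, k, r1, r2, ptr, sidx, scoef, out):
    v = k * y[r1]
    bi = r2 >= 0
    v[bi] *= y[r2[bi]]
    out[:] = 0.0
    np.add.at(out, sidx, scoef * np.repeat(v, np.diff(ptr)))
    return out


def _jac_py(y, k, r1, r2, ptr, sidx, scoef, jac):
    jac[:] = 0.0
    n_r = len(k)
    for j in range(n_r):
        a = r1[j]
        b = r2[j]
        if b < 0:
            d_a = k[j]
            cols = (a,)
            vals = (d_a,)
        else:
            cols = (a, b)
            vals = (k[j] * y[b], k[j] * y[a])
        for p in range(ptr[j], ptr[j + 1]):
            s = sidx[p]
            c = scoef[p]
            for col, dv in zip(cols, vals):
                jac[s, col] += c * dv
    return jac


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=True)
    def _rhs_nb(y, k, r1, r2, ptr, sidx, scoef, out):  # pragma: no cover
        n_r = k.shape[0]
        out[:] = 0.0
        for j in range(n_r):
            v = k[j] * y[r1[j]]
            if r2[j] >= 0:
                v *= y[r2[j]]
            for p in range(ptr[j], ptr[j + 1]):
                out[sidx[p]] += scoef[p] * v
        return out

    @njit(cache=True)
    def _jac_nb(y, k, r1, r2, ptr, sidx, scoef, jac):  # pragma: no cover
        jac[:, :] = 0.0
        n_r = k.shape[0]
        for j in range(n_r):
            a = r1[j]
            b = r2[j]
            if b < 0:
                for p in range(ptr[j], ptr[j + 1]):
                    jac[sidx[p], a] += scoef[p] * k[j]
            else:
                da = k[j] * y[b]
                db = k[j] * y[a]
                for p in range(ptr[j], ptr[j + 1]):
                    jac[sidx[p], a] += scoef[p] * da
                    jac[sidx[p], b] += scoef[p] * db
        return jac

    _RHS, _JAC = _rhs_nb, _jac_nb
except Exception:  # pragma: no cover
    _RHS, _JAC = _rhs_py, _jac_py


# ---------------------------------------------------------------------------
# rate system
# ---------------------------------------------------------------------------

class RateSystem:
    """A reaction network compiled to index arrays plus a rate evaluator.

    The symbolic per-reaction rate expressions are lambdified once; for each
    parameter set :meth:`rates` returns the effective rate-constant vector
    (rule rate x multiplicity x symmetry factor x volume correction).
    """

    def __init__(self, network: ReactionNetwork, volumes: Mapping[str, float]):
        self.network = network
        self.volumes = dict(volumes)
        n_r = len(network.reactions)
        self.n_species = len(network.species)

        self.r1 = np.empty(n_r, dtype=np.int64)
        self.r2 = np.empty(n_r, dtype=np.int64)
        factors = np.empty(n_r)
        sidx_list: list[int] = []
        scoef_list: list[float] = []
        ptr = [0]
        exprs = []
        for j, rxn in enumerate(network.reactions):
            if len(rxn.reactant_idx) == 1:
                self.r1[j], self.r2[j] = rxn.reactant_idx[0], -1
                vol = 1.0
            else:
                self.r1[j], self.r2[j] = rxn.reactant_idx
                assert rxn.bimolecular_compartment is not None
                vol = self.volumes[rxn.bimolecular_compartment]
            factors[j] = rxn.multiplicity * rxn.sym_factor / vol
            exprs.append(sympy.sympify(rxn.rate_expr, rational=False))
            delta: dict[int, float] = {}
            for i in rxn.reactant_idx:
                delta[i] = delta.get(i, 0.0) - 1.0
            for i in rxn.product_idx:
                delta[i] = delta.get(i, 0.0) + 1.0
            for s, c in sorted(delta.items()):
                if c != 0.0:
                    sidx_list.append(s)
                    scoef_list.append(c)
            ptr.append(len(sidx_list))
        self.ptr = np.asarray(ptr, dtype=np.int64)
        self.sidx = np.asarray(sidx_list, dtype=np.int64)
        self.scoef = np.asarray(scoef_list)
        self._factors = factors

        symbols = sorted({str(s) for e in exprs for s in e.free_symbols})
        self.rate_symbols = symbols
        syms = [sympy.Symbol(s) for s in symbols]
        self._rate_fun = sympy.lambdify(syms, sympy.Matrix(exprs), "numpy")

        # conservation weights per molecule type
        self.conservation = {
            name: self._weights(name) for name in network.molecule_defs
        }

    def _weights(self, mol: str) -> np.ndarray:
        w = np.zeros(self.n_species)
        for i, sp in enumerate(self.network.species):
            w[i] = sp.molecule_counts().get(mol, 0)
        return w

    def rates(self, params: Mapping[str, float]) -> np.ndarray:
        vals = [params[s] for s in self.rate_symbols]
        base = np.asarray(self._rate_fun(*vals), dtype=float).ravel()
        k = base * self._factors
        if np.any(k < 0):
            raise ValueError("negative rate constant")
        return k

    # -- integration --------------------------------------------------------

    def _odeint(self, y0, times, k, rtol=RTOL, atol=ATOL):
        n = self.n_species
        out = np.empty(n)
        jac = np.empty((n, n))

        def f(y, t):
            return _RHS(y, k, self.r1, self.r2, self.ptr, self.sidx, self.scoef, out).copy()

        def J(y, t):
            return _JAC(y, k, self.r1, self.r2, self.ptr, self.sidx, self.scoef, jac)

        import warnings

        # the analytic Jacobian is fastest; LSODA occasionally stalls with
        # it on degenerate (knockout) systems, so fall back once to an
        # internally estimated Jacobian; a sample that still exhausts its
        # step budget is flagged nonconvergent rather than ground on
        for mxstep, dfun in ((100_000, J), (200_000, None)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol, info = odeint(
                    f, y0, times, Dfun=dfun, rtol=rtol, atol=atol,
                    mxstep=mxstep, full_output=True,
                )
            if info["message"] == "Integration successful.":
                return sol
        raise NonconvergenceError(
            float("nan"), float(times[-1]), "stiff integration failed"
        )

    def dydt(self, y: np.ndarray, k: np.ndarray) -> np.ndarray:
        out = np.empty(self.n_species)
        return _RHS(
            y, k, self.r1, self.r2, self.ptr, self.sidx, self.scoef, out
        ).copy()

    def residual(self, y: np.ndarray, k: np.ndarray) -> float:
        return float(np.max(np.abs(self.dydt(y, k))))

    def steady_state(
        self,
        y0: np.ndarray,
        k: np.ndarray,
        t_start: float = 100.0,
        max_horizon: float = SS_MAX_HORIZON,
        ss_rel: float = SS_ATOL_REL,
        context: str = "",
    ) -> np.ndarray:
        """Integrate with step-doubling horizons until the residual test passes."""
        y = np.asarray(y0, dtype=float)
        t = t_start
        tol = ss_rel * max(float(np.max(y)), 1.0)
        if self.residual(y, k) < tol:
            return y
        while True:
            y = self._odeint(y, np.array([0.0, t]), k)[-1]
            y = np.clip(y, 0.0, None)
            res = self.residual(y, k)
            if res < tol:
                return y
            if t >= max_horizon:
                raise NonconvergenceError(res, t, context)
            t = min(2.0 * t, max_horizon)


def compile_odes(
    network: ReactionNetwork, volumes: Mapping[str, float] | None = None
) -> RateSystem:
    """Compile a reaction network into a :class:`RateSystem`.

    ``volumes`` maps compartment label to relative volume (V_CP = 1); the
    default places the membrane shell at 1% of the cytoplasmic volume.
    """
    if volumes is None:
        volumes = {"EC": 1.0, "PM": 0.01, "CP": 1.0}
    return RateSystem(network, volumes)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Protocol:
    """A simulation protocol (ground state / outside-in / inside-out)."""

    mode: str                       # "GS" | "OI" | "IO"
    ligand_total: float | None = None  # OI only; None = the L_tot parameter
    rule_7b_enabled: bool = False
    horizon: float = DEFAULT_HORIZON
    grid_points: int = GRID_POINTS

    def __post_init__(self):
        if self.mode not in ("GS", "OI", "IO"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if self.mode == "GS" and (self.ligand_total or self.rule_7b_enabled):
            raise ValueError("GS protocol has no ligand and no cross-talk")
        if self.mode == "IO" and self.ligand_total:
            raise ValueError("IO protocol has no ligand")

    @classmethod
    def gs(cls) -> "Protocol":
        return cls(mode="GS")

    @classmethod
    def oi(cls, ligand_total: float | None = None, **kw) -> "Protocol":
        return cls(mode="OI", ligand_total=ligand_total, **kw)

    @classmethod
    def io(cls, **kw) -> "Protocol":
        return cls(mode="IO", rule_7b_enabled=True, **kw)

    def times(self) -> np.ndarray:
        """Log-spaced output grid from 1 s to the horizon, starting at 0."""
        grid = np.geomspace(1.0, self.horizon, self.grid_points)
        return np.concatenate([[0.0], grid])


@dataclass
class Trajectory:
    """Time courses plus the refined steady state for one protocol run."""

    times: np.ndarray
    states: np.ndarray                  # (n_times, n_species) amounts
    observables: np.ndarray             # (n_times, n_observables)
    observable_names: list[str]
    protocol: Protocol
    steady_state: np.ndarray            # refined final state
    steady_observables: np.ndarray
    parameter_id: str | int | None = None

    def observable(self, name: str) -> np.ndarray:
        return self.observables[:, self.observable_names.index(name)]

    def steady(self, name: str) -> float:
        return float(self.steady_observables[self.observable_names.index(name)])

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.observables, columns=self.observable_names)
        df.insert(0, "time", self.times)
        return df


def _initial_state(model_spec, system: RateSystem, params) -> np.ndarray:
    y0 = np.zeros(system.n_species)
    index = system.network.index
    for label, amount in model_spec.seed_amounts(params).items():
        y0[index[label]] = amount
    return y0


def _protocol_params(model_spec, params, protocol: Protocol):
    p = dict(params)
    p["k7b"] = p.get("k7", 0.0) if protocol.rule_7b_enabled else 0.0
    if protocol.mode == "OI":
        if protocol.ligand_total is not None:
            p["L_tot"] = protocol.ligand_total
    else:
        p["L_tot"] = 0.0
    return p


def find_ground_state(
    model_spec,
    system: RateSystem,
    params: Mapping[str, float],
    ss_rel: float = SS_ATOL_REL,
) -> np.ndarray:
    """The steady state without ligand or cross-talk activation.

    This is the initial condition for every stimulation protocol.
    """
    p = _protocol_params(model_spec, params, Protocol.gs())
    k = system.rates(p)
    y0 = _initial_state(model_spec, system, p)
    return system.steady_state(y0, k, ss_rel=ss_rel, context="ground state")


def run_protocol(
    model_spec,
    system: RateSystem,
    params: Mapping[str, float],
    protocol: Protocol,
    ground_state: np.ndarray | None = None,
    observable_matrix: np.ndarray | None = None,
    parameter_id=None,
) -> Trajectory:
    """Simulate one protocol from the ground state on a log-spaced grid.

    The final state is additionally refined to steady state (step-doubling
    up to the 100 h cap) and stored separately on the trajectory.
    """
    p = _protocol_params(model_spec, params, protocol)
    k = system.rates(p)
    if ground_state is None:
        ground_state = find_ground_state(model_spec, system, params)
    y0 = ground_state.copy()
    if protocol.mode == "OI":
        lig_label = None
        for seed in model_spec.seeds:
            if seed.amount_expr == "L_tot":
                lig_label = seed.species.label
        assert lig_label is not None
        y0[system.network.index[lig_label]] = p["L_tot"]

    times = protocol.times()
    states = system._odeint(y0, times, k)
    if states.min() < -10.0 * ATOL * max(1.0, float(states.max())):
        import warnings

        warnings.warn(
            f"trajectory clipped: min state {states.min():.3g}", RuntimeWarning
        )
    states = np.clip(states, 0.0, None)
    # per-run mass conservation check (relative, per molecule type)
    for mol, w in system.conservation.items():
        tot = states @ w
        ref = max(float(np.max(np.abs(tot))), 1e-12)
        if np.ptp(tot) / ref > 1e-6:
            raise NonconvergenceError(
                float(np.ptp(tot) / ref), protocol.horizon,
                f"mass conservation violated for {mol}",
            )
    ss = system.steady_state(
        states[-1], k, t_start=protocol.horizon, context=f"{protocol.mode} refine"
    )
    if observable_matrix is None:
        observable_matrix = model_spec.observable_matrix(system.network)
    obs = states @ observable_matrix.T
    return Trajectory(
        times=times,
        states=states,
        observables=obs,
        observable_names=model_spec.observable_names,
        protocol=protocol,
        steady_state=ss,
        steady_observables=observable_matrix @ ss,
        parameter_id=parameter_id,
    )
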