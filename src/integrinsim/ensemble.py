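"""Ensemble sampling and simulation over the parameter uncertainty ranges.

Each of the 33 sampled parameters is drawn independently and log-uniformly
within ``[base/fold, base*fold]`` (so a value below the base is exactly as
likely as one above it); fixed parameters stay at their base value.  For
every sample the five-protocol battery is run and the eight criteria, the
S/P statistics and the outside-in observable time courses are recorded.

Convergence of the ensemble mean is assessed with a blocking procedure: the
sample is split into equal blocks, the time-dependent mean of each monitored
observable is computed per block, and the coefficient of variation across
blocks is reported; the ensemble counts as converged when the maximum CV
over time stays below a threshold (default 1%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import simulate as sim
from .criteria import CRITERIA_NAMES, MONITORED, CriteriaVector, criteria_vector, run_battery
from .model import ModelSpec, ParameterEntry

__all__ = [
    "ParameterSpace",
    "EnsembleResult",
    "sample_parameters",
    "run_ensemble",
    "convergence_blocking",
    "summarize_quantiles",
]

CV_THRESHOLD = 0.01
QUANTILES = (2.5, 25.0, 50.0, 75.0, 97.5)


@dataclass
class ParameterSpace:
    """The sampled parameter table (fixed entries excluded from perturbation)."""

    entries: list[ParameterEntry]

    @classmethod
    def from_model(cls, spec: ModelSpec) -> "ParameterSpace":
        return cls(entries=list(spec.entries))

    @property
    def symbols(self) -> list[str]:
        return [e.symbol for e in self.entries]

    @property
    def sampled_symbols(self) -> list[str]:
        return [e.symbol for e in self.entries if e.sampled]

    def bounds(self, symbol: str) -> tuple[float, float]:
        e = next(e for e in self.entries if e.symbol == symbol)
        if not e.sampled:
            return (e.base_value, e.base_value)
        f = float(e.fold)
        return (e.base_value / f, e.base_value * f)

    def log_uniform_cdf(self, symbol: str, x: np.ndarray) -> np.ndarray:
        """The analytic sampling CDF of one parameter."""
        lo, hi = self.bounds(symbol)
        x = np.asarray(x, dtype=float)
        if hi == lo:
            return (x >= lo).astype(float)
        out = (np.log(np.clip(x, lo, hi)) - np.log(lo)) / (np.log(hi) - np.log(lo))
        return out

    def sample(self, n: int, seed: int) -> pd.DataFrame:
        """n parameter sets; deterministic given the seed."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        cols = {}
        for e in self.entries:
            if e.sampled:
                u = rng.uniform(-1.0, 1.0, size=n)
                cols[e.symbol] = e.base_value * float(e.fold) ** u
            else:
                cols[e.symbol] = np.full(n, e.base_value)
        df = pd.DataFrame(cols)
        df.index.name = "sample_id"
        return df


def sample_parameters(space: ParameterSpace, n: int, seed: int) -> pd.DataFrame:
    return space.sample(n, seed)


@dataclass
class EnsembleResult:
    samples: pd.DataFrame               # n x n_params values
    criteria: pd.DataFrame              # n x (8 + S/P + valid)
    trajectories: np.ndarray            # (n, n_monitored, n_times) OI courses, float32
    times: np.ndarray
    monitored: list[str]
    seed: int | None = None
    n_failed: int = 0

    @property
    def valid(self) -> np.ndarray:
        return self.criteria["valid"].to_numpy(dtype=bool)

    def criteria_matrix(self) -> np.ndarray:
        return self.criteria[CRITERIA_NAMES].to_numpy()


def run_ensemble(
    spec: ModelSpec,
    samples: pd.DataFrame,
    volumes: Mapping[str, float] | None = None,
    oi_protocol: sim.Protocol | None = None,
    network=None,
    system: sim.RateSystem | None = None,
    seed: int | None = None,
    progress: bool = False,
) -> EnsembleResult:
    """Run the protocol battery for every sampled row.

    Rows whose simulations fail to converge are flagged invalid, never
    fabricated; more than 5% failures raises a warning in the result.
    """
    if system is None:
        network = network or spec.generate_network()
        system = sim.compile_odes(network, volumes)
    W = spec.observable_matrix(system.network)
    oi_protocol = oi_protocol or sim.Protocol.oi()
    times = oi_protocol.times()
    mon_idx = [spec.observable_names.index(m) for m in MONITORED]

    rows = []
    trajs = np.full(
        (len(samples), len(MONITORED), len(times)), np.nan, dtype=np.float32
    )
    n_failed = 0
    iterator = samples.iterrows()
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, total=len(samples))
    for row_i, (sid, row) in enumerate(iterator):
        params = dict(row)
        params["k7b"] = 0.0
        try:
            battery = run_battery(spec, system, params, W, oi_protocol)
        except sim.NonconvergenceError:
            battery = None
        cv = criteria_vector(
            spec, system, params, W, oi_protocol,
            battery=battery, parameter_id=sid,
        ) if battery is not None else CriteriaVector(
            c=np.full(8, np.nan),
            S={m: np.nan for m in MONITORED},
            P={m: np.nan for m in MONITORED},
            valid=False,
            parameter_id=sid,
        )
        if not cv.valid:
            n_failed += 1
        else:
            trajs[row_i] = battery.oi.observables[:, mon_idx].T
        d = cv.as_dict()
        d["sample_id"] = sid
        rows.append(d)

    crit = pd.DataFrame(rows).set_index("sample_id")
    return EnsembleResult(
        samples=samples,
        criteria=crit,
        trajectories=trajs,
        times=times,
        monitored=list(MONITORED),
        seed=seed,
        n_failed=n_failed,
    )


def convergence_blocking(
    trajectories: np.ndarray,
    n_blocks: int = 4,
    threshold: float = CV_THRESHOLD,
) -> tuple[np.ndarray, bool]:
    """Coefficient of variation of block means of the observable time courses.

    ``trajectories``: (n_samples, n_observables, n_times).  The sample is cut
    into ``n_blocks`` equal blocks (a trailing remainder is dropped); returns
    ``(cv, converged)`` with ``cv`` of shape (n_observables, n_times).
    """
    n = trajectories.shape[0]
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    per = n // n_blocks
    if per < 1:
        raise ValueError("fewer samples than blocks")
    cut = trajectories[: per * n_blocks]
    blocks = cut.reshape(n_blocks, per, *cut.shape[1:])
    means = np.nanmean(blocks, axis=1)          # (n_blocks, n_obs, n_times)
    mu = means.mean(axis=0)
    sd = means.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(np.abs(mu) > 0, sd / np.abs(mu), 0.0)
    converged = bool(np.nanmax(cv) < threshold)
    return cv, converged


def summarize_quantiles(
    trajectories: np.ndarray, quantiles: Sequence[float] = QUANTILES
) -> np.ndarray:
    """Pointwise percentile bands; shape (n_quantiles, n_observables, n_times)."""
    valid = ~np.isnan(trajectories).any(axis=(1, 2))
    if valid.sum() < 20:
        raise ValueError("need at least 20 valid trajectories")
    return np.nanpercentile(trajectories[valid], quantiles, axis=0)
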