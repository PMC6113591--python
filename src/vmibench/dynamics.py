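"""Simulation and sampling of virus-microbe community dynamics.

The community obeys a generalized Lotka-Volterra system: hosts grow
logistically against a shared carrying capacity with pairwise competition
and are lysed by the viruses that infect them; viruses grow from lysis and
decay at a constant rate,

    dH_i/dt = r_i H_i (1 - sum_i' a_ii' H_i' / K) - H_i sum_j M_ij phi_ij V_j
    dV_j/dt = V_j sum_i M_ij phi_ij beta_ij H_i - m_j V_j

with densities in cells/ml and virions/ml and time in days internally
(rates are per day); the public interface uses hours, matching sampling
conventions for microbial time series.

Initial conditions perturb the equilibrium multiplicatively by a fraction
``delta`` with a random sign per population, so the sampled series are
transients around the coexistence fixed point whose variability scales with
``delta``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .networks import InteractionNetwork
from .traits import TraitSet

__all__ = [
    "CommunityTimeSeries",
    "SampleSet",
    "simulate",
    "sample",
    "coefficient_of_variation",
    "community_cvs",
    "save_samples",
    "load_samples",
]

HOURS_PER_DAY = 24.0


@dataclass
class CommunityTimeSeries:
    """Dense community trajectories on a regular fine time grid (hours)."""

    t: np.ndarray          # (T,) hours, strictly increasing
    H: np.ndarray          # (N_H, T) cells/ml
    V: np.ndarray          # (N_V, T) virions/ml
    delta: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (np.diff(self.t) > 0).all():
            raise ValueError("time grid must be strictly increasing")
        if (self.H <= 0).any() or (self.V <= 0).any():
            raise ValueError("densities must stay strictly positive")


@dataclass
class SampleSet:
    """Log10-transformed abundances at S regular sample times."""

    t: np.ndarray          # (S,) hours, t_k = k * frequency
    h: np.ndarray          # (N_H, S) log10 host densities
    v: np.ndarray          # (N_V, S) log10 virus densities
    frequency: float       # hours between samples
    duration: float        # hours covered (t_S)
    delta: float = float("nan")
    seed: int | None = None

    @property
    def n_samples(self) -> int:
        return self.t.size


def _rhs_factory(traits: TraitSet, M: np.ndarray):
    r, K, a, m = traits.r, traits.K, traits.a, traits.m
    Mphi = M * traits.phi
    Mphibeta = Mphi * traits.beta
    nH = traits.n_hosts

    def rhs(t, y):
        H = y[:nH]
        V = y[nH:]
        dH = r * H * (1.0 - (a @ H) / K) - H * (Mphi @ V)
        dV = V * (Mphibeta.T @ H) - m * V
        return np.concatenate([dH, dV])

    return rhs


def _log_rhs_factory(traits: TraitSet, M: np.ndarray):
    """Per-capita rates on log state: d(ln y)/dt = f(y)/y, positivity exact."""
    r, K, a, m = traits.r, traits.K, traits.a, traits.m
    Mphi = M * traits.phi
    Mphibeta = Mphi * traits.beta
    nH = traits.n_hosts

    def rhs(t, z):
        H = np.exp(z[:nH])
        V = np.exp(z[nH:])
        dlogH = r * (1.0 - (a @ H) / K) - Mphi @ V
        dlogV = Mphibeta.T @ H - m
        return np.concatenate([dlogH, dlogV])

    return rhs


def simulate(traits: TraitSet, net: InteractionNetwork, delta: float,
             t_end: float = 300.0, rng=None, grid_dt: float = 0.25,
             rtol: float = 1e-8, atol: float = 1e-10) -> CommunityTimeSeries:
    """Integrate the community model from a perturbed equilibrium.

    Parameters
    ----------
    delta : fraction in [0, 1)
        Initial conditions are H*_i (1 +/- delta), V*_j (1 +/- delta) with
        independent random signs per population.
    t_end : hours
        Simulation horizon; the default 300 h leaves 100 h of virus
        trajectory beyond a 200-h sampling window for delayed correlations.
    grid_dt : hours
        Spacing of the stored solution grid; sampling frequencies should be
        integer multiples of it.
    """
    if not 0.0 <= delta < 1.0:
        raise ValueError("delta must lie in [0, 1)")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    M = net.M.astype(float)
    if M.shape != (traits.n_hosts, traits.n_viruses):
        raise ValueError("network and trait shapes disagree")

    signs_h = rng.choice([-1.0, 1.0], size=traits.n_hosts)
    signs_v = rng.choice([-1.0, 1.0], size=traits.n_viruses)
    y0 = np.concatenate([traits.H_star * (1.0 + signs_h * delta),
                         traits.V_star * (1.0 + signs_v * delta)])

    # integrate on log densities: positivity is exact and the relative error
    # tolerance keeps its meaning even when trajectories span many decades
    t_grid = np.arange(0.0, t_end + 0.5 * grid_dt, grid_dt)
    sol = solve_ivp(
        _log_rhs_factory(traits, M),
        (0.0, t_end / HOURS_PER_DAY),
        np.log(y0),
        method="LSODA",
        t_eval=t_grid / HOURS_PER_DAY,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    y = np.exp(sol.y)
    return CommunityTimeSeries(t=t_grid, H=y[:traits.n_hosts],
                               V=y[traits.n_hosts:], delta=delta)


def sample(ts: CommunityTimeSeries, frequency: float = 2.0,
           duration: float = 200.0) -> SampleSet:
    """Sample log10 abundances every ``frequency`` hours for ``duration``.

    The first sample is taken at t = frequency, giving
    S = duration / frequency samples (e.g. 100 samples for 200 h at 2 h).
    """
    if duration > ts.t[-1] + 1e-9:
        raise ValueError("requested window exceeds the simulated span")
    n = duration / frequency
    if abs(n - round(n)) > 1e-9:
        raise ValueError("frequency must divide duration")
    S = int(round(n))
    t_k = frequency * np.arange(1, S + 1)
    h = np.vstack([np.interp(t_k, ts.t, row) for row in ts.H]) if ts.H.size \
        else np.empty((0, S))
    v = np.vstack([np.interp(t_k, ts.t, row) for row in ts.V]) if ts.V.size \
        else np.empty((0, S))
    return SampleSet(t=t_k, h=np.log10(h), v=np.log10(v),
                     frequency=frequency, duration=duration,
                     delta=ts.delta, seed=ts.seed)


def coefficient_of_variation(series: np.ndarray) -> float:
    """CV = sigma / mu of a raw (not log) trajectory, sample (n-1) std."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        return 0.0
    if (x <= 0).any():
        raise ValueError("CV is defined here for strictly positive series")
    return float(np.std(x, ddof=1) / np.mean(x))


def community_cvs(ts: CommunityTimeSeries,
                  t_max: float = 200.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-trajectory CVs of raw host and virus densities over [0, t_max]."""
    mask = ts.t <= t_max + 1e-9
    host = np.array([coefficient_of_variation(row[mask]) for row in ts.H])
    virus = np.array([coefficient_of_variation(row[mask]) for row in ts.V])
    return host, virus


# ---------------------------------------------------------------------------
# I/O: CSV table (time, h_1.., v_1..) + JSON sidecar
# ---------------------------------------------------------------------------

def save_samples(samples: SampleSet, path: str | Path) -> None:
    path = Path(path)
    cols = {"time": samples.t}
    for i, row in enumerate(samples.h, start=1):
        cols[f"h_{i}"] = row
    for j, row in enumerate(samples.v, start=1):
        cols[f"v_{j}"] = row
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {"delta": samples.delta, "frequency": samples.frequency,
            "duration": samples.duration, "seed": samples.seed}
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_samples(path: str | Path) -> SampleSet:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text()) \
        if path.with_suffix(".json").exists() else {}
    h = df[[c for c in df.columns if c.startswith("h_")]].to_numpy().T
    v = df[[c for c in df.columns if c.startswith("v_")]].to_numpy().T
    t = df["time"].to_numpy()
    freq = meta.get("frequency", float(t[1] - t[0]) if t.size > 1 else float(t[0]))
    return SampleSet(t=t, h=h, v=v, frequency=freq,
                     duration=meta.get("duration", float(t[-1])),
                     delta=meta.get("delta", float("nan")),
                     seed=meta.get("seed"))
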