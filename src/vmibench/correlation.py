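"""Standard and time-delayed correlation networks between hosts and viruses.

Each host-virus pair of a log-transformed sample set receives a correlation
coefficient (Pearson, Spearman, or Kendall tau-b), arranged in a bipartite
matrix shaped like the interaction network.  The time-delayed variant slides
the virus series later in time on the sampling lattice and keeps, per pair,
the delay that maximizes the absolute coefficient; the number of samples per
coefficient stays fixed, so the virus series must extend beyond the host
sampling window by the maximum delay.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import kendalltau, rankdata

from .dynamics import SampleSet

__all__ = [
    "CorrelationNetwork",
    "standard_correlation",
    "delayed_correlation",
    "save_correlation",
    "load_correlation",
]

METRICS = ("pearson", "spearman", "kendall")


@dataclass
class CorrelationNetwork:
    """Host x virus coefficient matrix from one inference method."""

    R: np.ndarray                   # (N_H, N_V)
    method: str
    delays: np.ndarray | None = None   # (N_H, N_V) hours; None = no delays
    n_samples: int = 0
    frequency: float = float("nan")

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.delays is not None:
            self.delays = np.asarray(self.delays, dtype=float)
            if self.delays.shape != self.R.shape:
                raise ValueError("delays shape must match R")


def _pearson_matrix(h: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson coefficients between every row of h and every row of v.

    Constant series (zero variance) yield coefficient 0 with a warning:
    no evidence of association, and keeps downstream scoring total.
    """
    hc = h - h.mean(axis=1, keepdims=True)
    vc = v - v.mean(axis=1, keepdims=True)
    hn = np.sqrt((hc * hc).sum(axis=1))
    vn = np.sqrt((vc * vc).sum(axis=1))
    bad_h = hn == 0
    bad_v = vn == 0
    if bad_h.any() or bad_v.any():
        warnings.warn("constant series encountered; coefficient set to 0",
                      stacklevel=3)
    denom = np.outer(np.where(bad_h, 1.0, hn), np.where(bad_v, 1.0, vn))
    R = (hc @ vc.T) / denom
    R[bad_h, :] = 0.0
    R[:, bad_v] = 0.0
    return np.clip(R, -1.0, 1.0)


def _pair_matrix(h: np.ndarray, v: np.ndarray, metric: str) -> np.ndarray:
    if metric == "pearson":
        return _pearson_matrix(h, v)
    if metric == "spearman":
        return _pearson_matrix(rankdata(h, axis=1), rankdata(v, axis=1))
    if metric == "kendall":
        R = np.empty((h.shape[0], v.shape[0]))
        for i, hi in enumerate(h):
            for j, vj in enumerate(v):
                if np.ptp(hi) == 0 or np.ptp(vj) == 0:
                    R[i, j] = 0.0
                else:
                    R[i, j] = kendalltau(hi, vj).statistic
        return R
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def standard_correlation(samples: SampleSet,
                         metric: str = "pearson") -> CorrelationNetwork:
    """Correlation of every host-virus pair of log-transformed samples."""
    if samples.n_samples < 3:
        raise ValueError("need at least 3 samples")
    R = _pair_matrix(samples.h, samples.v, metric)
    return CorrelationNetwork(R, method=metric,
                              delays=np.zeros_like(R),
                              n_samples=samples.n_samples,
                              frequency=samples.frequency)


def delayed_correlation(samples: SampleSet, extended: SampleSet,
                        metric: str = "pearson",
                        max_delay: float = 100.0) -> CorrelationNetwork:
    """Time-delayed correlation, maximizing |r| over a delay grid per pair.

    The virus series is sampled later in time by a delay tau on the grid
    {0, f, 2f, ..., max_delay} (f = sampling frequency); the host series is
    fixed.  ``extended`` must provide virus samples on the same lattice out
    to the host window plus ``max_delay``.  Ties in |r| resolve to the
    smallest delay.
    """
    S = samples.n_samples
    f = samples.frequency
    n_steps = int(round(max_delay / f))
    if abs(n_steps * f - max_delay) > 1e-9:
        raise ValueError("max_delay must be a multiple of the frequency")
    if extended.frequency != f:
        raise ValueError("extended set must share the sampling frequency")
    if extended.v.shape[1] < S + n_steps:
        raise ValueError("extended virus samples too short for max_delay")

    h = samples.h
    best_R = None
    best_tau = None
    for k in range(n_steps + 1):
        Rk = _pair_matrix(h, extended.v[:, k:k + S], metric)
        if best_R is None:
            best_R = Rk
            best_tau = np.zeros_like(Rk)
        else:
            better = np.abs(Rk) > np.abs(best_R)  # strict: first/smallest tau wins
            best_R = np.where(better, Rk, best_R)
            best_tau = np.where(better, k * f, best_tau)
    method = metric if n_steps == 0 else f"delayed_{metric}"
    return CorrelationNetwork(best_R, method=method, delays=best_tau,
                              n_samples=S, frequency=f)


def save_correlation(net: CorrelationNetwork, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, net.R, delimiter=",")
    meta = {"method": net.method, "n_samples": net.n_samples,
            "frequency": net.frequency}
    path.with_suffix(".json").write_text(json.dumps(meta))
    if net.delays is not None:
        np.savetxt(path.with_name(path.stem + "_delays.csv"),
                   net.delays, delimiter=",")


def load_correlation(path: str | Path) -> CorrelationNetwork:
    path = Path(path)
    R = np.loadtxt(path, delimiter=",", ndmin=2)
    meta = json.loads(path.with_suffix(".json").read_text()) \
        if path.with_suffix(".json").exists() else {}
    dpath = path.with_name(path.stem + "_delays.csv")
    delays = np.loadtxt(dpath, delimiter=",", ndmin=2) if dpath.exists() else None
    return CorrelationNetwork(R, method=meta.get("method", "pearson"),
                              delays=delays,
                              n_samples=meta.get("n_samples", 0),
                              frequency=meta.get("frequency", float("nan")))
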