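"""Bipartite virus-microbe interaction networks.

Interaction networks are boolean matrices ``M`` of shape (hosts x viruses):
``M[i, j] = 1`` means virus ``j`` can infect and lyse host ``i``.  This module
generates maximally nested (staircase) and maximally modular (block-diagonal)
networks at a prescribed fill, degrades them toward lower structure by
fill-preserving rewiring, and measures nestedness (NODF) and Barber bipartite
modularity (BRIM maximization with adaptive module count).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "InteractionNetwork",
    "make_max_nested",
    "make_max_modular",
    "rewire_toward",
    "nodf",
    "bipartite_modularity",
    "save_network",
    "load_network",
]


@dataclass
class InteractionNetwork:
    """A boolean bipartite interaction network with provenance.

    Attributes
    ----------
    M : ndarray of bool, shape (n_hosts, n_viruses)
        Rows are microbial host populations, columns are virus populations.
    structure_label : {"nested", "modular"}
        Which structural gradient the network belongs to.
    structure_value : float
        NODF (nested) or normalized Barber modularity (modular) measured on M.
    seed : int or None
        Seed of the random stream that produced the network, if any.
    """

    M: np.ndarray
    structure_label: str = "nested"
    structure_value: float = float("nan")
    seed: int | None = None

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=bool)
        if self.M.ndim != 2:
            raise ValueError("M must be a 2-D matrix")

    @property
    def n_hosts(self) -> int:
        return self.M.shape[0]

    @property
    def n_viruses(self) -> int:
        return self.M.shape[1]

    @property
    def fill(self) -> float:
        """Fraction of realized host-virus interactions."""
        return float(self.M.sum()) / self.M.size

    def validate(self) -> None:
        """Raise if any row or column is empty (an isolated population)."""
        if not self.M.any(axis=1).all():
            raise ValueError("network has a host with no infecting virus")
        if not self.M.any(axis=0).all():
            raise ValueError("network has a virus with no susceptible host")


def _staircase_degrees(n: int, n_ones: int) -> np.ndarray:
    """Non-increasing row-degree sequence of a maximally nested n x n matrix.

    Starts from the strict staircase (n, n-1, ..., 1) and repairs the total:
    surplus ones are added to the topmost incrementable row (filling leading
    rows to full), deficit ones are removed from the bottommost decrementable
    row.  Keeping the sequence as close to strictly decreasing as possible
    maximizes the number of decreasing-fill pairs, which NODF rewards.
    """
    d = np.arange(n, 0, -1)
    diff = n_ones - d.sum()
    while diff > 0:
        for i in range(n):
            if d[i] < n and (i == 0 or d[i] < d[i - 1]):
                d[i] += 1
                diff -= 1
                break
        else:  # pragma: no cover - unreachable for n_ones <= n*n
            raise ValueError("cannot place that many ones")
        if (d == n).all() and diff > 0:
            raise ValueError("more ones than cells")
    while diff < 0:
        for i in range(n - 1, -1, -1):
            if d[i] > 1 and (i == n - 1 or d[i] > d[i + 1]):
                d[i] -= 1
                diff += 1
                break
        else:
            raise ValueError("too few ones for a nested matrix with "
                             "nonempty rows and columns")
    return d


def make_max_nested(N: int, F: float) -> InteractionNetwork:
    """Maximally nested square network of size ``N`` at fill ``F``.

    The matrix is a staircase (each row's interactions are a prefix of the
    columns, with non-increasing row degrees), which maximizes NODF among
    matrices of the same size and fill.  Requires round(F*N^2) >= 2N - 1 so
    that a staircase with no empty row or column exists.
    """
    if N < 1:
        raise ValueError("N must be positive")
    if not 0.0 < F <= 1.0:
        raise ValueError("fill F must lie in (0, 1]")
    n_ones = int(round(F * N * N))
    if n_ones < max(2 * N - 1, 1):
        raise ValueError(
            f"fill {F} too small: a nested {N}x{N} matrix with nonempty rows "
            f"and columns needs at least {2 * N - 1} ones, got {n_ones}")
    d = _staircase_degrees(N, n_ones)
    M = np.zeros((N, N), dtype=bool)
    for i, di in enumerate(d):
        M[i, :di] = True
    net = InteractionNetwork(M, structure_label="nested")
    net.structure_value = nodf(net)
    net.validate()
    return net


def make_max_modular(N: int, F: float, n_modules: int) -> InteractionNetwork:
    """Maximally modular square network: ``n_modules`` blocks on the diagonal.

    ``n_modules`` must divide ``N``; the requested fill must fit inside the
    blocks (F <= 1/n_modules) and leave every row and column nonempty.  Ones
    are spread as evenly as possible across blocks; within a block they form
    a nested staircase (or the full block).
    """
    if N < 1 or n_modules < 1:
        raise ValueError("N and n_modules must be positive")
    if N % n_modules != 0:
        raise ValueError("n_modules must divide N")
    if not 0.0 < F <= 1.0:
        raise ValueError("fill F must lie in (0, 1]")
    B = N // n_modules
    n_ones = int(round(F * N * N))
    if n_ones > n_modules * B * B:
        raise ValueError(
            f"fill {F} exceeds the block-diagonal maximum {1.0 / n_modules}")
    if n_ones < N:
        raise ValueError("too few ones for nonempty rows and columns")
    # distribute ones across blocks as evenly as possible
    base, extra = divmod(n_ones, n_modules)
    counts = [base + (1 if b < extra else 0) for b in range(n_modules)]
    if min(counts) < B:
        raise ValueError("too few ones per block for nonempty rows/columns")
    M = np.zeros((N, N), dtype=bool)
    for b, q in enumerate(counts):
        r0 = c0 = b * B
        if q == B * B:
            M[r0:r0 + B, c0:c0 + B] = True
        elif q >= 2 * B - 1 or B == 1:
            for i, di in enumerate(_staircase_degrees(B, q)):
                M[r0 + i, c0:c0 + di] = True
        else:
            # diagonal guarantees nonempty rows/columns; pad row-major
            blk = np.eye(B, dtype=bool)
            flat = blk.ravel()
            for pos in range(B * B):
                if flat.sum() >= q:
                    break
                flat[pos] = True
            M[r0:r0 + B, c0:c0 + B] = flat.reshape(B, B)
    net = InteractionNetwork(M, structure_label="modular")
    net.structure_value = bipartite_modularity(net)[1]
    net.validate()
    return net


# ---------------------------------------------------------------------------
# structure metrics
# ---------------------------------------------------------------------------

def _as_matrix(net) -> np.ndarray:
    M = net.M if isinstance(net, InteractionNetwork) else np.asarray(net)
    return M.astype(float)


def _nodf_pairs(A: np.ndarray) -> float:
    """Sum of NODF paired-overlap terms over all row pairs of ``A``."""
    d = A.sum(axis=1)
    if (d == 0).any():
        raise ValueError("empty row/column in NODF computation")
    overlap = A @ A.T
    # term for unordered pair {i, k}: overlap/d_k iff d_i > d_k (decreasing fill)
    decreasing = d[:, None] > d[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        paired = np.where(decreasing, overlap / d[None, :], 0.0)
    return float(paired.sum())  # each unordered pair contributes once


def nodf(net) -> float:
    """Nestedness metric based on overlap and decreasing fill, in [0, 100].

    Mean over all row pairs and column pairs of the paired-overlap term:
    the fraction of the lower-degree member's interactions shared with the
    higher-degree member, zero when the two degrees are equal.
    """
    A = _as_matrix(net)
    m, n = A.shape
    n_pairs = m * (m - 1) / 2 + n * (n - 1) / 2
    if n_pairs == 0:
        return 0.0
    return 100.0 * (_nodf_pairs(A) + _nodf_pairs(A.T)) / n_pairs


def _one_hot(labels: np.ndarray, c: int) -> np.ndarray:
    out = np.zeros((labels.size, c))
    out[np.arange(labels.size), labels] = 1.0
    return out


def _brim_run(Bmat: np.ndarray, m: float, c: int, rng: np.random.Generator,
              max_iter: int = 60) -> float:
    """One BRIM maximization from a random initial column partition."""
    nV = Bmat.shape[1]
    T = _one_hot(rng.integers(0, c, size=nV), c)
    q_prev = -np.inf
    for _ in range(max_iter):
        RB = Bmat @ T
        R = _one_hot(np.argmax(RB, axis=1), c)
        TB = Bmat.T @ R
        T = _one_hot(np.argmax(TB, axis=1), c)
        q = float(np.sum(TB * T)) / m
        if q <= q_prev + 1e-13:
            break
        q_prev = q
    return q_prev if q_prev > -np.inf else 0.0


def bipartite_modularity(net, n_restarts: int = 8, rng=None,
                         max_modules: int | None = None) -> tuple[float, float]:
    """Barber bipartite modularity ``(Qb, Qb_normalized)`` of the best
    partition found by BRIM with adaptive module count.

    Qb = (1/m) sum_ij (A_ij - k_i d_j / m) [g_i == h_j].  Module counts are
    scanned upward from 2 and the scan stops after three consecutive counts
    without improvement (adaptive-BRIM style).  ``Qb_normalized`` divides by
    the modularity of an ideal block-diagonal matrix with round(1/F) equal
    modules at the same fill, i.e. 1 - 1/k_ideal.
    """
    A = _as_matrix(net)
    nH, nV = A.shape
    m = A.sum()
    if m == 0:
        raise ValueError("empty network")
    if rng is None:
        rng = np.random.default_rng(0)
    Bmat = A - np.outer(A.sum(axis=1), A.sum(axis=0)) / m
    cap = max_modules if max_modules is not None else min(nH, nV)
    cap = max(2, min(cap, min(nH, nV)))
    best = 0.0  # c = 1 gives Qb = 0 identically
    stale = 0
    for c in range(2, cap + 1):
        qc = max(_brim_run(Bmat, m, c, rng) for _ in range(n_restarts))
        if qc > best + 1e-12:
            best = qc
            stale = 0
        else:
            stale += 1
            if stale >= 3:
                break
    F = m / (nH * nV)
    k_ideal = int(np.clip(round(1.0 / F), 2, min(nH, nV)))
    q_max = 1.0 - 1.0 / k_ideal
    return best, best / q_max


# ---------------------------------------------------------------------------
# rewiring
# ---------------------------------------------------------------------------

def _metric_fn(metric: str, fast: bool):
    if metric == "nodf":
        return nodf, 100.0
    if metric == "modularity":
        if fast:
            return (lambda M: bipartite_modularity(M, n_restarts=3)[1]), 1.0
        return (lambda M: bipartite_modularity(M)[1]), 1.0
    raise ValueError(f"unknown metric {metric!r}")


def rewire_toward(net: InteractionNetwork, metric: str, target: float,
                  rng, tol: float | None = None,
                  max_proposals: int | None = None) -> InteractionNetwork:
    """Degrade network structure to ``target`` by fill-preserving rewiring.

    Repeatedly swaps a randomly chosen interacting pair (a 1) with a randomly
    chosen noninteracting pair (a 0), never emptying a row or column, and
    re-measures the metric after each accepted swap, stopping at the first
    configuration at or below ``target + tol``.  Candidate pairs are drawn
    without replacement within a sweep; the pool refreshes after each
    accepted swap.

    Near the random-matrix equilibrium unbiased swapping stops making
    progress; after a patience budget of accepted swaps without a new metric
    minimum, metric-increasing swaps are reverted so that low targets remain
    reachable.

    Raises ``RuntimeError`` if the target is not reached within the proposal
    budget and ``ValueError`` if ``target`` exceeds the current metric value.
    """
    metric_eval, metric_max = _metric_fn(metric, fast=True)
    if tol is None:
        tol = 0.01 * metric_max
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    M = net.M.copy()
    net.validate()
    current = metric_eval(M)
    if target > current + tol:
        raise ValueError(
            f"target {target} above current {metric} value {current:.4g}; "
            "rewiring only degrades structure")
    out_label = net.structure_label

    n_ones = int(M.sum())
    if max_proposals is None:
        max_proposals = 400 * n_ones
    patience = 3 * n_ones
    proposals = 0
    since_min = 0
    min_seen = current
    guarded = False

    while current > target + tol:
        ones = np.flatnonzero(M.ravel())
        zeros = np.flatnonzero(~M.ravel())
        rng.shuffle(ones)
        rng.shuffle(zeros)
        accepted = False
        for o, z in zip(ones, zeros):
            proposals += 1
            if proposals > max_proposals:
                raise RuntimeError(
                    f"{metric} target {target} not reached "
                    f"(stuck at {current:.4g} after {proposals} proposals)")
            i, j = divmod(int(o), M.shape[1])
            i2, j2 = divmod(int(z), M.shape[1])
            # forbid swaps that would isolate a population
            if i != i2 and M[i, :].sum() == 1:
                continue
            if j != j2 and M[:, j].sum() == 1:
                continue
            M[i, j] = False
            M[i2, j2] = True
            value = metric_eval(M)
            if guarded and value > current:
                M[i, j] = True
                M[i2, j2] = False
                continue
            current = value
            accepted = True
            if current < min_seen - 1e-12:
                min_seen = current
                since_min = 0
            else:
                since_min += 1
                if since_min > patience:
                    guarded = True
            break
        if not accepted:
            raise RuntimeError(
                f"candidate pairs exhausted at {metric}={current:.4g} "
                f"before reaching target {target}")

    out = InteractionNetwork(M, structure_label=out_label,
                             structure_value=current, seed=net.seed)
    out.validate()
    assert out.fill == net.fill
    return out


# ---------------------------------------------------------------------------
# I/O: headerless integer CSV + JSON sidecar
# ---------------------------------------------------------------------------

def save_network(net: InteractionNetwork, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, net.M.astype(int), fmt="%d", delimiter=",")
    meta = {
        "N": net.n_hosts,
        "F": net.fill,
        "structure_label": net.structure_label,
        "structure_value": net.structure_value,
        "seed": net.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_network(path: str | Path) -> InteractionNetwork:
    path = Path(path)
    M = np.loadtxt(path, delimiter=",", ndmin=2).astype(bool)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return InteractionNetwork(
        M,
        structure_label=meta.get("structure_label", "nested"),
        structure_value=meta.get("structure_value", float("nan")),
        seed=meta.get("seed"),
    )
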