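"""SparCC-style correlation inference from relative abundances.

Sequencing-style data are compositional: per-sample fractions sum to one, so
naive correlations between components are biased negative.  The SparCC
approach estimates correlations between the unobserved absolute abundances
("basis" correlations) from the variances of pairwise log-ratios,

    t_ij = Var[ log(x_i / x_j) ] = w_i^2 + w_j^2 - 2 rho_ij w_i w_j,

solving for the basis variances w_i^2 under the assumption that the average
correlation of each component with the rest is negligible (sparsity), then
inverting for rho.  Strongly correlated pairs violate the assumption, so the
most correlated pair above a threshold is iteratively excluded from the
variance equations and the system re-solved.

Here hosts and viruses are normalized separately (host fractions of the host
total, virus fractions of the virus total, per sample time) and the two
compositions are pooled into one component table for the estimation; only
the host x virus block of the correlation matrix is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlation import CorrelationNetwork
from .dynamics import SampleSet

__all__ = [
    "CompositionSet",
    "normalize_compositions",
    "log_ratio_variances",
    "basis_variances",
    "sparcc_network",
]


@dataclass
class CompositionSet:
    """Host and virus relative abundances per sample time."""

    host_fractions: np.ndarray    # (N_H, S), columns sum to 1
    virus_fractions: np.ndarray   # (N_V, S), columns sum to 1
    frequency: float = float("nan")

    @property
    def n_components(self) -> int:
        return self.host_fractions.shape[0] + self.virus_fractions.shape[0]

    def pooled(self) -> np.ndarray:
        """Stack the two compositions into one (N_H + N_V) x S table."""
        return np.vstack([self.host_fractions, self.virus_fractions])


def normalize_compositions(samples: SampleSet) -> CompositionSet:
    """Convert log10 samples to separate host and virus compositions.

    Hosts are divided by the per-time host total and viruses by the
    per-time virus total, mirroring how relative-abundance profiling
    normalizes the two pools independently.
    """
    H = 10.0 ** samples.h
    V = 10.0 ** samples.v
    if (H <= 0).any() or (V <= 0).any():
        raise ValueError("abundances must be strictly positive")
    return CompositionSet(host_fractions=H / H.sum(axis=0, keepdims=True),
                          virus_fractions=V / V.sum(axis=0, keepdims=True),
                          frequency=samples.frequency)


def log_ratio_variances(frac: np.ndarray) -> np.ndarray:
    """t_ij = Var[log(x_i / x_j)] for all component pairs (sample variance)."""
    logx = np.log(frac)
    n = logx.shape[0]
    t = np.zeros((n, n))
    for i in range(n):
        d = logx[i] - logx
        t[i] = d.var(axis=1, ddof=1)
    np.fill_diagonal(t, 0.0)
    return t


def basis_variances(t: np.ndarray,
                    excluded: set[tuple[int, int]] | None = None) -> np.ndarray:
    """Solve the sparsity-approximation linear system for basis variances.

    Summing t_ij over j != i and dropping the correlation cross-terms gives
    (p - 2) w_i^2 + sum_j w_j^2 ~= sum_j t_ij, a linear system with matrix
    diag(p - 2) + ones.  Excluded pairs are removed from both the row sums
    and the coefficient matrix.  Negative solutions (possible when the
    sparsity assumption is badly violated) are clipped to a small positive
    value.
    """
    p = t.shape[0]
    if p < 3:
        raise ValueError("need at least 3 components to identify basis "
                         "variances")
    Mmat = np.ones((p, p)) + np.diag(np.full(p, p - 2.0))
    rhs = t.sum(axis=1)
    if excluded:
        for i, j in excluded:
            rhs[i] -= t[i, j]
            rhs[j] -= t[i, j]
            Mmat[i, j] -= 1.0
            Mmat[j, i] -= 1.0
            Mmat[i, i] -= 1.0
            Mmat[j, j] -= 1.0
    try:
        w2 = np.linalg.solve(Mmat, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular basis-variance system (p={p}, "
            f"{len(excluded or ())} exclusions)") from exc
    return np.maximum(w2, 1e-15)


def _correlation_from_variances(t: np.ndarray, w2: np.ndarray) -> np.ndarray:
    w = np.sqrt(w2)
    rho = (w2[:, None] + w2[None, :] - t) / (2.0 * np.outer(w, w))
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def sparcc_network(comp: CompositionSet, n_exclusion_iters: int = 10,
                   sparsity_threshold: float = 0.1) -> CorrelationNetwork:
    """Basis correlations of the pooled composition; host x virus block.

    Defaults mirror the upstream tool: 10 exclusion iterations with
    threshold 0.1.  The data here contain no zeros, so no pseudo-count
    resampling is involved and the estimate is deterministic.
    """
    frac = comp.pooled()
    if frac.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    nH = comp.host_fractions.shape[0]
    t = log_ratio_variances(frac)
    excluded: set[tuple[int, int]] = set()
    w2 = basis_variances(t)
    rho = _correlation_from_variances(t, w2)
    for _ in range(n_exclusion_iters):
        mask = np.abs(rho)
        np.fill_diagonal(mask, 0.0)
        for i, j in excluded:
            mask[i, j] = mask[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(mask), mask.shape)
        if mask[i, j] <= sparsity_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
        try:
            w2 = basis_variances(t, excluded)
        except np.linalg.LinAlgError:
            break
        rho = _correlation_from_variances(t, w2)
    return CorrelationNetwork(rho[:nH, nH:], method="sparcc",
                              n_samples=frac.shape[1],
                              frequency=comp.frequency)
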