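"""Life-history traits guaranteeing coexistence of hosts and viruses.

For a given interaction network, target equilibrium densities (H*, V*) and
virus-free densities H0* are sampled from biologically feasible uniform
ranges; host-host competition coefficients are then constructed so the
virus-free community sits exactly at carrying capacity, and viral decay rates
m and host growth rates r are solved from the fixed-point conditions of the
community dynamics.  The resulting trait set makes (H*, V*) an exact
equilibrium of the virus-microbe model.

Sampling ranges (uniform):
    H*  in [1e3, 1e4]  cells/ml        phi  in [1e-7, 1e-6]  ml/day
    V*  in [1e6, 1e7]  virions/ml      beta in [10, 100]     virions/cell
    H0* in [1e3, 1e6]  cells/ml        a_ii' in [0, 1], a_ii = 1
    K = 1e6 cells/ml (fixed)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .networks import InteractionNetwork

__all__ = [
    "TraitSet",
    "RANGES",
    "CARRYING_CAPACITY",
    "sample_traits",
    "build_competition",
    "effective_network",
    "save_traits",
    "load_traits",
]

CARRYING_CAPACITY = 1e6  # cells/ml, community-wide

RANGES = {
    "H_star": (1e3, 1e4),
    "V_star": (1e6, 1e7),
    "phi": (1e-7, 1e-6),
    "beta": (10.0, 100.0),
    "H0_star": (1e3, 1e6),
}


@dataclass
class TraitSet:
    """All model rates and equilibrium targets for one community.

    r : host growth rates (1/day), shape (N_H,)
    K : community carrying capacity (cells/ml)
    a : host-host competition matrix (dimensionless), shape (N_H, N_H)
    phi : adsorption rates (ml/day), shape (N_H, N_V)
    beta : burst sizes (virions/cell), shape (N_H, N_V)
    m : viral decay rates (1/day), shape (N_V,)
    H_star, V_star : target equilibrium densities
    H0_star : target virus-free host densities
    seed : seed of the generating random stream
    """

    r: np.ndarray
    K: float
    a: np.ndarray
    phi: np.ndarray
    beta: np.ndarray
    m: np.ndarray
    H_star: np.ndarray
    V_star: np.ndarray
    H0_star: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("r", "a", "phi", "beta", "m", "H_star", "V_star", "H0_star"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def n_hosts(self) -> int:
        return self.r.size

    @property
    def n_viruses(self) -> int:
        return self.m.size


def build_competition(H0_star: np.ndarray, K: float,
                      rng: np.random.Generator) -> np.ndarray | None:
    """Host-host competition matrix pinning the virus-free equilibrium at K.

    Starts from a_ii = 1, a_ii' = 0 and, row by row, keeps drawing a random
    partner k != i with a_ik ~ U(0, 1) until the weighted sum
    sum_i' a_ii' H0*_i' exceeds K, then clips the last coefficient so the sum
    equals K exactly.  Returns None when a row walks through every partner
    without exceeding K (the caller resamples H0* and retries).
    """
    H0 = np.asarray(H0_star, dtype=float)
    n = H0.size
    if n == 1:
        # single host: the constraint a_11 * H0_1 = K forces H0_1 = K
        return np.ones((1, 1))
    a = np.eye(n)
    for i in range(n):
        total = H0[i]
        if total > K:  # cannot happen for H0* <= K, kept as a guard
            raise ValueError("single-host density exceeds carrying capacity")
        order = rng.permutation([k for k in range(n) if k != i])
        done = False
        for k in order:
            draw = rng.uniform(0.0, 1.0)
            if total + draw * H0[k] > K:
                a[i, k] = (K - total) / H0[k]
                done = True
                break
            a[i, k] = draw
            total += draw * H0[k]
        if not done:
            return None
    return a


def sample_traits(net: InteractionNetwork, rng,
                  max_retries: int = 100) -> TraitSet:
    """Sample a coexistence-guaranteeing trait set for ``net``.

    phi, beta, H*, V* and H0* are drawn uniformly from the feasible ranges;
    the competition matrix enforces the virus-free equilibrium exactly, and
    m and r are solved from the fixed-point conditions:

        m_j = sum_i M_ij phi_ij beta_ij H*_i
        r_i = (sum_j M_ij phi_ij V*_j) / (1 - sum_i' a_ii' H*_i' / K)

    Raises ``RuntimeError`` if no feasible competition matrix is found after
    ``max_retries`` resamplings of H0*.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    net.validate()
    nH, nV = net.n_hosts, net.n_viruses
    M = net.M.astype(float)
    K = CARRYING_CAPACITY

    H_star = rng.uniform(*RANGES["H_star"], size=nH)
    V_star = rng.uniform(*RANGES["V_star"], size=nV)
    phi = rng.uniform(*RANGES["phi"], size=(nH, nV))
    beta = rng.uniform(*RANGES["beta"], size=(nH, nV))

    a = None
    for _ in range(max_retries):
        H0_star = rng.uniform(*RANGES["H0_star"], size=nH)
        if nH == 1:
            H0_star = np.array([K])
        a = build_competition(H0_star, K, rng)
        if a is not None:
            break
    if a is None:
        raise RuntimeError(
            "could not construct a feasible competition matrix after "
            f"{max_retries} resamplings of H0*")

    m = (M * phi * beta).T @ H_star                       # (N_V,)
    denom = 1.0 - (a @ H_star) / K                        # (N_H,)
    r = (M * phi) @ V_star / denom                        # (N_H,)
    if not (r > 0).all() or not (m > 0).all():
        raise RuntimeError("nonpositive growth or decay rate; "
                           "network must have no isolated populations")

    return TraitSet(r=r, K=K, a=a, phi=phi, beta=beta, m=m,
                    H_star=H_star, V_star=V_star, H0_star=H0_star)


def effective_network(net: InteractionNetwork, traits: TraitSet) -> np.ndarray:
    """Weighted interaction network M~_ij = M_ij * phi_ij * beta_ij."""
    if traits.phi.shape != net.M.shape:
        raise ValueError("trait and network shapes disagree")
    return net.M * traits.phi * traits.beta


def save_traits(traits: TraitSet, path: str | Path) -> None:
    doc = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
           for k, v in asdict(traits).items()}
    Path(path).write_text(json.dumps(doc))


def load_traits(path: str | Path) -> TraitSet:
    doc = json.loads(Path(path).read_text())
    return TraitSet(**doc)
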