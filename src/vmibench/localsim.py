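"""Local similarity (LS) scores for host-virus pairs.

Local similarity analysis detects associations confined to a sub-interval of
the sampling window, optionally with a bounded time offset between the two
series.  Both series are first mapped to normal scores (a rank-based
inverse-normal transform), then the LS statistic is the signed
maximal-magnitude contiguous sum of elementwise products over all offsets
|d| <= delay_limit, normalized by the series length.  It generalizes the
Pearson correlation: a pair that trends together only during part of the
window scores high locally even when the full-window correlation is low.

No permutation or bootstrap machinery is included: scores are compared by
threshold sweep downstream, not by p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

from .correlation import CorrelationNetwork
from .dynamics import SampleSet

__all__ = ["LSConfig", "normal_score_transform", "ls_score", "elsa_network"]


@dataclass(frozen=True)
class LSConfig:
    """delay_limit is in samples (3 samples = 6 h at 2-h sampling)."""

    delay_limit: int = 3
    transform: bool = True

    def __post_init__(self) -> None:
        if self.delay_limit < 0:
            raise ValueError("delay_limit must be nonnegative")


def normal_score_transform(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform.

    The value at rank k maps to the standard normal quantile at k/(S+1);
    ties share average ranks.  Invariant to any strictly monotone transform
    of the input.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    ranks = rankdata(x)
    return ndtri(ranks / (x.size + 1))


def _best_run(p: np.ndarray) -> tuple[float, int, int]:
    """Maximal-sum contiguous run of ``p``, with its [start, end) indices.

    Prefix-sum formulation of Kadane's scan: the best run ending at k is
    cumsum[k] minus the running minimum of earlier prefix sums.
    """
    cs = np.cumsum(p)
    prev = np.concatenate(([0.0], cs[:-1]))
    vals = cs - np.minimum.accumulate(prev)
    e = int(np.argmax(vals))
    s = int(np.argmin(prev[: e + 1]))
    return float(vals[e]), s, e + 1


def ls_score(x: np.ndarray, y: np.ndarray,
             cfg: LSConfig = LSConfig()) -> tuple[float, int, tuple[int, int]]:
    """Signed LS score, its offset, and the sub-interval where it occurred.

    For each offset d with |d| <= delay_limit, forms the products
    x[k] * y[k + d] over valid k and finds both the maximal positive run and
    the maximal negative run (so anticorrelated intervals yield negative
    scores).  Returns (score, offset, (start, length)) where score is the
    signed run sum of largest magnitude divided by the series length S, and
    start indexes the x series.  Offsets are scanned 0, +1, -1, +2, ... and
    runs must strictly exceed the incumbent magnitude, so ties resolve to
    the smallest |offset| (positive sign first within an offset).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    S = x.size
    best = 0.0
    best_d = 0
    best_iv = (0, 0)
    offsets = [0]
    for d in range(1, cfg.delay_limit + 1):
        offsets += [d, -d]
    for d in offsets:
        if d >= 0:
            p = x[: S - d] * y[d:]
            x_off = 0
        else:
            p = x[-d:] * y[: S + d]
            x_off = -d
        if p.size == 0:
            continue
        pos, ps, pe = _best_run(p)
        neg, ns, ne = _best_run(-p)
        if pos > abs(best):
            best, best_d, best_iv = pos, d, (x_off + ps, pe - ps)
        if neg > abs(best):
            best, best_d, best_iv = -neg, d, (x_off + ns, ne - ns)
    return best / S, best_d, best_iv


def elsa_network(samples: SampleSet,
                 cfg: LSConfig = LSConfig()) -> CorrelationNetwork:
    """LS score for every host-virus pair of a sample set.

    Only the virus-host block is computed; host-host and virus-virus pairs
    are not part of the benchmark.  Offsets are bounded by cfg.delay_limit
    samples; the reported per-pair delay is offset * frequency in hours.
    """
    hs = samples.h
    vs = samples.v
    if cfg.transform:
        hs = np.vstack([normal_score_transform(r) for r in hs]) if hs.size else hs
        vs = np.vstack([normal_score_transform(r) for r in vs]) if vs.size else vs
    nH, nV = hs.shape[0], vs.shape[0]
    R = np.zeros((nH, nV))
    delays = np.zeros((nH, nV))
    for i in range(nH):
        for j in range(nV):
            score, d, _ = ls_score(hs[i], vs[j], cfg)
            R[i, j] = score
            delays[i, j] = d * samples.frequency
    return CorrelationNetwork(R, method="elsa", delays=delays,
                              n_samples=samples.n_samples,
                              frequency=samples.frequency)
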