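"""Kimura two-parameter substitution process and distance estimator.

The same two-parameter model is used on both sides of the pipeline: the
simulator evolves sequences under the exact continuous-time K2P process
(per-site Poisson number of events, jump chain weighted by the
transition/transversion rate ratio kappa), and the estimator inverts the
observed transition proportion P and transversion proportion Q into the
expected number of substitutions per site,

    K = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)).

Because simulator and estimator share the model, dating recovery is a true
parameter-recovery experiment rather than a model-mismatch benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .util import N, TS_PARTNER, TV_PARTNER_1, TV_PARTNER_2

PURINE = frozenset((0, 2))  # A, G


def evolve_codes(
    codes: np.ndarray,
    distance: float,
    kappa: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve a coded sequence by an expected `distance` substitutions/site.

    Each site receives Poisson(distance) substitution events; each event is a
    transition with probability kappa/(kappa+2), otherwise one of the two
    transversions, matching the K2P rate matrix with total rate `distance`.
    Non-ACGT sites are left untouched.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    out = codes.copy()
    valid = out < 4
    n_events = np.zeros(out.shape, dtype=np.int64)
    n_events[valid] = rng.poisson(distance, size=int(valid.sum()))
    p_ts = kappa / (kappa + 2.0)
    max_events = int(n_events.max()) if n_events.size else 0
    for step in range(max_events):
        idx = np.nonzero(n_events > step)[0]
        u = rng.random(idx.size)
        cur = out[idx]
        nxt = np.where(
            u < p_ts,
            TS_PARTNER[cur],
            np.where(u < (1.0 + p_ts) / 2.0, TV_PARTNER_1[cur], TV_PARTNER_2[cur]),
        )
        out[idx] = nxt
    return out


@dataclass(frozen=True)
class K2PResult:
    K: float  # substitutions/site (nan when saturated)
    P: float  # transition proportion
    Q: float  # transversion proportion
    n_sites: int  # comparable (non-gap, non-N) columns
    saturated: bool


def k2p_from_codes(a: np.ndarray, b: np.ndarray) -> K2PResult:
    """K2P distance between two equal-length coded rows.

    Gap and N columns are excluded from the counts; raises if no column is
    comparable.
    """
    if a.shape != b.shape:
        raise ValueError("rows must have equal length")
    ok = (a < 4) & (b < 4)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable (non-gap, non-N) columns")
    x, y = a[ok], b[ok]
    diff = x != y
    # transitions are A<->G and C<->T: same parity of (code mod 2 groups)
    # purines are codes {0,2}, pyrimidines {1,3}: transition iff same (code & 1)
    ts = diff & ((x & 1) == (y & 1))
    p = float(ts.sum()) / n
    q = float(diff.sum() - ts.sum()) / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return K2PResult(K=float("nan"), P=p, Q=q, n_sites=n, saturated=True)
    k = 0.5 * np.log(1.0 / w1) + 0.25 * np.log(1.0 / w2)
    return K2PResult(K=float(k), P=p, Q=q, n_sites=n, saturated=False)
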