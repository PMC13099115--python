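"""Insertion dating from LTR-pair divergence.

At integration the two LTRs of a provirus are identical; each subsequently
accumulates substitutions independently at the neutral rate r, so the K2P
distance K between the pair estimates 2·r·T and the insertion age is

    T = K / (2 r)

with r defaulting to 2.3e-9 substitutions/site/year (domestic-cat neutral
rate) and an uncertainty interval [2.0e-9, 2.5e-9] propagated into age
bounds (a larger rate gives a younger bound). K = 0 (identical LTRs) is
reported as an age-0 lower bound: the estimator cannot resolve very recent
insertions. Saturated pairs (the K2P logarithms undefined) are flagged and
left undated rather than patched with a different estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .kimura import k2p_from_codes
from .util import encode

DEFAULT_RATE = 2.3e-9
DEFAULT_RATE_INTERVAL = (2.0e-9, 2.5e-9)


@dataclass(frozen=True)
class DatingResult:
    copy_id: str
    K: float
    P: float
    Q: float
    n_sites: int
    T_years: float
    T_low: float
    T_high: float
    identical_ltrs: bool
    saturated: bool


def align_ltr_pair(ltr5_seq: str, ltr3_seq: str) -> Align.Alignment:
    """Global affine-gap alignment of the two LTRs (deterministic best)."""
    if not ltr5_seq or not ltr3_seq:
        raise ValueError("empty LTR sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner.align(ltr5_seq, ltr3_seq)[0]


def k2p_distance(alignment: Align.Alignment) -> tuple[float, float, float, int]:
    """(K, P, Q, n_sites) over the non-gap, non-N columns of a pairwise alignment.

    K is nan with the saturation condition (1-2P-Q <= 0 or 1-2Q <= 0).
    """
    row_a, row_b = str(alignment[0]), str(alignment[1])
    res = k2p_from_codes(encode(row_a), encode(row_b))
    return res.K, res.P, res.Q, res.n_sites


def date_insertion(K: float, r: float = DEFAULT_RATE,
                   r_interval: tuple[float, float] = DEFAULT_RATE_INTERVAL,
                   copy_id: str = "", P: float = 0.0, Q: float = 0.0,
                   n_sites: int = 0, saturated: bool = False) -> DatingResult:
    """Age T = K/(2r) with bounds from the rate interval."""
    if r <= 0:
        raise ValueError("rate must be positive")
    if saturated or K != K:  # nan-safe
        return DatingResult(copy_id, float("nan"), P, Q, n_sites,
                            float("nan"), float("nan"), float("nan"),
                            identical_ltrs=False, saturated=True)
    if K < 0:
        raise ValueError("K must be >= 0")
    r_lo, r_hi = min(r_interval), max(r_interval)
    return DatingResult(
        copy_id=copy_id, K=K, P=P, Q=Q, n_sites=n_sites,
        T_years=K / (2 * r),
        T_low=K / (2 * r_hi),   # larger rate -> younger bound
        T_high=K / (2 * r_lo),
        identical_ltrs=(K == 0.0), saturated=False)


def date_ltr_pair(ltr5_seq: str, ltr3_seq: str, copy_id: str = "",
                  r: float = DEFAULT_RATE,
                  r_interval: tuple[float, float] = DEFAULT_RATE_INTERVAL) -> DatingResult:
    """Align an LTR pair, estimate K2P distance, and convert to age."""
    aln = align_ltr_pair(ltr5_seq, ltr3_seq)
    K, P, Q, n = k2p_distance(aln)
    return date_insertion(K, r, r_interval, copy_id=copy_id, P=P, Q=Q,
                          n_sites=n, saturated=(K != K))
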