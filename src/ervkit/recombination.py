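"""Triplet-based recombination screening with a multi-method consensus rule.

Three sliding statistics are implemented, each scanning every (candidate,
parent A, parent B) triplet of an alignment of typical copies:

* maxchi  — maximal chi-square contrast of pairwise match proportions in the
  w variable sites left vs right of a candidate breakpoint;
* chimaera — the same contrast restricted to sites where the two putative
  parents differ, scored on the candidate-vs-parent match vector;
* rdp_window — sliding-window pairwise identity: the longest run of windows
  in which the locally closest parent differs from the globally closest one.

Significance is assessed by permuting the order of the informative sites
(seeded, so deterministic); per method, p-values are Bonferroni-corrected
over the number of triplets scanned, and a copy flagged by at least
`min_methods` methods is removed from phylogenetic analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .util import encode, substream

__all__ = ["RecombinationCall", "ConsensusDecision", "variable_sites",
           "maxchi_scan", "chimaera_scan", "rdp_window_scan", "scan_triplets",
           "consensus_calls"]


@dataclass(frozen=True)
class RecombinationCall:
    triplet: tuple[str, str, str]   # (candidate, parent A, parent B)
    method: str
    statistic: float
    breakpoint: int | None          # alignment column
    p_value: float
    no_call: bool = False
    reason: str = ""


@dataclass(frozen=True)
class ConsensusDecision:
    copy_id: str
    methods_supporting: int
    removed: bool


def _codes_matrix(rows: list[str]) -> np.ndarray:
    return np.vstack([encode(r) for r in rows])


def variable_sites(rows: list[str] | np.ndarray) -> np.ndarray:
    """Alignment columns where the sequences differ (gap/N columns excluded)."""
    m = rows if isinstance(rows, np.ndarray) else _codes_matrix(list(rows))
    if m.shape[0] < 2:
        raise ValueError("need at least 2 sequences")
    ok = (m < 4).all(axis=0)
    var = (m != m[0]).any(axis=0)
    return np.nonzero(ok & var)[0]


def _max_chi2_profile(match: np.ndarray, w: int) -> tuple[float, int]:
    """Max chi2 over breakpoints of a 0/1 match vector, windows of w sites.

    chi2 = N (ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) on the 2x2 table of
    matches/mismatches in the left vs right window; returns (max, argmax index
    into `match`)."""
    n = match.size
    if n < 2 * w:
        return float("nan"), -1
    cs = np.concatenate([[0], np.cumsum(match)])
    ks = np.arange(w, n - w + 1)
    a = cs[ks] - cs[ks - w]          # left matches
    c = cs[ks + w] - cs[ks]          # right matches
    b, d = w - a, w - c
    N = 2.0 * w
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, N * (a * d - b * c) ** 2 / denom, 0.0)
    i = int(np.argmax(chi2))
    return float(chi2[i]), int(ks[i])


def _permutation_p(observed: float, vectors: list[np.ndarray], w: int,
                   n_permutations: int, rng: np.random.Generator) -> float:
    """Permute site order (same permutation across vectors), rescan, rank."""
    n = vectors[0].size
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        best = max(_max_chi2_profile(v[perm], w)[0] for v in vectors)
        if best >= observed:
            exceed += 1
    return (1.0 + exceed) / (n_permutations + 1.0)


def maxchi_scan(rows: list[str], ids: tuple[str, str, str],
                window_halfwidth: int = 20, n_permutations: int = 199,
                seed: int = 0) -> RecombinationCall:
    """MaxChi scan of one triplet (candidate first)."""
    m = _codes_matrix(rows)
    sites = variable_sites(m)
    if sites.size < 2 * window_halfwidth:
        return RecombinationCall(ids, "maxchi", float("nan"), None, 1.0,
                                 no_call=True, reason="insufficient variable sites")
    sub = m[:, sites]
    vectors = [(sub[i] == sub[j]).astype(np.int8)
               for i, j in ((0, 1), (0, 2), (1, 2))]
    best_stat, best_idx = -1.0, -1
    for v in vectors:
        stat, idx = _max_chi2_profile(v, window_halfwidth)
        if stat > best_stat:
            best_stat, best_idx = stat, idx
    rng = substream(seed, "maxchi", *ids)
    p = _permutation_p(best_stat, vectors, window_halfwidth, n_permutations, rng)
    return RecombinationCall(ids, "maxchi", best_stat, int(sites[best_idx]), p)


def chimaera_scan(rows: list[str], ids: tuple[str, str, str],
                  window_halfwidth: int = 20, n_permutations: int = 199,
                  seed: int = 0) -> RecombinationCall:
    """Chimaera variant: candidate match vector at parent-informative sites."""
    m = _codes_matrix(rows)
    ok = (m < 4).all(axis=0)
    informative = np.nonzero(ok & (m[1] != m[2]))[0]
    if informative.size < 2 * window_halfwidth:
        return RecombinationCall(ids, "chimaera", float("nan"), None, 1.0,
                                 no_call=True, reason="insufficient informative sites")
    v = (m[0, informative] == m[1, informative]).astype(np.int8)
    stat, idx = _max_chi2_profile(v, window_halfwidth)
    rng = substream(seed, "chimaera", *ids)
    p = _permutation_p(stat, [v], window_halfwidth, n_permutations, rng)
    return RecombinationCall(ids, "chimaera", stat, int(informative[idx]), p)


def rdp_window_scan(rows: list[str], ids: tuple[str, str, str],
                    window_len: int = 100, step: int = 25,
                    n_permutations: int = 199, seed: int = 0) -> RecombinationCall:
    """Sliding-window identity ranking: longest run where the locally closest
    parent differs from the globally closest parent."""
    if window_len < 30:
        raise ValueError("window_len must be >= 30 columns")
    m = _codes_matrix(rows)
    ok = (m < 4).all(axis=0)
    cols = np.nonzero(ok)[0]
    if cols.size <= window_len:
        return RecombinationCall(ids, "rdp_window", float("nan"), None, 1.0,
                                 no_call=True, reason="alignment shorter than window")
    a = (m[0, cols] == m[1, cols]).astype(np.int8)
    b = (m[0, cols] == m[2, cols]).astype(np.int8)

    def longest_run(av: np.ndarray, bv: np.ndarray) -> tuple[int, int]:
        csa = np.concatenate([[0], np.cumsum(av)])
        csb = np.concatenate([[0], np.cumsum(bv)])
        starts = np.arange(0, av.size - window_len + 1, step)
        ia = csa[starts + window_len] - csa[starts]
        ib = csb[starts + window_len] - csb[starts]
        global_parent = 0 if csa[-1] >= csb[-1] else 1
        local = np.where(ia == ib, global_parent, (ib > ia).astype(int))
        run = best = 0
        best_start = -1
        cur_start = 0
        for i, loc in enumerate(local):
            if loc != global_parent:
                if run == 0:
                    cur_start = i
                run += 1
                if run > best:
                    best, best_start = run, cur_start
            else:
                run = 0
        return best, best_start

    obs, obs_start = longest_run(a, b)
    rng = substream(seed, "rdp", *ids)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(a.size)
        if longest_run(a[perm], b[perm])[0] >= obs:
            exceed += 1
    p = (1.0 + exceed) / (n_permutations + 1.0)
    bp = int(cols[obs_start * step]) if obs_start >= 0 else None
    return RecombinationCall(ids, "rdp_window", float(obs), bp, p)


METHODS = {"maxchi": maxchi_scan, "chimaera": chimaera_scan,
           "rdp_window": rdp_window_scan}


def _best_parents(alignment: dict[str, str], candidate: str) -> tuple[str, str]:
    """The two sequences most similar to the candidate (putative parents)."""
    cand = _codes_matrix([alignment[candidate]])[0]
    scored = []
    for other in sorted(alignment):
        if other == candidate:
            continue
        row = _codes_matrix([alignment[other]])[0]
        ok = (cand < 4) & (row < 4)
        ident = float((cand[ok] == row[ok]).mean()) if ok.any() else 0.0
        scored.append((-ident, other))
    scored.sort()
    return scored[0][1], scored[1][1]


def scan_triplets(alignment: dict[str, str], seed: int = 0,
                  methods: tuple[str, ...] = ("maxchi", "chimaera", "rdp_window"),
                  max_triplets: int | None = 500,
                  exhaustive: bool = False,
                  **kwargs) -> list[RecombinationCall]:
    """Scan candidate/parent triplets of an alignment.

    By default each sequence takes the candidate role once, with its two most
    similar sequences as the putative parents — this keeps the per-method
    Bonferroni family at the number of candidates, so permutation p-values
    retain resolution. With `exhaustive=True` every member of every 3-subset
    is scanned as candidate (capped deterministically in sorted-id order).
    """
    ids = sorted(alignment)
    triplets: list[tuple[str, str, str]] = []
    if exhaustive:
        for combo in combinations(ids, 3):
            for cand in combo:
                parents = tuple(x for x in combo if x != cand)
                triplets.append((cand, *parents))
    elif len(ids) >= 3:
        for cand in ids:
            triplets.append((cand, *_best_parents(alignment, cand)))
    if max_triplets is not None:
        triplets = triplets[:max_triplets]
    calls: list[RecombinationCall] = []
    for trip in triplets:
        rows = [alignment[t] for t in trip]
        for meth in methods:
            calls.append(METHODS[meth](rows, trip, seed=seed, **kwargs))
    return calls


def consensus_calls(calls: list[RecombinationCall], min_methods: int = 2,
                    alpha: float = 0.05) -> list[ConsensusDecision]:
    """Per-candidate consensus after Bonferroni correction within each method.

    A copy is removed when at least `min_methods` methods flag it in any of
    its triplets.
    """
    n_tests = {}
    for c in calls:
        if not c.no_call:
            n_tests[c.method] = n_tests.get(c.method, 0) + 1
    support: dict[str, set[str]] = {}
    for c in calls:
        if c.no_call:
            continue
        p_corr = min(1.0, c.p_value * n_tests[c.method])
        if p_corr <= alpha:
            support.setdefault(c.triplet[0], set()).add(c.method)
    candidates = sorted({c.triplet[0] for c in calls})
    return [ConsensusDecision(cid, len(support.get(cid, ())),
                              removed=len(support.get(cid, ())) >= min_methods)
            for cid in candidates]
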