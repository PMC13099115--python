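"""Benchmark scenario builders with exact ground truth.

These construct genomes directly (no host pedigree) for targeted evaluations:

* `mining_benchmark` — full-length copies implanted at explicit divergences
  (up to 15%, i.e. well beyond the divergence reached at the simulated age
  range), plus solo LTRs and deleted copies, to stress the homology search;
* `erv_free_genomes` — random backgrounds with no implants (false-positive
  control);
* `clean_class_scenario` — one young exemplar of each of the five structural
  classes per genome, for classification benchmarking.

All truth coordinates refer to the emitted genome (0-based half-open element
intervals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kimura import evolve_codes
from .reference import ProvirusReference, synthetic_reference
from .simulate import SimulationConfig, TruthRecord, apply_structural_events
from .util import decode, encode, random_background, revcomp_codes, substream


@dataclass
class BenchmarkDataset:
    genomes: dict[str, dict[str, str]]
    truth: pd.DataFrame
    reference: ProvirusReference


def _implant(bg: np.ndarray, inserts: list[tuple[int, np.ndarray, dict]],
             tsd_len: int = 4, cut_after: int | None = None
             ) -> tuple[str, list[dict]]:
    """Insert elements with exact TSD duplication; returns genome and truth rows.

    `inserts` are (background position, element codes, info) sorted by
    position. `cut_after` truncates the scaffold right after that insert index
    (scaffold ends inside the element tail).
    """
    segments = []
    rows = []
    prev, shift = 0, 0
    for idx, (pos, ele, info) in enumerate(sorted(inserts, key=lambda x: x[0])):
        tsd = bg[pos: pos + tsd_len]
        segments.append(bg[prev: pos + tsd_len])
        start = pos + tsd_len + shift
        if cut_after == idx:
            keep = info.get("keep", len(ele) // 3)
            ele = ele[:keep]
            segments.append(ele)
            rows.append({**info, "start": start, "end": start + len(ele),
                         "tsd": decode(tsd), "truncated": True})
            return decode(np.concatenate(segments)), rows
        segments.append(ele)
        segments.append(tsd)
        rows.append({**info, "start": start, "end": start + len(ele),
                     "tsd": decode(tsd), "truncated": False})
        shift += len(ele) + tsd_len
        prev = pos + tsd_len
    segments.append(bg[prev:])
    return decode(np.concatenate(segments)), rows


def mining_benchmark(seed: int = 0, n_genomes: int = 3, bg_len: int = 1_000_000,
                     divergences: tuple[float, ...] = (0.0, 0.02, 0.05, 0.08,
                                                       0.10, 0.12, 0.15),
                     reference: ProvirusReference | None = None) -> BenchmarkDataset:
    """Implanted full copies at fixed divergences + solo LTRs + a deleted copy.

    Per genome: one full-length copy per divergence level (alternating
    strands), two solo LTRs (1% and 5% diverged) and one copy with a 1.5 kb
    internal deletion at 5% divergence.
    """
    ref = reference or synthetic_reference()
    ref_codes = encode(ref.seq)
    ltr_codes = encode(ref.ltr_seq)
    kappa = 2.0
    genomes, rows = {}, []
    n_items = len(divergences) + 3
    spacing = (bg_len - 60_000) // n_items
    for g in range(n_genomes):
        rng = substream(seed, "bench", g)
        bg = random_background(bg_len, rng)
        inserts = []
        k = 0
        for i, d in enumerate(divergences):
            ele = evolve_codes(ref_codes, d, kappa, rng)
            minus = i % 2 == 1
            if minus:
                ele = revcomp_codes(ele)
            pos = 30_000 + k * spacing + int(rng.integers(0, 5000))
            inserts.append((pos, ele, {"copy_id": f"g{g}_full{i}", "kind": "full",
                                       "divergence": d,
                                       "strand": "-" if minus else "+"}))
            k += 1
        for i, d in enumerate((0.01, 0.05)):
            ele = evolve_codes(ltr_codes, d, kappa, rng)
            pos = 30_000 + k * spacing + int(rng.integers(0, 5000))
            inserts.append((pos, ele, {"copy_id": f"g{g}_solo{i}", "kind": "solo",
                                       "divergence": d, "strand": "+"}))
            k += 1
        ele = evolve_codes(ref_codes, 0.05, kappa, rng)
        i0, i1 = ref.internal_interval
        ds = int(rng.integers(i0 + 200, i1 - 1900))
        ele = np.concatenate([ele[:ds], ele[ds + 1500:]])
        pos = 30_000 + k * spacing + int(rng.integers(0, 5000))
        inserts.append((pos, ele, {"copy_id": f"g{g}_del", "kind": "deleted",
                                   "divergence": 0.05, "strand": "+"}))
        genome_seq, truth_rows = _implant(bg, inserts)
        name = f"bench_{g}"
        genomes[name] = {"scaffold_0": genome_seq}
        for r in truth_rows:
            r["genome"] = name
            r["scaffold"] = "scaffold_0"
        rows.extend(truth_rows)
    return BenchmarkDataset(genomes=genomes, truth=pd.DataFrame(rows), reference=ref)


def erv_free_genomes(seed: int = 0, n_genomes: int = 1,
                     bg_len: int = 1_000_000) -> dict[str, dict[str, str]]:
    """Random genomes with no ERV content (false-positive control)."""
    out = {}
    for g in range(n_genomes):
        rng = substream(seed, "ervfree", g)
        out[f"ervfree_{g}"] = {"scaffold_0": decode(random_background(bg_len, rng))}
    return out


def clean_class_scenario(seed: int = 0, n_genomes: int = 6,
                         bg_len: int = 300_000,
                         max_age_years: float = 1.0e6,
                         reference: ProvirusReference | None = None
                         ) -> BenchmarkDataset:
    """One young exemplar of each structural class per genome (5 x n copies).

    Ages are drawn uniformly below `max_age_years` (about 0.2% expected LTR
    divergence at most), so every class signal is unambiguous: the confusion
    matrix of a correct classifier is exactly diagonal here.
    """
    ref = reference or synthetic_reference()
    ref_codes = encode(ref.seq)
    config = SimulationConfig(seed=seed, background_length=bg_len)
    r, kappa = config.r, config.kappa
    genomes, rows = {}, []
    classes = ("typical", "solo_ltr", "atypical", "paired_solo_ltr",
               "incomplete_segment")
    events = {
        "typical": [],
        "solo_ltr": [{"type": "solo_collapse", "keep_ltr": "5"}],
        "atypical": [{"type": "internal_duplication"}],
        "paired_solo_ltr": [{"type": "paired_solo", "gap": 50}],
        "incomplete_segment": [],
    }
    for g in range(n_genomes):
        rng = substream(seed, "classes", g)
        bg = random_background(bg_len, rng)
        inserts = []
        cut_after = None
        for i, cls in enumerate(classes):
            age = float(rng.uniform(0, max_age_years))
            truth = TruthRecord(copy_id=f"g{g}_{cls}", scaffold=0,
                                insertion_position=0, age_years=age, tsd="",
                                class_truth=cls, events=list(events[cls]),
                                carriers=[f"class_{g}"])
            if cls == "typical" and g % 2 == 0:
                # a 1.5 kb pol deletion must stay typical
                i0, _ = ref.internal_interval
                pf = ref.features["pol"]
                truth.events.append({"type": "deletion", "start": pf.start,
                                     "end": pf.start + 1500, "size": 1500})
            ele = evolve_codes(ref_codes, r * age, kappa, rng)
            ele = apply_structural_events(ele, truth, ref)
            if cls == "incomplete_segment":
                pos = bg_len - 24_000   # clipped: scaffold ends inside the copy
                cut_after = i
                info = {"copy_id": truth.copy_id, "kind": cls, "age_years": age,
                        "strand": "+", "keep": 2500}
            else:
                pos = 25_000 + i * 50_000 + int(rng.integers(0, 8000))
                info = {"copy_id": truth.copy_id, "kind": cls, "age_years": age,
                        "strand": "+"}
            inserts.append((pos, ele, info))
        genome_seq, truth_rows = _implant(bg, inserts, cut_after=cut_after)
        name = f"class_{g}"
        genomes[name] = {"scaffold_0": genome_seq}
        for row in truth_rows:
            row["genome"] = name
            row["scaffold"] = "scaffold_0"
        rows.extend(truth_rows)
    return BenchmarkDataset(genomes=genomes, truth=pd.DataFrame(rows), reference=ref)
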