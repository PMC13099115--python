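"""Simulator: pedigree, endogenization process, copy evolution, emission."""

import numpy as np
import pandas as pd
import pytest

from ervkit.simulate import (IntrogressionEdge, SimulationConfig, TruthRecord,
                             build_host_pedigree, emit_genomes, evolve_copy,
                             simulate, simulate_endogenization, single_tip_tree)
from ervkit.util import substream


def small_config(**kw):
    base = dict(seed=3, background_length=200_000, min_spacing=25_000,
                position_margin=15_000, endogenization_rate=1.0)
    base.update(kw)
    return SimulationConfig(**base)


def test_default_pedigree_topology():
    tree = build_host_pedigree(SimulationConfig())
    assert tree.tips() == ["catus_1", "catus_2", "catus_3", "chaus", "nigripes"]
    # earliest split is the chaus branch at 2.0 My
    assert tree.nodes["root"].time == pytest.approx(2.0e6)
    assert tree.branch_interval("chaus") == (0.0, 2.0e6)
    assert tree.tips_below("anc_felis") == ["catus_1", "catus_2", "catus_3",
                                            "nigripes"]


def test_single_tip_tree_has_no_shared_copies():
    tree = single_tip_tree("ind", duration_years=0.0)
    assert tree.tips() == ["ind"]
    assert tree.total_branch_length_my() == 0.0


def test_introgression_time_outside_branch_is_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(
            introgression=IntrogressionEdge("anc_catus", "chaus", 1.5e6)
        ) and build_host_pedigree(SimulationConfig(
            introgression=IntrogressionEdge("anc_catus", "chaus", 1.5e6)))


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(tsd_length=5)
    with pytest.raises(ValueError):
        SimulationConfig(deletion_prob=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(endogenization_rate=-1)


def test_zero_rate_gives_empty_truth(ref):
    cfg = small_config(endogenization_rate=0.0)
    truths = simulate_endogenization(build_host_pedigree(cfg), ref, cfg)
    assert truths == []


def test_poisson_event_count_expectation(ref):
    """Mean event count over replicates within 3 SE of rate x branch length."""
    lam_per_my = 1.5
    counts = []
    for seed in range(60):
        cfg = small_config(seed=seed, endogenization_rate=lam_per_my,
                           min_spacing=1_000, position_margin=5_000)
        tree = build_host_pedigree(cfg)
        counts.append(len(simulate_endogenization(tree, ref, cfg)))
    expected = lam_per_my * tree.total_branch_length_my()
    se = np.sqrt(expected / len(counts))
    assert abs(np.mean(counts) - expected) < 3 * se


def test_inheritance_follows_branch(ref):
    """A copy on branch b is carried by exactly the tips below b."""
    cfg = small_config(seed=11, endogenization_rate=2.0)
    tree = build_host_pedigree(cfg)
    truths = simulate_endogenization(tree, ref, cfg)
    assert truths
    for t in truths:
        assert t.carriers == tree.tips_below(t.branch)
        assert 0 <= t.age_years <= tree.branch_interval(t.branch)[1]


def test_introgressed_copies_reach_recipient(ref):
    cfg = small_config(seed=2, endogenization_rate=3.0,
                       introgression=IntrogressionEdge("anc_catus", "chaus",
                                                       0.5e6, burst=0))
    tree = build_host_pedigree(cfg)
    truths = simulate_endogenization(tree, ref, cfg)
    donors = [t for t in truths if t.branch in ("anc_catus", "anc_felis", "root")
              and t.age_years > 0.5e6]
    assert donors, "scenario should produce transferable copies"
    for t in donors:
        assert "chaus" in t.carriers


def test_evolve_copy_age_zero_is_reference(ref):
    cfg = small_config()
    t = TruthRecord("copy000", 0, 50_000, 0.0, "ACGT", "typical",
                    carriers=["catus_1"])
    seq = evolve_copy(ref, t, cfg)
    assert seq == ref.seq
    assert seq[:500] == seq[-500:]     # 5' LTR == 3' LTR


def test_evolve_copy_solo_collapse_is_single_ltr(ref):
    cfg = small_config()
    t = TruthRecord("copy001", 0, 50_000, 0.0, "ACGT", "solo_ltr",
                    events=[{"type": "solo_collapse", "keep_ltr": "5"}],
                    carriers=["catus_1"])
    assert evolve_copy(ref, t, cfg) == ref.ltr_seq


def test_evolve_copy_ltr_divergence_matches_clock(ref):
    """Mean LTR-pair differences within 3 SE of Poisson mean 2 r t L."""
    cfg = small_config()
    L = 500
    diffs = []
    for i in range(300):
        t = TruthRecord(f"copy{i:03d}", 0, 0, 1.0e6, "ACGT", "typical",
                        carriers=["x"])
        seq = evolve_copy(ref, t, cfg, rng=substream(9, "clocktest", i))
        ltr5, ltr3 = seq[:L], seq[-L:]
        diffs.append(sum(a != b for a, b in zip(ltr5, ltr3)))
    lam = 2 * cfg.r * 1.0e6 * L
    assert abs(np.mean(diffs) - lam) < 3 * np.sqrt(lam / len(diffs)) + 0.05


def test_emitted_genome_length_and_tsd(ref):
    """Length = background + element + 4; TSD duplicated at age ~0."""
    cfg = small_config(seed=21, endogenization_rate=0.0)
    tree = single_tip_tree("ind")
    t = TruthRecord("copy000", 0, 60_000, 0.0, "", "typical", carriers=["ind"],
                    branch="ind")
    from ervkit.simulate import root_backgrounds
    from ervkit.util import decode
    bg = root_backgrounds(cfg)[0]
    t.tsd = decode(bg[60_000:60_004])
    ds = emit_genomes([t], ref, cfg, host_tree=tree)
    g = ds.genomes["ind"]["scaffold_0"]
    assert len(g) == cfg.background_length + ref.length + 4
    row = ds.truth.iloc[0]
    assert g[row.start: row.end] == ref.seq
    assert g[row.start - 4: row.start] == g[row.end: row.end + 4] == row.tsd_up


def test_truncated_copy_marked_incomplete(ref):
    cfg = small_config(seed=4, truncate_at_end=True, end_margin=5_000)
    tree = single_tip_tree("ind")
    pos = cfg.background_length - 3_000
    t = TruthRecord("copy000", 0, pos, 0.0, "ACGT", "typical",
                    carriers=["ind"], branch="ind")
    ds = emit_genomes([t], ref, cfg, host_tree=tree)
    assert ds.truth.iloc[0].class_truth == "incomplete_segment"
    assert ds.truth.iloc[0].truncated


def test_determinism_byte_identical(ref):
    a = simulate(small_config(seed=77), reference=ref)
    b = simulate(small_config(seed=77), reference=ref)
    assert a.genomes == b.genomes
    pd.testing.assert_frame_equal(a.truth, b.truth)


def test_shared_flanks_diverge_by_background_rate(ref):
    """Carriers of one locus show ~host_background_divergence in flanks."""
    cfg = small_config(seed=13, endogenization_rate=1.5,
                       host_background_divergence=0.005)
    ds = simulate(cfg, reference=ref)
    shared = ds.truth.groupby("copy_id").filter(lambda g: len(g) >= 2)
    assert len(shared), "scenario should contain shared loci"
    copy_id = shared.copy_id.iloc[0]
    rows = shared[shared.copy_id == copy_id].iloc[:2]
    flanks = []
    for _, r in rows.iterrows():
        g = ds.genomes[r.carrier][r.scaffold]
        flanks.append(g[r.start - 2000: r.start - 4])
    div = np.mean([a != b for a, b in zip(*flanks)])
    assert 0.0 < div < 0.02
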