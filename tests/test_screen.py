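"""Candidate selection, positional filters, activation mechanism, overlap
classification and ddCt arithmetic."""

import numpy as np
import pandas as pd
import pytest

from srnascreen.interact import InteractionSite
from srnascreen.screen import (ScreenConfig, SearchRegion, antisense_overlap,
                               build_search_region, classify_candidate,
                               fold_change_from_ct, rbs_accessibility_change,
                               repression_filter, run_screen, select_candidates)
from srnascreen.rbs import RBSLocation
from srnascreen.seqio import (ExpressionRecord, GeneAnnotation,
                              NucleotideSequence, TranscriptModel)
from srnascreen.synth import make_cis_pair

from oracles import EnsembleOracle


def _site(codon_iv, e_hybrid=-10.0, ed_s=0.0, ed_m=0.0, mrna_iv=(1, 10)):
    s = InteractionSite(srna_interval=(60, 75), mrna_interval=mrna_iv,
                        pairing=[(60 + k, mrna_iv[1] - k) for k in range(8)],
                        E_hybrid=e_hybrid, ED_srna=ed_s, ED_mrna=ed_m)
    s.mrna_interval_codon = codon_iv
    return s


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def _ann(gene, operon=None, rank=None, start=101):
    return GeneAnnotation(gene, "c", (start, start + 299), "+", start,
                          operon_id=operon, operon_rank=rank)


def test_select_candidates_threshold_and_symmetry():
    expr = [ExpressionRecord("a", 3.0), ExpressionRecord("b", 0.30),
            ExpressionRecord("c", 2.9), ExpressionRecord("d", 1.0)]
    anns = [_ann(g) for g in "abcd"]
    sel, skipped = select_candidates(expr, anns, ScreenConfig())
    assert sel == ["a", "b"]       # 3.0 inclusive; 0.30 is 3.33-fold down
    assert not skipped


def test_select_candidates_pulls_operon_head():
    expr = [ExpressionRecord("g1", 1.1), ExpressionRecord("g2", 4.0)]
    anns = [_ann("g1", "opA", 1), _ann("g2", "opA", 2, start=501)]
    sel, _ = select_candidates(expr, anns, ScreenConfig())
    assert set(sel) == {"g1", "g2"}
    assert sel[0] == "g2"          # directly selected genes come first


def test_select_candidates_reports_missing_annotation():
    expr = [ExpressionRecord("ghost", 5.0)]
    sel, skipped = select_candidates(expr, [], ScreenConfig())
    assert sel == []
    assert any("ghost" in s for s in skipped)


# ---------------------------------------------------------------------------
# search region
# ---------------------------------------------------------------------------

def _transcript(utr, cds=150, unknown=False):
    seq = "C" * utr + "AUG" + "A" * (cds - 3)
    return TranscriptModel("g", NucleotideSequence("g", seq),
                           None if unknown else utr, utr + 1)


def test_search_region_lengths():
    cfg = ScreenConfig()
    assert len(build_search_region(_transcript(36), cfg).sequence) == 136
    assert len(build_search_region(_transcript(200, unknown=True),
                                   cfg).sequence) == 300
    leaderless = build_search_region(_transcript(0), cfg)
    assert len(leaderless.sequence) == 100
    assert leaderless.codon_offset == 1


def test_search_region_truncates_short_cds():
    with pytest.warns(UserWarning):
        reg = build_search_region(_transcript(30, cds=60), ScreenConfig())
    assert len(reg.sequence) == 90


# ---------------------------------------------------------------------------
# repression filter boundaries
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("iv,expected", [
    ((-10, 5), True),
    ((-39, -39), True),
    ((19, 19), True),
    ((-45, -39), True),    # single-position overlap
    ((-40, -40), False),
    ((20, 20), False),
    ((20, 35), False),
])
def test_repression_filter_boundaries(iv, expected):
    assert repression_filter(_site(iv), ScreenConfig()) is expected


def test_repression_filter_containment_toggle():
    cfg = ScreenConfig(contained=True)
    assert repression_filter(_site((-10, 5)), cfg)
    assert not repression_filter(_site((-45, -39)), cfg)


# ---------------------------------------------------------------------------
# activation mechanism (enumeration-checkable toy)
# ---------------------------------------------------------------------------

def _toy_region(tract="CCUCCU"):
    #        1-6: anti-RBS tract   11-16: RBS (AGGAGG)   19-21: AUG
    seq = tract + "AAAA" + "AGGAGG" + "AA" + "AUGCC"
    return SearchRegion("toy", seq, codon_offset=19, utr_known=True)


def test_rbs_release_matches_enumeration(model):
    """Forcing the planted site open raises Pu(RBS); both probabilities
    match the exhaustive ensemble."""
    reg = _toy_region()
    site = _site(codon_iv=(-18, -13), mrna_iv=(1, 6))
    rbs = RBSLocation((-8, -3), -7.0, True)
    d = rbs_accessibility_change(reg, site, rbs, model, ScreenConfig())
    oro = EnsembleOracle(reg.sequence, model)
    oro_c = EnsembleOracle(reg.sequence, model, forced_unpaired=frozenset(range(6)))
    before, after = oro.unpaired_probability((11, 16)), \
        oro_c.unpaired_probability((11, 16))
    assert d == pytest.approx(after - before, abs=1e-9)
    assert d > 0.001
    assert after > 0.9 * (1 - before) + before - 1e-9 or after > before


def test_rbs_release_no_coupling_control(model):
    # all-A surroundings: the forced interval shares no pairing partner
    # with the RBS, so its opening cannot change RBS accessibility
    reg = SearchRegion("toy", "AAAAAA" + "AAAA" + "AGGAGG" + "AA" + "AAAAA",
                       codon_offset=19, utr_known=True)
    site = _site(codon_iv=(-18, -13), mrna_iv=(1, 6))
    rbs = RBSLocation((-8, -3), -7.0, True)
    d = rbs_accessibility_change(reg, site, rbs, model, ScreenConfig())
    assert abs(d) < 1e-6


def test_rbs_release_requires_site_upstream(model):
    reg = _toy_region()
    overlapping = _site(codon_iv=(-10, -3), mrna_iv=(9, 16))
    rbs = RBSLocation((-8, -3), -7.0, True)
    with pytest.raises(ValueError):
        rbs_accessibility_change(reg, overlapping, rbs, model, ScreenConfig())


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def test_classify_down_branch():
    cfg = ScreenConfig()
    call = classify_candidate("g", [_site((-12, 3))], None, "down", None,
                              0.2, cfg)
    assert call.verdict == "repression_candidate"
    call = classify_candidate("g", [_site((25, 40))], None, "down", None,
                              0.2, cfg)
    assert call.verdict == "none"
    assert call.rationale == "site_outside_ribosome_window"


def test_classify_up_branch_thresholds():
    cfg = ScreenConfig()
    rbs = RBSLocation((-12, -7), -7.0, True)
    site = _site((-30, -20))
    up = classify_candidate("g", [site], rbs, "up", 0.002, 5.0, cfg)
    assert up.verdict == "activation_candidate"
    low = classify_candidate("g", [site], rbs, "up", 0.0005, 5.0, cfg)
    assert low.verdict == "none"
    assert low.rationale == "dPu_below_threshold"


def test_classification_requires_favorable_total_energy():
    buried = _site((-12, 3), e_hybrid=-8.0, ed_s=20.0)
    call = classify_candidate("g", [buried], None, "down", None, 0.2,
                              ScreenConfig())
    assert call.verdict == "none"
    assert call.rationale == "no_favorable_site"


def test_verdict_soundness_on_benchmark(default_benchmark):
    """Every call's invariant re-checked post hoc against its evidence."""
    b = default_benchmark
    report = run_screen(b.srna.residues, b.transcripts, b.expression,
                        b.annotations, b.config)
    cfg = b.config
    for c in report.calls:
        if c.verdict == "repression_candidate":
            assert c.direction == "down"
            assert c.best_site is not None and c.best_site.E_total < 0
            assert repression_filter(c.best_site, cfg)
        elif c.verdict == "activation_candidate":
            assert c.direction == "up"
            assert c.rbs is not None
            assert c.dPu is not None and c.dPu > cfg.dPu_threshold
            assert c.best_site.mrna_interval_codon[1] < c.rbs.interval[0]
        else:
            assert c.rationale != ""


def test_run_screen_empty_expression(default_benchmark):
    b = default_benchmark
    report = run_screen(b.srna.residues, b.transcripts, [], b.annotations,
                        b.config)
    assert report.table.empty


# ---------------------------------------------------------------------------
# cis-antisense overlap
# ---------------------------------------------------------------------------

def test_cis_pair_default_geometry():
    a, b, contig = make_cis_pair(65)
    rec = antisense_overlap(a, b)
    assert rec.overlap == 65
    assert rec.classification == "5'-5'"


def test_overlap_disjoint_and_internal_and_same_strand():
    a, b, _ = make_cis_pair(0)
    assert antisense_overlap(a, b).classification == "none"
    x = GeneAnnotation("x", "c", (100, 200), "+", 100)
    y = GeneAnnotation("y", "c", (100, 200), "-", 200)
    rec = antisense_overlap(x, y)
    assert rec.overlap == 101 and rec.classification == "internal"
    z = GeneAnnotation("z", "c", (150, 250), "+", 150)
    assert antisense_overlap(x, z).classification == "not_antisense"


def test_overlap_convergent_is_3p3p():
    x = GeneAnnotation("x", "c", (100, 200), "+", 100)
    y = GeneAnnotation("y", "c", (180, 300), "-", 290)
    assert antisense_overlap(x, y).classification == "3'-3'"


# ---------------------------------------------------------------------------
# ddCt
# ---------------------------------------------------------------------------

def _ct_table(target_wt=20.0, target_mut=18.0, ref=15.0):
    rows = []
    for g in ["r1", "r2", "r3"]:
        for cond in ("wt", "mut"):
            rows.append({"gene_id": g, "condition": cond, "ct": ref})
    rows.append({"gene_id": "t", "condition": "wt", "ct": target_wt})
    rows.append({"gene_id": "t", "condition": "mut", "ct": target_mut})
    return pd.DataFrame(rows)


def test_ddct_hand_computed_values():
    folds = fold_change_from_ct(_ct_table(), ["r1", "r2", "r3"])
    assert folds["t"] == pytest.approx(4.0)    # ddCt = -2
    same = fold_change_from_ct(_ct_table(target_mut=20.0), ["r1", "r2", "r3"])
    assert same["t"] == pytest.approx(1.0)     # ddCt = 0


def test_ddct_shift_invariance():
    base = fold_change_from_ct(_ct_table(), ["r1", "r2", "r3"])
    shifted_tbl = _ct_table()
    shifted_tbl["ct"] += 7.3
    shifted = fold_change_from_ct(shifted_tbl, ["r1", "r2", "r3"])
    assert shifted["t"] == pytest.approx(base["t"])


def test_ddct_missing_condition_is_error():
    tbl = _ct_table()
    tbl = tbl[~((tbl.gene_id == "t") & (tbl.condition == "mut"))]
    with pytest.raises(ValueError):
        fold_change_from_ct(tbl, ["r1", "r2", "r3"])
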