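"""Partition-function engine against exhaustive structure enumeration."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnascreen.energy import GAS_CONSTANT, EnergyModel
from srnascreen.thermo import (AccessibilityCalculator, FoldConstraint,
                               local_accessibility_profile, opening_energy,
                               partition_function, unpaired_probability)

from conftest import random_rna
from oracles import EnsembleOracle


def test_unpairable_sequences_have_trivial_ensemble(model):
    es = partition_function("AAAAAAA", model)
    assert es.Z == pytest.approx(1.0)
    assert all(p == 0.0 for p in es.pair_prob.values())
    assert partition_function("G", model).Z == pytest.approx(1.0)


def test_partition_function_matches_enumeration(model):
    """Z, pair probabilities and interval Pu agree with brute force on the
    fully pairable GC/A test sequence."""
    seq = "GGGGAAAACCCC"
    oro = EnsembleOracle(seq, model)
    es = partition_function(seq, model)
    assert es.Z == pytest.approx(oro.Z, rel=1e-9)
    for (i, j), p in es.pair_prob.items():
        assert p == pytest.approx(oro.pair_prob(i - 1, j - 1), abs=1e-9)
    assert es.unpaired_probability((5, 8)) == pytest.approx(
        oro.unpaired_probability((5, 8)), rel=1e-9)


@pytest.mark.parametrize("trial", range(25))
def test_random_ensembles_match_enumeration(model, trial):
    """Randomized spot of the enumeration contract including span limits
    and forced-unpaired constraints."""
    rng = random.Random(500 + trial)
    n = rng.randint(5, 14)
    seq = random_rna(rng, n)
    span = rng.choice([None, 6, 10])
    forced = frozenset(rng.sample(range(n), rng.randint(0, 2)))
    oro = EnsembleOracle(seq, model, span, forced)
    es = partition_function(seq, model, max_span=span,
                            constraint=FoldConstraint(
                                frozenset(p + 1 for p in forced)))
    assert es.Z == pytest.approx(oro.Z, rel=1e-9)
    a = rng.randint(1, n)
    b = min(n, a + rng.randint(0, 4))
    assert es.unpaired_probability((a, b)) == pytest.approx(
        oro.unpaired_probability((a, b)), abs=1e-9)
    i = rng.randint(1, n - 1)
    j = rng.randint(i + 1, n)
    assert es.pair_probability(i, j) == pytest.approx(
        oro.pair_prob(i - 1, j - 1), abs=1e-9)


def test_forced_unpaired_interval_has_pu_one(model):
    seq = "GCGCAAAAGCGC"
    c = FoldConstraint.from_intervals((5, 8))
    assert unpaired_probability(seq, (5, 8), model, constraint=c) == 1.0
    # empty interval convention
    assert partition_function(seq, model).unpaired_probability((5, 4)) == 1.0


def test_central_loop_pu_matches_enumeration(model):
    seq = "GCGCAAAAGCGC"
    oro = EnsembleOracle(seq, model)
    assert unpaired_probability(seq, (5, 8), model) == pytest.approx(
        oro.unpaired_probability((5, 8)), rel=1e-9)


def test_constraint_never_increases_partition_function(model):
    rng = random.Random(42)
    for _ in range(15):
        seq = random_rna(rng, rng.randint(8, 16))
        z = partition_function(seq, model).Z
        pos = rng.sample(range(1, len(seq) + 1), 3)
        zc_prev = z
        for k in range(1, 4):
            zc = partition_function(
                seq, model,
                constraint=FoldConstraint(frozenset(pos[:k]))).Z
            assert zc <= zc_prev + 1e-12
            zc_prev = zc


def test_interval_pu_monotone_under_extension(model):
    rng = random.Random(7)
    for _ in range(10):
        seq = random_rna(rng, 15)
        es = partition_function(seq, model)
        a, b = 4, 9
        outer = es.unpaired_probability((a, b))
        for (sa, sb) in [(a + 1, b), (a, b - 1), (a + 2, b - 1)]:
            assert outer <= es.unpaired_probability((sa, sb)) + 1e-12


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGU", min_size=4, max_size=14),
       st.sets(st.integers(min_value=1, max_value=14), max_size=3))
def test_property_constraints_shrink_the_ensemble(seq, forced):
    """Forcing positions unpaired never increases Z, and the constrained
    ensemble's Pu of those positions is 1."""
    model = EnergyModel.default()
    forced = frozenset(p for p in forced if p <= len(seq))
    z = partition_function(seq, model).Z
    es = partition_function(seq, model, constraint=FoldConstraint(forced))
    assert es.Z <= z + 1e-12
    assert es.Z >= 1.0
    for p in forced:
        assert es.unpaired_probability((p, p)) == pytest.approx(1.0)


def test_zero_energy_model_gives_uniform_ensemble():
    """With all energies zero every legal structure is equiprobable and Pu
    reduces to a combinatorial fraction."""
    m = EnergyModel(stack=np.zeros((6, 6)), hairpin_a=0, hairpin_b=0,
                    bulge_a=0, bulge_b=0, interior_a=0, interior_b=0,
                    ml_a=0, ml_b=0, ml_c=0, duplex_init=0, temperature=310.15)
    seq = "GGCAAAAGCC"
    oro = EnsembleOracle(seq, m)
    n_structures = sum(1 for w in oro.weights if w > 0)
    es = partition_function(seq, m)
    assert es.Z == pytest.approx(n_structures, rel=1e-9)
    pu = es.unpaired_probability((1, 2))
    frac = oro.unpaired_probability((1, 2))
    assert pu == pytest.approx(frac, rel=1e-9)


def test_opening_energy_closed_forms(model):
    assert opening_energy(1.0, model) == 0.0
    rt = GAS_CONSTANT * 310.15
    assert opening_energy(0.5, model) == pytest.approx(rt * math.log(2), rel=1e-12)
    assert opening_energy(0.5, model) == pytest.approx(0.4272, abs=2e-4)
    assert math.isinf(opening_energy(0.0, model))
    with pytest.raises(ValueError):
        opening_energy(1.5, model)


def test_profile_trivial_and_degenerate_cases(model):
    prof = local_accessibility_profile("A" * 30, model, window=20,
                                       max_span=10, probe_len=4)
    assert all(p == pytest.approx(1.0) for p in prof.Pu.values())
    # shorter than the window: identical to the global span-capped ensemble
    seq = "GGGCAAAACGGGCC"
    prof = local_accessibility_profile(seq, model, window=100, max_span=50,
                                       probe_len=3)
    es = partition_function(seq, model, max_span=50)
    for iv, pu in prof.Pu.items():
        assert pu == pytest.approx(es.unpaired_probability(iv), rel=1e-9)


def test_profile_matches_direct_per_window_recomputation(model):
    """Window-averaged Pu equals an independent average of per-window
    constrained/unconstrained Z ratios on a hairpin carrier."""
    rng = random.Random(9)
    stem = "GCGGCUAGC"
    from srnascreen.seqio import reverse_complement
    seq = (random_rna(rng, 40) + stem + "AAAA" + reverse_complement(stem)
           + random_rna(rng, 40))
    window, span, probe = 40, 20, 5
    prof = local_accessibility_profile(seq, model, window, span, probe)
    n = len(seq)
    for a in [1, 18, 44, 60, n - probe + 1]:
        iv = (a, a + probe - 1)
        vals = []
        for w in range(max(1, iv[1] - window + 1),
                       min(iv[0], n - window + 1) + 1):
            sub = seq[w - 1:w - 1 + window]
            z = partition_function(sub, model, max_span=span).Z
            zc = partition_function(
                sub, model, max_span=span,
                constraint=FoldConstraint.from_intervals(
                    (iv[0] - w + 1, iv[1] - w + 1))).Z
            vals.append(zc / z)
        assert prof.Pu[iv] == pytest.approx(sum(vals) / len(vals), rel=1e-9)


def test_single_window_mode_sees_distant_stem_partner(model):
    """A centered single window keeps a long-range partner arm in view, so
    a stem position stays (correctly) inaccessible."""
    from srnascreen.seqio import reverse_complement
    rng = random.Random(3)
    arm = "GCGCGGCCGGCUCG"
    seq = random_rna(rng, 60) + arm + "AAAAA" + reverse_complement(arm) \
        + random_rna(rng, 60)
    calc = AccessibilityCalculator(seq, model, window=80, max_span=50,
                                   mode="single")
    assert calc.pu((63, 70)) < 1e-4
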