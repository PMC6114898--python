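"""Feature quantification: identities, oracles and conventions."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

import _oracles as O
from tirnakit.candidate_library import LibrarySpec, generate_library
from tirnakit.feature_quant import (
    FEATURE_COLUMNS,
    RbsCenterError,
    UtrContext,
    _unpaired_runs,
    feature_table,
    feature_vector,
    paired_termini,
    pau,
    rbs_center,
    rbs_coverage,
    seed_energies,
    thermo_features,
)
from tirnakit.fold_engine import RnaSequence, concat, reverse_complement


def test_all_a_candidate_degenerate_row(engine):
    # an all-A tiRNA can pair with nothing in a U-free context: every
    # energy/probability feature collapses to zero
    utr = RnaSequence("ACGACGACGACGACGACGACG", "u")
    cds = RnaSequence("ACGACGACGACG", "c")
    ctx = UtrContext.build(utr, cds, engine=engine, c_rbs=15)
    vec = feature_vector(RnaSequence("A" * 20, "polyA"), ctx, seed=1, engine=engine)
    for key in ("EA", "EAA", "FAA", "ETS", "EIS", "PAU", "RBS5", "RBS11", "PT"):
        assert vec[key] == 0.0
    assert vec["L"] == 20.0


def test_formation_energy_identities(toy_context, engine):
    tirna = RnaSequence("GGCAUGCAAGCCAAUGCAGG", "t")
    ea, eaa, eab, faa, fab = thermo_features(tirna, toy_context, engine)
    assert faa == pytest.approx(eaa - 2 * ea, abs=1e-9)
    dg_utr = toy_context.monomer_fold.mfe_energy
    assert fab == pytest.approx(eab - ea - dg_utr, abs=1e-9)


def test_fab_equals_duplex_energy_for_unstructured_pair(engine):
    # a fully unstructured 8-nt "UTR" and its perfect reverse complement:
    # monomer terms vanish and FAB equals the pure duplex energy, checked
    # against the two-strand enumeration oracle
    utr = RnaSequence("AAAA", "u")  # dG_UTR = 0
    cds = RnaSequence("AAAA", "c")
    ctx = UtrContext.build(utr, cds, engine=engine, c_rbs=4)
    tirna = reverse_complement(ctx.combined)
    assert engine.fold(tirna).mfe_energy == 0.0
    ea, eaa, eab, faa, fab = thermo_features(tirna, ctx, engine)
    canon = sorted([tirna.residues, ctx.combined.residues])
    e_oracle, _ = O.mfe_oracle(canon[0] + canon[1], nick=len(canon[0]))
    assert fab == pytest.approx(e_oracle, abs=1e-9)
    assert fab == -2.0 * 8  # eight A.U pairs


def test_unpaired_run_extraction():
    assert _unpaired_runs("....", 3) == [(0, 4)]
    assert _unpaired_runs("((..))...", 3) == [(6, 9)]
    assert _unpaired_runs("((..))", 3) == []
    assert _unpaired_runs(".((....)).", 4) == [(3, 7)]


def test_seed_energies_no_binding(toy_context, engine):
    ets, eis = seed_energies(RnaSequence("AAAA"), toy_context, n_samples=10, seed=0, engine=engine)
    # all-A tiRNA binds nothing complementary strongly enough... it can pair
    # with U-rich stretches, so only assert the ordering invariant here
    assert ets >= eis


def test_seed_energies_unstructured_tirna_zero_variance(engine):
    # tiRNA with no intramolecular pairs: every sample is the open chain and
    # the seed energies equal the single-run interaction energetics
    utr = RnaSequence("GGGGGGGG", "u")
    cds = RnaSequence("GGGGGGGG", "c")
    ctx = UtrContext.build(utr, cds, engine=engine, c_rbs=0)
    tirna = RnaSequence("CCCCC", "t")
    assert engine.fold(tirna).mfe_energy == 0.0
    res = engine.interact(tirna, ctx.combined)
    ets, eis = seed_energies(tirna, ctx, n_samples=25, seed=3, engine=engine)
    assert ets == pytest.approx(res.e_total, abs=1e-12)
    assert eis == pytest.approx(res.e_interaction, abs=1e-12)


def test_seed_energies_match_exact_ensemble_expectation(engine):
    """ETS sampled at n=10,000 sits within 3 SE of the exact expectation
    computed by enumerating the full Boltzmann ensemble of a 12-nt tiRNA."""
    tirna = RnaSequence("GGCAUGCAAGCC", "t")
    utr = RnaSequence("GGCUUGCAUGCCAAUU", "u")
    cds = RnaSequence("AUGAAAA", "c")
    ctx = UtrContext.build(utr, cds, engine=engine, c_rbs=10)
    _, probs, _, _ = O.boltzmann_oracle(tirna.residues)
    exact = 0.0
    sq = 0.0
    for struct, p in probs.items():
        runs = _unpaired_runs(struct, 3)
        val = 0.0
        if runs:
            val = min(
                engine.interact(tirna.window(a, b), ctx.combined).e_total
                for a, b in runs
            )
            val = min(val, 0.0)
        exact += p * val
        sq += p * val * val
    n = 10_000
    se = math.sqrt(max(sq - exact**2, 0.0) / n)
    ets, _ = seed_energies(tirna, ctx, n_samples=n, seed=5, engine=engine)
    assert abs(ets - exact) <= 3 * max(se, 1e-6)


def test_pau_direct_recomputation(toy_context, engine):
    tirna = RnaSequence("UUCCUCCUGCAG", "t")
    value = pau(tirna, toy_context, engine)
    dimer = engine.cofold(tirna, toy_context.combined)
    u = toy_context.monomer_fold.unpaired_prob
    na = len(tirna)
    num = den = 0.0
    for i in range(len(toy_context.combined)):
        w_i = sum(dimer.bpp[j, na + i] for j in range(na))
        num += w_i * u[i]
        den += w_i
    assert value == pytest.approx(num / den, abs=1e-12)
    assert 0.0 <= value <= 1.0


def test_pau_degenerate_zero_binding(engine):
    utr = RnaSequence("ACGACGACGACGACGACGACG", "u")
    ctx = UtrContext.build(utr, RnaSequence("ACG", "c"), engine=engine, c_rbs=5)
    assert pau(RnaSequence("AAAA"), ctx, engine) == 0.0


def test_rbs_center_on_clean_sd_site(engine):
    # one perfect SD site on a C background that cannot pair with the
    # anti-SD (C/U letters pair with G/A only)
    utr = RnaSequence("CCCCCCCCCC" + "AGGAGG" + "CCCCCCCCCC", "u")
    anti = RnaSequence("CCUCCU", "anti")
    c = rbs_center(utr, anti, engine)
    assert 10 <= c <= 15  # inside the AGGAGG site (positions 10..15)


def test_rbs_center_two_sites_and_direct_recomputation(engine):
    # with two identical SD sites the weight splits across both and the
    # centre lands between them; the value equals the hand recomputation
    # from the printed inter-strand bpp matrix
    site = "AGGAGG"
    gap = "CCCCCC"
    seq = RnaSequence(gap + site + gap + site + gap, "u")
    anti = RnaSequence("CCUCCU", "anti")
    c = rbs_center(seq, anti, engine)
    assert 12 <= c <= 17  # inside the inter-site gap
    dimer = engine.cofold(anti, seq)
    b = dimer.inter_bpp.sum(axis=0)
    expected = int(np.floor(np.dot(np.arange(len(b)), b) / b.sum() + 0.5))
    assert c == expected


def test_rbs_center_error_without_binding(engine):
    with pytest.raises(RbsCenterError):
        rbs_center(RnaSequence("AAAAAAAAAA"), RnaSequence("AAAA"), engine)


def test_rbs_coverage_bounds_and_strong_binder(engine):
    # strong-binding limit: an unstructured G-clamp (overhanging the site so
    # that every site nucleotide is paired in any maximal duplex) against
    # the only C-run of an otherwise inert, unstructured context
    utr = RnaSequence("AAAAAAAAAA" + "CCCCCCCCCCC" + "AAAAAAAAAA", "u")
    cds = RnaSequence("AAAAAA", "c")
    ctx = UtrContext.build(utr, cds, engine=engine, c_rbs=15)  # C-run centre
    tirna = RnaSequence("G" * 14, "clamp")
    cov11 = rbs_coverage(tirna, ctx, 11, engine)
    cov5 = rbs_coverage(tirna, ctx, 5, engine)
    assert cov11 >= 0.95
    assert cov5 >= cov11 - 1e-9  # centre of the duplex is bound at least as well
    assert 0.0 <= cov5 <= 1.0
    # no binding at all -> zero coverage ("GGGG" pairs with neither A nor C)
    assert rbs_coverage(RnaSequence("AAAA"), ctx, 5, engine) == 0.0
    assert rbs_coverage(RnaSequence("AAAA"), ctx, 11, engine) == 0.0


def test_paired_termini_conventions(engine):
    assert paired_termini(RnaSequence("AAAA"), n_samples=5, seed=0, engine=engine) == 0.0
    # MFE of GGGGAAAACCCC has 4 pairs crossing the halves [0,6) / [6,12);
    # the sampled mean at n=10,000 must sit within 3 SE of the exact
    # ensemble expectation
    from tirnakit.fold_engine import pairs_from_dotbracket

    s = "GGGGAAAACCCC"
    _, probs, _, _ = O.boltzmann_oracle(s)
    half = 6
    exact = sq = 0.0
    for struct, p in probs.items():
        cross = sum(1 for i, j in pairs_from_dotbracket(struct) if i < half <= j)
        exact += p * cross
        sq += p * cross * cross
    mfe_cross = sum(
        1 for i, j in pairs_from_dotbracket(O.mfe_oracle(s)[1]) if i < half <= j
    )
    assert mfe_cross == 4
    n = 10_000
    se = math.sqrt(max(sq - exact**2, 0.0) / n)
    pt = paired_termini(RnaSequence(s), n_samples=n, seed=11, engine=engine)
    assert abs(pt - exact) <= 3 * max(se, 1e-6)
    # odd length: halves are [0, L//2) and [L//2, L)
    pt9 = paired_termini(RnaSequence("GGGGAAAAC"), n_samples=50, seed=2, engine=engine)
    assert 0.0 <= pt9 <= 4  # floor(9/2) = 4 cross-half pairs at most


def test_feature_table_contract(toy_context, engine):
    lib = generate_library(
        LibrarySpec(target_utr=toy_context.utr, n_candidates=12, seed=3)
    )
    t1 = feature_table(lib, toy_context, seed=5, engine=engine, n_samples=20)
    t2 = feature_table(lib, toy_context, seed=5, engine=engine, n_samples=20)
    pd.testing.assert_frame_equal(t1, t2)
    assert list(t1.columns) == list(FEATURE_COLUMNS)
    assert t1.attrs["failures"] == {}
    # row-wise invariants
    dg_utr = toy_context.monomer_fold.mfe_energy
    for _, row in t1.iterrows():
        assert row["FAA"] == pytest.approx(row["EAA"] - 2 * row["EA"], abs=1e-9)
        assert row["FAB"] == pytest.approx(
            row["EAB"] - row["EA"] - dg_utr, abs=1e-9
        )
        assert row["ETS"] >= row["EIS"] - 1e-12
        assert row["EIS"] <= 0.0
        for col in ("PAU", "RBS5", "RBS11"):
            assert 0.0 <= row[col] <= 1.0
        assert 0.0 <= row["PT"] <= row["L"] // 2


def test_monte_carlo_se_scaling(toy_context, engine):
    """Quadrupling n_samples halves the Monte-Carlo SE of ETS."""
    tirna = RnaSequence("GGCAUGCAAGCCAAUGCAGG", "t")
    small = [
        seed_energies(tirna, toy_context, n_samples=25, seed=s, engine=engine)[0]
        for s in range(25)
    ]
    large = [
        seed_energies(tirna, toy_context, n_samples=100, seed=1000 + s, engine=engine)[0]
        for s in range(25)
    ]
    sd_small = np.std(small, ddof=1)
    sd_large = np.std(large, ddof=1)
    assert sd_small > 0
    # expected ratio 2; allow a generous band for 25-replicate sd estimates
    assert 1.2 <= sd_small / sd_large <= 3.5
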