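"""Unit and property tests for the NG86/JC divergence machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_pair_differences, brute_pairwise_divergence, brute_site_counts
from wgdkit import genetics
from wgdkit.codon_evolution import (
    CodonAlignment,
    branch_divergence,
    build_codon_alignment,
    fourdtv,
    jukes_cantor,
    neutrality_screen,
    pairwise_divergence,
    sliding_window_branch,
    sliding_window_dnds,
)

codons = st.sampled_from(genetics.SENSE_CODONS)


# ---------------------------------------------------------------------------
# site and difference counting


@pytest.mark.parametrize(
    "codon,expected",
    [("TTT", (1 / 3, 8 / 3)), ("GGG", (1.0, 2.0)), ("ATG", (0.0, 3.0))],
)
def test_site_counts_known_codons(codon, expected):
    s, n = genetics.codon_site_counts(codon)
    assert s == pytest.approx(expected[0])
    assert n == pytest.approx(expected[1])


def test_site_counts_sum_to_three_for_every_sense_codon():
    for codon in genetics.SENSE_CODONS:
        s, n = genetics.codon_site_counts(codon)
        assert s + n == pytest.approx(3.0, abs=1e-12)
        assert (s, n) == pytest.approx(brute_site_counts(codon))


def test_site_counts_reject_stop_codons():
    with pytest.raises(ValueError):
        genetics.codon_site_counts("TAA")


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("GTT", "GTA", (1.0, 0.0)),  # Val->Val, synonymous
        ("TTT", "TTA", (0.0, 1.0)),  # Phe->Leu, nonsynonymous
        ("TTT", "GTA", (0.5, 1.5)),  # two 2-step pathways averaged
        ("AAA", "AAA", (0.0, 0.0)),
    ],
)
def test_pair_differences_known_cases(a, b, expected):
    assert genetics.codon_pair_differences(a, b) == pytest.approx(expected)


@given(codons, codons)
@settings(max_examples=300, deadline=None)
def test_pair_differences_match_oracle_and_are_symmetric(a, b):
    sd, nd = genetics.codon_pair_differences(a, b)
    assert (sd, nd) == pytest.approx(brute_pair_differences(a, b))
    assert (sd, nd) == pytest.approx(genetics.codon_pair_differences(b, a))
    n_diff = sum(x != y for x, y in zip(a, b))
    assert sd + nd == pytest.approx(n_diff)


# ---------------------------------------------------------------------------
# Jukes-Cantor


def test_jukes_cantor_closed_form():
    assert jukes_cantor(0.0) == 0.0
    assert jukes_cantor(0.05) == pytest.approx(-0.75 * math.log(1 - 0.2 / 3), abs=1e-12)
    assert jukes_cantor(0.05) == pytest.approx(0.0517449, abs=1e-6)
    assert math.isnan(jukes_cantor(0.75))
    assert math.isnan(jukes_cantor(0.9))
    with pytest.raises(ValueError):
        jukes_cantor(-0.01)


@given(st.floats(0.0, 0.74), st.floats(0.0, 0.74))
@settings(max_examples=200, deadline=None)
def test_jukes_cantor_monotone(p1, p2):
    lo, hi = sorted((p1, p2))
    assert jukes_cantor(lo) <= jukes_cantor(hi) + 1e-15


# ---------------------------------------------------------------------------
# alignment construction


def test_ungapped_alignment_drops_stop_and_ambiguous_columns():
    # column 3 is a stop in seq a; column 2 carries an N in seq b
    a = "ATG" + "GTT" + "TAA" + "AAA"
    b = "ATG" + "GNT" + "GGG" + "AAA"
    aln = CodonAlignment.from_ungapped([a, b])
    assert aln.n_columns == 2
    assert aln.n_dropped == 2
    assert aln.columns == (("ATG", "ATG"), ("AAA", "AAA"))


def test_protein_guided_alignment_backtranslates_and_drops_gap_columns():
    cds_a = "ATGGTTAAA"  # M V K
    cds_b = "ATGAAA"  # M K
    aln = build_codon_alignment([cds_a, cds_b], ["MVK", "M-K"], ["a", "b"])
    assert aln.n_columns == 2
    assert aln.n_dropped == 1
    assert aln.columns == (("ATG", "ATG"), ("AAA", "AAA"))
    assert aln.column_origin == ((0, 0), (2, 1))


def test_protein_guided_alignment_tolerates_trailing_stop():
    aln = build_codon_alignment(["ATGAAATAA", "ATGAAA"], ["MK", "MK"])
    assert aln.n_columns == 2


def test_protein_guided_alignment_reports_translation_mismatch():
    with pytest.raises(ValueError, match="codon 1"):
        build_codon_alignment(["ATGGTT", "ATGAAA"], ["MM", "MK"])


# ---------------------------------------------------------------------------
# pairwise divergence


def test_identical_sequences_have_zero_divergence():
    cds = "ATG" + "GTT" * 50
    est = pairwise_divergence(CodonAlignment.from_ungapped([cds, cds]))
    assert est.ds == 0.0 and est.dn == 0.0
    assert math.isnan(est.omega)


def test_pure_synonymous_columns():
    # every column differs synonymously: ps = 1 saturates dS, dn stays 0
    a, b = "GTT" * 100, "GTA" * 100
    est = pairwise_divergence(CodonAlignment.from_ungapped([a, b]))
    assert est.sd == pytest.approx(100.0)
    assert est.nd == pytest.approx(0.0)
    assert est.dn == 0.0
    assert math.isnan(est.ds) and est.saturated


def test_sites_sum_to_three_times_columns_and_symmetry(random_codon_pair_factory):
    a, b = random_codon_pair_factory(80)
    aln = CodonAlignment.from_ungapped([a, b])
    est = pairwise_divergence(aln)
    assert est.s_sites + est.n_sites == pytest.approx(3 * aln.n_columns)
    swapped = pairwise_divergence(CodonAlignment.from_ungapped([b, a]))
    for field in ("s_sites", "n_sites", "sd", "nd", "ds", "dn"):
        assert getattr(est, field) == pytest.approx(
            getattr(swapped, field), nan_ok=True
        )


def test_pairwise_divergence_matches_bruteforce_oracle(random_codon_pair_factory):
    """200 random 50-codon pairs agree with pathway enumeration exactly."""
    for _ in range(200):
        a, b = random_codon_pair_factory(50)
        est = pairwise_divergence(CodonAlignment.from_ungapped([a, b]))
        ref = brute_pairwise_divergence(a, b)
        assert est.sd == pytest.approx(ref["sd"], abs=1e-9)
        assert est.nd == pytest.approx(ref["nd"], abs=1e-9)
        assert est.s_sites == pytest.approx(ref["S"], abs=1e-9)
        assert est.ds == pytest.approx(ref["ds"], abs=1e-12, nan_ok=True)
        assert est.dn == pytest.approx(ref["dn"], abs=1e-12, nan_ok=True)


def test_empty_alignment_is_an_error():
    aln = CodonAlignment.from_ungapped(["TAA", "TAA"])
    with pytest.raises(ValueError):
        pairwise_divergence(aln)


# ---------------------------------------------------------------------------
# 4DTv


@pytest.mark.parametrize(
    "col_a,col_b,sites,tv",
    [
        ("GGA", "GGT", 1, 1),  # Gly fourfold, A<->T transversion
        ("GGA", "GGG", 1, 0),  # A<->G transition
        ("TTT", "TTC", 0, 0),  # Phe is twofold, excluded
        ("GGA", "GAA", 0, 0),  # prefixes differ, excluded
    ],
)
def test_fourdtv_single_columns(col_a, col_b, sites, tv):
    res = fourdtv(CodonAlignment.from_ungapped([col_a, col_b]))
    assert res.n_fourfold_sites == sites
    assert res.n_transversions == tv
    if sites == 0:
        assert math.isnan(res.rate)
    else:
        assert res.rate == tv / sites


def test_fourdtv_swap_invariant(random_codon_pair_factory):
    a, b = random_codon_pair_factory(200)
    r1 = fourdtv(CodonAlignment.from_ungapped([a, b]))
    r2 = fourdtv(CodonAlignment.from_ungapped([b, a]))
    assert r1 == r2


# ---------------------------------------------------------------------------
# sliding windows


def test_window_count_and_coordinates():
    cds = "ATG" * 100  # 300 bp
    profile = sliding_window_dnds(CodonAlignment.from_ungapped([cds, cds]))
    assert len(profile.windows) == 6  # floor((300-150)/30)+1
    assert [w[0] for w in profile.windows] == [0, 30, 60, 90, 120, 150]
    assert all(w[1] - w[0] == 150 for w in profile.windows)
    assert all(w[2].ds == 0 and w[2].dn == 0 for w in profile.windows)
    assert not profile.truncated


def test_short_alignment_yields_single_truncated_window():
    cds = "ATG" * 10
    profile = sliding_window_dnds(CodonAlignment.from_ungapped([cds, cds]))
    assert profile.truncated
    assert profile.windows[0][:2] == (0, 30)


def test_window_step_must_be_codon_aligned():
    cds = "ATG" * 60
    with pytest.raises(ValueError):
        sliding_window_dnds(CodonAlignment.from_ungapped([cds, cds]), 150, 25)


# ---------------------------------------------------------------------------
# branch-anchored divergence


def test_branch_assignment_by_parsimony():
    # col 1: P1 differs, P2==O -> synonymous change on P1's branch
    # col 2: all equal; col 3: O differs from both equal ingroups -> no change
    p1 = "TTC" + "AAA" + "GGG"
    p2 = "TTT" + "AAA" + "GGG"
    o = "TTT" + "AAA" + "GGC"
    bd = branch_divergence(
        CodonAlignment.from_ungapped([p1, p2, o], ["p1", "p2", "o"]), "o"
    )
    assert bd.branch_labels == ("p1", "p2")
    assert bd.estimates[0].sd == pytest.approx(1.0)
    assert bd.estimates[0].nd == 0.0
    assert bd.estimates[1].sd == 0.0 and bd.estimates[1].nd == 0.0
    assert bd.n_ambiguous == 0


def test_branch_all_three_different_is_ambiguous():
    p1, p2, o = "TTA", "TTC", "TTG"
    bd = branch_divergence(
        CodonAlignment.from_ungapped([p1, p2, o], ["p1", "p2", "o"]), "o"
    )
    assert bd.n_ambiguous == 1
    assert bd.estimates[0].sd + bd.estimates[1].sd == 0


def test_branch_counts_bounded_by_pairwise(rng):
    from wgdkit.genetics import SENSE_CODONS

    for _ in range(30):
        idx = rng.integers(0, len(SENSE_CODONS), size=(3, 40))
        seqs = ["".join(SENSE_CODONS[i] for i in row) for row in idx]
        aln3 = CodonAlignment.from_ungapped(seqs, ["p1", "p2", "o"])
        bd = branch_divergence(aln3, "o")
        pair = pairwise_divergence(
            CodonAlignment.from_ungapped(seqs[:2], ["p1", "p2"])
        )
        assert bd.estimates[0].sd + bd.estimates[1].sd <= pair.sd + 1e-9
        assert bd.estimates[0].nd + bd.estimates[1].nd <= pair.nd + 1e-9


def test_branch_requires_valid_outgroup():
    aln = CodonAlignment.from_ungapped(["ATG", "ATG", "ATG"], ["a", "b", "c"])
    with pytest.raises(ValueError, match="outgroup"):
        branch_divergence(aln, "missing")


def test_branch_sliding_windows_cover_both_branches():
    cds = "ATG" * 100
    profiles = sliding_window_branch(
        CodonAlignment.from_ungapped([cds, cds, cds], ["p1", "p2", "o"]), "o"
    )
    assert set(profiles) == {"p1", "p2"}
    assert len(profiles["p1"].windows) == 6


# ---------------------------------------------------------------------------
# neutrality screen


def _est(sd, nd, S, N):
    from wgdkit.codon_evolution import _estimate_from_counts

    return _estimate_from_counts(S, N, sd, nd, n_used=100, n_dropped=0)


def test_neutrality_screen_at_null_proportion_is_one():
    # nd/sd exactly at p0 = N/(N+S): 75 of 100 differences nonsynonymous
    p = neutrality_screen(_est(sd=25, nd=75, S=75, N=225))
    assert p == pytest.approx(1.0, abs=0.05)


def test_neutrality_screen_boundary_matches_enumeration():
    from oracles import exact_binom_two_sided

    p = neutrality_screen(_est(sd=0, nd=20, S=75, N=225))
    assert p == pytest.approx(exact_binom_two_sided(20, 20, 0.75), rel=1e-9)


def test_neutrality_screen_undefined_without_differences():
    assert math.isnan(neutrality_screen(_est(sd=0, nd=0, S=75, N=225)))
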