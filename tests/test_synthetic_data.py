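"""Generator determinism, calibration accuracy, and parameter recovery."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from wgdkit.codon_evolution import (
    CodonAlignment,
    pairwise_divergence,
    sliding_window_dnds,
)
from wgdkit.expression_divergence import expression_correlation, sex_bias_test
from wgdkit.pair_catalog import filter_genes, make_pairs
from wgdkit.synthetic_data import (
    calibrate_time,
    evolve_pair,
    expected_ds,
    get_process,
    sim_ancestral_cds,
    sim_expression,
    sim_pair_set,
    sim_sex_contig,
    sim_triple,
)


# ---------------------------------------------------------------------------
# ancestral sequences and the substitution process


def test_ancestral_cds_starts_with_atg_and_is_deterministic():
    assert sim_ancestral_cds(1, 0) == "ATG"
    s1 = sim_ancestral_cds(500, 42)
    s2 = sim_ancestral_cds(500, 42)
    assert s1 == s2
    assert s1.startswith("ATG")
    assert len(s1) == 1500


def test_ancestral_cds_contains_no_stop_codons():
    from wgdkit.genetics import STOP_CODONS, codons_of

    s = sim_ancestral_cds(10000, 3)
    assert not any(c in STOP_CODONS for c in codons_of(s))


def test_transition_matrix_matches_expm():
    proc = get_process(0.3, 2.0)
    for t in (0.01, 0.2, 1.5):
        ref = expm(proc.Q * t)
        assert np.max(np.abs(proc.transition_matrix(t) - ref)) < 1e-10


def test_process_rejects_invalid_parameters():
    with pytest.raises(ValueError):
        get_process(-0.1, 2.0)
    with pytest.raises(ValueError):
        get_process(0.2, 0.0)


# ---------------------------------------------------------------------------
# calibration


def test_calibration_hits_target_expected_ds():
    proc = get_process(0.2, 2.0)
    anc = sim_ancestral_cds(300, 1)
    from wgdkit.genetics import CODON_INDEX, codons_of

    w = np.bincount(
        [CODON_INDEX[c] for c in codons_of(anc)], minlength=61
    ).astype(float)
    for target in (0.05, 0.3, 0.69, 1.5):
        t = calibrate_time([(proc, w)], target)
        assert expected_ds([(proc, w)], t) == pytest.approx(target, rel=1e-3)


def test_calibration_beyond_saturation_raises():
    proc = get_process(0.2, 2.0)
    w = np.ones(61)
    with pytest.raises(ValueError, match="saturation"):
        calibrate_time([(proc, w)], 10.0)


# ---------------------------------------------------------------------------
# evolve_pair


def test_evolve_pair_target_zero_gives_identical_sequences():
    anc = sim_ancestral_cds(100, 2)
    a, b, truth = evolve_pair(anc, 0.0, 0.2, 2.0, 5)
    assert a == b == anc
    assert truth["t_total"] == 0.0


def test_evolve_pair_deterministic_given_seed():
    anc = sim_ancestral_cds(200, 2)
    out1 = evolve_pair(anc, 0.3, 0.2, 2.0, 9)
    out2 = evolve_pair(anc, 0.3, 0.2, 2.0, 9)
    assert out1[:2] == out2[:2]


def test_evolve_pair_omega_zero_has_no_nonsynonymous_flux():
    anc = sim_ancestral_cds(10000, 4)
    a, b, _ = evolve_pair(anc, 0.3, 0.0, 2.0, 6)
    est = pairwise_divergence(CodonAlignment.from_ungapped([a, b]))
    assert est.dn <= 0.005
    assert est.ds == pytest.approx(0.3, abs=0.03)


def test_evolve_pair_neutral_omega_recovered_at_kappa_one():
    # at kappa=1 the NG86 estimator is unbiased for omega=1
    anc = sim_ancestral_cds(20000, 5)
    a, b, _ = evolve_pair(anc, 0.3, 1.0, 1.0, 7)
    est = pairwise_divergence(CodonAlignment.from_ungapped([a, b]))
    assert est.omega == pytest.approx(1.0, abs=0.05)


def test_elevated_omega_window_localized_by_sliding_scan():
    """Planted high-omega codons 16-55 put the profile max over bp 45-165."""
    anc = sim_ancestral_cds(300, 8)
    a, b, _ = evolve_pair(
        anc, 0.35, 0.05, 2.0, 11, omega_windows=[(15, 55, 3.0)]
    )
    profile = sliding_window_dnds(CodonAlignment.from_ungapped([a, b]))
    scored = [
        (w[2].omega if math.isfinite(w[2].omega) else -1.0, w[0], w[1])
        for w in profile.windows
    ]
    _, start, end = max(scored)
    assert start < 165 and end > 45


# ---------------------------------------------------------------------------
# pair sets


def test_pair_set_round_trips_through_catalog():
    genes, hits, truth = sim_pair_set(5, 5, n_codons=60, seed=3)
    retained, report = filter_genes(genes, hits)
    assert len(report) == 0
    pairs = make_pairs(retained, hits)
    assert {p.pair_id for p in pairs} == set(truth)
    # one family per planted pair
    assert len({p.family_id for p in pairs}) == len(pairs)


def test_pair_set_without_background_is_unimodal_burst():
    genes, hits, truth = sim_pair_set(30, 0, n_codons=60, seed=4)
    ds = [v["true_ds"] for v in truth.values()]
    assert all(v["origin"] == "wgd" for v in truth.values())
    assert np.std(np.log(ds)) < 0.2  # lognormal sigma 0.08 plus no background


# ---------------------------------------------------------------------------
# triples


def test_triple_zero_branch_lengths_are_identical():
    anc = sim_ancestral_cds(100, 6)
    seqs, _ = sim_triple(
        anc,
        {"outgroup": 0.2, "ingroup1": 0.2, "ingroup2": 0.2},
        {"outgroup": 0.0, "ingroup1": 0.0, "ingroup2": 0.0},
        kappa=2.0,
        seed=8,
    )
    assert seqs["ingroup1"] == seqs["ingroup2"] == seqs["outgroup"] == anc


def test_triple_symmetric_branches_have_similar_counts():
    from wgdkit.codon_evolution import branch_divergence

    anc = sim_ancestral_cds(4000, 7)
    seqs, _ = sim_triple(
        anc,
        {"outgroup": 0.2, "ingroup1": 0.2, "ingroup2": 0.2},
        {"outgroup": 0.4, "ingroup1": 0.15, "ingroup2": 0.15},
        kappa=2.0,
        seed=9,
    )
    aln = CodonAlignment.from_ungapped(
        [seqs["ingroup1"], seqs["ingroup2"], seqs["outgroup"]],
        ["ingroup1", "ingroup2", "outgroup"],
    )
    bd = branch_divergence(aln, "outgroup")
    tot = [e.sd + e.nd for e in bd.estimates]
    assert tot[0] == pytest.approx(tot[1], rel=0.2)


def test_triple_elevated_branch_window_peaks_on_right_branch():
    from wgdkit.codon_evolution import sliding_window_branch

    anc = sim_ancestral_cds(300, 10)
    seqs, _ = sim_triple(
        anc,
        {"outgroup": 0.1, "ingroup1": 0.05, "ingroup2": 0.05},
        {"outgroup": 0.5, "ingroup1": 0.25, "ingroup2": 0.25},
        kappa=2.0,
        seed=12,
        branch_omega_windows={"ingroup1": [(15, 55, 4.0)]},
    )
    aln = CodonAlignment.from_ungapped(
        [seqs["ingroup1"], seqs["ingroup2"], seqs["outgroup"]],
        ["ingroup1", "ingroup2", "outgroup"],
    )
    profiles = sliding_window_branch(aln, "outgroup")
    peak_nd = {
        label: max(w[2].nd for w in profile.windows)
        for label, profile in profiles.items()
    }
    assert peak_nd["ingroup1"] > peak_nd["ingroup2"]


# ---------------------------------------------------------------------------
# expression


def test_expression_matrix_shape_and_determinism():
    m1, pairs1, truth1 = sim_expression(20, 0.5, seed=13)
    m2, pairs2, truth2 = sim_expression(20, 0.5, seed=13)
    assert m1.values.equals(m2.values)
    assert pairs1 == pairs2 and truth1 == truth2
    assert m1.values.shape == (40, 16)
    assert truth1["n_divergent"] == 10


def test_expression_no_divergent_pairs_keeps_false_positives_low():
    m, pairs, _ = sim_expression(400, 0.0, seed=14)
    called = sum(expression_correlation(p, m)[2] for p in pairs)
    assert called / len(pairs) <= 0.02


def test_expression_planted_bias_detected_with_power():
    m, pairs, truth = sim_expression(
        60, 0.0, seed=15, n_bias_pairs=30, bias_odds=10.0, mean_depth=300.0
    )
    stages = [f"st{i + 1}" for i in range(4)]  # developing pool
    significant = 0
    for pair in pairs[:30]:
        p, _ = sex_bias_test(pair, m, stages)
        significant += p < 0.01
    assert significant / 30 >= 0.95


# ---------------------------------------------------------------------------
# depth tracks


def test_sex_contig_deterministic_and_class_lambdas():
    layout = [((0, 1000), "male-specific"), ((1000, 2000), "repetitive")]
    t1, _ = sim_sex_contig(3000, layout, seed=16)
    t2, _ = sim_sex_contig(3000, layout, seed=16)
    assert (t1.male_depth == t2.male_depth).all()
    assert (t1.female_depth == t2.female_depth).all()
    # male-specific: female lambda 0
    assert t1.female_depth[:1000].sum() == 0
    assert t1.male_depth[:1000].mean() == pytest.approx(20, abs=2)
    # repetitive: both around 80
    assert t1.male_depth[1000:2000].mean() == pytest.approx(80, abs=5)
    # background default: both around 20
    assert t1.female_depth[2000:].mean() == pytest.approx(20, abs=2)


def test_sex_contig_rejects_bad_layout():
    with pytest.raises(ValueError):
        sim_sex_contig(1000, [((0, 2000), "PAR-like")])
    with pytest.raises(ValueError):
        sim_sex_contig(1000, [((0, 500), "nonsense")])
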