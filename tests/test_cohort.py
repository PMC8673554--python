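"""Junction-set matching, density binning, cohort split and DE."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from disco.cohort import (
    LocusSplit,
    MatchParams,
    bin_junction_density,
    chromosomal_de,
    match_junction_sets,
    restrict_interchromosomal,
    split_cohort_by_locus,
    track_correlation,
)
from disco.model import LEFT, RIGHT, BreakEnd, JunctionCall


def jc(chromA, posA, chromB, posB, circ=False, passed=True):
    call = JunctionCall(
        breakendA=BreakEnd(chromA, posA, LEFT if not circ else RIGHT, "+"),
        breakendB=BreakEnd(chromB, posB, RIGHT if not circ else LEFT, "+"),
        n_split=3,
        circ_flag=circ,
    )
    call.filter_status = "passed" if passed else "failed"
    return call


# --- matching --------------------------------------------------------------


def test_identical_junctions_match_at_zero_distance():
    a = [jc("chr1", 100, "chr2", 900)]
    b = [jc("chr1", 100, "chr2", 900)]
    res = match_junction_sets(a, b)
    assert res.n_matched == 1 and not res.only_a and not res.only_b


@pytest.mark.parametrize(
    "dA,dB,expect", [(40, 40, True), (41, 0, False), (0, 41, False), (40, 0, True)]
)
def test_window_boundary_inclusive_at_40(dA, dB, expect):
    a = [jc("chr1", 1000, "chr2", 5000)]
    b = [jc("chr1", 1000 + dA, "chr2", 5000 + dB)]
    res = match_junction_sets(a, b)
    assert (res.n_matched == 1) is expect


def test_head_to_tail_and_alt_loci_excluded_before_matching():
    a = [
        jc("chr1", 100, "chr1", 900, circ=True),
        jc("chr1_fake_alt", 100, "chr2", 900),
        jc("chr3", 100, "chr4", 900),
    ]
    b = [jc("chr3", 100, "chr4", 900)]
    res = match_junction_sets(a, b)
    assert res.n_matched == 1
    assert res.only_a == []  # excluded junctions are not reported as A-only


def test_greedy_assignment_each_junction_used_once():
    a = [jc("chr1", 100, "chr2", 900), jc("chr1", 110, "chr2", 910)]
    b = [jc("chr1", 101, "chr2", 901)]
    res = match_junction_sets(a, b)
    assert res.n_matched == 1
    # nearest pair wins
    assert res.matched[0][0].breakendA.pos == 100
    assert len(res.only_a) == 1


def test_matching_symmetric_and_bounded():
    rng = np.random.default_rng(3)
    a = [jc("chr1", int(p), "chr2", int(p) + 500) for p in rng.integers(0, 10_000, 15)]
    b = [jc("chr1", int(p), "chr2", int(p) + 500) for p in rng.integers(0, 10_000, 9)]
    ab = match_junction_sets(a, b)
    ba = match_junction_sets(b, a)
    assert ab.n_matched == ba.n_matched <= min(len(a), len(b))


def test_mixed_genome_builds_hard_error():
    a = [jc("chr1", 100, "chr2", 900)]
    b = [jc("1", 100, "2", 900)]
    with pytest.raises(ValueError, match="build"):
        match_junction_sets(a, b)


# --- interchromosomal restriction ------------------------------------------


def test_restrict_interchromosomal_counts_and_idempotence():
    calls = [jc("chr1", i, "chr2", i) for i in range(5)] + [
        jc("chr1", i, "chr1", i + 1000) for i in range(3)
    ]
    sub = restrict_interchromosomal(calls)
    assert len(sub) == 5
    assert restrict_interchromosomal(sub) == sub
    assert restrict_interchromosomal([jc("chr1", 1, "chr1", 99)]) == []


# --- density binning -------------------------------------------------------


def test_empty_sets_give_zero_bins():
    df = bin_junction_density({"s1": []}, 1000, {"chr1": 5000})
    assert (df["s1"] == 0).all()


def test_three_junctions_in_one_bin_count_six_endpoints():
    calls = [jc("chr1", 100 + i, "chr1", 900 - i) for i in range(3)]
    df = bin_junction_density({"s": calls}, 1000, {"chr1": 5000})
    assert df.loc[("chr1", 0), "s"] == 6
    assert df["s"].sum() == 6


def test_density_conserves_endpoints_and_drops_circ():
    calls = [jc("chr1", 100, "chr2", 900), jc("chr1", 5, "chr1", 600, circ=True)]
    df = bin_junction_density({"s": calls}, 500, {"chr1": 2000, "chr2": 2000})
    assert df["s"].sum() == 2 * 1  # circ-flagged junction discarded


def test_track_self_correlation_is_one():
    rng = np.random.default_rng(5)
    calls = [jc("chr1", int(p), "chr2", int(q)) for p, q in rng.integers(0, 50_000, (30, 2))]
    df = bin_junction_density({"a": calls, "b": calls}, 5000, {"chr1": 50_000, "chr2": 50_000})
    assert track_correlation(df, "a", "b") == pytest.approx(1.0)


# --- cohort split ----------------------------------------------------------


def test_split_cohort_partitions_exactly():
    samples = {
        "s1": [jc("chr11", 70_000_000, "chr11", 70_000_500)],
        "s2": [jc("chr11", 95_000_000, "chr11", 95_000_500)],
        "s3": [],
    }
    split = split_cohort_by_locus(samples, ("chr11", 60_000_000, 90_000_000))
    assert split.mutant_samples == {"s1"}
    assert split.wildtype_samples == {"s2", "s3"}
    assert split.mutant_samples | split.wildtype_samples == set(samples)
    assert not split.mutant_samples & split.wildtype_samples


def test_single_junction_inside_locus_is_mutant():
    samples = {"s": [jc("chr5", 1000, "chr5", 1500)]}
    split = split_cohort_by_locus(samples, ("chr5", 900, 1100))
    assert split.mutant_samples == {"s"}


def test_junction_one_bp_outside_locus_is_wildtype():
    samples = {"s": [jc("chr5", 1100, "chr5", 11_000)]}
    split = split_cohort_by_locus(samples, ("chr5", 900, 1100))
    assert split.wildtype_samples == {"s"}


def test_failed_junctions_do_not_make_a_sample_mutant():
    samples = {"s": [jc("chr5", 1000, "chr5", 1500, passed=False)]}
    split = split_cohort_by_locus(samples, ("chr5", 900, 1100))
    assert split.wildtype_samples == {"s"}


# --- differential expression ------------------------------------------------


def _nb_counts(rng, mu, phi, n):
    r = 1 / phi
    return rng.negative_binomial(r, r / (r + mu[:, None]), size=(len(mu), n))


def _cohort(rng, n_genes=300, n1=6, n2=6, fold=None, n_up=0):
    mu = rng.lognormal(4, 1, n_genes)
    mu_mut = mu.copy()
    up = rng.choice(n_genes, n_up, replace=False) if n_up else np.array([], dtype=int)
    if fold:
        mu_mut[up] *= fold
    cols = [f"M{i}" for i in range(n1)] + [f"W{i}" for i in range(n2)]
    counts = pd.DataFrame(
        np.hstack([_nb_counts(rng, mu_mut, 0.1, n1), _nb_counts(rng, mu, 0.1, n2)]),
        index=[f"G{i}" for i in range(n_genes)],
        columns=cols,
    )
    split = LocusSplit(("chr1", 0, 10**9), set(cols[:n1]), set(cols[n1:]))
    return counts, split, [f"G{i}" for i in up]


def test_logfc_sign_flips_when_groups_swap():
    rng = np.random.default_rng(21)
    counts, split, _ = _cohort(rng, n_genes=100)
    res = chromosomal_de(counts, split)
    flipped = LocusSplit(split.locus, split.wildtype_samples, split.mutant_samples)
    res2 = chromosomal_de(counts, flipped)
    np.testing.assert_allclose(
        res.set_index("gene")["logFC"], -res2.set_index("gene")["logFC"], atol=1e-9
    )


def test_q_values_monotone_in_p_values():
    rng = np.random.default_rng(22)
    counts, split, _ = _cohort(rng, n_genes=200)
    res = chromosomal_de(counts, split).sort_values("p_value")
    assert res["q_value"].is_monotonic_increasing


def test_zero_q_threshold_yields_no_significant_gene():
    rng = np.random.default_rng(23)
    counts, split, _ = _cohort(rng, n_genes=100)
    res = chromosomal_de(counts, split, q_threshold=0.0)
    assert not res["significant"].any()
    assert (res["direction"] == "ns").all()


def test_small_group_is_an_error():
    rng = np.random.default_rng(24)
    counts, split, _ = _cohort(rng, n_genes=50)
    bad = LocusSplit(split.locus, set(list(split.mutant_samples)[:1]), split.wildtype_samples)
    with pytest.raises(ValueError, match="2 samples"):
        chromosomal_de(counts, bad)


def test_gene_table_ordered_by_genomic_center():
    from disco.annotate import GeneModel

    rng = np.random.default_rng(25)
    counts, split, _ = _cohort(rng, n_genes=10)
    models = [
        GeneModel(f"G{i}", f"G{i}", "chr1", "+", [(1000 * (10 - i), 1000 * (10 - i) + 500)])
        for i in range(10)
    ]
    res = chromosomal_de(counts, split, gene_models=models)
    assert res["genomic_center"].is_monotonic_increasing
    assert set(res["gene"]) == set(counts.index)
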