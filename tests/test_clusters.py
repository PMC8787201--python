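"""Cluster metrics, GCC-repeat detection and homopolymer translation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import regex_gcc_run
from xenoscan.clusters import (
    DegenerateClusterError,
    classify_run,
    cluster_sites,
    compaction,
    find_gcc_run,
    find_tolerant_run,
    frame_offset_of,
    position_frequency_matrix,
    start_spacings,
    translate_repeat,
)
from xenoscan.scan import BindingSite


def mk_site(start, length=20, mirna_id="m1", transcript_id="tx"):
    return BindingSite(
        mirna_id=mirna_id, transcript_id=transcript_id, gene="g", start=start,
        length=length, dG=-110.0, dGm=-120.0, ratio=91.7, region="CDS",
    )


def test_cluster_of_overlapping_sites_metrics():
    (cl,) = cluster_sites([mk_site(100), mk_site(102), mk_site(104)])
    assert (cl.first_start, cl.last_end, cl.span) == (100, 124, 24)
    assert cl.start_spacings == [2, 2]
    assert cl.total_site_length == 60
    assert cl.compaction == pytest.approx(60 / 24)


def test_cluster_span_with_21nt_sites():
    # a 30-nt cluster covered by 21-nt sites: 276..306
    (cl,) = cluster_sites([mk_site(276, length=21), mk_site(285, length=21)])
    assert (cl.first_start, cl.last_end, cl.span) == (276, 306, 30)


def test_distant_sites_form_singletons():
    clusters = cluster_sites([mk_site(100), mk_site(150)])
    assert [c.n_sites for c in clusters] == [1, 1]


def test_gap_parameter_merges_near_misses():
    sites = [mk_site(100), mk_site(125)]  # 5-nt gap between intervals
    assert len(cluster_sites(sites, gap=0)) == 2
    assert len(cluster_sites(sites, gap=5)) == 1


@given(st.lists(st.integers(1, 300), min_size=1, max_size=25), st.permutations(range(25)))
def test_clustering_is_a_partition_and_order_free(starts, order):
    sites = [mk_site(s, length=10, mirna_id=f"m{i % 3}") for i, s in enumerate(starts)]
    clusters = cluster_sites(sites)
    members = [s for c in clusters for s in c.sites]
    assert sorted(members, key=lambda s: (s.start, s.mirna_id)) == sorted(
        sites, key=lambda s: (s.start, s.mirna_id)
    )
    shuffled = [sites[i] for i in order if i < len(sites)]
    if len(shuffled) == len(sites):
        again = cluster_sites(shuffled)
        assert [{(s.start, s.mirna_id) for s in c.sites} for c in again] == [
            {(s.start, s.mirna_id) for s in c.sites} for c in clusters
        ]


@pytest.mark.parametrize(
    "total, span, value, reported",
    [(281, 28, 10.036, 10), (20, 20, 1.0, 1), (528, 42, 12.571, 13)],
)
def test_compaction_values(total, span, value, reported):
    assert compaction(total, span) == pytest.approx(value, abs=1e-3)
    assert int(round(compaction(total, span))) == reported


def test_compaction_degenerate_span():
    with pytest.raises(DegenerateClusterError):
        compaction(100, 0)


@pytest.mark.parametrize(
    "starts, spacings",
    [((10, 11, 12), [1, 1]), ((10, 13, 16), [3, 3]), ((10, 16), [6]), ((10,), [])],
)
def test_start_spacings_patterns(starts, spacings):
    assert start_spacings([mk_site(s) for s in starts]) == spacings


# ---------------------------------------------------------------------------
# GCC repeats


ATOH8_5UTR_STYLE = "CUCCCCACGCCGCCGCCGCCGCCGCCUCCUGCGC"


@pytest.mark.parametrize(
    "seq, run_length",
    [
        (ATOH8_5UTR_STYLE, 18),
        ("GCCGCC", 6),
        ("GCGCGC", 0),
        ("", 0),
        ("GCC", 3),
    ],
)
def test_find_gcc_run_lengths(seq, run_length):
    run = find_gcc_run(seq)
    assert run.run_length == run_length
    assert run.run_length == 3 * run.k
    assert run.mismatched_triplets == 0


def test_find_gcc_run_reports_leftmost_longest():
    run = find_gcc_run("AAGCCGCCAAAGCCGCCAA")
    assert (run.start, run.run_length) == (3, 6)


@given(st.text(alphabet="GCAU", max_size=120))
def test_find_gcc_run_matches_regex_oracle(seq):
    run = find_gcc_run(seq)
    start, length = regex_gcc_run(seq)
    assert (run.start, run.run_length) == (start, length)


def test_tolerant_run_bridges_interior_bad_triplet():
    # (GCC)x3 UUU (GCC)x2: exact run 9, one interior bad triplet bridges to 18
    seq = "GCCGCCGCCUUUGCCGCC"
    assert find_tolerant_run(seq, 0).run_length == 9
    bridged = find_tolerant_run(seq, 1)
    assert (bridged.run_length, bridged.mismatched_triplets) == (18, 1)


def test_tolerant_run_never_ends_on_bad_triplet():
    run = find_tolerant_run("GCCGCCUUU", 1)
    assert run.run_length == 6
    assert run.mismatched_triplets == 0


@given(st.text(alphabet="GC", max_size=60), st.integers(0, 3))
def test_tolerant_run_is_monotone_and_reduces_to_exact(seq, m):
    exact = find_gcc_run(seq)
    assert find_tolerant_run(seq, 0).run_length == exact.run_length
    tol = find_tolerant_run(seq, m)
    assert tol.run_length >= exact.run_length
    assert find_tolerant_run(seq, m + 1).run_length >= tol.run_length


@pytest.mark.parametrize(
    "length, cls",
    [(18, "18"), (21, "21"), (24, "24"), (27, "27plus"), (48, "27plus"),
     (15, "none"), (0, "none")],
)
def test_classify_run(length, cls):
    assert classify_run(length) == cls


def test_classify_run_rejects_non_triplet_length():
    with pytest.raises(ValueError):
        classify_run(19)


def test_translate_repeat_rotations():
    run = find_gcc_run("GCC" * 7)
    assert translate_repeat(run, 2) == "RRRRRRR"
    run6 = find_gcc_run("GCC" * 6)
    assert translate_repeat(run6, 0) == "AAAAAA"
    assert translate_repeat(run6, 1) == "PPPPPP"


def test_translate_repeat_refuses_non_cds():
    run = find_gcc_run("GCC" * 6)
    with pytest.raises(ValueError, match="region"):
        translate_repeat(run, 0, region="5UTR")


@given(st.integers(6, 16), st.integers(0, 2))
def test_translate_repeat_length_and_alphabet(k, offset):
    peptide = translate_repeat(find_gcc_run("GCC" * k), offset)
    assert len(peptide) == k and set(peptide) <= set("APR")


def test_frame_offset_of_matches_codon_rotation():
    # CDS starts at 101; a run at 103 has its first full codon 1 base in
    assert frame_offset_of(103, 101) == 1
    assert frame_offset_of(101, 101) == 0
    assert frame_offset_of(102, 101) == 2


# ---------------------------------------------------------------------------
# Position-frequency matrix


def test_pfm_identical_sequences():
    pfm = position_frequency_matrix(["ACGU", "ACGU", "ACGU"])
    assert pfm.loc["A", 1] == 1.0 and pfm.loc["U", 4] == 1.0
    assert np.allclose(pfm.sum(axis=0), 1.0)


def test_pfm_split_column():
    pfm = position_frequency_matrix(["ACGU", "AGGU"])
    assert pfm.loc["C", 2] == 0.5 and pfm.loc["G", 2] == 0.5


@given(st.lists(st.text(alphabet="ACGU", min_size=8, max_size=8), min_size=1, max_size=20))
def test_pfm_columns_are_stochastic(seqs):
    pfm = position_frequency_matrix(seqs)
    assert np.allclose(pfm.sum(axis=0), 1.0)


def test_pfm_rejects_unequal_lengths():
    with pytest.raises(ValueError, match="aligned"):
        position_frequency_matrix(["ACGU", "ACG"])
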