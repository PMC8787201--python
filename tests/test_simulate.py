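"""Synthetic-study generator: determinism, planting, recovery, FP control."""

import numpy as np
import pytest

from xenoscan.clusters import cluster_sites, find_gcc_run, frame_offset_of, translate_repeat
from xenoscan.scan import scan
from xenoscan.simulate import (
    ConfigError,
    PlacementError,
    SimulationConfig,
    demo_config,
    generate_study,
    plant_gcc_cluster,
    plant_site,
    plant_tandem_sites,
    random_mirna,
    random_transcript,
)
from xenoscan.transcripts import MiRNA, Transcript


def bg_transcript(length=400, seed=7, tx_id="bg1"):
    return random_transcript(length, 0.5, seed, tx_id=tx_id)


def test_random_transcript_is_deterministic():
    a = random_transcript(500, 0.5, seed=3, tx_id="x")
    b = random_transcript(500, 0.5, seed=3, tx_id="x")
    assert a.seq == b.seq
    assert a.seq != random_transcript(500, 0.5, seed=4, tx_id="x").seq


def test_random_transcript_gc_fraction_within_3_se():
    tx = random_transcript(10_000, 0.5, seed=11, tx_id="gc")
    gc = (tx.seq.count("G") + tx.seq.count("C")) / tx.length
    se = (0.25 / 10_000) ** 0.5
    assert abs(gc - 0.5) < 3 * se


@pytest.mark.parametrize("gc", [0.0, 1.0, -0.1])
def test_degenerate_gc_fraction_rejected(gc):
    with pytest.raises(ConfigError):
        random_transcript(500, gc, seed=1)


def test_plant_site_exact_recovery():
    tx = bg_transcript()
    m = random_mirna(20, seed=5, mirna_id="m")
    tx2, truth = plant_site(tx, m, start=100, n_wobbles=0, seed=1)
    sites = scan(m, tx2, threshold=99.9)
    assert any(s.start == 100 and s.ratio == pytest.approx(100.0) for s in sites)
    assert truth.expected_ratio == 100.0


def test_plant_site_wobble_ratio_is_analytic():
    # single wobble opposite the miRNA's G: loss 6.37 - 2.12 = 4.25
    m = MiRNA(id="m", seq="AUGC")
    tx = Transcript(id="t", seq="A" * 40)
    tx2, truth = plant_site(tx, m, start=10, n_wobbles=1, seed=3)
    assert truth.expected_ratio in (
        pytest.approx(100 * (21.24 - 4.25) / 21.24),  # wobble opposite G
        pytest.approx(100 * (21.24 - 2.13) / 21.24),  # wobble opposite A
    )
    (hit,) = [s for s in scan(m, tx2, threshold=truth.expected_ratio - 1e-9)
              if s.start == 10]
    assert hit.ratio == pytest.approx(truth.expected_ratio, abs=1e-9)


def test_plant_site_overlap_refused():
    tx = bg_transcript()
    m = random_mirna(20, seed=5, mirna_id="m")
    occupied = []
    tx, _ = plant_site(tx, m, start=100, seed=1, occupied=occupied)
    with pytest.raises(PlacementError, match="overlaps"):
        plant_site(tx, m, start=110, seed=1, occupied=occupied)


def test_plant_site_shift_covariance():
    tx = bg_transcript()
    m = random_mirna(20, seed=5, mirna_id="m")
    tx2, _ = plant_site(tx, m, start=50, seed=1)
    shifted = Transcript(id="s", seq="GAUCGAU" + tx2.seq)
    assert any(s.start == 57 for s in scan(m, shifted, threshold=99.9))


def test_plant_tandem_builds_one_cluster_with_requested_spacing():
    m = MiRNA(id="mt", seq="UG" * 9)  # reverse complement CACA... has period 2
    tx = bg_transcript(600, seed=9)
    tx2, truths = plant_tandem_sites(tx, m, n=14, spacing=2, start=100)
    assert [t.start for t in truths] == [100 + 2 * j for j in range(14)]
    sites = scan(m, tx2, threshold=90)
    (cl,) = cluster_sites(sites)
    assert cl.n_sites == 14
    assert cl.span == 18 + 2 * 13 == 44
    assert set(cl.start_spacings) == {2}


def test_plant_tandem_nonperiodic_mirna_refused():
    m = MiRNA(id="m", seq="AUGCAUGCAU")
    tx = bg_transcript()
    with pytest.raises(PlacementError, match="position"):
        plant_tandem_sites(tx, m, n=2, spacing=1, start=50)


def test_plant_tandem_wide_spacing_gives_singleton_clusters():
    m = random_mirna(18, seed=6, mirna_id="m")
    tx = bg_transcript(800, seed=10)
    tx2, truths = plant_tandem_sites(tx, m, n=2, spacing=50, start=100)
    sites = [s for s in scan(m, tx2, threshold=99.9) if s.start in (100, 150)]
    clusters = cluster_sites(sites)
    assert [c.n_sites for c in clusters] == [1, 1]


@pytest.mark.parametrize(
    "k, region, offset, peptide",
    [(6, "5UTR", 0, ""), (7, "CDS", 2, "RRRRRRR"), (9, "CDS", 0, "AAAAAAAAA"),
     (8, "CDS", 1, "PPPPPPPP")],
)
def test_plant_gcc_cluster_classes_and_peptides(k, region, offset, peptide):
    tx = random_transcript(1500, 0.5, seed=21, tx_id=f"g{k}{offset}")
    tx2, truth = plant_gcc_cluster(tx, k, region=region, frame_offset=offset, seed=2)
    assert truth.expected_class == ("27plus" if 3 * k >= 27 else str(3 * k))
    assert truth.expected_peptide == peptide
    lo, hi = (1, tx2.utr5_end) if region == "5UTR" else (tx2.cds_start, tx2.cds_end)
    run = find_gcc_run(tx2.seq[lo - 1 : hi])
    run_start = lo + run.start - 1
    assert run_start == truth.start and run.run_length == 3 * k
    if region == "CDS":
        assert translate_repeat(run, frame_offset_of(run_start, tx2.cds_start)) == peptide


def test_generate_study_demo_recovers_every_truth_feature(demo_bundle):
    b = demo_bundle
    assert len(b.truth) == 30
    mirs = {m.id: m for m in b.mirnas}
    txs = {t.id: t for t in b.transcripts}
    for r in b.truth.itertuples():
        if r.feature == "site":
            hits = [
                s for s in scan(mirs[r.unit], txs[r.transcript_id],
                                threshold=min(r.expected_ratio, 100.0) - 1e-9)
                if s.start == r.start
            ]
            assert hits, f"planted site not recovered: {r}"
            assert hits[0].ratio == pytest.approx(r.expected_ratio, abs=1e-6)
            assert hits[0].region == r.expected_region
        else:
            t = txs[r.transcript_id]
            lo, hi = (1, t.utr5_end) if r.expected_region == "5UTR" else (t.cds_start, t.cds_end)
            run = find_gcc_run(t.seq[lo - 1 : hi])
            assert lo + run.start - 1 == r.start
            assert run.length_class == r.expected_class


def test_generate_study_empty_config_is_valid(tmp_path):
    bundle = generate_study(SimulationConfig(seed=1, n_transcripts=0, n_mirnas=0),
                            out_dir=tmp_path)
    assert bundle.transcripts == [] and len(bundle.truth) == 0
    assert (tmp_path / "transcripts.fasta").exists()


def test_generate_study_byte_identical_across_runs(tmp_path):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    generate_study(demo_config(seed=7), out_dir=d1)
    generate_study(demo_config(seed=7), out_dir=d2)
    for name in ("transcripts.fasta", "mirnas.fasta", "annotation.tsv", "truth.tsv"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


def test_background_false_positive_rate_is_tiny():
    """On pure background, ratio >= 90% windows for a random 20-mer are
    essentially absent (<= 1 per 1e5 windows)."""
    m = random_mirna(20, seed=101, mirna_id="fp")
    n_windows = 0
    n_hits = 0
    for i in range(10):
        tx = random_transcript(10_019, 0.5, seed=200 + i, tx_id=f"fp{i}")
        n_windows += tx.length - 19
        n_hits += len(scan(m, tx, threshold=90))
    assert n_windows == 100_000
    assert n_hits <= 1
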