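"""End-to-end orchestration: scan -> overlap resolution -> clustering ->
repeat analysis -> TSV reports, plus the packaged-fixture self-check.

The pipeline is a pure function of its inputs and configuration: identical
input bytes and config produce byte-identical reports.  Rounding (integer
kJ/mol, integer percent, integer compaction) happens only at the report
layer; all filtering uses unrounded values.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import fixtures as fixtures_mod
from .clusters import (
    classify_run,
    cluster_sites,
    find_gcc_run,
    find_tolerant_run,
    frame_offset_of,
    position_frequency_matrix,
    translate_repeat,
)
from .energy import EnergyModel, default_model
from .scan import DEFAULT_THRESHOLD, resolve_overlaps, scan_all, sites_to_frame
from .transcripts import load_mirnas, load_transcripts


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class PipelineConfig:
    mirna_path: str
    transcript_path: str
    annotation_path: str | None = None
    threshold: float = DEFAULT_THRESHOLD
    overlap_resolution: bool = False
    cluster_gap: int = 0
    min_cluster_sites: int = 14
    repeat_tolerance: int = 0
    out_dir: str = "xenoscan_out"
    seed: int = 0
    energy_config: str | None = None

    def validate(self) -> None:
        if not 0 < self.threshold <= 100:
            raise PipelineError(f"config: threshold must be in (0, 100], got {self.threshold}")
        if self.cluster_gap < 0 or self.min_cluster_sites < 1 or self.repeat_tolerance < 0:
            raise PipelineError("config: gap/min_cluster_sites/tolerance out of range")
        for path in (self.mirna_path, self.transcript_path, self.annotation_path):
            if path and not Path(path).exists():
                raise PipelineError(f"config: input file {path} not found")


def _render_range(lo: float, hi: float) -> str:
    lo, hi = int(round(lo)), int(round(hi))
    return str(lo) if lo == hi else f"{lo}÷{hi}"  # '÷' range notation


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full pipeline and write the report bundle.

    Outputs in ``config.out_dir``: ``sites.tsv`` (per-site report),
    ``clusters.tsv`` (clusters with >= min_cluster_sites members),
    ``repeats.tsv`` (per-region GCC runs with length class and peptide),
    ``pfm.tsv`` (position-frequency matrix of the modal site length),
    ``run_log.txt`` and a serialized config copy.  Any stage error aborts
    with a stage-tagged message and removes partial outputs.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    try:
        model = (
            EnergyModel.from_config(config.energy_config)
            if config.energy_config
            else default_model()
        )
        stage = "load"
        mirnas = load_mirnas(config.mirna_path, model)
        transcripts = load_transcripts(config.transcript_path, config.annotation_path)
        log(f"[load] {len(mirnas)} miRNAs ({_sha256(config.mirna_path)[:12]}), "
            f"{len(transcripts)} transcripts ({_sha256(config.transcript_path)[:12]})")
        for t in transcripts:
            if not t.annotated:
                log(f"[load] warning: transcript {t.id} lacks annotation")

        stage = "scan"
        sites = scan_all(mirnas, transcripts, model=model, threshold=config.threshold)
        log(f"[scan] threshold {config.threshold}%: {len(sites)} sites")

        stage = "overlap"
        if config.overlap_resolution:
            sites = resolve_overlaps(sites)
            log(f"[overlap] {len(sites)} sites after inter-miRNA resolution")

        stage = "report-sites"
        sites_path = out_dir / "sites.tsv"
        sites_to_frame(sites).to_csv(sites_path, sep="\t", index=False)
        written.append(sites_path)

        stage = "clusters"
        cluster_rows = []
        by_tx: dict[str, list] = {}
        for s in sites:
            by_tx.setdefault(s.transcript_id, []).append(s)
        for tx_id in sorted(by_tx):
            for cl in cluster_sites(by_tx[tx_id], gap=config.cluster_gap):
                if cl.n_sites < config.min_cluster_sites:
                    continue
                dg_lo, dg_hi = cl.dG_range
                r_lo, r_hi = cl.ratio_range
                cluster_rows.append({
                    "transcript_id": cl.transcript_id,
                    "gene": cl.gene,
                    "mirna_ids": ";".join(sorted(cl.site_count_by_mirna)),
                    "first_start": cl.first_start,
                    "last_end": cl.last_end,
                    "site_count": cl.n_sites,
                    "span": cl.span,
                    "total_site_length": cl.total_site_length,
                    "compaction": int(round(cl.compaction)),
                    "dG_range": _render_range(dg_lo, dg_hi),
                    "ratio_range": _render_range(r_lo, r_hi),
                })
        clusters_path = out_dir / "clusters.tsv"
        pd.DataFrame(cluster_rows, columns=[
            "transcript_id", "gene", "mirna_ids", "first_start", "last_end",
            "site_count", "span", "total_site_length", "compaction",
            "dG_range", "ratio_range",
        ]).to_csv(clusters_path, sep="\t", index=False)
        written.append(clusters_path)
        log(f"[clusters] {len(cluster_rows)} clusters with >= "
            f"{config.min_cluster_sites} sites (gap {config.cluster_gap})")

        stage = "repeats"
        repeat_rows = []
        for t in transcripts:
            regions = []
            if t.annotated:
                if t.utr5_end > 0:
                    regions.append(("5UTR", 1, t.utr5_end))
                regions.append(("CDS", t.cds_start, t.cds_end))
                if t.cds_end < t.length:
                    regions.append(("3UTR", t.cds_end + 1, t.length))
            else:
                regions.append(("unknown", 1, t.length))
            for region, lo, hi in regions:
                sub = t.seq[lo - 1 : hi]
                run = (
                    find_gcc_run(sub, sequence_id=t.id)
                    if config.repeat_tolerance == 0
                    else find_tolerant_run(sub, config.repeat_tolerance, sequence_id=t.id)
                )
                if run.length_class == "none":
                    continue
                run_start = lo + run.start - 1
                peptide = ""
                if region == "CDS":
                    peptide = translate_repeat(
                        run, frame_offset_of(run_start, t.cds_start), region
                    )
                repeat_rows.append({
                    "transcript_id": t.id,
                    "gene": t.gene,
                    "region": region,
                    "run_start": run_start,
                    "run_length": run.run_length,
                    "length_class": run.length_class,
                    "mismatched_triplets": run.mismatched_triplets,
                    "peptide": peptide,
                })
        repeats_path = out_dir / "repeats.tsv"
        pd.DataFrame(repeat_rows, columns=[
            "transcript_id", "gene", "region", "run_start", "run_length",
            "length_class", "mismatched_triplets", "peptide",
        ]).to_csv(repeats_path, sep="\t", index=False)
        written.append(repeats_path)
        log(f"[repeats] {len(repeat_rows)} classified GCC runs "
            f"(tolerance {config.repeat_tolerance})")

        stage = "pfm"
        pfm_path = out_dir / "pfm.tsv"
        site_seqs = [
            next(t.seq[s.start - 1 : s.end - 1] for t in transcripts if t.id == s.transcript_id)
            for s in sites
        ]
        if site_seqs:
            lengths = pd.Series([len(s) for s in site_seqs])
            modal = int(lengths.mode().iloc[0])
            aligned = [s for s in site_seqs if len(s) == modal]
            pfm = position_frequency_matrix(aligned)
            pfm.to_csv(pfm_path, sep="\t")
            log(f"[pfm] {len(aligned)} sites of modal length {modal}")
        else:
            pfm_path.write_text("")
            log("[pfm] no sites; empty matrix")
        written.append(pfm_path)

        stage = "provenance"
        config_path = out_dir / "config.yaml"
        config_path.write_text(yaml.safe_dump(asdict(config), sort_keys=True))
        written.append(config_path)
        log_path = out_dir / "run_log.txt"
        log_path.write_text("\n".join(log_lines) + "\n")
        written.append(log_path)
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"[{stage}] {exc}") from exc
    return {p.stem: p for p in written}


# ---------------------------------------------------------------------------
# Packaged-fixture self-check


def _table4_class_counts(data_dir=None) -> dict[str, int]:
    df = fixtures_mod.load_table("T4", data_dir)
    counts = {"18": 0, "21": 0, "24": 0, "27plus": 0, "none": 0}
    for seq in df["clean_sequence"]:
        counts[classify_run(find_gcc_run(seq).run_length)] += 1
    return counts


def check_fixtures(data_dir=None) -> tuple[bool, pd.DataFrame]:
    """Recompute the reference-table summary counts and compare to the
    published values.  Returns (all_pass, per-check table)."""
    t1 = fixtures_mod.load_table("T1", data_dir)
    t2 = fixtures_mod.load_table("T2", data_dir)
    t3 = fixtures_mod.load_table("T3", data_dir)
    t4 = fixtures_mod.load_table("T4", data_dir)
    cc = _table4_class_counts(data_dir)
    checks = [
        ("table1 genes with >= 14 clustered sites", int((t1["site_count"] >= 14).sum()), 28),
        ("table2 records", len(t2), 38),
        ("table2 distinct genes at 100% complementarity",
         t2.loc[t2["ratio"] == 100, "gene"].nunique(), 13),
        ("table2 distinct genes with 3UTR sites",
         t2.loc[t2["region"] == "3UTR", "gene"].nunique(), 15),
        ("table2 distinct genes with CDS sites",
         t2.loc[t2["region"] == "CDS", "gene"].nunique(), 10),
        ("table3 CDS repeat sequences", len(t3), 66),
        ("table4 5UTR repeat sequences", len(t4), 52),
        ("table4 exact GCC runs of 18 nt", cc["18"], 18),
        ("table4 exact GCC runs of 21 nt", cc["21"], 11),
        ("table4 exact GCC runs of 24 nt", cc["24"], 14),
        ("table4 exact GCC runs of 27+ nt", cc["27plus"], 9),
    ]
    df = pd.DataFrame(checks, columns=["check", "observed", "expected"])
    df["pass"] = df["observed"] == df["expected"]
    return bool(df["pass"].all()), df
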