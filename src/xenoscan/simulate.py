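"""Seeded synthetic studies with planted binding sites and GCC repeats.

The generator emulates the statistical structure the scanner is built to
detect: transcripts with 5'UTR/CDS/3'UTR geometry carrying (a) reverse-
complement miRNA binding sites with a controlled number of wobble
substitutions, (b) tandem site runs with fixed start spacing (the heavily
overlapping clusters seen for repetitive miRNAs), and (c) (GCC)^k repeat
runs in a designated region with known reading frame.  Every planted
feature is recorded in a truth table with its analytically expected
complementarity ratio, region, length class and encoded homopolymer, so
the whole pipeline is testable end to end without downloads.

All randomness flows through numpy generators seeded from (seed, stream
index); identical config + seed reproduce byte-identical outputs.
Wobble substitutions are made on the mRNA side only (C->U opposite miRNA G,
U->C opposite miRNA A), mirroring fixed reference miRNAs against variable
transcripts.  Planted features carry 3-nt flank guards that prevent
accidental extension of a site run or repeat run by the flanking sequence.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .energy import default_model, perfect_energy, reverse_complement
from .transcripts import MiRNA, Transcript, region_of, write_fasta
from .clusters import classify_run, frame_offset_of, _FRAME_RESIDUE

BASES = np.array(list("ACGU"))
#: substitution turning a canonical mRNA partner into the wobble partner
_WOBBLE_SUB = {"G": ("C", "U"), "A": ("U", "C")}  # miRNA base -> (canonical, wobble)
#: guard base forming no bond against a given miRNA base
_NO_BOND = {"G": "A", "C": "C", "A": "A", "U": "U", "N": "A"}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class PlacementError(ValueError):
    """A planted feature does not fit or conflicts with an earlier one."""


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted feature (1-based coordinates)."""

    transcript_id: str
    feature: str  # "site" or "repeat"
    unit: str  # miRNA id, or repeat unit "GCC"
    start: int
    length: int
    expected_ratio: float | None = None
    expected_region: str = ""
    expected_class: str = ""
    expected_peptide: str = ""


@dataclass(frozen=True)
class SiteSpec:
    """A planted binding site (or tandem run of them) on one transcript."""

    transcript_index: int
    mirna_id: str
    start: int | None = None  # None: choose randomly
    n_tandem: int = 1
    spacing: int = 0
    n_wobbles: int = 0


@dataclass(frozen=True)
class RepeatSpec:
    """A planted (GCC)^k run on one transcript."""

    transcript_index: int
    k_units: int
    region: str = "5UTR"  # "5UTR" or "CDS"
    frame_offset: int = 0
    start: int | None = None


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 42
    n_transcripts: int = 20
    transcript_length: tuple[int, int] = (1200, 2000)
    gc_fraction: float = 0.5
    utr5_fraction: float = 0.2
    cds_fraction: float = 0.5
    mirnas: tuple = ()  # explicit (id, seq) pairs; generated when empty
    n_mirnas: int = 5
    mirna_length: tuple[int, int] = (20, 22)
    site_specs: tuple = ()
    repeat_specs: tuple = ()

    def validate(self) -> None:
        if self.n_transcripts < 0 or self.n_mirnas < 0:
            raise ConfigError("counts must be >= 0")
        if not 0 < self.gc_fraction < 1:
            raise ConfigError(f"gc_fraction must lie strictly in (0, 1), got {self.gc_fraction}")
        if self.utr5_fraction + self.cds_fraction >= 1:
            raise ConfigError("utr5_fraction + cds_fraction must be < 1")


def _rng(seed: int, *stream) -> np.random.Generator:
    # stable across processes (no built-in hash()): independent streams per
    # (seed, label...) so planting one feature never perturbs another
    key = [int(seed) & 0x7FFFFFFF] + [
        zlib.crc32(repr(s).encode()) & 0x7FFFFFFF for s in stream
    ]
    return np.random.default_rng(key)


def random_transcript(
    length: int,
    gc_fraction: float,
    seed: int,
    utr5_fraction: float = 0.2,
    cds_fraction: float = 0.5,
    tx_id: str = "tx1",
) -> Transcript:
    """I.i.d. background transcript with configured region geometry.

    Base probabilities are P(G)=P(C)=gc/2 and P(A)=P(U)=(1-gc)/2.  The CDS
    length is snapped to a multiple of 3 so planted repeats have a
    well-defined reading frame.
    """
    if length < 50:
        raise ConfigError(f"transcript length must be >= 50, got {length}")
    if not 0 < gc_fraction < 1:
        raise ConfigError(f"gc_fraction must lie strictly in (0, 1), got {gc_fraction}")
    rng = _rng(seed, "tx", tx_id)
    p = np.array([
        (1 - gc_fraction) / 2,
        gc_fraction / 2,
        gc_fraction / 2,
        (1 - gc_fraction) / 2,
    ])
    seq = "".join(rng.choice(BASES, size=length, p=p))
    utr5_end = int(round(utr5_fraction * length))
    cds_len = int(round(cds_fraction * length)) // 3 * 3
    cds_end = min(utr5_end + max(cds_len, 3), length - 1)
    return Transcript(id=tx_id, seq=seq, utr5_end=utr5_end, cds_end=cds_end)


def random_mirna(length: int, seed: int, mirna_id: str = "mir1") -> MiRNA:
    rng = _rng(seed, "mirna", mirna_id)
    seq = "".join(rng.choice(BASES, size=length))
    return MiRNA(id=mirna_id, seq=seq)


def _free_interval(occupied, start: int, end: int, margin: int = 3) -> bool:
    return all(end + margin <= s or e + margin <= start for s, e in occupied)


def _choose_start(rng, lo: int, hi: int, occupied, width: int, step: int = 1) -> int:
    """Random 1-based start in [lo, hi] clear of occupied intervals."""
    candidates = [
        s for s in range(lo, hi + 1, step)
        if _free_interval(occupied, s, s + width)
    ]
    if not candidates:
        raise PlacementError("no free position left for planted feature")
    return int(rng.choice(candidates))


def _write(seq: str, start: int, payload: str) -> str:
    """Overwrite seq[start-1 : start-1+len(payload)] (1-based start)."""
    i = start - 1
    return seq[:i] + payload + seq[i + len(payload):]


def plant_site(
    tx: Transcript,
    mirna: MiRNA,
    start: int,
    n_wobbles: int = 0,
    seed: int = 0,
    occupied=None,
) -> tuple[Transcript, TruthRecord]:
    """Write a binding site for *mirna* at *start* with *n_wobbles* wobbles.

    The canonical reverse complement of the miRNA is written, then
    ``n_wobbles`` positions opposite miRNA G or A bases (chosen without
    replacement) are substituted with the wobble partner.  The truth record
    carries the analytic expected ratio
    100·(|ΔGm| - Σ per-substitution losses)/|ΔGm|.
    """
    model = default_model()
    L = len(mirna.seq)
    if not 1 <= start <= tx.length - L + 1:
        raise PlacementError(f"site window [{start}, {start + L}) outside transcript {tx.id!r}")
    occupied = occupied if occupied is not None else []
    if not _free_interval(occupied, start, start + L):
        raise PlacementError(f"site window at {start} overlaps a previously planted feature")
    site = list(reverse_complement(mirna.seq))
    # site position i pairs miRNA position L-1-i
    eligible = [i for i in range(L) if mirna.seq[L - 1 - i] in _WOBBLE_SUB]
    if n_wobbles > len(eligible):
        raise PlacementError(
            f"cannot place {n_wobbles} wobbles: only {len(eligible)} G/A-opposed positions"
        )
    rng = _rng(seed, "wobble", tx.id, start)
    chosen = sorted(rng.choice(eligible, size=n_wobbles, replace=False)) if n_wobbles else []
    loss = 0.0
    for i in chosen:
        m = mirna.seq[L - 1 - i]
        canonical, wobble = _WOBBLE_SUB[m]
        assert site[i] == canonical
        site[i] = wobble
        loss += model.energy(m, canonical) - model.energy(m, wobble)
    dGm = perfect_energy(mirna.seq, model)
    expected_ratio = 100.0 * (abs(dGm) - loss) / abs(dGm)
    new_seq = _write(tx.seq, start, "".join(site))
    new_seq = _guard_site_flanks(new_seq, mirna, start, start + L, period=1)
    occupied.append((start, start + L))
    new_tx = Transcript(id=tx.id, seq=new_seq, gene=tx.gene,
                        utr5_end=tx.utr5_end, cds_end=tx.cds_end)
    truth = TruthRecord(
        transcript_id=tx.id, feature="site", unit=mirna.id, start=start, length=L,
        expected_ratio=expected_ratio, expected_region=region_of(new_tx, start),
    )
    return new_tx, truth


def _guard_site_flanks(seq: str, mirna: MiRNA, start: int, end: int,
                       period: int = 1) -> str:
    """Make the 3 nt on each side of [start, end) bond-free against the
    miRNA positions they would face in a window shifted by the planting
    period, so shifted windows lose energy instead of extending a site run.

    For a tandem run of period p, the dangerous window is the one shifted by
    exactly p (it retains all but p of the canonical pairs); the guard base
    at distance t from the run faces miRNA position L-1-((p-t) mod p) on the
    left and (p-t) mod p on the right of that window.
    """
    L = len(mirna.seq)
    chars = list(seq)
    for t in range(1, 4):
        left = start - t
        if left >= 1:
            chars[left - 1] = _NO_BOND[mirna.seq[L - 1 - ((period - t) % period)]]
        right = end - 1 + t
        if right <= len(chars):
            chars[right - 1] = _NO_BOND[mirna.seq[(period - t) % period]]
    return "".join(chars)


def plant_tandem_sites(
    tx: Transcript,
    mirna: MiRNA,
    n: int,
    spacing: int,
    seed: int = 0,
    start: int | None = None,
    occupied=None,
) -> tuple[Transcript, list[TruthRecord]]:
    """Plant *n* exact sites at starts s, s+spacing, ... (a tandem cluster).

    Overlapping copies (spacing < miRNA length) are only mutually consistent
    when the miRNA's reverse complement is periodic with period = spacing;
    otherwise the overlapped positions would demand two different bases and
    the call refuses, naming the first conflicting position.
    """
    if n < 2:
        raise ConfigError("tandem planting needs n >= 2")
    if spacing < 1:
        raise ConfigError("spacing must be >= 1")
    L = len(mirna.seq)
    rc = reverse_complement(mirna.seq)
    if spacing < L:
        for i in range(L - spacing):
            if rc[i] != rc[i + spacing]:
                raise PlacementError(
                    f"inconsistent overlap: site position {i + spacing + 1} would need "
                    f"{rc[i]!r} (period {spacing}) but the reverse complement has {rc[i + spacing]!r}"
                )
    occupied = occupied if occupied is not None else []
    total = L + spacing * (n - 1)
    if start is None:
        rng = _rng(seed, "tandem", tx.id)
        start = _choose_start(rng, 5, tx.length - total - 4, occupied, total)
    if not 1 <= start <= tx.length - total + 1:
        raise PlacementError(f"tandem run [{start}, {start + total}) outside transcript")
    if not _free_interval(occupied, start, start + total):
        raise PlacementError(f"tandem run at {start} overlaps a previously planted feature")
    if spacing < L:
        # rc has period `spacing`, so the whole run is its periodic extension
        run = "".join(rc[i % spacing] for i in range(total))
    else:
        run_chars = list(tx.seq[start - 1 : start - 1 + total])
        for j in range(n):
            off = j * spacing
            run_chars[off : off + L] = list(rc)
        run = "".join(run_chars)
    new_seq = _write(tx.seq, start, run)
    new_seq = _guard_site_flanks(new_seq, mirna, start, start + total,
                                 period=spacing if spacing < L else 1)
    occupied.append((start, start + total))
    new_tx = Transcript(id=tx.id, seq=new_seq, gene=tx.gene,
                        utr5_end=tx.utr5_end, cds_end=tx.cds_end)
    truths = [
        TruthRecord(
            transcript_id=tx.id, feature="site", unit=mirna.id,
            start=start + j * spacing, length=L, expected_ratio=100.0,
            expected_region=region_of(new_tx, start + j * spacing),
        )
        for j in range(n)
    ]
    return new_tx, truths


def plant_gcc_cluster(
    tx: Transcript,
    k_units: int,
    region: str = "5UTR",
    frame_offset: int = 0,
    seed: int = 0,
    start: int | None = None,
    occupied=None,
) -> tuple[Transcript, TruthRecord]:
    """Plant an exact (GCC)^k run inside the requested region.

    For CDS runs the start is chosen so that the first full codon begins
    ``frame_offset`` bases into the run (0 reads GCC/polyA, 1 CCG/polyP,
    2 CGC/polyR).  AUA flank guards keep the maximal run at exactly 3k nt.
    """
    if not 6 <= k_units <= 16:
        raise ConfigError(f"k_units must be in [6, 16], got {k_units}")
    if region not in ("5UTR", "CDS"):
        raise ConfigError(f"region must be 5UTR or CDS, got {region!r}")
    if not tx.annotated:
        raise PlacementError(f"transcript {tx.id!r} lacks annotation; cannot target {region}")
    run_len = 3 * k_units
    pad = 3  # AUA guards
    if region == "5UTR":
        lo, hi = 1 + pad, tx.utr5_end - run_len + 1 - pad
        step = 1
    else:
        cds_start = tx.cds_start
        lo = cds_start + pad
        lo += (-frame_offset - lo + cds_start) % 3  # align (cds_start - lo) % 3 == frame_offset
        hi = tx.cds_end - run_len + 1 - pad
        step = 3
    if hi < lo:
        raise PlacementError(f"region {region} of {tx.id!r} too short for a {run_len}-nt run")
    occupied = occupied if occupied is not None else []
    if start is None:
        rng = _rng(seed, "gcc", tx.id)
        start = _choose_start(rng, lo, hi, occupied, run_len + pad, step=step)
    if region == "CDS" and frame_offset_of(start, tx.cds_start) != frame_offset:
        raise PlacementError(
            f"start {start} has frame offset {frame_offset_of(start, tx.cds_start)}, "
            f"requested {frame_offset}"
        )
    if not _free_interval(occupied, start, start + run_len):
        raise PlacementError(f"repeat run at {start} overlaps a previously planted feature")
    payload = "AUA" + "GCC" * k_units + "AUA"
    new_seq = _write(tx.seq, start - pad, payload)
    occupied.append((start - pad, start + run_len + pad))
    new_tx = Transcript(id=tx.id, seq=new_seq, gene=tx.gene,
                        utr5_end=tx.utr5_end, cds_end=tx.cds_end)
    peptide = _FRAME_RESIDUE[frame_offset] * k_units if region == "CDS" else ""
    truth = TruthRecord(
        transcript_id=tx.id, feature="repeat", unit="GCC", start=start,
        length=run_len, expected_region=region,
        expected_class=classify_run(run_len), expected_peptide=peptide,
    )
    return new_tx, truth


@dataclass
class StudyBundle:
    """In-memory result of :func:`generate_study`."""

    mirnas: list
    transcripts: list
    truth: pd.DataFrame

    def write(self, out_dir) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "transcripts": out_dir / "transcripts.fasta",
            "mirnas": out_dir / "mirnas.fasta",
            "annotation": out_dir / "annotation.tsv",
            "truth": out_dir / "truth.tsv",
        }
        write_fasta([(t.id, t.seq) for t in self.transcripts], paths["transcripts"])
        write_fasta([(m.id, m.seq) for m in self.mirnas], paths["mirnas"])
        with open(paths["annotation"], "w") as fh:
            fh.write("transcript_id\tutr5_end\tcds_end\n")
            for t in self.transcripts:
                if t.annotated:
                    fh.write(f"{t.id}\t{t.utr5_end}\t{t.cds_end}\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def generate_study(config: SimulationConfig, out_dir=None) -> StudyBundle:
    """Generate the full self-consistent study described by *config*.

    Every planted feature is recoverable by the pipeline at any threshold at
    or below its expected ratio.  Placement failures abort with the seed
    needed to reproduce them.
    """
    config.validate()
    seed = config.seed
    if config.mirnas:
        mirnas = [MiRNA(id=i, seq=s) for i, s in config.mirnas]
    else:
        lo, hi = config.mirna_length
        mirnas = []
        for i in range(config.n_mirnas):
            length = int(_rng(seed, "mirlen", i).integers(lo, hi + 1))
            mirnas.append(random_mirna(length, seed, mirna_id=f"mir{i + 1}"))
    by_id = {m.id: m for m in mirnas}

    transcripts = []
    lo, hi = config.transcript_length
    for i in range(config.n_transcripts):
        tx_id = f"tx{i + 1:03d}"
        length = int(_rng(seed, "txlen", i).integers(lo, hi + 1))
        transcripts.append(
            random_transcript(length, config.gc_fraction, seed,
                              config.utr5_fraction, config.cds_fraction, tx_id=tx_id)
        )

    occupied: dict[int, list] = {i: [] for i in range(len(transcripts))}
    truths: list[TruthRecord] = []
    try:
        for spec in config.repeat_specs:
            tx = transcripts[spec.transcript_index]
            tx, t = plant_gcc_cluster(
                tx, spec.k_units, spec.region, spec.frame_offset, seed,
                start=spec.start, occupied=occupied[spec.transcript_index],
            )
            transcripts[spec.transcript_index] = tx
            truths.append(t)
        for spec in config.site_specs:
            tx = transcripts[spec.transcript_index]
            mirna = by_id[spec.mirna_id]
            if spec.n_tandem > 1:
                tx, ts = plant_tandem_sites(
                    tx, mirna, spec.n_tandem, spec.spacing, seed,
                    start=spec.start, occupied=occupied[spec.transcript_index],
                )
                truths.extend(ts)
            else:
                start = spec.start
                if start is None:
                    rng = _rng(seed, "site", tx.id)
                    start = _choose_start(
                        rng, 5, tx.length - len(mirna.seq) - 4,
                        occupied[spec.transcript_index], len(mirna.seq),
                    )
                tx, t = plant_site(
                    tx, mirna, start, spec.n_wobbles, seed,
                    occupied=occupied[spec.transcript_index],
                )
                truths.append(t)
            transcripts[spec.transcript_index] = tx
    except PlacementError as exc:
        raise PlacementError(f"{exc} (config seed {seed})") from exc

    truth_df = pd.DataFrame([asdict(t) for t in truths], columns=[
        "transcript_id", "feature", "unit", "start", "length",
        "expected_ratio", "expected_region", "expected_class", "expected_peptide",
    ])
    bundle = StudyBundle(mirnas=mirnas, transcripts=transcripts, truth=truth_df)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def demo_config(seed: int = 42) -> SimulationConfig:
    """The packaged demonstration study: 20 transcripts, 5 miRNAs, 30
    planted features (15 single sites with 0-2 wobbles, 3 tandem triples,
    6 GCC repeats across 5'UTR and CDS)."""
    mirna_ids = [f"mir{i}" for i in range(1, 5)] + ["mir-tandem"]
    site_specs = tuple(
        SiteSpec(transcript_index=i, mirna_id=mirna_ids[i % 4], n_wobbles=i % 3)
        for i in range(15)
    ) + tuple(
        SiteSpec(transcript_index=15 + j, mirna_id="mir-tandem",
                 n_tandem=3, spacing=2)
        for j in range(3)
    )
    repeat_specs = (
        RepeatSpec(transcript_index=14, k_units=6, region="5UTR"),
        RepeatSpec(transcript_index=18, k_units=7, region="5UTR"),
        RepeatSpec(transcript_index=19, k_units=9, region="5UTR"),
        RepeatSpec(transcript_index=16, k_units=6, region="CDS", frame_offset=0),
        RepeatSpec(transcript_index=17, k_units=7, region="CDS", frame_offset=2),
        RepeatSpec(transcript_index=19, k_units=8, region="CDS", frame_offset=1),
    )
    # four random miRNAs plus one period-2 miRNA whose reverse complement
    # (CACA...) supports spacing-2 tandem planting
    generated = []
    for i, mid in enumerate(mirna_ids[:4]):
        length = int(_rng(seed, "mirlen", i).integers(20, 23))
        generated.append((mid, random_mirna(length, seed, mirna_id=mid).seq))
    generated.append(("mir-tandem", "UG" * 9))
    return SimulationConfig(
        seed=seed,
        mirnas=tuple(generated),
        site_specs=site_specs,
        repeat_specs=repeat_specs,
    )
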