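"""Sequence and annotation I/O plus mRNA region arithmetic.

Transcripts are modelled with 1-based inclusive coordinates on the mature
mRNA: positions ``1..utr5_end`` are the 5'UTR, ``utr5_end+1..cds_end`` the
CDS, and ``cds_end+1..length`` the 3'UTR.  A site is assigned the region
containing its start position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .energy import EnergyModel, check_alphabet, perfect_energy

REGIONS = ("5UTR", "CDS", "3UTR")


class FormatError(ValueError):
    """A sequence or annotation file is malformed."""


class AnnotationError(ValueError):
    """Region coordinates violate the transcript invariants."""


def clean_sequence(text: str) -> str:
    """Normalize raw sequence text to uppercase RNA.

    Strips every non-letter character (whitespace, digits, zero-width
    separators and other typesetting artifacts), uppercases, and maps T to U.
    """
    return "".join(ch for ch in text if ch.isalpha()).upper().replace("T", "U")


@dataclass(frozen=True)
class FastaRecord:
    id: str
    seq: str
    description: str = ""


@dataclass(frozen=True)
class MiRNA:
    """A miRNA with its cached perfect-complement energy ΔGm (kJ/mol)."""

    id: str
    seq: str
    dGm: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"miRNA {self.id!r} has an empty sequence")
        check_alphabet(self.seq, f"miRNA {self.id!r}")
        if self.dGm is None:
            object.__setattr__(self, "dGm", perfect_energy(self.seq))

    @classmethod
    def from_record(cls, record: FastaRecord, model: EnergyModel | None = None) -> "MiRNA":
        return cls(id=record.id, seq=record.seq, dGm=perfect_energy(record.seq, model))


@dataclass(frozen=True)
class Transcript:
    """An mRNA with optional 5'UTR/CDS annotation.

    ``utr5_end`` is the 1-based last position of the 5'UTR (0 if the
    transcript has no 5'UTR); ``cds_end`` the last position of the CDS.
    Unannotated transcripts carry ``utr5_end = cds_end = None``; they are
    scanned normally but every position maps to region "unknown".
    """

    id: str
    seq: str
    gene: str = ""
    utr5_end: int | None = None
    cds_end: int | None = None

    def __post_init__(self):
        check_alphabet(self.seq, f"transcript {self.id!r}")
        if (self.utr5_end is None) != (self.cds_end is None):
            raise AnnotationError(
                f"transcript {self.id!r}: utr5_end and cds_end must be given together"
            )
        if self.cds_end is not None:
            if not (0 <= self.utr5_end < self.cds_end <= len(self.seq)):
                raise AnnotationError(
                    f"transcript {self.id!r}: require 0 <= utr5_end ({self.utr5_end}) "
                    f"< cds_end ({self.cds_end}) <= length ({len(self.seq)})"
                )

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def annotated(self) -> bool:
        return self.cds_end is not None

    @property
    def cds_start(self) -> int | None:
        """1-based first CDS position, or None if unannotated."""
        return None if self.utr5_end is None else self.utr5_end + 1

    @property
    def cds_in_frame(self) -> bool | None:
        """Whether the annotated CDS length is a multiple of 3 (None if unannotated)."""
        if not self.annotated:
            return None
        return (self.cds_end - self.utr5_end) % 3 == 0

    def region_of(self, position: int) -> str:
        return region_of(self, position)


def region_of(tx: Transcript, position: int) -> str:
    """Region of a 1-based position: '5UTR', 'CDS', '3UTR' or 'unknown'."""
    if not 1 <= position <= tx.length:
        raise IndexError(
            f"position {position} out of range 1..{tx.length} for transcript {tx.id!r}"
        )
    if not tx.annotated:
        return "unknown"
    if position <= tx.utr5_end:
        return "5UTR"
    if position <= tx.cds_end:
        return "CDS"
    return "3UTR"


def read_fasta(path) -> list[FastaRecord]:
    """Read a FASTA file into normalized uppercase-RNA records.

    DNA input is accepted (T mapped to U); mixed case and separator
    characters inside sequences are cleaned away.  Duplicate ids get a
    numeric suffix with a warning.  Record order is preserved.
    """
    path = Path(path)
    records: list[FastaRecord] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        first = fh.read(1)
        if not first:
            raise FormatError(f"{path}: empty FASTA file")
        if first != ">":
            raise FormatError(f"{path}: line 1: expected FASTA header starting with '>'")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            seq = clean_sequence(str(rec.seq))
            check_alphabet(seq, f"record {rec.id!r}")
            rid = rec.id
            if rid in seen:
                seen[rid] += 1
                new_id = f"{rid}.{seen[rid]}"
                warnings.warn(f"{path}: duplicate id {rid!r}, renamed to {new_id!r}")
                rid = new_id
            else:
                seen[rid] = 1
            records.append(FastaRecord(id=rid, seq=seq, description=rec.description))
    return records


def write_fasta(records, path) -> None:
    """Write records (FastaRecord or (id, seq) pairs) as FASTA."""
    seqrecords = []
    for rec in records:
        if isinstance(rec, FastaRecord):
            rid, seq = rec.id, rec.seq
        else:
            rid, seq = rec
        seqrecords.append(SeqRecord(Seq(seq), id=rid, description=""))
    with open(path, "w") as fh:
        SeqIO.write(seqrecords, fh, "fasta-2line")


def read_annotation(path) -> dict[str, tuple[int, int]]:
    """Read region annotation as transcript id -> (utr5_end, cds_end).

    Two dialects are accepted and produce identical results on equivalent
    inputs: a headered/headerless TSV with columns
    ``transcript_id, utr5_end, cds_end`` (1-based inclusive), or a GFF3
    subset with ``five_prime_UTR``/``CDS`` features per mRNA (seqid column
    names the transcript; multi-row features are merged by min/max).
    """
    path = Path(path)
    with open(path) as fh:
        text = fh.read()
    if text.lstrip().startswith("##gff") or _looks_like_gff(text):
        return _parse_gff3(text, path)
    return _parse_tsv(text, path)


def _looks_like_gff(text: str) -> bool:
    for line in text.splitlines():
        if line and not line.startswith("#"):
            return len(line.split("\t")) == 9
    return False


def _parse_tsv(text: str, path) -> dict[str, tuple[int, int]]:
    mapping: dict[str, tuple[int, int]] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: line {lineno}: expected 3 tab-separated columns")
        if lineno == 1 and parts[0] in ("transcript_id", "id"):
            continue
        tid = parts[0]
        try:
            utr5_end, cds_end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: non-integer coordinate") from exc
        if utr5_end >= cds_end:
            raise AnnotationError(
                f"{path}: line {lineno}: transcript {tid!r} has inverted coordinates "
                f"(utr5_end {utr5_end} >= cds_end {cds_end})"
            )
        mapping[tid] = (utr5_end, cds_end)
    return mapping


def _parse_gff3(text: str, path) -> dict[str, tuple[int, int]]:
    utr_end: dict[str, int] = {}
    cds_bounds: dict[str, tuple[int, int]] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise FormatError(f"{path}: line {lineno}: expected 9 GFF3 columns")
        seqid, _, ftype, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
        try:
            start, end = int(start), int(end)
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: non-integer coordinate") from exc
        if ftype == "five_prime_UTR":
            utr_end[seqid] = max(utr_end.get(seqid, 0), end)
        elif ftype == "CDS":
            lo, hi = cds_bounds.get(seqid, (start, end))
            cds_bounds[seqid] = (min(lo, start), max(hi, end))
    mapping: dict[str, tuple[int, int]] = {}
    for tid, (cds_start, cds_end) in cds_bounds.items():
        u5 = utr_end.get(tid, cds_start - 1)
        if u5 >= cds_end:
            raise AnnotationError(f"{path}: transcript {tid!r} has inverted coordinates")
        mapping[tid] = (u5, cds_end)
    return mapping


def load_transcripts(fasta_path, annotation_path=None) -> list[Transcript]:
    """Join a transcript FASTA with its region annotation.

    Transcripts absent from the annotation are kept with region "unknown";
    annotation rows whose coordinates exceed the sequence length raise a
    validation error naming the transcript.
    """
    annotation = read_annotation(annotation_path) if annotation_path else {}
    transcripts = []
    for rec in read_fasta(fasta_path):
        if rec.id in annotation:
            utr5_end, cds_end = annotation[rec.id]
            if cds_end > len(rec.seq):
                raise AnnotationError(
                    f"transcript {rec.id!r}: cds_end {cds_end} exceeds "
                    f"sequence length {len(rec.seq)}"
                )
            transcripts.append(
                Transcript(id=rec.id, seq=rec.seq, gene=rec.description.split()[-1]
                           if rec.description and rec.description != rec.id else "",
                           utr5_end=utr5_end, cds_end=cds_end)
            )
        else:
            if annotation_path:
                warnings.warn(f"transcript {rec.id!r} has no annotation; regions unknown")
            transcripts.append(Transcript(id=rec.id, seq=rec.seq))
    return transcripts


def load_mirnas(fasta_path, model: EnergyModel | None = None) -> list[MiRNA]:
    """Read a miRNA FASTA and cache each ΔGm."""
    return [MiRNA.from_record(rec, model) for rec in read_fasta(fasta_path)]
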