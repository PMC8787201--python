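"""Packaged reference tables of predicted bovine-miRNA binding sites in human mRNAs.

Four TSV fixtures ship with the package, transcribed row-for-row from the
published summary tables of a genome-scale scan of 1025 bovine miRNAs against
17,508 human mRNAs:

* ``table1.tsv`` — 28 human genes whose mRNAs carry clusters of 14+ repeated
  bta-miR-574-5p sites (start of first/last site, site count, ΔG and ΔG/ΔGm
  ranges as printed, e.g. ``-115÷-119``).
* ``table2.tsv`` — 38 high-complementarity (98-100%) site records for
  bta-miRNAs on human mRNAs, with start, region, ΔG, ratio and length.
* ``table3.tsv`` — 66 GCC-repeat binding-site sequences of bta-miR-11975/
  -11976/-2885 in CDS regions, with the encoded oligopeptide.
* ``table4.tsv`` — 52 GCC-repeat binding-site sequences in 5'UTR regions.

Sequence cells are stored exactly as printed, including the zero-width
separators and mixed T/U typesetting of the source; :func:`load_fixtures`
cleans them (strip non-letters, T to U).  File integrity is verified against
packaged SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .transcripts import clean_sequence

TABLE_IDS = ("T1", "T2", "T3", "T4")
_FILES = {"T1": "table1.tsv", "T2": "table2.tsv", "T3": "table3.tsv", "T4": "table4.tsv"}


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture file does not match its recorded checksum."""


@dataclass(frozen=True)
class FixtureRecord:
    """One printed table row, with numeric fields parsed where present."""

    table_id: str
    gene: str
    mirna_id: str = ""
    region: str = ""
    start: int | None = None
    end: int | None = None
    site_count: int | None = None
    dG_text: str = ""
    ratio_text: str = ""
    length_nt: int | None = None
    sequence: str = ""
    peptide: str = ""


def data_path(name: str = "") -> Path:
    base = resources.files("xenoscan") / "data"
    return Path(str(base / name if name else base))


def _verify_checksums(data_dir: Path) -> None:
    sumfile = data_dir / "checksums.sha256"
    if not sumfile.exists():
        raise FixtureIntegrityError(f"missing checksum manifest {sumfile}")
    for line in sumfile.read_text().splitlines():
        if not line.strip():
            continue
        digest, name = line.split()
        payload = (data_dir / name).read_bytes()
        if hashlib.sha256(payload).hexdigest() != digest:
            raise FixtureIntegrityError(f"fixture {name} failed its checksum")


_RANGE_RE = re.compile(r"(\d+)[–\-—‒](\d+)\s*\((\d+)\)")


def _parse_sites_text(text: str) -> tuple[int, int, int]:
    """Parse 'first–last (count)' cluster notation, e.g. '861–903 (22)'."""
    m = _RANGE_RE.match(text.strip())
    if not m:
        raise ValueError(f"unparseable cluster text {text!r}")
    return int(m.group(1)), int(m.group(2)), int(m.group(3))


def parse_printed_range(text: str) -> tuple[float, float]:
    """Parse a printed numeric range like '-115÷-119', '90–93' or a single value."""
    text = text.strip().replace("−", "-")
    parts = re.split(r"[÷–—‒]|(?<=\d)-(?=-?\d)", text)
    values = [float(p) for p in parts if p not in ("", "-")]
    if not values:
        raise ValueError(f"unparseable range {text!r}")
    return min(values), max(values)


def _read(data_dir: Path, table_id: str) -> pd.DataFrame:
    return pd.read_csv(data_dir / _FILES[table_id], sep="\t", dtype=str).fillna("")


def load_table(table_id: str, data_dir=None, verify: bool = True) -> pd.DataFrame:
    """Load one fixture table as a DataFrame with parsed numeric columns."""
    data_dir = Path(data_dir) if data_dir else data_path()
    if verify:
        _verify_checksums(data_dir)
    df = _read(data_dir, table_id)
    if table_id == "T1":
        parsed = df["sites_text"].map(_parse_sites_text)
        df["first_start"] = [p[0] for p in parsed]
        df["last_start"] = [p[1] for p in parsed]
        df["site_count"] = [p[2] for p in parsed]
    elif table_id == "T2":
        for col in ("start", "dG", "ratio", "length_nt"):
            df[col] = df[col].astype(int)
        for col in ("identical_human", "milk"):
            df[col] = df[col].astype(int)
    else:
        df["clean_sequence"] = df["sequence"].map(clean_sequence)
    return df


def load_fixtures(data_dir=None, verify: bool = True) -> list[FixtureRecord]:
    """Load all four tables as a flat list of :class:`FixtureRecord`."""
    data_dir = Path(data_dir) if data_dir else data_path()
    if verify:
        _verify_checksums(data_dir)
    records: list[FixtureRecord] = []
    t1 = load_table("T1", data_dir, verify=False)
    for row in t1.itertuples():
        records.append(
            FixtureRecord(
                table_id="T1", gene=row.gene, mirna_id="bta-miR-574-5p",
                start=row.first_start, end=row.last_start, site_count=row.site_count,
                dG_text=row.dG_text, ratio_text=row.ratio_text,
            )
        )
    t2 = load_table("T2", data_dir, verify=False)
    for row in t2.itertuples():
        records.append(
            FixtureRecord(
                table_id="T2", gene=row.gene, mirna_id=row.mirna_id, region=row.region,
                start=row.start, site_count=1, dG_text=str(row.dG),
                ratio_text=str(row.ratio), length_nt=row.length_nt,
            )
        )
    for table_id, region in (("T3", "CDS"), ("T4", "5UTR")):
        df = load_table(table_id, data_dir, verify=False)
        for row in df.itertuples():
            records.append(
                FixtureRecord(
                    table_id=table_id, gene=row.gene, region=region,
                    sequence=row.clean_sequence,
                    length_nt=len(row.clean_sequence),
                    peptide=getattr(row, "peptide", ""),
                )
            )
    return records
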