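"""Binding-site cluster metrics and GCC-repeat / homopolymer analysis.

Repeated miRNA binding sites in a transcript often overlap heavily — up to
dozens of sites packed into a few tens of nucleotides.  A cluster is a
maximal group of sites whose intervals overlap or lie within a configurable
gap of each other.  Its headline metrics are the span (last site end minus
first site start), the multiset of successive start spacings ("through one
nucleotide", "through three"), and the degree of compaction: summed site
length divided by span, a measure of overlap density.

The GCC-rich clusters in 5'UTRs and CDSs correspond to trinucleotide
repeats: a maximal contiguous (GCC)^k substring.  Inside a CDS such a run
encodes a homopolymeric tract whose residue depends on the codon phase —
GCC reads polyalanine, CCG polyproline, CGC polyarginine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


class DegenerateClusterError(ValueError):
    """A cluster has non-positive span."""


@dataclass
class SiteCluster:
    """A maximal group of mutually overlapping/abutting binding sites."""

    transcript_id: str
    gene: str
    sites: list = field(default_factory=list)

    def __post_init__(self):
        self.sites = sorted(self.sites, key=lambda s: (s.start, s.mirna_id))

    @property
    def first_start(self) -> int:
        return self.sites[0].start

    @property
    def last_end(self) -> int:
        return max(s.end for s in self.sites)

    @property
    def span(self) -> int:
        return self.last_end - self.first_start

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_count_by_mirna(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.sites:
            counts[s.mirna_id] = counts.get(s.mirna_id, 0) + 1
        return counts

    @property
    def total_site_length(self) -> int:
        return sum(s.length for s in self.sites)

    @property
    def compaction(self) -> float:
        return compaction(self.total_site_length, self.span)

    @property
    def start_spacings(self) -> list[int]:
        return start_spacings(self)

    @property
    def dG_range(self) -> tuple[float, float]:
        values = [s.dG for s in self.sites]
        return min(values), max(values)

    @property
    def ratio_range(self) -> tuple[float, float]:
        values = [s.ratio for s in self.sites]
        return min(values), max(values)


def cluster_sites(sites, gap: int = 0) -> list[SiteCluster]:
    """Partition one transcript's sites into maximal proximity clusters.

    Two sites belong to the same cluster when their intervals overlap or are
    separated by at most ``gap`` nucleotides (gap 0: overlap or abut).  The
    partition is independent of input order; singletons are allowed.
    """
    if not sites:
        return []
    ordered = sorted(sites, key=lambda s: (s.start, s.mirna_id))
    tids = {s.transcript_id for s in ordered}
    if len(tids) > 1:
        raise ValueError(f"cluster_sites expects sites of one transcript, got {sorted(tids)}")
    clusters = []
    current = [ordered[0]]
    reach = ordered[0].end
    for s in ordered[1:]:
        if s.start <= reach + gap:
            current.append(s)
        else:
            clusters.append(current)
            current = [s]
        reach = max(reach, s.end)
    clusters.append(current)
    return [
        SiteCluster(transcript_id=c[0].transcript_id, gene=c[0].gene, sites=c)
        for c in clusters
    ]


def compaction(total_site_length: float, span: float) -> float:
    """Degree of compaction: summed site length / cluster span.

    Stored unrounded; reports round to the nearest integer.  >= 1 for any
    gap-0 cluster.
    """
    if span <= 0:
        raise DegenerateClusterError(f"cluster span must be positive, got {span}")
    return total_site_length / span


def start_spacings(cluster) -> list[int]:
    """Successive start differences of cluster members in 5'->3' order."""
    sites = cluster.sites if isinstance(cluster, SiteCluster) else sorted(
        cluster, key=lambda s: s.start
    )
    starts = [s.start for s in sites]
    return [b - a for a, b in zip(starts, starts[1:])]


# ---------------------------------------------------------------------------
# GCC repeats


LENGTH_CLASSES = ("18", "21", "24", "27plus")


@dataclass(frozen=True)
class RepeatRun:
    """A maximal GCC-phase trinucleotide run.

    ``k`` counts complete triplets (GCC plus up to ``mismatched_triplets``
    interior non-GCC triplets for tolerant detection); ``run_length`` = 3k.
    ``homopolymer`` is filled by :func:`translate_repeat` for CDS runs.
    """

    sequence_id: str
    start: int  # 1-based; 0 when k == 0
    k: int
    run_length: int
    length_class: str
    mismatched_triplets: int = 0
    homopolymer: str = ""


def _make_run(sequence_id: str, start: int, k: int, bad: int = 0) -> RepeatRun:
    return RepeatRun(
        sequence_id=sequence_id,
        start=start,
        k=k,
        run_length=3 * k,
        length_class=classify_run(3 * k),
        mismatched_triplets=bad,
    )


def find_gcc_run(seq: str, sequence_id: str = "") -> RepeatRun:
    """Locate the maximal exact (GCC)^k contiguous substring.

    Leftmost occurrence wins ties; k = 0 (no GCC unit at all) is allowed and
    reported with start 0.
    """
    best_k, best_start = 0, 0
    L = len(seq)
    for i in range(max(L - 2, 0)):
        if seq[i : i + 3] == "GCC":
            j, k = i, 0
            while seq[j : j + 3] == "GCC":
                k += 1
                j += 3
            if k > best_k:
                best_k, best_start = k, i + 1
    return _make_run(sequence_id, best_start, best_k)


def find_tolerant_run(seq: str, max_bad_triplets: int = 0, sequence_id: str = "") -> RepeatRun:
    """Maximal GCC-phase triplet run allowing interior non-GCC triplets.

    At most ``max_bad_triplets`` triplets in the run may differ from GCC and
    never at either end.  With ``max_bad_triplets = 0`` this reduces exactly
    to :func:`find_gcc_run`.  Longest run wins; leftmost on ties.
    """
    if max_bad_triplets < 0:
        raise ValueError("max_bad_triplets must be >= 0")
    best_k, best_start, best_bad = 0, 0, 0
    L = len(seq)
    for i in range(L - 2):
        if seq[i : i + 3] != "GCC":
            continue
        # extend triplet-wise from i, tracking the furthest GCC end
        k = 0
        bad = 0
        bad_used_at_best = 0
        run_k = 0
        j = i
        while j + 3 <= L:
            triplet = seq[j : j + 3]
            if triplet == "GCC":
                k += 1
                run_k = k
                bad_used_at_best = bad
            else:
                bad += 1
                if bad > max_bad_triplets:
                    break
                k += 1
            j += 3
        if run_k > best_k:
            best_k, best_start, best_bad = run_k, i + 1, bad_used_at_best
    return _make_run(sequence_id, best_start, best_k, best_bad)


def classify_run(run_length: int) -> str:
    """Length class of a run: '18', '21', '24', '27plus' or 'none' (< 18)."""
    if run_length % 3 != 0:
        raise ValueError(f"run length must be a multiple of 3, got {run_length}")
    if run_length < 18:
        return "none"
    if run_length >= 27:
        return "27plus"
    return str(run_length)


_FRAME_RESIDUE = {0: "A", 1: "P", 2: "R"}  # GCC=Ala, CCG=Pro, CGC=Arg


def frame_offset_of(run_start: int, cds_start: int) -> int:
    """Codon phase of a CDS run: offset into the run where the first full
    codon begins, i.e. ``(cds_start - run_start) mod 3`` for 1-based
    coordinates."""
    return (cds_start - run_start) % 3


def translate_repeat(run: RepeatRun, frame_offset: int, region: str = "CDS") -> str:
    """Homopolymer encoded by a CDS GCC run under the standard code.

    ``frame_offset`` selects the codon rotation read from the run: 0 reads
    GCC (polyalanine), 1 reads CCG (polyproline), 2 reads CGC
    (polyarginine).  Length equals ``run.k``.  Non-CDS runs are refused.
    """
    if region != "CDS":
        raise ValueError(f"repeat run is in region {region!r}; only CDS runs encode peptide")
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    return _FRAME_RESIDUE[frame_offset] * run.k


# ---------------------------------------------------------------------------
# Position-frequency matrix (numeric sequence-logo equivalent)


def position_frequency_matrix(sequences) -> pd.DataFrame:
    """Column-stochastic base x position frequency table of aligned sequences."""
    sequences = list(sequences)
    if not sequences:
        raise ValueError("need at least one sequence")
    length = len(sequences[0])
    for s in sequences:
        if len(s) != length:
            raise ValueError(
                f"sequences must be aligned to equal length ({length} != {len(s)})"
            )
    bases = "ACGUN" if any("N" in s for s in sequences) else "ACGU"
    counts = {b: [0] * length for b in bases}
    for s in sequences:
        for pos, base in enumerate(s):
            counts[base][pos] += 1
    df = pd.DataFrame(counts).T
    df.columns = range(1, length + 1)
    return df / len(sequences)
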