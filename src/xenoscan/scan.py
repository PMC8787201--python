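"""Sliding-window binding-site prediction over full transcripts.

Every window of miRNA length, starting from the first nucleotide of the
mRNA with step 1, is scored as an ungapped antiparallel duplex; windows whose
unrounded complementarity ratio reaches the threshold become binding sites.
Windows containing more than 10% N are skipped to avoid spurious calls on
masked sequence.  When sites of *different* miRNAs overlap, the one with the
greater binding energy magnitude |ΔG| is preferred; heavily overlapping
tandem sites of the *same* miRNA are a real reported phenomenon and are
always kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energy import EnergyModel, default_model, perfect_energy
from .transcripts import MiRNA, Transcript, region_of

DEFAULT_THRESHOLD = 90.0
MAX_N_FRACTION = 0.10

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}


@dataclass(frozen=True)
class BindingSite:
    """An accepted miRNA binding site on one transcript.

    ``start`` is 1-based; ``end = start + length`` follows the cluster-span
    convention used throughout (span = last end - first start).
    """

    mirna_id: str
    transcript_id: str
    gene: str
    start: int
    length: int
    dG: float
    dGm: float
    ratio: float
    region: str

    @property
    def end(self) -> int:
        return self.start + self.length


def _energy_matrix(model: EnergyModel) -> np.ndarray:
    E = np.zeros((5, 5))
    for i, x in enumerate("ACGU"):
        for j, y in enumerate("ACGU"):
            E[i, j] = model.energy(x, y)
    return E


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.int8, count=len(seq))


def scan(
    mirna: MiRNA,
    tx: Transcript,
    model: EnergyModel | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[BindingSite]:
    """Score every window of one transcript against one miRNA.

    Returns sites sorted by start, each annotated with the region containing
    its start position.  A miRNA longer than the transcript yields an empty
    list with a warning rather than an error.
    """
    model = model or default_model()
    if not 0 < threshold <= 100:
        raise ValueError(f"threshold must be in (0, 100], got {threshold}")
    L = len(mirna.seq)
    if L > tx.length:
        warnings.warn(
            f"miRNA {mirna.id!r} (length {L}) longer than transcript "
            f"{tx.id!r} (length {tx.length}); no windows to scan"
        )
        return []
    E = _energy_matrix(model)
    tx_codes = _encode(tx.seq)
    # site position i pairs miRNA position L-1-i, so score windows against
    # the reversed miRNA
    mir_rev = _encode(mirna.seq[::-1])
    windows = np.lib.stride_tricks.sliding_window_view(tx_codes, L)
    magnitudes = E[windows, mir_rev[np.newaxis, :]].sum(axis=1)
    n_counts = (windows == _BASE_INDEX["N"]).sum(axis=1)
    dGm = perfect_energy(mirna.seq, model)
    if dGm == 0:
        warnings.warn(f"miRNA {mirna.id!r} has zero dGm; nothing to scan")
        return []
    ratios = 100.0 * magnitudes / abs(dGm)
    # epsilon absorbs summation-order float noise so a perfect site always
    # passes threshold 100
    keep = (ratios >= threshold - 1e-9) & (n_counts <= MAX_N_FRACTION * L)
    sites = []
    for idx in np.flatnonzero(keep):
        start = int(idx) + 1
        sites.append(
            BindingSite(
                mirna_id=mirna.id,
                transcript_id=tx.id,
                gene=tx.gene,
                start=start,
                length=L,
                dG=-float(magnitudes[idx]),
                dGm=dGm,
                ratio=float(ratios[idx]),
                region=region_of(tx, start),
            )
        )
    return sites


def scan_all(
    mirnas,
    transcripts,
    model: EnergyModel | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    log=None,
) -> list[BindingSite]:
    """Scan every miRNA against every transcript.

    Output order is deterministic — (transcript id, start, miRNA id) —
    regardless of input ordering.
    """
    sites: list[BindingSite] = []
    for tx in transcripts:
        for mirna in mirnas:
            sites.extend(scan(mirna, tx, model=model, threshold=threshold))
        if log is not None:
            log(f"{tx.id}: {sum(s.transcript_id == tx.id for s in sites)} sites")
    sites.sort(key=lambda s: (s.transcript_id, s.start, s.mirna_id))
    return sites


def resolve_overlaps(sites) -> list[BindingSite]:
    """Resolve partial overlaps between sites of different miRNAs.

    Among sites of different miRNAs whose intervals intersect, only the site
    with the larger |ΔG| survives; applied transitively over overlap chains
    by iteratively discarding the weakest conflicted site.  Ties keep the
    5'-most start, then the lexicographically smallest miRNA id.  Overlaps
    between sites of the same miRNA (tandem repeats) are never removed.
    The result is a pure, idempotent, order-independent function of the set.
    """
    alive = sorted(sites, key=lambda s: (s.transcript_id, s.start, s.mirna_id))
    while True:
        conflicted: set[int] = set()
        for i, a in enumerate(alive):
            for j in range(i + 1, len(alive)):
                b = alive[j]
                if b.transcript_id != a.transcript_id or b.start >= a.end:
                    break
                if b.mirna_id != a.mirna_id:
                    conflicted.update((i, j))
        if not conflicted:
            return alive
        # weakest = smallest |dG|; tie-break removes the 3'-most start, then
        # the lexicographically larger miRNA id
        weakest = max(
            conflicted,
            key=lambda i: (-abs(alive[i].dG), alive[i].start, alive[i].mirna_id),
        )
        del alive[weakest]


def sites_to_frame(sites) -> pd.DataFrame:
    """Tabulate sites with the printed-table column conventions.

    ΔG and ratio are rounded at this reporting layer only (integer kJ/mol
    and integer percent); ``start`` is the 1-based 'Start of site, nt'.
    """
    rows = [
        {
            "gene": s.gene,
            "mirna_id": s.mirna_id,
            "transcript_id": s.transcript_id,
            "start": s.start,
            "region": s.region,
            "dG": int(round(s.dG)),
            "ratio": int(round(s.ratio)),
            "length": s.length,
        }
        for s in sites
    ]
    return pd.DataFrame(
        rows,
        columns=["gene", "mirna_id", "transcript_id", "start", "region", "dG", "ratio", "length"],
    )
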