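"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's vectorized/loop code paths: the scan
oracle rescored every window by direct per-pair summation, and the repeat
oracle uses a regular-expression search.
"""

import re

_E = {
    ("G", "C"): 6.37, ("C", "G"): 6.37,
    ("A", "U"): 4.25, ("U", "A"): 4.25,
    ("G", "U"): 2.12, ("U", "G"): 2.12,
    ("A", "C"): 2.12, ("C", "A"): 2.12,
}
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def brute_force_scan(mirna_seq: str, tx_seq: str, threshold: float):
    """All (start, dG, ratio) with unrounded ratio >= threshold, start 1-based."""
    L = len(mirna_seq)
    mir_rev = mirna_seq[::-1]
    dGm_mag = sum(_E[(b, _COMP[b])] for b in mirna_seq)
    hits = []
    for i in range(len(tx_seq) - L + 1):
        window = tx_seq[i : i + L]
        mag = sum(_E.get(pair, 0.0) for pair in zip(window, mir_rev))
        ratio = 100.0 * mag / dGm_mag
        if ratio >= threshold:
            hits.append((i + 1, -mag, ratio))
    return hits


def regex_gcc_run(seq: str):
    """(start, run_length) of the leftmost-longest exact (GCC)^k run."""
    best = (0, 0)
    for m in re.finditer(r"(?:GCC)+", seq):
        k3 = len(m.group()) // 3 * 3
        if k3 > best[1]:
            best = (m.start() + 1, k3)
    return best


def overlap_resolution_oracle(sites):
    """Exhaustive restatement of the overlap-resolution rule.

    Repeatedly find any pair of different-miRNA overlapping sites and delete
    the weaker by (|dG|, then 3'-most start, then larger miRNA id).
    """
    alive = list(sites)
    while True:
        conflicted = [
            s for s in alive
            if any(
                o is not s
                and o.transcript_id == s.transcript_id
                and o.mirna_id != s.mirna_id
                and o.start < s.end
                and s.start < o.end
                for o in alive
            )
        ]
        if not conflicted:
            return sorted(alive, key=lambda s: (s.transcript_id, s.start, s.mirna_id))
        loser = min(conflicted, key=lambda s: (abs(s.dG), -s.start, _neg_str(s.mirna_id)))
        alive.remove(loser)


class _neg_str(str):
    """Reverses comparison order so min() picks the lexicographically largest id."""

    def __lt__(self, other):
        return str(self) > str(other)
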