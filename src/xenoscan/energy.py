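"""Additive hybridization free-energy model for full-length miRNA:mRNA duplexes.

A binding site is an mRNA window of the same length as the miRNA, paired
antiparallel and ungapped: site position ``i`` (0-based) pairs miRNA position
``L - 1 - i``.  Each bonded base pair contributes a fixed free-energy magnitude
(kJ/mol) and the duplex energy is the negated sum:

    ΔG = -Σ_i E(site[i], mirna[L-1-i])

Bonded pairs are the canonical Watson-Crick pairs G:C (6.37 kJ/mol, 3 hydrogen
bonds) and A:U (4.25 kJ/mol, 2 bonds) plus the non-canonical wobbles G:U and
A:C (2.12 kJ/mol, 1 bond each).  All other pairs form no bond and contribute
nothing.  ΔGm is the energy of the miRNA against its exact canonical
complement — a composition-only lower bound on ΔG — and the site-quality
statistic is the complementarity ratio 100·ΔG/ΔGm (%), which is 100 exactly
when the site is the canonical reverse complement of the miRNA.

There are no gap, bulge, stacking or nearest-neighbour terms: the model is
strictly per-pair additive over the full miRNA length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

RNA_BASES = frozenset("ACGU")
#: Bases accepted in normalized sequences.  N is allowed and never bonds.
RNA_ALPHABET = frozenset("ACGUN")

CANONICAL_PAIRS = (frozenset("GC"), frozenset("AU"))
WOBBLE_PAIRS = (frozenset("GU"), frozenset("AC"))

#: Canonical Watson-Crick complement, used for ΔGm and reverse complements.
COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}


class AlphabetError(ValueError):
    """A sequence contains a symbol outside {A, C, G, U, N}."""


class DuplexLengthError(ValueError):
    """miRNA and site sequences have different lengths."""


class DegenerateInputError(ValueError):
    """An input makes the requested statistic undefined (e.g. ΔGm = 0)."""


def _check_base(base: str, position: int | None = None) -> str:
    if base not in RNA_ALPHABET:
        where = "" if position is None else f" at position {position + 1}"
        raise AlphabetError(f"unknown nucleotide symbol {base!r}{where}")
    return base


def check_alphabet(seq: str, name: str = "sequence") -> str:
    """Validate that *seq* is over {A,C,G,U,N}; return it unchanged."""
    for i, base in enumerate(seq):
        if base not in RNA_ALPHABET:
            raise AlphabetError(
                f"unknown nucleotide symbol {base!r} at position {i + 1} of {name}"
            )
    return seq


@dataclass(frozen=True)
class EnergyModel:
    """Per-pair free-energy magnitudes (kJ/mol) and hydrogen-bond counts.

    Both tables are keyed by the unordered base pair; any pair absent from
    the tables (including every pair involving N) is non-bonding.
    """

    pair_energy: dict[frozenset, float] = field(
        default_factory=lambda: {
            frozenset("GC"): 6.37,
            frozenset("AU"): 4.25,
            frozenset("GU"): 2.12,
            frozenset("AC"): 2.12,
        }
    )
    hbond_count: dict[frozenset, int] = field(
        default_factory=lambda: {
            frozenset("GC"): 3,
            frozenset("AU"): 2,
            frozenset("GU"): 1,
            frozenset("AC"): 1,
        }
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for pair, energy in self.pair_energy.items():
            if energy < 0:
                raise ValueError(f"pair energy for {set(pair)} must be a magnitude >= 0")
            bonds = self.hbond_count.get(pair, 0)
            if energy > 0 and bonds < 1:
                raise ValueError(f"bonded pair {set(pair)} must have >= 1 hydrogen bond")
            if energy == 0 and bonds != 0:
                raise ValueError(f"non-bonding pair {set(pair)} must have 0 hydrogen bonds")
        # Energy ordering must match hydrogen-bond ordering.
        ranked = sorted(
            (p for p in self.pair_energy if self.pair_energy[p] > 0),
            key=lambda p: self.pair_energy[p],
        )
        bonds = [self.hbond_count[p] for p in ranked]
        if bonds != sorted(bonds):
            raise ValueError("pair energy ordering disagrees with hydrogen-bond ordering")

    def energy(self, x: str, y: str) -> float:
        return self.pair_energy.get(frozenset((x, y)), 0.0)

    def bonds(self, x: str, y: str) -> int:
        return self.hbond_count.get(frozenset((x, y)), 0)

    @classmethod
    def default(cls) -> "EnergyModel":
        return cls()

    @classmethod
    def from_config(cls, path) -> "EnergyModel":
        """Load an override model from a flat YAML mapping.

        Keys are two-letter pairs (e.g. ``GC``), values are ``[energy, hbonds]``.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        energies: dict[frozenset, float] = {}
        bonds: dict[frozenset, int] = {}
        for key, value in raw.items():
            key = str(key).upper()
            if len(key) != 2 or any(b not in RNA_BASES for b in key):
                raise ValueError(f"energy-model key must be a two-letter RNA pair, got {key!r}")
            energy, nb = value
            pair = frozenset(key)
            energies[pair] = float(energy)
            bonds[pair] = int(nb)
        return cls(pair_energy=energies, hbond_count=bonds)


_DEFAULT_MODEL = EnergyModel.default()


def default_model() -> EnergyModel:
    return _DEFAULT_MODEL


def pair_energy(base_mrna: str, base_mirna: str, model: EnergyModel | None = None) -> float:
    """Free-energy magnitude (kJ/mol) of one mRNA:miRNA base pair.

    Symmetric in its arguments; any pair involving N returns 0.
    """
    model = model or _DEFAULT_MODEL
    _check_base(base_mrna)
    _check_base(base_mirna)
    return model.energy(base_mrna, base_mirna)


def hydrogen_bonds(base_mrna: str, base_mirna: str, model: EnergyModel | None = None) -> int:
    """Hydrogen-bond count of one mRNA:miRNA base pair (0 for non-bonding)."""
    model = model or _DEFAULT_MODEL
    _check_base(base_mrna)
    _check_base(base_mirna)
    return model.bonds(base_mrna, base_mirna)


def perfect_energy(mirna: str, model: EnergyModel | None = None) -> float:
    """ΔGm: free energy (kJ/mol, <= 0) of the miRNA against its exact complement.

    Depends only on base composition: each base contributes the energy of its
    canonical pair, so under the default model
    ΔGm = -(6.37·(#G + #C) + 4.25·(#A + #U)).
    """
    model = model or _DEFAULT_MODEL
    if not mirna:
        raise ValueError("miRNA sequence must be non-empty")
    check_alphabet(mirna, "miRNA")
    return -sum(model.energy(b, COMPLEMENT[b]) for b in mirna)


def classify_pair(base_mrna: str, base_mirna: str) -> str:
    """Label one pair as 'canonical', 'wobble' or 'none'."""
    pair = frozenset((base_mrna, base_mirna))
    if pair in CANONICAL_PAIRS:
        return "canonical"
    if pair in WOBBLE_PAIRS:
        return "wobble"
    return "none"


@dataclass(frozen=True)
class Duplex:
    """One miRNA paired antiparallel against one equal-length mRNA site.

    ``pair_classes[i]`` labels the pair formed by site position ``i`` and
    miRNA position ``L - 1 - i``.  Energies are negative; ``ratio`` is the
    complementarity ratio 100·ΔG/ΔGm in percent.
    """

    mirna_seq: str
    site_seq: str
    pair_classes: tuple
    dG: float
    dGm: float
    ratio: float


def duplex_energy(mirna: str, site: str, model: EnergyModel | None = None) -> Duplex:
    """Score one ungapped antiparallel duplex over the full miRNA length."""
    model = model or _DEFAULT_MODEL
    if len(mirna) != len(site):
        raise DuplexLengthError(
            f"miRNA length {len(mirna)} != site length {len(site)}"
        )
    check_alphabet(mirna, "miRNA")
    check_alphabet(site, "site")
    dGm = perfect_energy(mirna, model)
    total = 0.0
    classes = []
    L = len(mirna)
    for i, site_base in enumerate(site):
        mirna_base = mirna[L - 1 - i]
        total += model.energy(site_base, mirna_base)
        classes.append(classify_pair(site_base, mirna_base))
    dG = -total
    return Duplex(
        mirna_seq=mirna,
        site_seq=site,
        pair_classes=tuple(classes),
        dG=dG,
        dGm=dGm,
        ratio=complementarity_ratio(dG, dGm),
    )


def complementarity_ratio(dG: float, dGm: float) -> float:
    """100·ΔG/ΔGm in percent, unrounded.

    Reports round this to the nearest integer; filtering always uses the
    unrounded value.
    """
    if dGm == 0:
        raise DegenerateInputError("dGm is zero; complementarity ratio undefined")
    if dGm > 0 or dG > 0:
        raise ValueError("energies must be <= 0 (stored as negative dG values)")
    if abs(dG) > abs(dGm) + 1e-9:
        raise ValueError("|dG| cannot exceed |dGm|")
    return 100.0 * dG / dGm


_BOND_CHAR = {"canonical": "|", "wobble": ":", "none": " "}
_CHAR_BOND = {v: k for k, v in _BOND_CHAR.items()}


def render_scheme(duplex: Duplex) -> str:
    """Three-line interaction scheme: site 5'->3', bond row, miRNA 3'->5'.

    '|' marks a canonical pair, ':' a wobble, space no bond.  The block is
    parseable back into the pair classes with :func:`parse_scheme`.
    """
    bonds = "".join(_BOND_CHAR[c] for c in duplex.pair_classes)
    return (
        f"5'-{duplex.site_seq}-3'\n"
        f"   {bonds}\n"
        f"3'-{duplex.mirna_seq[::-1]}-5'"
    )


def parse_scheme(block: str) -> tuple:
    """Recover (site_seq, pair_classes, mirna_seq) from a rendered scheme."""
    lines = block.split("\n")
    if len(lines) != 3:
        raise ValueError("scheme must have exactly three lines")
    site = lines[0][3:-3]
    mirna_rev = lines[2][3:-3]
    bonds = lines[1][3:].ljust(len(site))
    classes = tuple(_CHAR_BOND[ch] for ch in bonds[: len(site)])
    return site, classes, mirna_rev[::-1]


def reverse_complement(seq: str) -> str:
    """Canonical reverse complement over {A,C,G,U,N}."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))
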