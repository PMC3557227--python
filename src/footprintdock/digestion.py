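"""In-silico limited proteolysis.

Limited proteolysis cuts a folded protein briefly with a sequence-specific
protease; because digestion is partial, the observable species are not only
the fully digested peptides but every fragment delimited by any pair of
boundaries (termini or cleavage sites).  This module detects cleavage sites
for a protease specificity rule, enumerates all such partial-digestion
fragments, and computes their (monoisotopic or average) masses.

Residue numbering is 1-based and inclusive throughout; a
``numbering_offset`` lets positions match published construct numbering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from pyteomics import mass as _pmass

__all__ = [
    "STANDARD_AA",
    "ProteinSequence",
    "ProteaseRule",
    "CleavageSite",
    "Fragment",
    "TRYPSIN",
    "CHYMOTRYPSIN",
    "V8",
    "BUILTIN_PROTEASES",
    "cleavage_sites",
    "enumerate_fragments",
    "fragment_mass",
    "multi_protease_coverage",
    "read_fasta",
    "digest",
    "digest_report",
]

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Monoisotopic mass of water, Da (added once per peptide chain).
WATER_MONO = _pmass.calculate_mass(formula="H2O")
WATER_AVERAGE = _pmass.calculate_mass(formula="H2O", average=True)


class SequenceFormatError(ValueError):
    """A residue letter outside the 20 standard amino acids."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein chain with its residue numbering.

    Parameters
    ----------
    id : str
        Identifier (FASTA header word).
    residues : str
        One-letter sequence, standard 20 amino acids only.
    numbering_offset : int
        Residue number of the first residue (default 1).
    """

    id: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceFormatError(f"{self.id}: empty sequence")
        for i, aa in enumerate(self.residues):
            if aa not in STANDARD_AA:
                raise SequenceFormatError(
                    f"{self.id}: non-standard residue {aa!r} at position "
                    f"{self.numbering_offset + i}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def first_residue(self) -> int:
        return self.numbering_offset

    @property
    def last_residue(self) -> int:
        return self.numbering_offset + len(self.residues) - 1

    def residue_at(self, number: int) -> str:
        """One-letter code of the residue with the given residue number."""
        i = number - self.numbering_offset
        if not 0 <= i < len(self.residues):
            raise IndexError(f"residue number {number} outside {self.id}")
        return self.residues[i]

    def subsequence(self, start: int, end: int) -> str:
        """Residues ``start..end`` inclusive, in residue numbers."""
        if start > end:
            raise ValueError(f"start {start} > end {end}")
        if start < self.first_residue or end > self.last_residue:
            raise IndexError(f"{start}-{end} outside {self.id}")
        a = start - self.numbering_offset
        return self.residues[a : a + (end - start + 1)]


@dataclass(frozen=True)
class ProteaseRule:
    """Cleavage specificity: cut C-terminal of any P1 residue.

    ``exceptions`` are P1' residues (the residue after the bond) that block
    cleavage — e.g. proline for trypsin when the classical Keil exception is
    wanted.  Built-ins carry no exceptions: the bare specificities are used.
    """

    name: str
    p1_residues: frozenset[str]
    exceptions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.p1_residues:
            raise ValueError(f"{self.name}: empty P1 residue set")
        bad = (set(self.p1_residues) | set(self.exceptions)) - STANDARD_AA
        if bad:
            raise ValueError(f"{self.name}: non-standard residues {sorted(bad)}")


TRYPSIN = ProteaseRule("trypsin", frozenset("KR"))
CHYMOTRYPSIN = ProteaseRule("chymotrypsin", frozenset("YWFLM"))
V8 = ProteaseRule("v8", frozenset("DE"))

BUILTIN_PROTEASES: dict[str, ProteaseRule] = {
    r.name: r for r in (TRYPSIN, CHYMOTRYPSIN, V8)
}


@dataclass(frozen=True)
class CleavageSite:
    """A cleavable peptide bond, named by its P1 residue number.

    The bond cut lies between ``position`` and ``position + 1``.
    """

    position: int
    protease: str


@dataclass(frozen=True)
class Fragment:
    """A contiguous stretch ``start..end`` (inclusive residue numbers).

    ``boundary_sites`` holds the 0–2 internal cleavage-site positions that
    delimit it (a chain terminus is not a site).
    """

    start: int
    end: int
    mass: float
    boundary_sites: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"fragment start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def cleavage_sites(seq: ProteinSequence, rule: ProteaseRule) -> list[CleavageSite]:
    """All cleavage sites of ``rule`` in ``seq``, sorted by position.

    Every P1 residue except the C-terminal one yields a site (cutting after
    the last residue releases nothing), unless the following residue is in
    the rule's exception set.
    """
    sites = []
    for i, aa in enumerate(seq.residues[:-1]):
        if aa in rule.p1_residues and seq.residues[i + 1] not in rule.exceptions:
            sites.append(CleavageSite(seq.numbering_offset + i, rule.name))
    return sites


def _boundaries(seq: ProteinSequence, sites: Sequence[CleavageSite]) -> list[int]:
    # A boundary is the residue number after which the chain is (or may be)
    # severed: the virtual bond before residue 1 plus each site, plus the end.
    positions = sorted({s.position for s in sites})
    if positions and (
        positions[0] < seq.first_residue or positions[-1] >= seq.last_residue
    ):
        raise ValueError("cleavage site outside sequence")
    return [seq.first_residue - 1] + positions + [seq.last_residue]


def enumerate_fragments(
    seq: ProteinSequence,
    sites: Sequence[CleavageSite],
    mode: str = "mono",
) -> list[Fragment]:
    """Every fragment delimited by a pair of distinct boundaries.

    With *b* boundaries (N-terminus, each site, C-terminus) there are
    exactly C(b, 2) fragments, including the intact chain — the species mix
    a partial digest can produce.
    """
    bounds = _boundaries(seq, sites)
    site_set = {s.position for s in sites}
    frags = []
    for i, left in enumerate(bounds):
        for right in bounds[i + 1 :]:
            start, end = left + 1, right
            internal = tuple(p for p in (left, right) if p in site_set)
            frags.append(
                Fragment(
                    start,
                    end,
                    mass=_sequence_mass(seq.subsequence(start, end), mode),
                    boundary_sites=internal,
                )
            )
    return frags


def _sequence_mass(residues: str, mode: str) -> float:
    if not residues:
        raise ValueError("empty fragment")
    if mode not in ("mono", "average"):
        raise ValueError(f"unknown mass mode {mode!r}")
    return _pmass.calculate_mass(sequence=residues, average=(mode == "average"))


def fragment_mass(frag: Fragment, seq: ProteinSequence, mode: str = "mono") -> float:
    """Neutral peptide mass of ``frag`` in Da: residue masses plus one water."""
    return _sequence_mass(seq.subsequence(frag.start, frag.end), mode)


def multi_protease_coverage(
    seq: ProteinSequence, rules: Iterable[ProteaseRule]
) -> float:
    """Fraction of residues cleavable by at least one protease in ``rules``.

    Limited proteolysis only reports on residues a protease can cut, so this
    is the upper bound on the footprinting coverage of the sequence; it is
    monotone non-decreasing as proteases are added.
    """
    rules = list(rules)
    if not rules:
        raise ValueError("at least one protease rule required")
    p1_union: set[str] = set()
    for r in rules:
        p1_union |= r.p1_residues
    n = sum(1 for aa in seq.residues if aa in p1_union)
    return n / len(seq.residues)


def read_fasta(path, numbering_offset: int = 1) -> list[ProteinSequence]:
    """Read protein sequences from a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceFormatError(f"{path}: no FASTA records")
    return [
        ProteinSequence(rec.id, str(rec.seq).upper(), numbering_offset)
        for rec in records
    ]


def digest(
    seq: ProteinSequence, rule: ProteaseRule, mode: str = "mono"
) -> list[Fragment]:
    """Convenience: cleavage-site detection plus fragment enumeration."""
    return enumerate_fragments(seq, cleavage_sites(seq, rule), mode=mode)


def digest_report(
    seq: ProteinSequence, rule: ProteaseRule, mode: str = "mono"
) -> pd.DataFrame:
    """Tabular digest: one row per fragment (start, end, sequence, mass, sites)."""
    frags = digest(seq, rule, mode=mode)
    return pd.DataFrame(
        {
            "start": [f.start for f in frags],
            "end": [f.end for f in frags],
            "sequence": [seq.subsequence(f.start, f.end) for f in frags],
            "mass": [f.mass for f in frags],
            "boundary_sites": [
                ",".join(map(str, f.boundary_sites)) for f in frags
            ],
        }
    ).sort_values(["start", "end"], ignore_index=True)
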