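"""In-silico tryptic digestion of crosslinkable proteins.

Trypsin cleaves C-terminal to lysine and arginine unless the next residue
is proline.  Because the crosslinking chemistry reacts with lysine side
chains *before* digestion, a crosslinker-modified lysine cannot be cleaved,
so crosslink enumeration always works on peptides carrying missed
cleavages; peptides are therefore generated for every missed-cleavage
count up to a configurable maximum (default 3).

Residue numbering is 1-based from the first residue of the sequence as
given.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .chem import DEFAULT_TABLE, MassTable, STANDARD_RESIDUES


class LabelState(enum.Enum):
    """Metabolic nitrogen labeling state of a protein pool."""

    N14 = "14N"
    N15 = "15N"


@dataclass(frozen=True)
class ProteinEntry:
    """A named amino-acid sequence, the source of tryptic peptides."""

    id: str
    sequence: str
    label_state: LabelState = LabelState.N14

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.id!r}: non-standard residue {sorted(bad)[0]!r}"
            )


@dataclass(frozen=True)
class Peptide:
    """A tryptic digestion product with 1-based protein coordinates."""

    protein_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int
    oxidized_met_positions: frozenset[int] = frozenset()
    is_protein_nterm: bool = False

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def span_label(self) -> str:
        return f"{self.sequence}[{self.start}-{self.end}]"


class SiteKind(enum.Enum):
    PROTEIN_NTERM = "protein_nterm"
    LYSINE = "lysine"


@dataclass(frozen=True, order=True)
class Site:
    """A crosslinkable primary amine, identified by protein residue index."""

    protein_id: str
    residue_index: int
    kind: SiteKind = SiteKind.LYSINE

    @property
    def label(self) -> str:
        prefix = "Nterm" if self.kind is SiteKind.PROTEIN_NTERM else "K"
        return f"{self.protein_id}:{prefix}{self.residue_index}"


def read_fasta(path: str | Path) -> list[ProteinEntry]:
    """Read protein entries from a FASTA file.

    Record ids are the header up to the first whitespace; sequences are
    upper-cased.  Raises ``ValueError`` for an empty file or for records
    containing non-standard residues (naming record and character).
    """
    entries: list[ProteinEntry] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - STANDARD_RESIDUES
        if bad:
            raise ValueError(
                f"record {record.id!r}: non-standard residue {sorted(bad)[0]!r}"
            )
        entries.append(ProteinEntry(id=record.id, sequence=seq))
    if not entries:
        raise ValueError(f"no sequences in {path}")
    return entries


def cleavage_positions(sequence: str) -> list[int]:
    """0-based positions i such that trypsin cuts between i and i+1."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    protein: ProteinEntry,
    max_missed_cleavages: int = 3,
    met_oxidation: bool = False,
) -> list[Peptide]:
    """All tryptic peptides with up to ``max_missed_cleavages`` missed cuts.

    With ``met_oxidation`` every combination of oxidized methionines is
    emitted as an additional peptide variant.  Output is ordered by
    (start, end, oxidation pattern) and is deterministic.
    """
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    seq = protein.sequence
    bounds = [0] + [i + 1 for i in cleavage_positions(seq)] + [len(seq)]
    peptides: list[Peptide] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed_cleavages, len(bounds))):
            start, end = bounds[i], bounds[j]
            base = Peptide(
                protein_id=protein.id,
                start=start + 1,
                end=end,
                sequence=seq[start:end],
                missed_cleavages=j - i - 1,
                is_protein_nterm=start == 0,
            )
            peptides.append(base)
            if met_oxidation:
                met_pos = [
                    start + 1 + k for k, aa in enumerate(base.sequence) if aa == "M"
                ]
                for r in range(1, len(met_pos) + 1):
                    for combo in combinations(met_pos, r):
                        peptides.append(
                            Peptide(
                                protein_id=base.protein_id,
                                start=base.start,
                                end=base.end,
                                sequence=base.sequence,
                                missed_cleavages=base.missed_cleavages,
                                oxidized_met_positions=frozenset(combo),
                                is_protein_nterm=base.is_protein_nterm,
                            )
                        )
    peptides.sort(key=lambda p: (p.start, p.end, sorted(p.oxidized_met_positions)))
    return peptides


def digest_all(
    proteins: Iterable[ProteinEntry],
    max_missed_cleavages: int = 3,
    met_oxidation: bool = False,
) -> list[Peptide]:
    out: list[Peptide] = []
    for protein in proteins:
        out.extend(digest(protein, max_missed_cleavages, met_oxidation))
    return out


def peptide_mass(p: Peptide, table: MassTable = DEFAULT_TABLE) -> float:
    """Neutral monoisotopic mass including any methionine oxidations."""
    if not p.sequence:
        raise ValueError("empty peptide")
    return table.mass_of_sequence(p.sequence) + table.met_oxidation_delta * len(
        p.oxidized_met_positions
    )


def count_nitrogens(p: Peptide, table: MassTable = DEFAULT_TABLE) -> int:
    """Total nitrogen atoms in the peptide (backbone + side chains)."""
    return table.nitrogens_of_sequence(p.sequence)


def crosslinkable_sites(p: Peptide) -> list[Site]:
    """Primary amines on this peptide that the linker can have reacted with.

    The protein N-terminal alpha-amine (only on the N-terminal peptide) and
    every lysine side chain except a lysine at the peptide C-terminus: a
    C-terminal lysine was cleaved by trypsin, hence was unmodified.
    Peptide-internal alpha-amines do not exist at the protein stage and are
    never sites.
    """
    sites: list[Site] = []
    if p.is_protein_nterm:
        sites.append(Site(p.protein_id, 1, SiteKind.PROTEIN_NTERM))
    for k, aa in enumerate(p.sequence):
        idx = p.start + k
        if aa == "K" and idx != p.end:
            sites.append(Site(p.protein_id, idx, SiteKind.LYSINE))
    return sites
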