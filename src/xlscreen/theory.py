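"""Enumeration of the theoretical crosslink mass space.

Species nomenclature follows the common type-0/1/2 classification:

* type 0 (dead-end): one linker end on an amine, the other hydrolyzed
  (or, optionally, quenched by Tris);
* type 1 (intra-peptide loop): both ends on amines within one peptide;
* type 2 (inter-peptide): the linker bridges two peptides — the
  structurally informative class.

For an amine-reactive homobifunctional linker supplied as a 1:1 mixture of
light (H12) and deuterated heavy (D12) forms, every species appears in MS
as an isotope doublet separated by a fixed spacing.  The number of type-2
species grows quadratically with the number of crosslinkable sites, which
is why downstream screening needs the doublet and intensity filters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .chem import DEFAULT_TABLE, MassTable
from .digestion import Peptide, ProteinEntry, Site, crosslinkable_sites, digest_all, peptide_mass

# BS3 linker arithmetic, monoisotopic:
#   bridging residue C8H10O2 once both NHS esters have reacted
#   dead-end: bridge + H2O (hydrolyzed second ester)
#   Tris-quenched dead-end: bridge + Tris (C4H11NO3)
_BS3_BRIDGE = 138.0680795
_BS3_DEADEND = _BS3_BRIDGE + 18.0105647
_BS3_TRIS = _BS3_BRIDGE + 121.0738932


@dataclass(frozen=True)
class CrosslinkerSpec:
    """Mass deltas of an isotope-coded amine-reactive crosslinker."""

    name: str
    interpeptide_delta: float
    deadend_delta: float
    isotope_spacing: float
    tris_deadend_delta: float | None = None


#: BS3 (bis(sulfosuccinimidyl)suberate), H12/D12 pair.  The heavy-light
#: spacing is the fixed doublet-filter constant 12.0757 Da.
BS3 = CrosslinkerSpec(
    name="BS3",
    interpeptide_delta=_BS3_BRIDGE,
    deadend_delta=_BS3_DEADEND,
    isotope_spacing=12.0757,
    tris_deadend_delta=_BS3_TRIS,
)

XTYPE_DEADEND = "type0"
XTYPE_LOOP = "type1"
XTYPE_INTER = "type2"


@dataclass(frozen=True)
class CandidateSpecies:
    """One theoretical crosslink product with light/heavy MH+ masses."""

    xtype: str
    peptides: tuple[Peptide, ...]
    sites: tuple[Site, ...]
    neutral_mass: float
    mh_light: float
    mh_heavy: float
    extra_deadends: int = 0
    #: for type0 only: dead-end quenched by Tris instead of water
    tris_quenched: bool = False

    @property
    def label(self) -> str:
        peps = "--".join(p.span_label for p in self.peptides)
        sites = "/".join(s.label for s in self.sites)
        extra = f"+{self.extra_deadends}DE" if self.extra_deadends else ""
        return f"{self.xtype} {peps} {sites}{extra}"


def _species(
    xtype: str,
    peptides: tuple[Peptide, ...],
    sites: tuple[Site, ...],
    neutral: float,
    linker: CrosslinkerSpec,
    table: MassTable,
    extra_deadends: int = 0,
    tris_quenched: bool = False,
) -> CandidateSpecies:
    mh_light = neutral + table.proton_mass
    # doublet spacing of a single isotope-coded linker; species carrying an
    # extra dead-end hold two linkers but are still reported at the
    # single-linker spacing and flagged via extra_deadends
    return CandidateSpecies(
        xtype=xtype,
        peptides=peptides,
        sites=sites,
        neutral_mass=neutral,
        mh_light=mh_light,
        mh_heavy=mh_light + linker.isotope_spacing,
        extra_deadends=extra_deadends,
        tris_quenched=tris_quenched,
    )


def _assignments(peptides: Iterable[Peptide]) -> list[tuple[Peptide, Site]]:
    return [(p, s) for p in peptides for s in crosslinkable_sites(p)]


def enumerate_type0(
    peptides: Sequence[Peptide],
    linker: CrosslinkerSpec = BS3,
    table: MassTable = DEFAULT_TABLE,
    include_tris: bool = False,
) -> list[CandidateSpecies]:
    """One dead-end candidate per (peptide, crosslinkable site) pair."""
    out = []
    for pep, site in _assignments(peptides):
        base = peptide_mass(pep, table)
        out.append(
            _species(XTYPE_DEADEND, (pep,), (site,), base + linker.deadend_delta, linker, table)
        )
        if include_tris and linker.tris_deadend_delta is not None:
            out.append(
                _species(
                    XTYPE_DEADEND, (pep,), (site,),
                    base + linker.tris_deadend_delta, linker, table,
                    tris_quenched=True,
                )
            )
    return out


def enumerate_type1(
    peptides: Sequence[Peptide],
    linker: CrosslinkerSpec = BS3,
    table: MassTable = DEFAULT_TABLE,
) -> list[CandidateSpecies]:
    """One loop-link candidate per unordered pair of sites in one peptide."""
    out = []
    for pep in peptides:
        sites = crosslinkable_sites(pep)
        for i in range(len(sites)):
            for j in range(i + 1, len(sites)):
                out.append(
                    _species(
                        XTYPE_LOOP, (pep,), (sites[i], sites[j]),
                        peptide_mass(pep, table) + linker.interpeptide_delta,
                        linker, table,
                    )
                )
    return out


def enumerate_type2(
    peptides: Sequence[Peptide],
    linker: CrosslinkerSpec = BS3,
    table: MassTable = DEFAULT_TABLE,
) -> list[CandidateSpecies]:
    """Inter-peptide candidates over unordered pairs of (peptide, site).

    A peptide may pair with a second copy of itself (homomeric crosslink);
    with multi-protein input, pairs span proteins, so inter-subunit
    crosslinks are enumerated alongside intra-subunit ones.
    """
    assignments = _assignments(peptides)
    out = []
    for i in range(len(assignments)):
        pep_a, site_a = assignments[i]
        mass_a = peptide_mass(pep_a, table)
        for j in range(i, len(assignments)):
            # i == j models two copies of the same peptide bridged via the
            # equivalent site on each copy (homomeric crosslink)
            pep_b, site_b = assignments[j]
            out.append(
                _species(
                    XTYPE_INTER, (pep_a, pep_b), (site_a, site_b),
                    mass_a + peptide_mass(pep_b, table) + linker.interpeptide_delta,
                    linker, table,
                )
            )
    return out


def with_extra_deadend(
    candidates: Sequence[CandidateSpecies],
    linker: CrosslinkerSpec = BS3,
) -> list[CandidateSpecies]:
    """Variants of candidates carrying one extra dead-end linker.

    Only emitted for species with at least one crosslinkable site left
    unused by the link itself.  At most one extra dead-end per species.
    """
    out = []
    for c in candidates:
        free = {
            s for p in set(c.peptides) for s in crosslinkable_sites(p)
        } - set(c.sites)
        if free:
            out.append(
                replace(
                    c,
                    neutral_mass=c.neutral_mass + linker.deadend_delta,
                    mh_light=c.mh_light + linker.deadend_delta,
                    mh_heavy=c.mh_heavy + linker.deadend_delta,
                    extra_deadends=1,
                )
            )
    return out


def filter_mass_window(
    candidates: Sequence[CandidateSpecies], low: float, high: float
) -> list[CandidateSpecies]:
    """Retain candidates whose light MH+ lies in [low, high], order kept."""
    if not low < high:
        raise ValueError("mass window requires low < high")
    return [c for c in candidates if low <= c.mh_light <= high]


def enumerate_candidates(
    proteins: Sequence[ProteinEntry],
    linker: CrosslinkerSpec = BS3,
    table: MassTable = DEFAULT_TABLE,
    max_missed_cleavages: int = 3,
    met_oxidation: bool = False,
    extra_deadend: bool = False,
    include_tris: bool = False,
    mass_window: tuple[float, float] | None = (600.0, 5000.0),
) -> list[CandidateSpecies]:
    """Full theoretical list: type 0 + 1 + 2 for a set of proteins."""
    peptides = digest_all(proteins, max_missed_cleavages, met_oxidation)
    candidates = (
        enumerate_type0(peptides, linker, table, include_tris)
        + enumerate_type1(peptides, linker, table)
        + enumerate_type2(peptides, linker, table)
    )
    if extra_deadend:
        candidates = candidates + with_extra_deadend(candidates, linker)
    if mass_window is not None:
        candidates = filter_mass_window(candidates, *mass_window)
    return candidates


def candidates_to_frame(candidates: Sequence[CandidateSpecies]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        row = {
            "xtype": c.xtype,
            "protein_a": c.peptides[0].protein_id,
            "seq_a": c.peptides[0].sequence,
            "start_a": c.peptides[0].start,
            "end_a": c.peptides[0].end,
            "site_a": c.sites[0].label,
            "protein_b": c.peptides[1].protein_id if len(c.peptides) > 1 else "",
            "seq_b": c.peptides[1].sequence if len(c.peptides) > 1 else "",
            "start_b": c.peptides[1].start if len(c.peptides) > 1 else 0,
            "end_b": c.peptides[1].end if len(c.peptides) > 1 else 0,
            "site_b": c.sites[1].label if len(c.sites) > 1 else "",
            "extra_deadends": c.extra_deadends,
            "mh_light": round(c.mh_light, 4),
            "mh_heavy": round(c.mh_heavy, 4),
        }
        rows.append(row)
    return pd.DataFrame(rows)


def write_candidates_tsv(candidates: Sequence[CandidateSpecies], path: str | Path) -> None:
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False)
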