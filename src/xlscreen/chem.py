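"""Monoisotopic mass bookkeeping for peptides.

All masses are monoisotopic and in daltons.  The residue table covers the
20 standard amino acids; nonstandard/ambiguity codes (B, J, O, U, X, Z) are
rejected at parse time rather than approximated, because a wrong residue
mass silently shifts every downstream crosslink mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

# IUPAC monoisotopic residue (i.e. dehydrated) masses, Da.
_RESIDUE_MASSES: Mapping[str, float] = MappingProxyType({
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
})

# Nitrogen atoms per residue (backbone amide N plus side-chain N).
_RESIDUE_NITROGENS: Mapping[str, int] = MappingProxyType({
    **{aa: 1 for aa in _RESIDUE_MASSES},
    "K": 2, "R": 4, "N": 2, "Q": 2, "H": 3, "W": 2,
})

STANDARD_RESIDUES = frozenset(_RESIDUE_MASSES)

WATER = 18.0105646863
PROTON = 1.0072764666
MET_OXIDATION = 15.9949146221
#: mass gain per nitrogen upon full 15N labeling (15N minus 14N), Da
N15_DELTA = 0.99703


@dataclass(frozen=True)
class MassTable:
    """Residue-level mass and composition constants.

    A single default instance (:data:`DEFAULT_TABLE`) serves almost every
    use; the type exists so alternative constant sets (e.g. recalibrated
    residue masses) can be threaded through without touching call sites.
    """

    residue_masses: Mapping[str, float] = field(default_factory=lambda: _RESIDUE_MASSES)
    residue_nitrogens: Mapping[str, int] = field(default_factory=lambda: _RESIDUE_NITROGENS)
    water_mass: float = WATER
    proton_mass: float = PROTON
    met_oxidation_delta: float = MET_OXIDATION

    def mass_of_sequence(self, sequence: str) -> float:
        """Neutral monoisotopic mass of an unmodified linear peptide."""
        try:
            return sum(self.residue_masses[aa] for aa in sequence) + self.water_mass
        except KeyError as exc:  # pragma: no cover - message detail only
            raise ValueError(f"unknown residue {exc.args[0]!r} in {sequence!r}") from None

    def nitrogens_of_sequence(self, sequence: str) -> int:
        try:
            return sum(self.residue_nitrogens[aa] for aa in sequence)
        except KeyError as exc:
            raise ValueError(f"unknown residue {exc.args[0]!r} in {sequence!r}") from None


DEFAULT_TABLE = MassTable()
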