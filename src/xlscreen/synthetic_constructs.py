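"""Synthetic test proteins.

:data:`SYNTHETIC_SHSP_CONSTRUCT` is a 184-residue stand-in for an
oligomeric small heat-shock protein construct used in crosslinking method
development.  Residues 1-32, 84-136 and 154-184 are real, reconstructed
from overlapping published tryptic peptides of that construct; the two
remaining stretches (33-83 and 137-153) are SYNTHETIC filler composed of
lysine-free G/S/A spacer segments terminated by arginine, so they digest
into inert peptides and contribute no crosslinkable sites.  The construct
therefore reproduces the published crosslinkable peptides and crosslink
masses exactly while remaining a fabricated sequence overall.

:data:`CLP_PROTEASE_PEPTIDES` carries the two published peptides of an
inter-subunit crosslink in a multisubunit AAA+ protease (proteolytic-core
subunits of the Clp protease), at their published residue coordinates; the
surrounding subunit sequences are not included.
"""

from __future__ import annotations

from .digestion import Peptide, ProteinEntry

_SEGMENT_1_32 = "MQDQR" "ENSIDVVQQGQQKGNQGSSVEK" "RPQQR"
_FILLER_33_83 = "GSAGSAGSR" * 5 + "GSAGSR"  # synthetic, 51 residues, no K
_SEGMENT_84_136 = "APWDIKEEEHEIK" "MR" "FDMPGLSKEDVK" "ISVEDNVLVIKGEQK" "KEDSDDSWSGR"
_FILLER_137_153 = "GSAGSAGSRGSAGSAGR"  # synthetic, 17 residues, no K
_SEGMENT_154_184 = "DKIK" "AELKNGVLFITIPK" "TKVER" "KVIDVQIQ"

SYNTHETIC_SHSP_SEQUENCE = (
    _SEGMENT_1_32 + _FILLER_33_83 + _SEGMENT_84_136 + _FILLER_137_153 + _SEGMENT_154_184
)
assert len(SYNTHETIC_SHSP_SEQUENCE) == 184

#: synthetic small heat-shock protein construct (see module docstring)
SYNTHETIC_SHSP_CONSTRUCT = ProteinEntry(id="sHSP_synthetic", sequence=SYNTHETIC_SHSP_SEQUENCE)


def clp_protease_peptides() -> tuple[Peptide, Peptide]:
    """The published peptide pair of the inter-subunit Clp-core crosslink.

    Returns the proteolytic-subunit peptide IEKDTDR (residues 169-175,
    linked via K171) and the partner-subunit peptide AKEVLANK (residues
    164-171, linked via K165).
    """
    pep_p = Peptide("ClpP3", 169, 175, "IEKDTDR", 1)
    pep_r = Peptide("ClpR", 164, 171, "AKEVLANK", 1)
    return pep_p, pep_r
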