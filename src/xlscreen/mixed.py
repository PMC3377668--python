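"""Intra- vs inter-monomeric classification by 14N/15N mixed labeling.

Crosslinking a 1:1 mixture of unlabeled and fully 15N-labeled oligomers
(after subunit exchange) with a *non*-isotope-coded linker makes the
quaternary origin of an inter-peptide crosslink readable from the MS
pattern: a crosslink formed within one monomer can only combine
like-labeled peptides (two peaks, 14N-14N and 15N-15N, about 1:1), while a
crosslink between monomers also produces the mixed 14N-15N and 15N-14N
combinations (four peaks).  Each 15N combination mass follows from the
peptide's nitrogen-atom count times the 15N-14N mass difference.

When the two peptides contain equal nitrogen numbers the two mixed forms
coincide, so an inter-monomeric crosslink shows three mass positions with
the middle one carrying the summed intensity of both mixed species; the
classifier handles that case with an explicit ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .chem import DEFAULT_TABLE, MassTable, N15_DELTA
from .digestion import Peptide, count_nitrogens
from .screen import PeakList, intensity_parameter
from .theory import CandidateSpecies, XTYPE_INTER

VERDICT_INTRA = "intra"
VERDICT_INTER = "inter"
VERDICT_UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class MixedIsotopePattern:
    """The up to four combination masses of a type-2 crosslink."""

    crosslink: CandidateSpecies
    n_a: int
    n_b: int
    mass_aa: float  # 14N-14N
    mass_ab: float  # 14N(pepA)-15N(pepB)
    mass_ba: float  # 15N(pepA)-14N(pepB)
    mass_bb: float  # 15N-15N
    verdict: str = VERDICT_UNDETERMINED
    observed: tuple = ()

    @property
    def equal_nitrogens(self) -> bool:
        return self.n_a == self.n_b


def n15_shift(p: Peptide, table: MassTable = DEFAULT_TABLE) -> float:
    """Mass gain of a peptide upon full 15N labeling (Da)."""
    return count_nitrogens(p, table) * N15_DELTA


def combination_masses(
    c: CandidateSpecies, table: MassTable = DEFAULT_TABLE
) -> MixedIsotopePattern:
    """The four 14N/15N combination MH+ values of a type-2 crosslink.

    Masses are computed with the light linker only (mixed-isotope
    experiments use the non-coded crosslinker).  Raises ``ValueError``
    for type 0/1 input.
    """
    if c.xtype != XTYPE_INTER:
        raise ValueError("mixed-isotope analysis requires a type 2 crosslink")
    pep_a, pep_b = c.peptides
    shift_a = n15_shift(pep_a, table)
    shift_b = n15_shift(pep_b, table)
    aa = c.mh_light
    return MixedIsotopePattern(
        crosslink=c,
        n_a=count_nitrogens(pep_a, table),
        n_b=count_nitrogens(pep_b, table),
        mass_aa=aa,
        mass_ab=aa + shift_b,
        mass_ba=aa + shift_a,
        mass_bb=aa + shift_a + shift_b,
    )


def swap_labels(pattern: MixedIsotopePattern) -> MixedIsotopePattern:
    """Pattern with the 15N-labeled pool swapped (AB and BA exchange)."""
    return replace(pattern, mass_ab=pattern.mass_ba, mass_ba=pattern.mass_ab)


def _peak_intensity(peaks: PeakList, mz: float, tol_ppm: float) -> float | None:
    window = tol_ppm * 1e-6 * mz
    lo = np.searchsorted(peaks.mz, mz - window, side="left")
    hi = np.searchsorted(peaks.mz, mz + window, side="right")
    if hi == lo:
        return None
    return float(peaks.intensity[lo:hi].max())


def classify_pattern(
    pattern: MixedIsotopePattern,
    peaks: PeakList,
    tol_ppm: float = 50.0,
    intensity_balance: float = 0.22,
) -> MixedIsotopePattern:
    """Assign an intra/inter/undetermined verdict from observed peaks.

    Rules: both outer peaks (14N-14N and 15N-15N) present near 1:1 with no
    mixed forms -> intra; all four combinations present -> inter, even
    with unbalanced 1:x mixed intensities, because a partially exchanged
    oligomer population still implies genuinely inter-monomeric links;
    any other partial pattern -> undetermined.  ``intensity_balance``
    bounds the allowed 14N-14N vs 15N-15N imbalance for the intra call
    (same dimensionless parameter as the doublet intensity filter).
    """
    i_aa = _peak_intensity(peaks, pattern.mass_aa, tol_ppm)
    i_bb = _peak_intensity(peaks, pattern.mass_bb, tol_ppm)

    if pattern.equal_nitrogens:
        i_mid = _peak_intensity(peaks, pattern.mass_ab, tol_ppm)
        observed = (
            ("AA", pattern.mass_aa, i_aa),
            ("AB/BA", pattern.mass_ab, i_mid),
            ("BB", pattern.mass_bb, i_bb),
        )
        if i_aa is None or i_bb is None:
            verdict = VERDICT_UNDETERMINED
        elif i_mid is None:
            verdict = (
                VERDICT_INTRA
                if intensity_parameter(i_aa, i_bb) <= intensity_balance
                else VERDICT_UNDETERMINED
            )
        else:
            # coincident mixed forms: the middle peak must be consistent
            # with the *sum* of the two mixed species
            verdict = (
                VERDICT_INTER
                if intensity_parameter(i_mid, i_aa + i_bb) <= 2 * intensity_balance
                else VERDICT_UNDETERMINED
            )
        return replace(pattern, verdict=verdict, observed=observed)

    i_ab = _peak_intensity(peaks, pattern.mass_ab, tol_ppm)
    i_ba = _peak_intensity(peaks, pattern.mass_ba, tol_ppm)
    observed = (
        ("AA", pattern.mass_aa, i_aa),
        ("AB", pattern.mass_ab, i_ab),
        ("BA", pattern.mass_ba, i_ba),
        ("BB", pattern.mass_bb, i_bb),
    )
    if i_aa is not None and i_bb is not None and i_ab is not None and i_ba is not None:
        verdict = VERDICT_INTER
    elif i_aa is not None and i_bb is not None and i_ab is None and i_ba is None:
        verdict = (
            VERDICT_INTRA
            if intensity_parameter(i_aa, i_bb) <= intensity_balance
            else VERDICT_UNDETERMINED
        )
    else:
        verdict = VERDICT_UNDETERMINED
    return replace(pattern, verdict=verdict, observed=observed)
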