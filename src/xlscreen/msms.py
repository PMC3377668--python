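"""MSMS-mode validation of crosslink candidates from fragment spectra.

MALDI-TOF/TOF fragment spectra are dominated by singly charged b/y ions,
so that is the fragment model used: for each constituent peptide all
b1..b(n-1) and y1..y(n-1) ions.  A fragment whose residue span covers the
crosslinked site keeps the linker — and, for an inter-peptide crosslink,
the entire (unfragmented) partner peptide — attached, and therefore shows
up as a light/heavy doublet separated by the exact linker spacing.  These
crosslinker-containing doublet fragments are the decisive evidence that a
precursor really is a crosslinked peptide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from pyteomics import mgf as pymgf

from .chem import DEFAULT_TABLE, MassTable
from .digestion import Peptide, SiteKind
from .theory import BS3, CandidateSpecies, CrosslinkerSpec, XTYPE_DEADEND, XTYPE_INTER, XTYPE_LOOP


@dataclass
class MsmsSpectrum:
    """One MSMS spectrum (precursor MH+ and fragment peaks)."""

    title: str
    precursor_mh: float
    fragment_mz: np.ndarray
    fragment_intensity: np.ndarray
    fraction_index: int | None = None

    def __post_init__(self) -> None:
        self.fragment_mz = np.asarray(self.fragment_mz, dtype=float)
        self.fragment_intensity = np.asarray(self.fragment_intensity, dtype=float)
        order = np.argsort(self.fragment_mz, kind="stable")
        self.fragment_mz = self.fragment_mz[order]
        self.fragment_intensity = self.fragment_intensity[order]


@dataclass(frozen=True)
class FragmentIon:
    """A theoretical singly protonated b or y ion of one candidate."""

    source_peptide: str  # "A" or "B"
    series: str  # "b" or "y"
    index: int
    carries_crosslinker: bool
    mz_light: float
    mz_heavy: float | None = None

    @property
    def label(self) -> str:
        suffix = "x" if self.carries_crosslinker else ""
        return f"{self.series}{self.index}{self.source_peptide}{suffix}"


@dataclass
class FragmentAssignment:
    fragment: FragmentIon
    isotope_form: str  # "light" or "heavy"
    observed_mz: float
    error_da: float


@dataclass
class ValidationReport:
    """Fragment-matching evidence for one candidate against one spectrum."""

    candidate: CandidateSpecies
    spectrum_title: str
    total_theoretical: int
    matched_fragments: int
    matched_doublets: int
    assignments: list[FragmentAssignment] = field(default_factory=list)
    min_fragments: int = 4
    min_doublets: int = 1

    @property
    def validated(self) -> bool:
        return (
            self.matched_fragments >= self.min_fragments
            and self.matched_doublets >= self.min_doublets
        )


def _parse_fraction(title: str) -> int | None:
    import re

    m = re.search(r"(?:frac(?:tion)?|well)[_ ]?0*(\d+)", title, flags=re.IGNORECASE)
    return int(m.group(1)) if m else None


def read_mgf(path: str | Path) -> list[MsmsSpectrum]:
    """Parse one MGF file into spectra (precursor stored as MH+)."""
    spectra: list[MsmsSpectrum] = []
    try:
        with pymgf.read(str(path), use_index=False) as reader:
            for block, entry in enumerate(reader, start=1):
                params = entry.get("params", {})
                if "pepmass" not in params:
                    raise ValueError(f"{path}: block {block}: missing PEPMASS")
                title = str(params.get("title", f"spectrum_{block}"))
                spectra.append(
                    MsmsSpectrum(
                        title=title,
                        precursor_mh=float(params["pepmass"][0]),
                        fragment_mz=entry["m/z array"],
                        fragment_intensity=entry["intensity array"],
                        fraction_index=_parse_fraction(title),
                    )
                )
    except ValueError:
        raise
    except Exception as exc:
        raise ValueError(f"{path}: malformed MGF ({exc})") from exc
    return spectra


def write_mgf(spectra: Sequence[MsmsSpectrum], path: str | Path) -> None:
    entries = [
        {
            "m/z array": s.fragment_mz,
            "intensity array": s.fragment_intensity,
            "params": {"title": s.title, "pepmass": (round(s.precursor_mh, 5),)},
        }
        for s in spectra
    ]
    pymgf.write(entries, str(path), file_mode="w")


def merge_mgf(
    paths: Sequence[str | Path], out_path: str | Path | None = None
) -> list[MsmsSpectrum]:
    """Concatenate MGF files (e.g. one per LC fraction) into one spectrum
    list, optionally writing the merged MGF; input order is preserved."""
    if not paths:
        raise ValueError("no input MGF files")
    spectra: list[MsmsSpectrum] = []
    for path in paths:
        spectra.extend(read_mgf(path))
    if out_path is not None:
        write_mgf(spectra, out_path)
    return spectra


def match_precursor(
    spec: MsmsSpectrum,
    candidates: Sequence[CandidateSpecies],
    tol_ppm: float = 50.0,
) -> list[CandidateSpecies]:
    """Candidates whose light *or* heavy MH+ matches the precursor.

    Both forms are checked because the instrument's timed ion selector
    window is wide enough to co-select and fragment both doublet members.
    """
    out = []
    for c in candidates:
        for mh in (c.mh_light, c.mh_heavy):
            if abs(spec.precursor_mh - mh) <= tol_ppm * 1e-6 * mh:
                out.append(c)
                break
    return out


def _site_positions(pep: Peptide, c: CandidateSpecies) -> list[int]:
    """0-based positions within pep of the candidate sites it carries."""
    positions = []
    for site in c.sites:
        if site.protein_id != pep.protein_id:
            continue
        if site.kind is SiteKind.PROTEIN_NTERM:
            if pep.is_protein_nterm:
                positions.append(0)
        elif pep.start <= site.residue_index <= pep.end:
            positions.append(site.residue_index - pep.start)
    return positions


def theoretical_fragments(
    c: CandidateSpecies,
    table: MassTable = DEFAULT_TABLE,
    linker: CrosslinkerSpec = BS3,
) -> list[FragmentIon]:
    """Singly charged b/y ions of all constituent peptides.

    A fragment spanning the crosslinked residue gains the linker bridge
    plus the whole partner peptide (inter-peptide), the bridge alone
    (loop-link spanning both sites), or the dead-end delta (type 0), and
    is emitted with both light and heavy m/z.  Loop-link fragments that
    would span exactly one of the two sites cannot exist as plain b/y ions
    (the ring is still closed) and are omitted.
    """
    out: list[FragmentIon] = []
    names = ("A", "B") if len(c.peptides) > 1 else ("A",)
    for pep_idx, pep in enumerate(c.peptides):
        name = names[pep_idx]
        seq = pep.sequence
        n = len(seq)
        sites = _site_positions(pep, c)
        if c.xtype == XTYPE_INTER:
            partner = c.peptides[1 - pep_idx]
            partner_neutral = table.mass_of_sequence(partner.sequence) + (
                table.met_oxidation_delta * len(partner.oxidized_met_positions)
            )
            carrier_delta = linker.interpeptide_delta + partner_neutral
        elif c.xtype == XTYPE_LOOP:
            carrier_delta = linker.interpeptide_delta
        elif c.xtype == XTYPE_DEADEND:
            carrier_delta = (
                linker.tris_deadend_delta if c.tris_quenched else linker.deadend_delta
            )
        else:  # pragma: no cover
            raise ValueError(f"unknown crosslink type {c.xtype}")

        residue = [table.residue_masses[aa] for aa in seq]
        for k, aa in enumerate(seq):
            if pep.start + k in pep.oxidized_met_positions:
                residue[k] += table.met_oxidation_delta
        prefix = np.cumsum(residue)

        for i in range(1, n):
            for series in ("b", "y"):
                if series == "b":
                    span = range(0, i)
                    base = prefix[i - 1] + table.proton_mass
                else:
                    span = range(n - i, n)
                    base = (
                        prefix[n - 1]
                        - (prefix[n - i - 1] if n - i >= 1 else 0.0)
                        + table.water_mass
                        + table.proton_mass
                    )
                covered = sum(1 for s in sites if s in span)
                if c.xtype == XTYPE_LOOP and covered == 1:
                    continue  # ring-opened fragment, not a plain b/y ion
                carries = covered == len(sites) and covered > 0 if c.xtype == XTYPE_LOOP else covered > 0
                mz_light = base + (carrier_delta if carries else 0.0)
                out.append(
                    FragmentIon(
                        source_peptide=name,
                        series=series,
                        index=i,
                        carries_crosslinker=carries,
                        mz_light=mz_light,
                        mz_heavy=mz_light + linker.isotope_spacing if carries else None,
                    )
                )
    return out


def match_fragments(
    spec: MsmsSpectrum,
    fragments: Sequence[FragmentIon],
    frag_tol_da: float = 0.3,
    candidate: CandidateSpecies | None = None,
    min_fragments: int = 4,
    min_doublets: int = 1,
) -> ValidationReport:
    """Greedy nearest-first assignment of observed peaks to theoretical ions.

    Each observed peak is assigned to at most one theoretical ion form and
    vice versa.  The report tallies matched fragments and crosslinker
    doublets (a doublet counts only when both the light and the heavy
    fragment m/z are matched).
    """
    if frag_tol_da <= 0:
        raise ValueError("frag_tol_da must be positive")
    forms: list[tuple[FragmentIon, str, float]] = []
    for f in fragments:
        forms.append((f, "light", f.mz_light))
        if f.mz_heavy is not None:
            forms.append((f, "heavy", f.mz_heavy))

    obs = spec.fragment_mz
    pairs: list[tuple[float, int, int]] = []
    for fi, (_, _, theo_mz) in enumerate(forms):
        lo = np.searchsorted(obs, theo_mz - frag_tol_da, side="left")
        hi = np.searchsorted(obs, theo_mz + frag_tol_da, side="right")
        for oi in range(lo, hi):
            pairs.append((abs(obs[oi] - theo_mz), fi, oi))
    pairs.sort()

    used_forms: set[int] = set()
    used_obs: set[int] = set()
    assignments: list[FragmentAssignment] = []
    matched_forms: dict[int, set[str]] = {}
    for err, fi, oi in pairs:
        if fi in used_forms or oi in used_obs:
            continue
        used_forms.add(fi)
        used_obs.add(oi)
        frag, form, theo_mz = forms[fi]
        assignments.append(
            FragmentAssignment(frag, form, float(obs[oi]), float(obs[oi] - theo_mz))
        )
        matched_forms.setdefault(id(frag), set()).add(form)

    frag_by_id = {id(f): f for f in fragments}
    matched_fragments = len(matched_forms)
    matched_doublets = sum(
        1
        for key, forms_hit in matched_forms.items()
        if frag_by_id[key].carries_crosslinker and {"light", "heavy"} <= forms_hit
    )
    return ValidationReport(
        candidate=candidate,
        spectrum_title=spec.title,
        total_theoretical=len(fragments),
        matched_fragments=matched_fragments,
        matched_doublets=matched_doublets,
        assignments=assignments,
        min_fragments=min_fragments,
        min_doublets=min_doublets,
    )


def validate_spectrum(
    spec: MsmsSpectrum,
    candidates: Sequence[CandidateSpecies],
    table: MassTable = DEFAULT_TABLE,
    linker: CrosslinkerSpec = BS3,
    precursor_tol_ppm: float = 50.0,
    frag_tol_da: float = 0.3,
    min_fragments: int = 4,
    min_doublets: int = 1,
) -> list[ValidationReport]:
    """Match precursor, then fragments, for every candidate hit."""
    reports = []
    for c in match_precursor(spec, candidates, precursor_tol_ppm):
        fragments = theoretical_fragments(c, table, linker)
        reports.append(
            match_fragments(
                spec, fragments, frag_tol_da, c, min_fragments, min_doublets
            )
        )
    return reports
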