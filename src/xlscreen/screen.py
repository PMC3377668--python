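"""MS-mode screening: isotope doublet detection and candidate matching.

Workflow, per LC fraction spotted onto the MALDI target plate:

1. read the centroided peak list (m/z, intensity);
2. keep only peak pairs whose spacing matches the fixed light/heavy
   linker spacing (12.0757 Da for the H12/D12 linker) within 7 ppm,
   20 ppm, or a free tolerance — the spacing of the two co-recorded
   doublet peaks is far more accurate than the absolute calibration,
   which is what makes the fixed-spacing filter so selective;
3. optionally require near-1:1 doublet intensities via the intensity
   parameter |dI| / mean(I), allowing for the heavy form eluting
   slightly earlier than the light form;
4. merge fractions, match surviving doublets to the theoretical
   candidate list, and emit a precursor inclusion list of *light*
   peak masses for targeted MSMS.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .theory import BS3, CandidateSpecies, CrosslinkerSpec

SpacingMode = Literal["fixed7ppm", "fixed20ppm", "free"]

_SPACING_TOL = {"fixed7ppm": 7.0, "fixed20ppm": 20.0}


@dataclass
class PeakList:
    """Centroided peaks of one fraction/well, sorted by m/z."""

    fraction_index: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(self.intensity <= 0):
            raise ValueError("non-positive intensity in peak list")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class IsotopeDoublet:
    """A detected light/heavy peak pair in one fraction."""

    fraction_index: int
    mz_light: float
    mz_heavy: float
    intensity_light: float
    intensity_heavy: float
    spacing_error_ppm: float
    intensity_parameter: float
    cluster_id: int | None = None


@dataclass(frozen=True)
class MatchedCandidate:
    doublet: IsotopeDoublet
    candidate: CandidateSpecies
    precursor_error_ppm: float


def read_peaklists(
    directory: str | Path, pattern: str = "frac{index}.txt"
) -> list[PeakList]:
    """Read one peak-list file per fraction from a directory.

    ``pattern`` is a filename template whose ``{index}`` placeholder
    captures the fraction number.  Files hold one "mz intensity" pair per
    line, whitespace- or comma-separated; a single non-numeric header line
    is tolerated.  Unparseable data lines and duplicate fraction indices
    raise ``ValueError``.
    """
    directory = Path(directory)
    regex = re.compile(
        re.escape(pattern).replace(re.escape("{index}"), r"(\d+)") + r"$"
    )
    out: list[PeakList] = []
    seen: set[int] = set()
    for path in sorted(directory.iterdir()):
        m = regex.match(path.name)
        if not m:
            continue
        index = int(m.group(1))
        if index in seen:
            raise ValueError(f"duplicate fraction index {index} ({path.name})")
        seen.add(index)
        mz, inten = [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                fields = re.split(r"[\s,;]+", line)
                try:
                    a, b = float(fields[0]), float(fields[1])
                except (ValueError, IndexError):
                    if lineno == 1:
                        continue  # header
                    raise ValueError(
                        f"{path.name}:{lineno}: cannot parse line {line!r}"
                    ) from None
                mz.append(a)
                inten.append(b)
        if not mz:
            warnings.warn(f"empty peak list {path.name}", stacklevel=2)
        out.append(PeakList(index, np.array(mz), np.array(inten)))
    if not out:
        raise ValueError(f"no peak-list files matching {pattern!r} in {directory}")
    out.sort(key=lambda pl: pl.fraction_index)
    return out


def intensity_parameter(i1: float, i2: float) -> float:
    """Doublet intensity imbalance: |i1 - i2| divided by their mean.

    0 for a perfect 1:1 doublet; ~0.22 when one peak is 80% of the other;
    0.67 at 50%.  Symmetric in its arguments.
    """
    if i1 <= 0 or i2 <= 0:
        raise ValueError("intensities must be positive")
    return abs(i1 - i2) / ((i1 + i2) / 2.0)


def detect_doublets(
    pl: PeakList,
    linker: CrosslinkerSpec = BS3,
    spacing_mode: SpacingMode = "fixed7ppm",
    search_tolerance_ppm: float = 50.0,
    max_intensity_parameter: float | None = 0.22,
) -> list[IsotopeDoublet]:
    """All light/heavy peak pairs at the linker spacing within tolerance.

    The spacing window is 7 ppm, 20 ppm, or ``search_tolerance_ppm``
    (mode "free"), with ppm computed on the spacing relative to the light
    m/z.  A peak may participate in several doublets (as light member of
    one and heavy member of another); no exclusivity is enforced, the
    theoretical match disambiguates later.  Results are ordered by
    (mz_light, |spacing error|).
    """
    tol_ppm = _SPACING_TOL.get(spacing_mode, search_tolerance_ppm)
    spacing = linker.isotope_spacing
    mz, inten = pl.mz, pl.intensity
    out: list[IsotopeDoublet] = []
    for i in range(len(mz)):
        light = mz[i]
        window = tol_ppm * 1e-6 * light
        lo = np.searchsorted(mz, light + spacing - window, side="left")
        hi = np.searchsorted(mz, light + spacing + window, side="right")
        for j in range(lo, hi):
            if j == i:
                continue
            param = intensity_parameter(inten[i], inten[j])
            if max_intensity_parameter is not None and param > max_intensity_parameter:
                continue
            err_ppm = (mz[j] - light - spacing) / light * 1e6
            out.append(
                IsotopeDoublet(
                    fraction_index=pl.fraction_index,
                    mz_light=light,
                    mz_heavy=mz[j],
                    intensity_light=inten[i],
                    intensity_heavy=inten[j],
                    spacing_error_ppm=err_ppm,
                    intensity_parameter=param,
                )
            )
    out.sort(key=lambda d: (d.mz_light, abs(d.spacing_error_ppm)))
    return out


def merge_doublets(
    per_fraction: Sequence[Sequence[IsotopeDoublet]],
    cluster_tol_ppm: float = 50.0,
) -> list[IsotopeDoublet]:
    """Merge per-fraction doublets into one list with elution clusters.

    Doublets whose light masses agree within ``cluster_tol_ppm`` share a
    cluster id (the same species eluting over consecutive fractions, with
    the heavy form leading); rows are kept separate per fraction.  Output
    is ordered by (fraction, light m/z).
    """
    merged = [d for fraction in per_fraction for d in fraction]
    by_mass = sorted(merged, key=lambda d: d.mz_light)
    cluster = -1
    prev_mz = None
    for d in by_mass:
        if prev_mz is None or d.mz_light - prev_mz > cluster_tol_ppm * 1e-6 * d.mz_light:
            cluster += 1
        d.cluster_id = cluster
        prev_mz = d.mz_light
    merged.sort(key=lambda d: (d.fraction_index, d.mz_light))
    return merged


def match_doublets(
    doublets: Sequence[IsotopeDoublet],
    candidates: Sequence[CandidateSpecies],
    ms_tolerance_ppm: float = 50.0,
) -> list[MatchedCandidate]:
    """All (doublet, candidate) pairs with light masses within tolerance.

    A doublet may match several candidates and vice versa; every pairing
    is reported and site-level ambiguity is left to the MSMS stage.
    """
    if not candidates:
        return []
    order = np.argsort([c.mh_light for c in candidates], kind="stable")
    sorted_candidates = [candidates[k] for k in order]
    mh = np.array([c.mh_light for c in sorted_candidates])
    out: list[MatchedCandidate] = []
    for d in doublets:
        window = ms_tolerance_ppm * 1e-6 * d.mz_light
        lo = np.searchsorted(mh, d.mz_light - window, side="left")
        hi = np.searchsorted(mh, d.mz_light + window, side="right")
        for k in range(lo, hi):
            c = sorted_candidates[k]
            out.append(
                MatchedCandidate(
                    doublet=d,
                    candidate=c,
                    precursor_error_ppm=(d.mz_light - c.mh_light) / c.mh_light * 1e6,
                )
            )
    return out


def matches_to_frame(matches: Sequence[MatchedCandidate]) -> pd.DataFrame:
    """Full match report, one row per (doublet, candidate) pairing."""
    rows = []
    for m in matches:
        c, d = m.candidate, m.doublet
        rows.append(
            {
                "fraction_index": d.fraction_index,
                "mz_light": round(d.mz_light, 4),
                "mz_heavy": round(d.mz_heavy, 4),
                "spacing_error_ppm": round(d.spacing_error_ppm, 3),
                "intensity_parameter": round(d.intensity_parameter, 4),
                "cluster_id": d.cluster_id,
                "precursor_error_ppm": round(m.precursor_error_ppm, 3),
                "xtype": c.xtype,
                "candidate": c.label,
                "protein_a": c.peptides[0].protein_id,
                "seq_a": c.peptides[0].sequence,
                "start_a": c.peptides[0].start,
                "site_a": c.sites[0].label,
                "protein_b": c.peptides[1].protein_id if len(c.peptides) > 1 else "",
                "seq_b": c.peptides[1].sequence if len(c.peptides) > 1 else "",
                "start_b": c.peptides[1].start if len(c.peptides) > 1 else 0,
                "site_b": c.sites[1].label if len(c.sites) > 1 else "",
                "mh_light": round(c.mh_light, 4),
            }
        )
    return pd.DataFrame(rows)


_INCLUSION_COLUMNS = [
    "fraction_index",
    "mz_light",
    "candidates",
    "best_candidate",
    "spacing_error_ppm",
    "intensity_parameter",
]


def inclusion_list(matches: Sequence[MatchedCandidate]) -> pd.DataFrame:
    """Precursor inclusion rows: one per (fraction, light m/z).

    The inclusion list carries the observed *light* isotope peak masses
    (the heavy partner is co-selected by the instrument's wide timed ion
    selector window anyway).  Candidate annotations of a shared doublet
    are concatenated; the best candidate is the smallest |precursor error|.
    """
    rows: dict[tuple[int, float], dict] = {}
    for m in matches:
        d = m.doublet
        key = (d.fraction_index, round(d.mz_light, 4))
        entry = rows.setdefault(
            key,
            {
                "fraction_index": d.fraction_index,
                "mz_light": round(d.mz_light, 4),
                "spacing_error_ppm": round(d.spacing_error_ppm, 3),
                "intensity_parameter": round(d.intensity_parameter, 4),
                "_cands": [],
            },
        )
        entry["_cands"].append((abs(m.precursor_error_ppm), m.candidate.label))
    records = []
    for entry in rows.values():
        cands = sorted(entry.pop("_cands"))
        entry["candidates"] = ";".join(label for _, label in cands)
        entry["best_candidate"] = cands[0][1]
        records.append(entry)
    frame = pd.DataFrame(records, columns=_INCLUSION_COLUMNS)
    return frame.sort_values(["fraction_index", "mz_light"]).reset_index(drop=True)


def write_inclusion_list(matches: Sequence[MatchedCandidate], path: str | Path) -> pd.DataFrame:
    frame = inclusion_list(matches)
    frame.to_csv(path, sep="\t", index=False)
    return frame


def funnel_counts(
    peaklists: Sequence[PeakList],
    candidates: Sequence[CandidateSpecies],
    linker: CrosslinkerSpec = BS3,
    ms_tolerance_ppm: float = 50.0,
    search_tolerance_ppm: float = 250.0,
    max_intensity_parameter: float = 0.22,
) -> dict[str, int]:
    """Candidate counts under successively stricter doublet restrictions.

    The diagnostic funnel: peaks matching the theoretical list with no
    doublet requirement at all, then matched doublets at 20 ppm spacing,
    at 7 ppm, and at 7 ppm plus the intensity-parameter cut.  Counts are
    distinct (fraction, light m/z) entries.
    """
    mh = np.sort(
        np.concatenate(
            [[c.mh_light for c in candidates], [c.mh_heavy for c in candidates]]
        )
    ) if candidates else np.array([])

    no_restriction = 0
    for pl in peaklists:
        for mz in pl.mz:
            window = ms_tolerance_ppm * 1e-6 * mz
            lo = np.searchsorted(mh, mz - window, side="left")
            hi = np.searchsorted(mh, mz + window, side="right")
            if hi > lo:
                no_restriction += 1

    def matched_count(mode: SpacingMode, max_param: float | None) -> int:
        seen = set()
        for pl in peaklists:
            doublets = detect_doublets(
                pl, linker, mode, search_tolerance_ppm, max_param
            )
            for m in match_doublets(doublets, candidates, ms_tolerance_ppm):
                seen.add((m.doublet.fraction_index, round(m.doublet.mz_light, 4)))
        return len(seen)

    return {
        "no_restriction": no_restriction,
        "spacing_20ppm": matched_count("fixed20ppm", None),
        "spacing_7ppm": matched_count("fixed7ppm", None),
        "spacing_7ppm_intensity": matched_count("fixed7ppm", max_intensity_parameter),
    }
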