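"""Ground-truth-labeled synthetic LC-MALDI datasets.

The generator emulates the signal structure of an off-line LC-MALDI
crosslinking run so the screening, validation and classification stages
can be exercised end to end without instrument data:

* every crosslinker-carrying species (planted type-2 crosslinks, plus
  dead-end and loop-link species) elutes as a light/heavy doublet over a
  Gaussian profile of LC fractions, with the deuterated heavy form
  leading the light form by a configurable fraction offset — so the
  doublet intensity ratio drifts from heavy- to light-dominant across
  consecutive wells;
* unmodified peptides appear as abundant single peaks;
* uniform noise peaks and near-doublet decoys (peak pairs that match the
  theoretical list but violate the exact spacing or the 1:1 intensity
  rule) provide the false-positive classes that the doublet filters are
  meant to remove;
* a manifest attributes every written peak to exactly one source.

Two physical facts are built in rather than optional: the two members of
a doublet share one MALDI spot, so their intensity noise is mostly
common-mode; and the *relative* spacing of co-recorded peaks is far more
accurate than the absolute calibration, so calibration error is applied
jointly to both members, preserving the spacing.

All randomness flows from a single seed; fixed seed gives byte-identical
output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import DEFAULT_TABLE, MassTable
from .digestion import ProteinEntry, Site, crosslinkable_sites, digest_all, peptide_mass
from .msms import MsmsSpectrum, theoretical_fragments
from .screen import PeakList
from .synthetic_constructs import SYNTHETIC_SHSP_CONSTRUCT
from .theory import (
    BS3,
    CandidateSpecies,
    CrosslinkerSpec,
    XTYPE_INTER,
    enumerate_candidates,
)


@dataclass
class SimulationConfig:
    """Study conditions for a simulated crosslinking LC-MALDI run."""

    proteins: Sequence[ProteinEntry] = (SYNTHETIC_SHSP_CONSTRUCT,)
    #: site pairs to plant, or an integer k for "random k type-2 candidates"
    planted_crosslinks: Sequence[tuple[Site, Site]] | int = 10
    n_fractions: int = 64
    #: Gaussian elution profile sigma, in fractions
    elution_width: float = 1.5
    #: how many fractions earlier the heavy (D12) form elutes
    d12_lead: float = 0.5
    noise_peaks_per_fraction: int = 30
    near_doublet_decoys: int = 20
    #: log-normal coefficient of variation of spot intensities
    intensity_cv: float = 0.2
    #: absolute m/z calibration error (ppm, 1 sigma), spacing-preserving
    calibration_ppm: float = 5.0
    mass_window: tuple[float, float] = (600.0, 5000.0)
    max_missed_cleavages: int = 3
    include_type01: bool = True
    include_unmodified: bool = True
    rng_seed: int = 0


@dataclass
class SimulatedDataset:
    """Simulator output: files on disk plus in-memory ground truth."""

    out_dir: Path
    files: list[Path]
    manifest: pd.DataFrame
    candidates: list[CandidateSpecies]
    planted_type2: list[CandidateSpecies]
    config: SimulationConfig = field(repr=False, default=None)


def _elution_peaks(
    rng: np.random.Generator,
    center: float,
    sigma: float,
    base: float,
    n_fractions: int,
) -> dict[int, float]:
    """Noise-free Gaussian profile amplitudes per fraction (>=3% of base)."""
    out = {}
    lo = max(1, int(math.floor(center - 3 * sigma)))
    hi = min(n_fractions, int(math.ceil(center + 3 * sigma)))
    for f in range(lo, hi + 1):
        amp = base * math.exp(-((f - center) ** 2) / (2 * sigma**2))
        if amp >= 0.03 * base:
            out[f] = amp
    return out


def _resolve_planted(
    cfg: SimulationConfig,
    type2: list[CandidateSpecies],
    rng: np.random.Generator,
) -> list[CandidateSpecies]:
    if isinstance(cfg.planted_crosslinks, int):
        k = cfg.planted_crosslinks
        if k > len(type2):
            raise ValueError(f"cannot plant {k} crosslinks from {len(type2)} candidates")
        idx = rng.choice(len(type2), size=k, replace=False)
        return [type2[i] for i in sorted(idx)]
    planted = []
    for site_a, site_b in cfg.planted_crosslinks:
        pair = {site_a, site_b} if site_a != site_b else {site_a}
        hits = [c for c in type2 if set(c.sites) == pair]
        if not hits:
            raise ValueError(f"planted sites {site_a.label}--{site_b.label} not enumerable")
        # shortest total peptide length = the canonical observed form
        planted.append(min(hits, key=lambda c: sum(len(p) for p in c.peptides)))
    return planted


def simulate_fractions(
    cfg: SimulationConfig,
    out_dir: str | Path,
    linker: CrosslinkerSpec = BS3,
    table: MassTable = DEFAULT_TABLE,
    filename_template: str = "frac{index}.txt",
) -> SimulatedDataset:
    """Write per-fraction peak lists plus a ground-truth manifest.

    Returns the dataset object; ``truth.tsv`` in ``out_dir`` holds one
    row per written peak with its source attribution.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    candidates = enumerate_candidates(
        list(cfg.proteins),
        linker,
        table,
        max_missed_cleavages=cfg.max_missed_cleavages,
        mass_window=cfg.mass_window,
    )
    type2 = [c for c in candidates if c.xtype == XTYPE_INTER]
    planted_type2 = _resolve_planted(cfg, type2, rng)
    planted_keys = {id(c) for c in planted_type2}

    # species actually present in the sample, with relative abundances
    # reflecting the usual ordering: unmodified >> dead-end > loop > type 2
    species: list[tuple[str, str, float, float, bool]] = []
    # (source_id, kind, mh_light, base_intensity, is_doublet)
    if cfg.include_unmodified:
        peptides = digest_all(list(cfg.proteins), 1)
        seen = set()
        for p in peptides:
            mh = peptide_mass(p, table) + table.proton_mass
            if not cfg.mass_window[0] <= mh <= cfg.mass_window[1] or mh in seen:
                continue
            seen.add(mh)
            species.append((f"peptide:{p.span_label}", "peptide", mh, 5000.0, False))
    if cfg.include_type01:
        for c in candidates:
            if c.xtype == "type0" and c.peptides[0].missed_cleavages <= 1:
                species.append((f"xl0:{c.label}", "type0", c.mh_light, 2000.0, True))
            elif c.xtype == "type1":
                species.append((f"xl1:{c.label}", "type1", c.mh_light, 1000.0, True))
    for i, c in enumerate(planted_type2):
        species.append((f"xl2:{c.label}", "type2", c.mh_light, 800.0, True))

    peaks: dict[int, list[tuple[float, float, str, str]]] = {
        f: [] for f in range(1, cfg.n_fractions + 1)
    }

    def add_peak(fraction: int, mz: float, intensity: float, source: str, role: str) -> None:
        peaks[fraction].append((mz, intensity, source, role))

    sigma = cfg.elution_width
    for source_id, kind, mh, base_int, is_doublet in species:
        center = float(rng.uniform(1 + sigma, cfg.n_fractions - sigma))
        base = base_int * float(rng.lognormal(0.0, 0.4))
        light_profile = _elution_peaks(rng, center, sigma, base, cfg.n_fractions)
        if is_doublet:
            heavy_profile = _elution_peaks(
                rng, center - cfg.d12_lead, sigma, base, cfg.n_fractions
            )
            fractions = sorted(set(light_profile) & set(heavy_profile))
        else:
            heavy_profile = {}
            fractions = sorted(light_profile)
        for f in fractions:
            spot = float(rng.lognormal(0.0, cfg.intensity_cv))
            shift = 1.0 + float(rng.normal(0.0, cfg.calibration_ppm * 1e-6))
            jitter_l = float(rng.lognormal(0.0, cfg.intensity_cv / 5))
            add_peak(f, mh * shift, light_profile[f] * spot * jitter_l, source_id, "light")
            if is_doublet:
                jitter_h = float(rng.lognormal(0.0, cfg.intensity_cv / 5))
                add_peak(
                    f,
                    mh * shift + linker.isotope_spacing,
                    heavy_profile[f] * spot * jitter_h,
                    source_id,
                    "heavy",
                )

    # near-doublet decoys: peak pairs anchored at theoretical candidate
    # masses (so they pass the plain mass match) but failing exactly one
    # of the doublet constraints
    decoy_anchors = [c for c in candidates if id(c) not in planted_keys]
    decoy_classes = ("loose_spacing", "mid_spacing", "bad_intensity")
    for k in range(cfg.near_doublet_decoys):
        cls = decoy_classes[k % len(decoy_classes)]
        anchor = decoy_anchors[int(rng.integers(len(decoy_anchors)))]
        f = int(rng.integers(1, cfg.n_fractions + 1))
        light_mz = anchor.mh_light * (1.0 + float(rng.normal(0.0, 2e-6)))
        base = 600.0 * float(rng.lognormal(0.0, 0.3))
        if cls == "loose_spacing":
            off = float(rng.uniform(25e-6, 200e-6)) * float(rng.choice([-1, 1]))
            ratio = float(rng.uniform(0.85, 1.15))
        elif cls == "mid_spacing":
            off = float(rng.uniform(8.5e-6, 18e-6)) * float(rng.choice([-1, 1]))
            ratio = float(rng.uniform(0.85, 1.15))
        else:  # exact spacing, grossly unequal intensities
            off = 0.0
            ratio = float(rng.uniform(0.10, 0.45))
        heavy_mz = light_mz + linker.isotope_spacing + off * light_mz
        add_peak(f, light_mz, base, f"decoy:{cls}:{k}", "light")
        add_peak(f, heavy_mz, base * ratio, f"decoy:{cls}:{k}", "heavy")

    lo, hi = cfg.mass_window
    for f in range(1, cfg.n_fractions + 1):
        for _ in range(cfg.noise_peaks_per_fraction):
            add_peak(
                f,
                float(rng.uniform(lo, hi)),
                150.0 * float(rng.lognormal(0.0, 0.8)),
                "noise",
                "single",
            )

    files: list[Path] = []
    manifest_rows = []
    width = max(3, len(str(cfg.n_fractions)))
    for f in range(1, cfg.n_fractions + 1):
        rows = sorted(peaks[f])
        path = out_dir / filename_template.format(index=f"{f:0{width}d}")
        with open(path, "w") as fh:
            fh.write("m/z\tintensity\n")
            for mz, intensity, source, role in rows:
                fh.write(f"{mz:.5f}\t{intensity:.3f}\n")
        files.append(path)
        for mz, intensity, source, role in rows:
            manifest_rows.append(
                {
                    "fraction_index": f,
                    "mz": round(mz, 5),
                    "intensity": round(intensity, 3),
                    "source": source,
                    "role": role,
                }
            )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return SimulatedDataset(
        out_dir=out_dir,
        files=files,
        manifest=manifest,
        candidates=candidates,
        planted_type2=planted_type2,
        config=cfg,
    )


def trace_inclusion(
    inclusion: pd.DataFrame, manifest: pd.DataFrame, tol_ppm: float = 2.0
) -> pd.Series:
    """Attribute each inclusion row to its manifest source (or 'unknown').

    Matches on (fraction, light m/z) against non-noise light peaks within
    ``tol_ppm``.
    """
    lights = manifest[manifest["role"] == "light"]
    sources = []
    for _, row in inclusion.iterrows():
        sub = lights[lights["fraction_index"] == row["fraction_index"]]
        if len(sub):
            err = (sub["mz"] - row["mz_light"]).abs() / row["mz_light"] * 1e6
            best = err.idxmin()
            if err[best] <= tol_ppm:
                sources.append(sub.loc[best, "source"])
                continue
        sources.append("unknown")
    return pd.Series(sources, index=inclusion.index, name="source")


def simulate_msms(
    candidate: CandidateSpecies,
    completeness: float = 1.0,
    rng_seed: int = 0,
    noise_peaks: int = 0,
    fraction_index: int = 1,
    table: MassTable = DEFAULT_TABLE,
    linker: CrosslinkerSpec = BS3,
) -> MsmsSpectrum:
    """A fragment spectrum sampled from a candidate's theoretical ions.

    ``completeness`` is the sampled fraction of theoretical fragments;
    crosslinker-carrying fragments contribute their light and heavy forms
    jointly, so any sampled carrier yields a doublet.
    """
    if not 0 < completeness <= 1:
        raise ValueError("completeness must be in (0, 1]")
    rng = np.random.default_rng(rng_seed)
    fragments = theoretical_fragments(candidate, table, linker)
    n_keep = max(1, round(completeness * len(fragments)))
    keep_idx = sorted(rng.choice(len(fragments), size=n_keep, replace=False))
    mz, intensity = [], []
    for i in keep_idx:
        frag = fragments[i]
        height = float(rng.lognormal(math.log(500.0), 0.5))
        mz.append(frag.mz_light)
        intensity.append(height)
        if frag.mz_heavy is not None:
            mz.append(frag.mz_heavy)
            intensity.append(height * float(rng.lognormal(0.0, 0.1)))
    if noise_peaks:
        top = max(mz) if mz else 2000.0
        for _ in range(noise_peaks):
            mz.append(float(rng.uniform(100.0, top)))
            intensity.append(50.0 * float(rng.lognormal(0.0, 0.5)))
    return MsmsSpectrum(
        title=f"sim frac{fraction_index:03d} {candidate.label}",
        precursor_mh=candidate.mh_light,
        fragment_mz=np.array(mz),
        fragment_intensity=np.array(intensity),
        fraction_index=fraction_index,
    )


def simulate_mixed_pattern(
    pattern_masses: Sequence[float],
    kind: str,
    rng_seed: int = 0,
    base_intensity: float = 1000.0,
    mixture_x: float = 1.0,
    noise_peaks: int = 0,
    intensity_cv: float = 0.0,
    mass_window: tuple[float, float] = (600.0, 5000.0),
) -> PeakList:
    """Peaks of a 14N/15N mixed-isotope spectrum for one crosslink.

    ``pattern_masses`` is (AA, AB, BA, BB).  ``kind`` "intra" plants the
    outer peaks only; "inter" plants all four, with the mixed forms scaled
    by ``mixture_x`` (1.0 = fully exchanged 1:1:1:1).  Coincident mixed
    masses (equal nitrogen counts) merge into one peak of summed height.
    """
    if kind not in ("intra", "inter"):
        raise ValueError("kind must be 'intra' or 'inter'")
    aa, ab, ba, bb = pattern_masses
    rng = np.random.default_rng(rng_seed)

    def noisy(height: float) -> float:
        if intensity_cv <= 0:
            return height
        return height * float(rng.lognormal(0.0, intensity_cv))

    planted: dict[float, float] = {}
    planted[aa] = noisy(base_intensity)
    planted[bb] = planted.get(bb, 0.0) + noisy(base_intensity)
    if kind == "inter":
        planted[ab] = planted.get(ab, 0.0) + noisy(base_intensity * mixture_x)
        planted[ba] = planted.get(ba, 0.0) + noisy(base_intensity * mixture_x)
    mz = list(planted)
    intensity = [planted[m] for m in mz]
    for _ in range(noise_peaks):
        mz.append(float(rng.uniform(*mass_window)))
        intensity.append(50.0 * float(rng.lognormal(0.0, 0.5)))
    return PeakList(1, np.array(mz), np.array(intensity))
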