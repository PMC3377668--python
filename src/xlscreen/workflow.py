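"""High-level runs wiring digestion -> theory -> screen/validate/classify.

These functions are the programmatic equivalents of the CLI subcommands;
each takes a :class:`RunConfig`, logs the fully resolved configuration,
and returns DataFrames so they are equally usable from scripts and tests.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .chem import DEFAULT_TABLE
from .digestion import read_fasta
from .mixed import classify_pattern, combination_masses
from .msms import merge_mgf, validate_spectrum
from .screen import (
    detect_doublets,
    funnel_counts,
    inclusion_list,
    match_doublets,
    matches_to_frame,
    merge_doublets,
    read_peaklists,
)
from .theory import BS3, XTYPE_INTER, enumerate_candidates

log = logging.getLogger("xlscreen")


@dataclass
class RunConfig:
    """Resolved settings of one analysis run (YAML round-trippable)."""

    fasta: str = ""
    peaks_dir: str = ""
    peaks_pattern: str = "frac{index}.txt"
    mgf_dir: str = ""
    crosslinker: str = "BS3"
    spacing_mode: str = "fixed7ppm"
    max_intensity_parameter: float | None = 0.22
    ms_tolerance_ppm: float = 50.0
    search_tolerance_ppm: float = 50.0
    fragment_tolerance_da: float = 0.3
    mass_window: tuple[float, float] = (600.0, 5000.0)
    max_missed_cleavages: int = 3
    met_oxidation: bool = False
    extra_deadend: bool = False
    min_fragments: int = 4
    min_doublets: int = 1
    intensity_balance: float = 0.22
    out_dir: str = "."
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "mass_window" in data:
            data["mass_window"] = tuple(data["mass_window"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["mass_window"] = list(self.mass_window)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def log_resolved(self) -> None:
        for key, value in dataclasses.asdict(self).items():
            log.info("config %s = %r", key, value)


def _linker(cfg: RunConfig):
    if cfg.crosslinker != "BS3":
        raise ValueError(f"unsupported crosslinker {cfg.crosslinker!r}")
    return BS3


def _candidates(cfg: RunConfig):
    proteins = read_fasta(cfg.fasta)
    return enumerate_candidates(
        proteins,
        _linker(cfg),
        DEFAULT_TABLE,
        max_missed_cleavages=cfg.max_missed_cleavages,
        met_oxidation=cfg.met_oxidation,
        extra_deadend=cfg.extra_deadend,
        mass_window=cfg.mass_window,
    )


def run_ms(cfg: RunConfig) -> dict[str, pd.DataFrame | dict]:
    """MS-mode screen: doublets -> merge -> match -> inclusion list.

    Writes inclusion.tsv, match_report.tsv and funnel.tsv to
    ``cfg.out_dir``; returns the frames and the funnel counts.
    """
    cfg.log_resolved()
    linker = _linker(cfg)
    candidates = _candidates(cfg)
    if not candidates:
        raise RuntimeError("no theoretical candidates in the mass window")
    peaklists = read_peaklists(cfg.peaks_dir, cfg.peaks_pattern)
    per_fraction = [
        detect_doublets(
            pl,
            linker,
            cfg.spacing_mode,  # type: ignore[arg-type]
            cfg.search_tolerance_ppm,
            cfg.max_intensity_parameter,
        )
        for pl in peaklists
    ]
    merged = merge_doublets(per_fraction, cfg.ms_tolerance_ppm)
    matches = match_doublets(merged, candidates, cfg.ms_tolerance_ppm)
    funnel = funnel_counts(
        peaklists,
        candidates,
        linker,
        ms_tolerance_ppm=cfg.ms_tolerance_ppm,
        max_intensity_parameter=cfg.max_intensity_parameter or 0.22,
    )
    for stage, count in funnel.items():
        log.info("funnel %s: %d", stage, count)

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inclusion = inclusion_list(matches)
    inclusion.to_csv(out_dir / "inclusion.tsv", sep="\t", index=False)
    report = matches_to_frame(matches)
    report.to_csv(out_dir / "match_report.tsv", sep="\t", index=False)
    pd.DataFrame([funnel]).to_csv(out_dir / "funnel.tsv", sep="\t", index=False)
    return {"inclusion": inclusion, "report": report, "funnel": funnel}


def run_msms(cfg: RunConfig) -> pd.DataFrame:
    """MSMS-mode validation: merge MGFs, match precursors and fragments."""
    cfg.log_resolved()
    candidates = _candidates(cfg)
    if not candidates:
        raise RuntimeError("no theoretical candidates in the mass window")
    mgf_paths = sorted(Path(cfg.mgf_dir).glob("*.mgf"))
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spectra = merge_mgf(mgf_paths, out_dir / "merged.mgf")
    rows = []
    for spec in spectra:
        for rep in validate_spectrum(
            spec,
            candidates,
            precursor_tol_ppm=cfg.ms_tolerance_ppm,
            frag_tol_da=cfg.fragment_tolerance_da,
            min_fragments=cfg.min_fragments,
            min_doublets=cfg.min_doublets,
        ):
            rows.append(
                {
                    "spectrum": rep.spectrum_title,
                    "precursor_mh": round(spec.precursor_mh, 4),
                    "candidate": rep.candidate.label,
                    "xtype": rep.candidate.xtype,
                    "matched_fragments": rep.matched_fragments,
                    "matched_doublets": rep.matched_doublets,
                    "total_theoretical": rep.total_theoretical,
                    "validated": rep.validated,
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "spectrum", "precursor_mh", "candidate", "xtype",
            "matched_fragments", "matched_doublets", "total_theoretical", "validated",
        ],
    )
    frame.to_csv(out_dir / "validation_report.tsv", sep="\t", index=False)
    return frame


def run_mixed(cfg: RunConfig, crosslinks_tsv: str | Path) -> pd.DataFrame:
    """Mixed-isotope classification of previously validated crosslinks.

    ``crosslinks_tsv`` needs columns seq_a/start_a/site_a/seq_b/start_b/
    site_b (as written by the MS-mode match report); each row is matched
    to its enumerated type-2 candidate, the 14N/15N combination masses are
    computed and classified against the observed peak lists.
    """
    cfg.log_resolved()
    candidates = [c for c in _candidates(cfg) if c.xtype == XTYPE_INTER]
    peaklists = {pl.fraction_index: pl for pl in read_peaklists(cfg.peaks_dir, cfg.peaks_pattern)}
    wanted = pd.read_csv(crosslinks_tsv, sep="\t")
    rows = []
    for _, row in wanted.iterrows():
        hits = [
            c
            for c in candidates
            if {(p.sequence, p.start) for p in c.peptides}
            == {(row["seq_a"], int(row["start_a"])), (row["seq_b"], int(row["start_b"]))}
            and {s.label for s in c.sites} == {row["site_a"], row["site_b"]}
        ]
        if not hits:
            raise ValueError(
                f"crosslink {row['seq_a']}--{row['seq_b']} not in the enumerated list"
            )
        pattern = combination_masses(hits[0])
        best_verdict = "undetermined"
        best_fraction = None
        for fraction, pl in peaklists.items():
            result = classify_pattern(
                pattern, pl, cfg.ms_tolerance_ppm, cfg.intensity_balance
            )
            if result.verdict != "undetermined":
                best_verdict = result.verdict
                best_fraction = fraction
                break
        rows.append(
            {
                "candidate": hits[0].label,
                "mass_14N14N": round(pattern.mass_aa, 4),
                "mass_14N15N": round(pattern.mass_ab, 4),
                "mass_15N14N": round(pattern.mass_ba, 4),
                "mass_15N15N": round(pattern.mass_bb, 4),
                "verdict": best_verdict,
                "fraction_index": best_fraction,
            }
        )
    frame = pd.DataFrame(rows)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out_dir / "mixed_report.tsv", sep="\t", index=False)
    return frame
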