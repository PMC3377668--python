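"""MGF handling, fragment generation and fragment-evidence matching."""

import numpy as np
import pytest

from xlscreen.chem import DEFAULT_TABLE, PROTON
from xlscreen.digestion import peptide_mass
from xlscreen.msms import (
    MsmsSpectrum,
    match_fragments,
    match_precursor,
    merge_mgf,
    read_mgf,
    theoretical_fragments,
    write_mgf,
)
from xlscreen.simulate import simulate_msms
from xlscreen.synthetic_constructs import clp_protease_peptides
from xlscreen.theory import BS3, enumerate_type0, enumerate_type1, enumerate_type2

from conftest import make_peptide


@pytest.fixture(scope="module")
def clp_candidate():
    """The benchmark inter-subunit crosslink IEKDTDR(K171) x AKEVLANK(K165)."""
    pep_p, pep_r = clp_protease_peptides()
    cands = [
        c
        for c in enumerate_type2([pep_p, pep_r])
        if {p.protein_id for p in c.peptides} == {"ClpP3", "ClpR"}
        and {s.residue_index for s in c.sites} == {171, 165}
    ]
    assert len(cands) == 1
    return cands[0]


def spectrum_from(mz_values, precursor=1000.0, title="t"):
    mz = np.asarray(sorted(mz_values), dtype=float)
    return MsmsSpectrum(title, precursor, mz, np.full(len(mz), 100.0))


class TestMgfIO:
    def _spectra(self, n, offset=0):
        out = []
        for i in range(n):
            s = spectrum_from([200.0 + i, 300.5 + i], precursor=900.0 + i + offset,
                              title=f"frac{i + 1:03d} spec")
            s.fraction_index = i + 1
            out.append(s)
        return out

    def test_merge_counts_blocks(self, tmp_path):
        write_mgf(self._spectra(3), tmp_path / "a.mgf")
        write_mgf(self._spectra(3, offset=50), tmp_path / "b.mgf")
        merged = merge_mgf([tmp_path / "a.mgf", tmp_path / "b.mgf"],
                           tmp_path / "merged.mgf")
        assert len(merged) == 6
        assert len(read_mgf(tmp_path / "merged.mgf")) == 6

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no input"):
            merge_mgf([])

    def test_roundtrip_precursors(self, tmp_path):
        original = self._spectra(4)
        write_mgf(original, tmp_path / "rt.mgf")
        back = read_mgf(tmp_path / "rt.mgf")
        for a, b in zip(original, back):
            assert b.precursor_mh == pytest.approx(a.precursor_mh, abs=1e-4)
            assert b.fraction_index == a.fraction_index

    def test_malformed_block_reported(self, tmp_path):
        (tmp_path / "bad.mgf").write_text(
            "BEGIN IONS\nTITLE=x\n100.0 1.0\nEND IONS\n"
        )  # missing PEPMASS
        with pytest.raises(ValueError, match="PEPMASS|malformed"):
            read_mgf(tmp_path / "bad.mgf")


class TestMatchPrecursor:
    def test_light_and_heavy_both_match(self, clp_candidate):
        light = spectrum_from([], precursor=clp_candidate.mh_light)
        heavy = spectrum_from([], precursor=clp_candidate.mh_heavy)
        assert match_precursor(light, [clp_candidate], 50) == [clp_candidate]
        assert match_precursor(heavy, [clp_candidate], 50) == [clp_candidate]
        assert round(clp_candidate.mh_light) == 1886

    def test_out_of_tolerance_empty(self, clp_candidate):
        spec = spectrum_from([], precursor=clp_candidate.mh_light + 1.0)
        assert match_precursor(spec, [clp_candidate], 50) == []


class TestTheoreticalFragments:
    def test_site_spanning_fragments_are_doublets(self, clp_candidate):
        frags = theoretical_fragments(clp_candidate)
        by_label = {f.label: f for f in frags}
        # y5 of IEKDTDR ("KDTDR") spans K171 -> doublet carrying the
        # linker + whole partner peptide
        pep_a = clp_candidate.peptides[0]
        name_p = "A" if pep_a.protein_id == "ClpP3" else "B"
        y5 = by_label[f"y5{name_p}x"]
        assert y5.carries_crosslinker
        assert y5.mz_heavy - y5.mz_light == pytest.approx(12.0757, abs=1e-9)
        # y2 of IEKDTDR ("DR") does not span the site -> single peak
        y2 = by_label[f"y2{name_p}"]
        assert not y2.carries_crosslinker and y2.mz_heavy is None

    def test_crosslinked_fragment_mass_composition(self, clp_candidate):
        # b2 of AKEVLANK ("AK", spans K165): bridge + intact partner
        frags = theoretical_fragments(clp_candidate)
        pep_r_name = "A" if clp_candidate.peptides[0].protein_id == "ClpR" else "B"
        b2 = next(f for f in frags if f.label == f"b2{pep_r_name}x")
        expected = (
            DEFAULT_TABLE.residue_masses["A"]
            + DEFAULT_TABLE.residue_masses["K"]
            + PROTON
            + BS3.interpeptide_delta
            + peptide_mass(make_peptide("IEKDTDR"))
        )
        assert b2.mz_light == pytest.approx(expected, abs=1e-6)

    def test_by_complementarity_of_plain_fragments(self, clp_candidate):
        # b_i + y_(n-i) = peptide MH+ + proton for non-carrier fragments
        for pep_name, pep in zip(("A", "B"), clp_candidate.peptides):
            frags = {
                (f.series, f.index): f
                for f in theoretical_fragments(clp_candidate)
                if f.source_peptide == pep_name
            }
            n = len(pep.sequence)
            mh = peptide_mass(pep) + PROTON
            for i in range(1, n):
                b, y = frags[("b", i)], frags[("y", n - i)]
                if b.carries_crosslinker or y.carries_crosslinker:
                    continue
                assert b.mz_light + y.mz_light == pytest.approx(mh + PROTON, abs=1e-6)

    def test_loop_link_skips_ring_opened_fragments(self):
        pep = make_peptide("AKAKAR")
        (loop,) = enumerate_type1([pep])
        frags = theoretical_fragments(loop)
        # fragments spanning exactly one site are omitted entirely
        labels = {f.label for f in frags}
        assert "b2A" not in labels and "b2Ax" not in labels
        # spanning both sites -> carrier doublet
        carrier = next(f for f in frags if f.carries_crosslinker)
        assert carrier.mz_heavy is not None

    def test_deadend_fragments_use_deadend_delta(self):
        pep = make_peptide("AKAR")
        (de,) = enumerate_type0([pep])
        frags = {f.label: f for f in theoretical_fragments(de)}
        plain_b1 = DEFAULT_TABLE.residue_masses["A"] + PROTON
        assert frags["b1A"].mz_light == pytest.approx(plain_b1, abs=1e-6)
        assert frags["b2Ax"].mz_light == pytest.approx(
            plain_b1 + DEFAULT_TABLE.residue_masses["K"] + BS3.deadend_delta, abs=1e-6
        )


class TestMatchFragments:
    def test_self_consistent_spectrum_full_recall(self, clp_candidate):
        frags = theoretical_fragments(clp_candidate)
        mz = [f.mz_light for f in frags] + [
            f.mz_heavy for f in frags if f.mz_heavy is not None
        ]
        spec = spectrum_from(mz, precursor=clp_candidate.mh_light)
        report = match_fragments(spec, frags, 0.3, clp_candidate)
        assert report.matched_fragments == len(frags)
        assert report.matched_doublets == sum(f.carries_crosslinker for f in frags)
        assert report.validated

    def test_empty_spectrum_zero_matches(self, clp_candidate):
        frags = theoretical_fragments(clp_candidate)
        spec = spectrum_from([], precursor=clp_candidate.mh_light)
        report = match_fragments(spec, frags, 0.3)
        assert report.matched_fragments == 0 and not report.validated

    def test_planted_doublet_counted_once(self, clp_candidate):
        frags = theoretical_fragments(clp_candidate)
        pep_a = clp_candidate.peptides[0]
        name_p = "A" if pep_a.protein_id == "ClpP3" else "B"
        y5 = next(f for f in frags if f.label == f"y5{name_p}x")
        spec = spectrum_from([y5.mz_light, y5.mz_heavy],
                             precursor=clp_candidate.mh_light)
        report = match_fragments(spec, frags, 0.3)
        assert report.matched_doublets == 1

    def test_greedy_assignment_is_one_to_one(self, clp_candidate):
        frags = theoretical_fragments(clp_candidate)
        spec = spectrum_from([f.mz_light for f in frags],
                             precursor=clp_candidate.mh_light)
        report = match_fragments(spec, frags, 0.5)
        observed = [a.observed_mz for a in report.assignments]
        assert len(observed) == len(set(observed))


def test_simulated_spectrum_validates(clp_candidate):
    spec = simulate_msms(clp_candidate, completeness=1.0, rng_seed=7, noise_peaks=5)
    frags = theoretical_fragments(clp_candidate)
    report = match_fragments(spec, frags, 0.3, clp_candidate)
    assert report.matched_fragments == len(frags)
    assert report.matched_doublets >= 1
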