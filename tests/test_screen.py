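"""Doublet detection, intensity filter, merging, matching, inclusion list."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xlscreen.screen import (
    PeakList,
    detect_doublets,
    funnel_counts,
    inclusion_list,
    intensity_parameter,
    match_doublets,
    merge_doublets,
    read_peaklists,
    write_inclusion_list,
)
from xlscreen.theory import BS3, enumerate_type2

from conftest import make_peptide

SPACING = BS3.isotope_spacing


def peaklist(pairs, fraction=1):
    mz, inten = zip(*pairs)
    return PeakList(fraction, np.array(mz), np.array(inten))


def brute_force_doublets(pl, tol_ppm, max_param):
    """O(n^2) all-pairs reference for doublet detection."""
    found = set()
    for i in range(len(pl.mz)):
        for j in range(len(pl.mz)):
            if i == j:
                continue
            spacing = pl.mz[j] - pl.mz[i]
            if abs(spacing - SPACING) > tol_ppm * 1e-6 * pl.mz[i]:
                continue
            param = intensity_parameter(pl.intensity[i], pl.intensity[j])
            if max_param is not None and param > max_param:
                continue
            found.add((round(pl.mz[i], 6), round(pl.mz[j], 6)))
    return found


class TestReadPeaklists:
    def test_reads_indexed_files(self, tmp_path):
        for i in (1, 2, 3):
            (tmp_path / f"frac{i:03d}.txt").write_text("1000.0 500\n1500.0,300\n")
        pls = read_peaklists(tmp_path)
        assert [pl.fraction_index for pl in pls] == [1, 2, 3]
        assert len(pls[0]) == 2
        assert pls[0].mz[0] == 1000.0

    def test_header_tolerated_empty_file_warns(self, tmp_path):
        (tmp_path / "frac001.txt").write_text("m/z\tintensity\n900.5\t10\n")
        (tmp_path / "frac002.txt").write_text("")
        with pytest.warns(UserWarning, match="empty"):
            pls = read_peaklists(tmp_path)
        assert len(pls[0]) == 1 and len(pls[1]) == 0

    def test_bad_line_reports_location(self, tmp_path):
        (tmp_path / "frac001.txt").write_text("1000.0 500\nabc 5\n")
        with pytest.raises(ValueError, match="frac001.txt:2"):
            read_peaklists(tmp_path)

    def test_nonpositive_intensity_rejected(self, tmp_path):
        (tmp_path / "frac001.txt").write_text("1000.0 0\n")
        with pytest.raises(ValueError, match="intensity"):
            read_peaklists(tmp_path)


class TestIntensityParameter:
    @pytest.mark.parametrize(
        "frac,setting",
        [(0.82, 0.2), (0.80, 0.22), (0.74, 0.3), (0.50, 0.67)],
    )
    def test_published_correspondence(self, frac, setting):
        # one peak at X% of the other maps onto the documented settings
        assert round(intensity_parameter(100.0, 100.0 * frac), 2) == pytest.approx(
            setting
        )

    @given(
        i1=st.floats(1e-3, 1e9, allow_nan=False),
        i2=st.floats(1e-3, 1e9, allow_nan=False),
    )
    @settings(max_examples=100, derandomize=True)
    def test_symmetric_and_nonnegative(self, i1, i2):
        assert intensity_parameter(i1, i2) == intensity_parameter(i2, i1) >= 0

    def test_identical_peaks_zero(self):
        assert intensity_parameter(123.4, 123.4) == 0.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            intensity_parameter(0.0, 10.0)


class TestDetectDoublets:
    def test_exact_planted_pair(self):
        pl = peaklist([(1000.0, 500.0), (1000.0 + SPACING, 500.0)])
        (d,) = detect_doublets(pl)
        assert d.spacing_error_ppm == pytest.approx(0.0, abs=1e-6)
        assert d.intensity_parameter == 0.0
        assert d.mz_light < d.mz_heavy

    def test_intensity_filter_rejects_unbalanced(self):
        pl = peaklist([(1000.0, 500.0), (1000.0 + SPACING, 100.0)])
        assert detect_doublets(pl, max_intensity_parameter=0.22) == []
        assert len(detect_doublets(pl, max_intensity_parameter=None)) == 1

    def test_borderline_pair_at_published_settings(self):
        # spacing 12.076 at m/z 1712 is within 7 ppm; intensities 800/640
        # give parameter 0.2222: excluded at 0.22, included at 0.3
        pl = peaklist([(1711.995, 800.0), (1724.071, 640.0)])
        assert detect_doublets(pl, max_intensity_parameter=0.22) == []
        (d,) = detect_doublets(pl, max_intensity_parameter=0.3)
        assert abs(d.spacing_error_ppm) < 7
        assert d.intensity_parameter == pytest.approx(0.2222, abs=1e-4)

    def test_spacing_mode_monotonicity(self, rng):
        mz = np.sort(rng.uniform(600, 3000, 150))
        pl = PeakList(1, mz, np.full(150, 100.0))
        counts = [
            len(detect_doublets(pl, spacing_mode=mode, search_tolerance_ppm=60,
                                max_intensity_parameter=None))
            for mode in ("fixed7ppm", "fixed20ppm", "free")
        ]
        assert counts[0] <= counts[1] <= counts[2]

    @given(data=st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_agrees_with_brute_force(self, data):
        n = data.draw(st.integers(2, 60))
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        base = np.sort(rng.uniform(600, 2000, n))
        # plant some true/near pairs so the window is actually exercised
        planted = base[: n // 3] + SPACING * (1 + rng.normal(0, 10e-6, n // 3))
        mz = np.sort(np.concatenate([base, planted]))
        inten = rng.lognormal(5, 1, len(mz))
        pl = PeakList(1, mz, inten)
        for tol, max_param in ((7, None), (20, 0.22), (50, 0.5)):
            mode = {7: "fixed7ppm", 20: "fixed20ppm"}.get(tol, "free")
            got = {
                (round(d.mz_light, 6), round(d.mz_heavy, 6))
                for d in detect_doublets(pl, spacing_mode=mode,
                                         search_tolerance_ppm=tol,
                                         max_intensity_parameter=max_param)
            }
            assert got == brute_force_doublets(pl, tol, max_param)


class TestMergeAndMatch:
    def test_merge_preserves_rows_and_clusters(self):
        a = detect_doublets(peaklist([(1000.0, 100.0), (1000.0 + SPACING, 100.0)], 57))
        b = detect_doublets(peaklist([(1000.0001, 90.0), (1000.0001 + SPACING, 100.0)], 58))
        merged = merge_doublets([a, b])
        assert len(merged) == 2
        assert merged[0].cluster_id == merged[1].cluster_id
        assert [d.fraction_index for d in merged] == [57, 58]

    def test_merge_disjoint_masses_distinct_clusters(self):
        a = detect_doublets(peaklist([(800.0, 100.0), (800.0 + SPACING, 100.0)], 1))
        b = detect_doublets(peaklist([(2000.0, 100.0), (2000.0 + SPACING, 100.0)], 2))
        merged = merge_doublets([a, b])
        assert merged[0].cluster_id != merged[1].cluster_id

    def test_merge_empty(self):
        assert merge_doublets([]) == []

    def test_match_within_tolerance_only(self):
        cands = enumerate_type2(
            [make_peptide("TKVER", 172), make_peptide("KVIDVQIQ", 177, protein_id="q")]
        )
        pl = peaklist([(1711.995, 800.0), (1711.995 + SPACING, 780.0)])
        doublets = detect_doublets(pl)
        matches = match_doublets(doublets, cands, 50.0)
        assert matches and all(abs(m.precursor_error_ppm) <= 50 for m in matches)
        assert match_doublets(doublets, [], 50.0) == []
        # 0.1 ppm tolerance vs a ~0.1 mDa offset: no match
        tight = match_doublets(doublets, cands, 0.01)
        assert tight == []


class TestInclusionList:
    def _matches(self):
        cands = enumerate_type2(
            [make_peptide("TKVER", 172), make_peptide("KVIDVQIQ", 177, protein_id="q")]
        )
        pl = peaklist([(1711.995, 800.0), (1711.995 + SPACING, 780.0)])
        return match_doublets(detect_doublets(pl), cands, 50.0)

    def test_rows_use_light_mass(self, tmp_path):
        frame = write_inclusion_list(self._matches(), tmp_path / "inc.tsv")
        assert len(frame) == 1
        assert frame.loc[0, "mz_light"] == pytest.approx(1711.995)
        assert (tmp_path / "inc.tsv").exists()

    def test_no_matches_header_only(self, tmp_path):
        frame = write_inclusion_list([], tmp_path / "inc.tsv")
        assert len(frame) == 0
        header = (tmp_path / "inc.tsv").read_text().splitlines()[0]
        assert "mz_light" in header

    def test_multiple_candidates_one_row(self):
        matches = self._matches()
        if len(matches) < 2:  # build an artificial second candidate match
            matches = matches * 2
        frame = inclusion_list(matches)
        assert len(frame) == 1
        assert ";" in frame.loc[0, "candidates"] or len(set(
            m.candidate.label for m in matches)) == 1

    def test_inclusion_masses_subset_of_doublets(self, shsp_candidates, rng):
        mz = np.sort(rng.uniform(600, 4000, 200))
        pl = PeakList(1, mz, np.full(200, 100.0))
        doublets = detect_doublets(pl, spacing_mode="free",
                                   search_tolerance_ppm=100,
                                   max_intensity_parameter=None)
        matches = match_doublets(doublets, shsp_candidates, 100.0)
        lights = {round(d.mz_light, 4) for d in doublets}
        assert all(row in lights for row in inclusion_list(matches)["mz_light"])


def test_funnel_counts_monotone(shsp_candidates, rng):
    mz = np.sort(rng.uniform(600, 4000, 300))
    pl = PeakList(1, mz, rng.lognormal(5, 0.8, 300))
    counts = funnel_counts([pl], shsp_candidates)
    assert (
        counts["no_restriction"]
        >= counts["spacing_20ppm"]
        >= counts["spacing_7ppm"]
        >= counts["spacing_7ppm_intensity"]
    )
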