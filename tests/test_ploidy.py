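"""Minor-allele fraction spectra, peak detection, ploidy assignment."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import clonekit as ck
from clonekit.errors import NoPeakError, SpectrumError, ValidationError
from clonekit.ploidy import Peak

from conftest import depth_table_from_counts


class TestBuildSpectrum:
    def test_exact_two_to_one_ratio_fills_single_bin(self):
        ref = np.full(50, 40)
        alt = np.full(50, 20)
        spectrum = ck.build_spectrum(depth_table_from_counts(ref, alt), ["S"])
        assert spectrum.n_loci == 50
        occupied = np.flatnonzero(spectrum.counts)
        assert len(occupied) == 1
        center = (spectrum.bin_edges[occupied[0]] + spectrum.bin_edges[occupied[0] + 1]) / 2
        assert center == pytest.approx(1 / 3, abs=0.01)

    def test_monomorphic_loci_raise(self):
        table = depth_table_from_counts(np.full(30, 60), np.zeros(30, dtype=int))
        with pytest.raises(SpectrumError):
            ck.build_spectrum(table, ["S"])

    def test_coverage_filter_respected(self):
        # halving 24x loci below the 20x floor empties the spectrum
        table = depth_table_from_counts(np.full(30, 8), np.full(30, 4))
        with pytest.raises(SpectrumError):
            ck.build_spectrum(table, ["S"], min_total=20)

    def test_unknown_sample_rejected(self):
        table = depth_table_from_counts(np.full(5, 40), np.full(5, 20))
        with pytest.raises(ValidationError, match="nope"):
            ck.build_spectrum(table, ["nope"])

    def test_matches_scalar_minor_fraction(self):
        rng = np.random.default_rng(3)
        ref = rng.integers(0, 80, size=40)
        alt = rng.integers(0, 80, size=40)
        table = depth_table_from_counts(ref, alt)
        expected = sorted(
            f for f in (
                ck.minor_fraction({1: int(r), 2: int(a)}) for r, a in zip(ref, alt)
            ) if f is not None
        )
        spectrum = ck.build_spectrum(table, ["S"])
        assert sorted(spectrum.fractions.tolist()) == pytest.approx(expected)


class TestDetectPeaks:
    def test_unimodal_pile_at_half(self):
        spectrum = ck.spectrum_from_fractions([0.5] * 200)
        peaks = ck.detect_peaks(spectrum)
        assert len(peaks) == 1
        assert peaks[0].position == pytest.approx(0.5, abs=0.01)

    def test_bimodal_piles(self):
        fractions = [0.20] * 120 + [0.40] * 80
        peaks = ck.detect_peaks(ck.spectrum_from_fractions(fractions))
        assert len(peaks) == 2
        assert peaks[0].position == pytest.approx(0.20, abs=0.01)
        assert peaks[1].position == pytest.approx(0.40, abs=0.01)
        assert peaks[0].mass_frac > peaks[1].mass_frac

    def test_flat_noise_has_no_peak(self):
        # exactly 2 % of mass in each of the 50 bins: no local maximum
        centers = (np.arange(50) + 0.5) / 100
        fractions = np.repeat(centers, 4)
        with pytest.raises(NoPeakError):
            ck.detect_peaks(ck.spectrum_from_fractions(fractions), min_mass_frac=0.10)

    def test_minor_mass_peak_is_dropped(self):
        fractions = [0.25] * 950 + [0.45] * 50  # 5 % of mass off-peak
        peaks = ck.detect_peaks(ck.spectrum_from_fractions(fractions),
                                min_mass_frac=0.10)
        assert [round(p.position, 2) for p in peaks] == [0.25]


class TestInferPloidy:
    @pytest.mark.parametrize(
        "positions,expected",
        [
            ([0.50], 2),
            ([0.33], 3),
            ([0.25], 4),
            ([0.20, 0.40], 5),
            ([0.25, 0.50], 4),
            ([1 / 6, 1 / 3, 1 / 2], 6),
        ],
    )
    def test_assigns_smallest_consistent_ploidy(self, positions, expected):
        peaks = [Peak(p, 1.0 / len(positions)) for p in positions]
        call = ck.infer_ploidy(peaks)
        assert call.ploidy == expected
        assert call.consistency

    def test_inconsistent_peaks_flagged(self):
        call = ck.infer_ploidy([Peak(0.12, 0.5), Peak(0.46, 0.5)])
        assert not call.consistency

    def test_lowest_peak_must_anchor_one_over_p(self):
        # a lone 0.4 peak cannot be pentaploid (no 1/5 companion) nor any
        # other clean ploidy: flagged inconsistent
        call = ck.infer_ploidy([Peak(0.40, 1.0)])
        assert not call.consistency

    @given(data=st.data())
    def test_consistent_calls_satisfy_allowed_set(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        n_peaks = data.draw(st.integers(1, 3))
        positions = sorted(rng.uniform(0.05, 0.5, size=n_peaks))
        call = ck.infer_ploidy([Peak(float(p), 1 / n_peaks) for p in positions],
                               tolerance=0.03)
        if call.consistency:
            allowed = ck.allowed_peak_fractions(call.ploidy)
            for pos in call.peak_positions:
                assert min(abs(pos - a) for a in allowed) <= 0.03
            assert abs(call.peak_positions[0] - 1 / call.ploidy) <= 0.03


class TestSimulationRecovery:
    @pytest.mark.parametrize("ploidy,dosage", [(2, 1), (3, 1), (4, 1), (5, 2)])
    def test_peak_centroid_matches_dosage_fraction(self, ploidy, dosage):
        """Binomial allele sampling at 100x: the detected peak centroid lies
        within 0.02 of min(d, p-d)/p."""
        rng = np.random.default_rng(900 + ploidy)
        n = 4000
        alt = rng.binomial(100, dosage / ploidy, size=n)
        spectrum = ck.build_spectrum(
            depth_table_from_counts(100 - alt, alt), ["S"])
        peaks = ck.detect_peaks(spectrum)
        target = min(dosage, ploidy - dosage) / ploidy
        best = min(peaks, key=lambda p: abs(p.position - target))
        assert abs(best.position - target) < 0.02


class TestMergeStability:
    @staticmethod
    def _clone_tables(seed, ploidies=(3, 3)):
        """Depth tables for libraries of (possibly different-ploidy) genotypes."""
        rng = np.random.default_rng(seed)
        frames = []
        cfg = ck.SimConfig(seed=seed, n_loci=1500, depth_mean=120.0)
        founders: dict[int, np.ndarray] = {}
        for k, p in enumerate(ploidies):
            if p not in founders:  # same-ploidy libraries share one genotype
                founders[p] = ck.simulate_founder(p, 1500, (0.5, 0.5), rng)
            ref, alt, _ = ck.simulate_library(founders[p], p, cfg, rng)
            frames.append(depth_table_from_counts(ref, alt, f"LIB{k}").frame)
        import pandas as pd

        return ck.DepthTable(pd.concat(frames, ignore_index=True))

    def test_clonal_libraries_are_stable(self):
        table = self._clone_tables(21, ploidies=(3, 3))
        report = ck.merge_stability(table, [["LIB0"], ["LIB1"]])
        assert report.stable
        assert report.union_peaks[0].position == pytest.approx(1 / 3, abs=0.02)
        assert report.union_n_loci >= max(report.set_n_loci)

    def test_mixed_ploidy_merge_fails(self):
        table = self._clone_tables(22, ploidies=(2, 3))
        report = ck.merge_stability(table, [["LIB0"], ["LIB1"]])
        assert not report.stable
        with pytest.raises(ck.errors.StabilityError):
            ck.merge_stability(table, [["LIB0"], ["LIB1"]], strict=True)
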