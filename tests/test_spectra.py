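"""77 K spectrum processing: unit examples, invariants, dilution QC."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import photophen.spectra as spc
from conftest import naive_pipeline_psi
from photophen.synth import SpectrumGenConfig, gen_spectrum


def _flat(value=1.0, start=650.0, stop=810.0, step=1.0):
    wl = np.arange(start, stop + 1e-9, step)
    return spc.EmissionSpectrum(wl, np.full_like(wl, value))


class TestResample:
    def test_uniform_input_identity(self):
        s = _flat(3.0)
        r = spc.resample_uniform(s, 1.0)
        assert np.allclose(r.intensity, 3.0) and len(r.wavelength_nm) == len(s.wavelength_nm)

    def test_linear_midpoint(self):
        s = spc.EmissionSpectrum(np.array([700.0, 702.0]), np.array([0.0, 2.0]))
        r = spc.resample_uniform(s, 1.0)
        assert r.intensity[1] == pytest.approx(1.0)

    def test_non_monotone_wavelengths_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            spc.EmissionSpectrum(np.array([700.0, 699.0, 701.0]), np.zeros(3))

    def test_never_extrapolates(self):
        s = _flat()
        r = spc.resample_uniform(s, 0.7)
        assert r.wavelength_nm[0] >= s.wavelength_nm[0] - 1e-12
        assert r.wavelength_nm[-1] <= s.wavelength_nm[-1] + 1e-12


class TestSmooth:
    def test_constant_unchanged(self):
        s = spc.resample_uniform(_flat(5.0), 1.0)
        assert np.allclose(spc.smooth_running_average(s).intensity, 5.0)

    def test_unit_impulse_spreads_to_fifth(self):
        wl = np.arange(650.0, 811.0, 1.0)
        y = np.zeros_like(wl)
        y[80] = 1.0
        s = spc.EmissionSpectrum(wl, y, provenance=("resample",))
        sm = spc.smooth_running_average(s, window_nm=4.0)
        # +-2 nm inclusive window on a 1 nm grid: five points share the mass
        assert np.allclose(sm.intensity[78:83], 0.2)
        assert sm.intensity[77] == 0.0 and sm.intensity[83] == 0.0

    def test_window_below_step_rejected(self):
        s = spc.resample_uniform(_flat(), 2.0)
        with pytest.raises(ValueError, match="grid step"):
            spc.smooth_running_average(s, window_nm=1.0)

    def test_truncated_edges_preserve_constants(self):
        wl = np.arange(650.0, 811.0, 1.0)
        y = np.linspace(0.0, 1.0, len(wl))
        s = spc.EmissionSpectrum(wl, y, provenance=("resample",))
        sm = spc.smooth_running_average(s, window_nm=4.0)
        # a linear ramp is preserved in the interior, edge means are truncated
        assert np.allclose(sm.intensity[2:-2], y[2:-2])


class TestBaseline:
    def test_additive_shift_removed_exactly(self):
        wl = np.arange(650.0, 811.0, 1.0)
        y = np.exp(-0.5 * ((wl - 685.0) / 6.0) ** 2)
        s0 = spc.EmissionSpectrum(wl, y)
        s10 = spc.EmissionSpectrum(wl, y + 10.0)
        b0 = spc.subtract_baseline(s0)
        b10 = spc.subtract_baseline(s10)
        assert np.allclose(b0.intensity, b10.intensity, atol=1e-12)

    def test_hand_mean_on_toy_window(self):
        wl = np.array([650.0, 798.0, 799.0, 800.0, 801.0, 802.0])
        y = np.array([100.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        b = spc.subtract_baseline(spc.EmissionSpectrum(wl, y))
        assert b.intensity[0] == pytest.approx(100.0 - 3.0)

    def test_grid_short_of_800_rejected(self):
        wl = np.arange(650.0, 791.0, 1.0)
        with pytest.raises(ValueError, match="800"):
            spc.subtract_baseline(spc.EmissionSpectrum(wl, np.ones_like(wl)))

    def test_negatives_permitted_not_clamped(self):
        wl = np.arange(650.0, 811.0, 1.0)
        y = np.where(wl < 700, 0.0, 10.0)
        b = spc.subtract_baseline(spc.EmissionSpectrum(wl, y))
        assert b.intensity.min() < 0


class TestNormalize:
    def _gauss(self, amp=50.0):
        wl = np.arange(650.0, 811.0, 1.0)
        y = amp * np.exp(-0.5 * ((wl - 685.0) / 6.0) ** 2)
        return spc.EmissionSpectrum(wl, y, provenance=("resample", "smooth", "baseline"))

    def test_divides_by_window_max(self):
        p = spc.normalize_to_psii(self._gauss(50.0))
        mask = (p.wavelength_nm >= 680) & (p.wavelength_nm <= 690)
        assert p.intensity[mask].max() == pytest.approx(1.0, abs=1e-12)
        assert p.psii_peak_nm == pytest.approx(685.0)

    def test_tie_breaks_toward_shorter_wavelength(self):
        wl = np.arange(650.0, 811.0, 1.0)
        y = np.zeros_like(wl)
        y[(wl == 683.0) | (wl == 687.0)] = 7.0
        s = spc.EmissionSpectrum(wl, y, provenance=("baseline",))
        assert spc.normalize_to_psii(s).psii_peak_nm == 683.0

    def test_all_zero_spectrum_rejected(self):
        wl = np.arange(650.0, 811.0, 1.0)
        s = spc.EmissionSpectrum(wl, np.zeros_like(wl), provenance=("baseline",))
        with pytest.raises(ValueError, match="non-positive"):
            spc.normalize_to_psii(s)

    def test_requires_prior_baseline(self):
        with pytest.raises(ValueError, match="baseline"):
            spc.normalize_to_psii(_flat())

    def test_baseline_after_normalize_rejected(self):
        p = spc.normalize_to_psii(self._gauss())
        s = spc.EmissionSpectrum(p.wavelength_nm, p.intensity + 1.0, provenance=p.provenance)
        with pytest.raises(ValueError, match="precede"):
            spc.subtract_baseline(s)

    def test_normalization_idempotent(self):
        p1 = spc.normalize_to_psii(self._gauss())
        again = spc.EmissionSpectrum(
            p1.wavelength_nm, p1.intensity, provenance=("resample", "smooth", "baseline")
        )
        p2 = spc.normalize_to_psii(again)
        assert np.allclose(p1.intensity, p2.intensity, atol=1e-12)


class TestPsiStatistic:
    def test_psii_only_gaussian_tail_matches_oracle(self):
        """With no PSI band the statistic is just the smoothed PSII tail in
        the 710-730 nm window; frozen from the loop-based oracle."""
        cfg = SpectrumGenConfig(
            band_centers_nm=(685.0,),
            band_sigmas_nm=(6.0,),
            band_amplitudes=(1.0,),
            baseline_offset=0.0,
        )
        s, _ = gen_spectrum(cfg)
        value, wl, has_peak = spc.psi_statistic(spc.process_spectrum(s))
        assert value == pytest.approx(0.0002452524037927184, rel=1e-9)
        assert wl == pytest.approx(710.0)
        assert not has_peak  # monotone tail: no local PSI maximum

    def test_two_band_statistic_matches_frozen_oracle(self):
        cfg = SpectrumGenConfig(
            band_centers_nm=(685.0, 715.0),
            band_sigmas_nm=(6.0, 10.0),
            band_amplitudes=(1.0, 0.5),
            baseline_offset=0.0,
        )
        s, _ = gen_spectrum(cfg)
        value, _, has_peak = spc.psi_statistic(spc.process_spectrum(s))
        assert value == pytest.approx(0.5043189447611858, rel=1e-9)
        assert has_peak

    def test_flat_normalized_spectrum_gives_one(self):
        wl = np.arange(650.0, 811.0, 0.5)
        p = spc.ProcessedSpectrum(wl, np.ones_like(wl), psii_peak_nm=685.0)
        value, _, _ = spc.psi_statistic(p)
        assert value == 1.0

    def test_state2_statistic_exceeds_state1(self):
        cfg = SpectrumGenConfig(noise_sd=0.0)
        s1, _ = gen_spectrum(cfg, state="state1")
        s2, _ = gen_spectrum(cfg, state="state2")
        v1 = spc.psi_statistic(spc.process_spectrum(s1))[0]
        v2 = spc.psi_statistic(spc.process_spectrum(s2))[0]
        assert v2 > v1

    @given(k=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_invariance(self, k):
        cfg = SpectrumGenConfig(baseline_offset=0.0, noise_sd=0.0)
        s, _ = gen_spectrum(cfg)
        scaled = spc.EmissionSpectrum(s.wavelength_nm, s.intensity * k)
        v = spc.psi_statistic(spc.process_spectrum(s))[0]
        vk = spc.psi_statistic(spc.process_spectrum(scaled))[0]
        assert vk == pytest.approx(v, abs=1e-12)

    def test_monotone_in_psi_band_amplitude(self):
        values = []
        for amp in (100.0, 300.0, 600.0, 900.0):
            cfg = SpectrumGenConfig(band_amplitudes=(1000.0, 550.0, amp), noise_sd=0.0)
            s, _ = gen_spectrum(cfg)
            values.append(spc.psi_statistic(spc.process_spectrum(s))[0])
        assert all(np.diff(values) > 0)

    def test_full_pipeline_matches_naive_oracle_on_band_mixtures(self):
        """Vectorised pipeline vs plain-loop evaluation: <= 1e-9 relative."""
        for amps in [(1000.0, 550.0, 450.0), (800.0, 300.0, 900.0)]:
            cfg = SpectrumGenConfig(band_amplitudes=amps, baseline_offset=40.0, noise_sd=0.0)
            s, _ = gen_spectrum(cfg)
            got = spc.psi_statistic(spc.process_spectrum(s))[0]
            want = naive_pipeline_psi(
                cfg.band_centers_nm, cfg.band_sigmas_nm, amps, offset=40.0
            )
            assert got == pytest.approx(want, rel=1e-9)


class TestDilutionQC:
    def _processed(self, c, dilution, sample_id="rep1", seed=0):
        cfg = SpectrumGenConfig(self_absorption_strength=c, noise_sd=0.0, seed=seed)
        s, _ = gen_spectrum(cfg)
        s.meta.update({"sample_id": sample_id, "dilution_percent": dilution})
        return spc.process_spectrum(s)

    def test_distorted_100_agreeing_50_25_selects_50(self):
        series = [
            self._processed(0.5, 100),
            self._processed(0.02, 50),
            self._processed(0.0, 25),
        ]
        out = spc.qc_select_dilution(series)
        assert out.selected_dilution == 50
        assert not out.flags

    def test_all_agree_selects_100(self):
        series = [self._processed(0.0, d) for d in (100, 50, 25)]
        assert spc.qc_select_dilution(series).selected_dilution == 100

    def test_none_agree_selects_most_dilute_above_floor_with_warning(self):
        series = [self._processed(c, d) for c, d in ((1.0, 100), (0.5, 50), (0.25, 25))]
        out = spc.qc_select_dilution(series, noise_floor=1.0)
        assert out.selected_dilution == 25
        assert "self_absorption_warning" in out.flags

    def test_single_dilution_flagged_unverified(self):
        out = spc.qc_select_dilution([self._processed(0.0, 100)])
        assert out.selected_dilution == 100
        assert "unverified" in out.flags

    def test_mixed_sample_ids_rejected(self):
        series = [
            self._processed(0.0, 100, sample_id="a"),
            self._processed(0.0, 50, sample_id="b"),
        ]
        with pytest.raises(ValueError, match="sample ids"):
            spc.qc_select_dilution(series)


class TestCompareStates:
    def test_identical_groups_not_significant(self):
        g = [0.4, 0.4, 0.4, 0.4]
        out = spc.compare_states(g, g)
        assert out.p_value == 1.0 and not out.significant and out.effect == 0.0

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            spc.compare_states([0.4], [0.5])

    def test_doubled_psi_amplitude_detected(self, rng):
        """State-2 spectra (PSI band x2, small noise, n=5/group) separate
        from state-1 spectra at alpha = 0.05."""
        vals = {"state1": [], "state2": []}
        for state in vals:
            for i in range(5):
                cfg = SpectrumGenConfig(noise_sd=10.0, seed=int(rng.integers(2**31)))
                s, _ = gen_spectrum(cfg, state=state)
                vals[state].append(spc.psi_statistic(spc.process_spectrum(s))[0])
        out = spc.compare_states(vals["state1"], vals["state2"])
        assert out.significant
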