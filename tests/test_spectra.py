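import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vcdfit import (
    BroadeningConfig,
    ConformerRecord,
    ContinuousSpectrum,
    Ensemble,
    RegionMask,
    StickSpectrum,
    apply_mask,
    broaden,
    optimize_scaling,
    read_conformer_ensemble,
    read_experimental_spectrum,
    scale_frequencies,
    write_ensemble,
    write_spectrum,
)
from vcdfit.spectra import SpectrumFormatError
from vcdfit.weighting import boltzmann_weights, composite_spectrum


class TestStickSpectrum:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            StickSpectrum([1000.0], [1.0, 2.0], [0.1])  # unequal lengths
        with pytest.raises(ValueError):
            StickSpectrum([-5.0], [1.0], [0.1])  # non-positive frequency
        with pytest.raises(ValueError):
            StickSpectrum([1000.0], [-1.0], [0.1])  # negative dipole strength

    def test_scaling_moves_frequencies_only(self):
        s = StickSpectrum([1000.0, 1500.0], [1.0, 2.0], [0.1, -0.2])
        out = scale_frequencies(s, 0.98)
        assert np.allclose(out.frequencies, [980.0, 1470.0])
        assert np.array_equal(out.dipole_strengths, s.dipole_strengths)
        assert np.array_equal(out.rotational_strengths, s.rotational_strengths)
        assert scale_frequencies(s, 1.0) is not s
        assert np.array_equal(scale_frequencies(s, 1.0).frequencies, s.frequencies)

    @pytest.mark.parametrize("factor", [0.89, 1.2])
    def test_scaling_bounds(self, factor):
        s = StickSpectrum([1000.0], [1.0], [0.1])
        with pytest.raises(ValueError):
            scale_frequencies(s, factor)


class TestBroadening:
    def test_empty_sticks_give_zero_spectrum(self, broadening):
        out = broaden(StickSpectrum([], [], []), "VCD", broadening)
        assert np.all(out.values == 0.0)

    def test_unit_mode_peak_height_and_area(self):
        # peak of a unit-strength Lorentzian is 2/(pi*Gamma); its integral is 1
        cfg = BroadeningConfig(fwhm=8.0, grid_lo=800.0, grid_hi=1600.0, grid_step=1.0)
        out = broaden(StickSpectrum([1200.0], [1.0], [1.0]), "VA", cfg)
        peak = out.values[np.argmax(out.values)]
        assert out.grid[np.argmax(out.values)] == 1200.0
        assert peak == pytest.approx(2.0 / (np.pi * 8.0), rel=1e-6)
        area = np.trapezoid(out.values, out.grid)
        assert area == pytest.approx(1.0, abs=0.01)

    def test_area_equals_sum_of_strengths(self):
        # grid extends far beyond the modes: integral conserves total strength
        cfg = BroadeningConfig(fwhm=8.0, grid_lo=300.0, grid_hi=2400.0, grid_step=1.0)
        sticks = StickSpectrum([1000.0, 1100.0, 1350.0], [2.0, 0.5, 1.5], [1.0, -1.0, 0.5])
        va = broaden(sticks, "VA", cfg)
        vcd = broaden(sticks, "VCD", cfg)
        assert np.trapezoid(va.values, va.grid) == pytest.approx(4.0, rel=0.01)
        assert np.trapezoid(vcd.values, vcd.grid) == pytest.approx(0.5, rel=0.05)

    @given(c=st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_linearity_in_strengths(self, c):
        cfg = BroadeningConfig()
        base = StickSpectrum([1100.0, 1300.0], [1.0, 2.0], [0.5, -0.5])
        scaled = StickSpectrum([1100.0, 1300.0], [c, 2 * c], [0.5 * c, -0.5 * c])
        a = broaden(base, "VCD", cfg).values
        b = broaden(scaled, "VCD", cfg).values
        assert np.allclose(b, c * a, rtol=1e-10, atol=1e-12)

    def test_grid_must_resolve_lineshape(self):
        with pytest.raises(ValueError):
            BroadeningConfig(fwhm=8.0, grid_step=3.0)


class TestRegionMask:
    def test_full_range_mask_is_identity(self, broadening):
        spec = ContinuousSpectrum(broadening.grid(), np.ones(len(broadening.grid())))
        out = apply_mask(spec, RegionMask([(900.0, 1701.0)]))
        assert np.array_equal(out.grid, spec.grid)

    def test_exclusion_of_interval(self, broadening):
        # mid-IR fit excluding a structurally dynamic region
        mask = RegionMask.excluding([(1200.0, 1400.0)], (900.0, 1701.0))
        spec = ContinuousSpectrum(broadening.grid(), np.ones(len(broadening.grid())))
        out = apply_mask(spec, mask)
        assert not np.any((out.grid >= 1200.0) & (out.grid < 1400.0))
        assert np.any(out.grid < 1200.0) and np.any(out.grid >= 1400.0)

    def test_mask_outside_grid_errors(self, broadening):
        spec = ContinuousSpectrum(broadening.grid(), np.ones(len(broadening.grid())))
        with pytest.raises(ValueError):
            apply_mask(spec, RegionMask([(5000.0, 6000.0)]))

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError):
            RegionMask([(900.0, 1200.0), (1100.0, 1300.0)])

    def test_mask_idempotent(self, broadening):
        mask = RegionMask([(1000.0, 1100.0)])
        spec = ContinuousSpectrum(broadening.grid(), np.arange(len(broadening.grid()), dtype=float))
        once = apply_mask(spec, mask)
        twice = apply_mask(once, mask)
        assert np.array_equal(once.grid, twice.grid)
        assert np.array_equal(once.values, twice.values)

    def test_parse_syntax(self):
        mask = RegionMask.parse("900:1200,1400:1700")
        assert mask.intervals == ((900.0, 1200.0), (1400.0, 1700.0))


class TestSpectrumIO:
    def test_two_column_roundtrip(self, tmp_path, broadening):
        rng = np.random.default_rng(0)
        spec = ContinuousSpectrum(broadening.grid(), rng.normal(size=len(broadening.grid())))
        path = tmp_path / "s.dat"
        write_spectrum(spec, path)
        back = read_experimental_spectrum(path, "VCD", broadening)
        assert np.allclose(back.values, spec.values, rtol=1e-10)

    def test_interpolation_reproduces_given_points(self, tmp_path):
        cfg = BroadeningConfig(grid_lo=1000.0, grid_hi=1004.0, grid_step=1.0)
        (tmp_path / "p.dat").write_text(
            "1000 1.0\n1001 2.0\n1002 3.0\n1003 2.0\n1004 1.0\n"
        )
        out = read_experimental_spectrum(tmp_path / "p.dat", "VA", cfg)
        assert np.allclose(out.values, [1.0, 2.0, 3.0, 2.0, 1.0])

    def test_descending_order_sorted_on_load(self, tmp_path, broadening):
        up = "\n".join(f"{x} {x / 1000.0}" for x in range(950, 1651, 5))
        down = "\n".join(reversed(up.splitlines()))
        (tmp_path / "up.dat").write_text(up)
        (tmp_path / "down.dat").write_text(down)
        a = read_experimental_spectrum(tmp_path / "up.dat", "VA", broadening)
        b = read_experimental_spectrum(tmp_path / "down.dat", "VA", broadening)
        assert np.array_equal(a.values, b.values)

    def test_points_outside_range_flagged_unmeasured(self, tmp_path, broadening):
        (tmp_path / "narrow.dat").write_text("1100 1.0\n1200 1.0\n1300 1.0\n")
        out = read_experimental_spectrum(tmp_path / "narrow.dat", "VA", broadening)
        assert out.measured is not None
        assert not out.measured[out.grid < 1100.0].any()
        assert out.measured[(out.grid >= 1100.0) & (out.grid <= 1300.0)].all()
        assert np.all(out.values[~out.measured] == 0.0)

    def test_too_few_points_rejected(self, tmp_path):
        (tmp_path / "one.dat").write_text("1100 1.0\n")
        with pytest.raises(SpectrumFormatError):
            read_experimental_spectrum(tmp_path / "one.dat")

    def test_jcamp_xydata_block(self, tmp_path):
        cfg = BroadeningConfig(grid_lo=1000.0, grid_hi=1004.0, grid_step=1.0)
        (tmp_path / "j.jdx").write_text(
            "##TITLE=test\n##JCAMP-DX=4.24\n##XUNITS=1/CM\n##YUNITS=ABSORBANCE\n"
            "##XFACTOR=1.0\n##YFACTOR=0.5\n##FIRSTX=1000\n##LASTX=1004\n"
            "##NPOINTS=5\n##DELTAX=1\n##XYDATA=(X++(Y..Y))\n"
            "1000 2.0 4.0 6.0\n1003 4.0 2.0\n##END=\n"
        )
        out = read_experimental_spectrum(tmp_path / "j.jdx", "VA", cfg)
        assert np.allclose(out.values, [1.0, 2.0, 3.0, 2.0, 1.0])

    def test_jcamp_xypoints_block(self, tmp_path):
        cfg = BroadeningConfig(grid_lo=1000.0, grid_hi=1002.0, grid_step=1.0)
        (tmp_path / "j.jdx").write_text(
            "##TITLE=test\n##XYPOINTS=(XY..XY)\n1000, 1.0; 1001, 2.0; 1002, 3.0\n##END=\n"
        )
        out = read_experimental_spectrum(tmp_path / "j.jdx", "VCD", cfg)
        assert np.allclose(out.values, [1.0, 2.0, 3.0])


class TestEnsembleIO:
    def test_energies_min_shifted(self, tmp_path):
        s = StickSpectrum([1000.0], [1.0], [0.1])
        ens = Ensemble(
            [ConformerRecord("x", 2.0, s), ConformerRecord("y", 1.0, s), ConformerRecord("z", 3.0, s)]
        )
        assert np.allclose(ens.energies, [1.0, 0.0, 2.0])

    def test_duplicate_ids_rejected(self):
        s = StickSpectrum([1000.0], [1.0], [0.1])
        with pytest.raises(ValueError, match="c1"):
            Ensemble([ConformerRecord("c1", 0.0, s), ConformerRecord("c1", 1.0, s)])

    def test_manifest_roundtrip(self, tmp_path, noisy_synth):
        ensemble = noisy_synth[0]
        manifest = write_ensemble(ensemble, tmp_path / "ens")
        back = read_conformer_ensemble(manifest)
        assert back.ids == ensemble.ids
        assert np.allclose(back.energies, ensemble.energies, rtol=1e-10)
        for a, b in zip(back, ensemble):
            assert np.allclose(a.sticks.frequencies, b.sticks.frequencies, rtol=1e-10)
            assert np.allclose(a.sticks.rotational_strengths, b.sticks.rotational_strengths, rtol=1e-10)

    def test_missing_stick_file_reported(self, tmp_path):
        (tmp_path / "manifest.csv").write_text("id,energy_kcal,sticks_path\nc1,0.0,missing.sticks\n")
        with pytest.raises(SpectrumFormatError, match="missing.sticks"):
            read_conformer_ensemble(tmp_path / "manifest.csv")

    def test_single_conformer_ensemble(self):
        s = StickSpectrum([1000.0], [1.0], [0.1])
        ens = Ensemble([ConformerRecord("only", 7.3, s)])
        assert len(ens) == 1 and ens.energies[0] == 0.0


class TestFrequencyScaling:
    def test_self_match_returns_unity(self, clean_synth):
        ensemble, truth, exp_va, _ = clean_synth
        w = boltzmann_weights(truth.true_energies)
        f = optimize_scaling(truth.true_ensemble, w, exp_va, bounds=(0.98, 1.02), step=0.001)
        assert f == pytest.approx(1.0, abs=1e-9)

    def test_recovers_applied_scaling(self, clean_synth):
        ensemble, truth, exp_va, _ = clean_synth
        w = boltzmann_weights(truth.true_energies)
        shrunk = truth.true_ensemble.scaled(0.98)
        f = optimize_scaling(shrunk, w, exp_va, bounds=(0.98, 1.05), step=0.001)
        # compensating factor on the search grid, within one grid step
        assert f == pytest.approx(1.0 / 0.98, abs=0.0015)

    def test_scaling_requires_va_spectrum(self, clean_synth):
        ensemble, truth, _, exp_vcd = clean_synth
        w = boltzmann_weights(truth.true_energies)
        with pytest.raises(ValueError, match="VA"):
            optimize_scaling(ensemble, w, exp_vcd)
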