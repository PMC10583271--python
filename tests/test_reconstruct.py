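"""DFT processing chain, IST reconstruction, size rule, external scripts."""

import os
import stat
import sys

import numpy as np
import pytest

from nusbench import (
    ChallengeConfig,
    DimensionProcessing,
    IstParams,
    ParameterError,
    ScriptError,
    ValidationError,
    check_spectrum_size,
    expand_to_grid,
    gen_schedule,
    next_power_of_two,
    process_dft,
    reconstruct_ist,
    run_external_reconstruction,
    simulate_fid,
    subsample,
    write_challenge_config,
    write_nus,
    write_schedule,
    write_spectrum,
)
from nusbench.core_model import AcquisitionScheme, DimensionSpec
from nusbench.simulate import make_synthetic_reference
from conftest import plain_processing, single_peak_table


class TestProcessDft:
    def test_zero_fill_halves_hz_per_point(self, acq2d):
        cfg0 = ChallengeConfig("t", acq2d, processing=tuple(
            DimensionProcessing(apod_power=0, zero_fill=0) for _ in acq2d.dims))
        cfg1 = ChallengeConfig("t", acq2d, processing=tuple(
            DimensionProcessing(apod_power=0, zero_fill=1) for _ in acq2d.dims))
        fid = simulate_fid(single_peak_table(acq2d, (300.0, 175.0), (20.0, 10.0)), acq2d)
        s0, s1 = process_dft(fid, cfg0), process_dft(fid, cfg1)
        for a0, a1 in zip(s0.axes, s1.axes):
            assert a1.hz_per_point == pytest.approx(a0.hz_per_point / 2)
        assert s1.shape == tuple(2 * n for n in s0.shape)

    def test_roi_extraction(self, acq2d):
        cfg = ChallengeConfig("t", acq2d, direct_roi_ppm=(7.0, 9.0),
                              processing=plain_processing(acq2d))
        fid = simulate_fid(single_peak_table(acq2d, (0.0, 0.0)), acq2d)
        spec = process_dft(fid, cfg)
        ppm = np.asarray(spec.axes[0].ppm(np.arange(spec.shape[0])))
        assert ppm.max() <= 9.0 and ppm.min() >= 7.0
        assert spec.provenance["direct_size_pre_roi"] == 64
        assert spec.shape[0] < 64

    def test_axes_monotone_decreasing_ppm(self, acq2d, config2d_plain):
        fid = simulate_fid(single_peak_table(acq2d, (0.0, 0.0)), acq2d)
        spec = process_dft(fid, config2d_plain)
        for ax in spec.axes:
            ppm = np.asarray(ax.ppm(np.arange(ax.size)))
            assert np.all(np.diff(ppm) < 0)


class TestIst:
    def test_full_sampling_matches_dft(self, acq2d, config2d_plain):
        ref, _ = make_synthetic_reference(acq2d, 5, seed=3, noise_sigma=0.02)
        full = gen_schedule((64,), 64, [0.0], [1600.0], seed=0)
        res = reconstruct_ist(subsample(ref, full), config=config2d_plain,
                              params=IstParams(iterations=20))
        dft = process_dft(ref, config2d_plain)
        rel = (np.max(np.abs(res.spectrum.values - dft.values))
               / np.max(np.abs(dft.values)))
        assert rel < 1e-6

    def test_full_sampling_matches_dft_3d(self, acq3d, config3d_plain):
        ref, _ = make_synthetic_reference(acq3d, 4, seed=5, noise_sigma=0.02)
        full = gen_schedule((16, 20), 320, [0.0, 0.0], [1600.0, 4000.0], seed=0)
        res = reconstruct_ist(subsample(ref, full), config=config3d_plain,
                              params=IstParams(iterations=8))
        dft = process_dft(ref, config3d_plain)
        rel = (np.max(np.abs(res.spectrum.values - dft.values))
               / np.max(np.abs(dft.values)))
        assert rel < 1e-6

    def test_data_replacement_exit_restores_measured_exactly(self, acq2d, config2d_plain):
        fid = simulate_fid(single_peak_table(acq2d, (300.0, 175.0), (20.0, 0.0),
                                             amplitude=3.0), acq2d)
        sched = gen_schedule((64,), 32, [0.0], [1600.0], seed=7)
        res = reconstruct_ist(subsample(fid, sched), config=config2d_plain,
                              params=IstParams(iterations=50, exit_mode="data_replacement"))
        # inverse transform of the returned frequency-domain reconstruction
        time_back = np.fft.ifftn(res.freq_grids, axes=(2,))
        at_indels = time_back[(slice(None), slice(None)) + sched.index_arrays()]
        scale = np.abs(res.measured).max()
        assert np.max(np.abs(at_indels - res.measured)) < 1e-10 * scale

    def test_post_threshold_exit_differs_at_measured_points(self, acq2d, config2d_plain):
        fid = simulate_fid(single_peak_table(acq2d, (300.0, 175.0), (20.0, 15.0),
                                             amplitude=3.0), acq2d)
        sched = gen_schedule((64,), 16, [15.0], [1600.0], seed=7)
        res = reconstruct_ist(subsample(fid, sched), config=config2d_plain,
                              params=IstParams(iterations=50, exit_mode="post_threshold"))
        at_indels = res.time_grids[(slice(None), slice(None)) + sched.index_arrays()]
        assert np.max(np.abs(at_indels - res.measured)) > 1e-8 * np.abs(res.measured).max()

    def test_threshold_zero_one_iteration_is_zero_filled_dft(self, acq2d, config2d_plain):
        fid = simulate_fid(single_peak_table(acq2d, (300.0, 175.0), (20.0, 15.0)), acq2d)
        sched = gen_schedule((64,), 20, [15.0], [1600.0], seed=1)
        nus = subsample(fid, sched)
        res = reconstruct_ist(nus, config=config2d_plain,
                              params=IstParams(iterations=1, threshold_start=0.0,
                                               threshold_floor=0.0,
                                               exit_mode="post_threshold"))
        expanded, _ = expand_to_grid(nus)
        zf_dft = process_dft(expanded, config2d_plain)
        assert np.allclose(res.spectrum.values, zf_dft.values, atol=1e-9)

    def test_residual_at_indels_non_increasing(self, acq2d, config2d_plain):
        fid = simulate_fid(single_peak_table(acq2d, (300.0, 175.0), (20.0, 0.0),
                                             amplitude=3.0), acq2d)
        sched = gen_schedule((64,), 24, [0.0], [1600.0], seed=3)
        nus = subsample(fid, sched)
        idx = (slice(None), slice(None)) + sched.index_arrays()
        residuals = []
        for iters in (1, 5, 20, 60):
            res = reconstruct_ist(nus, config=config2d_plain,
                                  params=IstParams(iterations=iters,
                                                   exit_mode="post_threshold"))
            residuals.append(np.max(np.abs(res.time_grids[idx] - res.measured)))
        assert all(b <= a * (1 + 1e-9) for a, b in zip(residuals, residuals[1:]))

    def test_invalid_params(self):
        with pytest.raises(ParameterError):
            IstParams(iterations=0)
        with pytest.raises(ParameterError):
            IstParams(exit_mode="whenever")


class TestSizeRule:
    def test_limit_arithmetic_44(self, config2d_plain, acq2d):
        # 44 -> next power of two 64, times 2^3 = 512
        assert next_power_of_two(44) * 8 == 512
        assert next_power_of_two(64) * 8 == 512

    def test_boundary_inclusive(self, acq2d):
        from nusbench import AxisCalibration, Spectrum

        def spec_of(n_direct, n_ind):
            axes = (
                AxisCalibration(n_direct, 0.0, 1.0, 600.0),
                AxisCalibration(n_ind, 0.0, 1.0, 60.0),
            )
            return Spectrum(values=np.zeros((n_direct, n_ind)), axes=axes)

        limit = next_power_of_two(64) * 8  # = 512 for both dims here
        assert check_spectrum_size(spec_of(512, 512), acq2d).passed
        assert not check_spectrum_size(spec_of(512, 1024), acq2d).passed

    def test_pre_roi_direct_size_used(self, acq2d):
        cfg = ChallengeConfig("t", acq2d, direct_roi_ppm=(7.5, 8.5),
                              processing=tuple(
                                  DimensionProcessing(apod_power=0, zero_fill=3)
                                  for _ in acq2d.dims))
        fid = simulate_fid(single_peak_table(acq2d, (0.0, 0.0)), acq2d)
        spec = process_dft(fid, cfg)
        check = check_spectrum_size(spec, acq2d)
        assert check.sizes[0] == 512  # 64 * 2^3 before ROI extraction
        assert check.passed


class TestExternalScripts:
    def _inputs(self, tmp_path, acq2d, config2d_plain):
        fid = simulate_fid(single_peak_table(acq2d, (300.0, 175.0), (20.0, 0.0),
                                             amplitude=2.0), acq2d)
        sched = gen_schedule((64,), 32, [0.0], [1600.0], seed=1)
        nus = subsample(fid, sched)
        nus_file = tmp_path / "nus.nusb"
        sched_file = tmp_path / "sched.txt"
        cfg_file = tmp_path / "config.json"
        write_nus(nus_file, nus)
        write_schedule(sched_file, sched)
        write_challenge_config(cfg_file, config2d_plain)
        return nus, nus_file, sched_file, cfg_file

    def _script(self, tmp_path, body: str):
        path = tmp_path / "recon.py"
        path.write_text(f"#!{sys.executable}\n{body}")
        path.chmod(path.stat().st_mode | stat.S_IXUSR)
        return path

    def test_script_calling_builtin_ist_matches_direct_call(
            self, tmp_path, acq2d, config2d_plain):
        nus, nus_file, sched_file, cfg_file = self._inputs(tmp_path, acq2d, config2d_plain)
        script = self._script(tmp_path, (
            "import sys\n"
            "from nusbench import read_nus, read_challenge_config, reconstruct_ist, "
            "IstParams, write_spectrum\n"
            "nus = read_nus(sys.argv[1])\n"
            "config = read_challenge_config(sys.argv[3])\n"
            "res = reconstruct_ist(nus, config=config, params=IstParams(iterations=30))\n"
            "write_spectrum(sys.argv[4], res.spectrum)\n"
        ))
        spec = run_external_reconstruction(script, nus_file, sched_file, cfg_file,
                                           tmp_path / "run", acq2d)
        direct = reconstruct_ist(nus, config=config2d_plain,
                                 params=IstParams(iterations=30)).spectrum
        assert np.allclose(spec.values, direct.values)

    def test_oversized_spectrum_rejected(self, tmp_path, acq2d, config2d_plain):
        _, nus_file, sched_file, cfg_file = self._inputs(tmp_path, acq2d, config2d_plain)
        script = self._script(tmp_path, (
            "import sys, numpy as np\n"
            "from nusbench import AxisCalibration, Spectrum, write_spectrum\n"
            "axes = (AxisCalibration(1024, 0.0, 1.0, 600.0),"
            " AxisCalibration(64, 0.0, 1.0, 60.0))\n"
            "write_spectrum(sys.argv[4], Spectrum(np.zeros((1024, 64)), axes))\n"
        ))
        with pytest.raises(ValidationError, match="exceeds"):
            run_external_reconstruction(script, nus_file, sched_file, cfg_file,
                                        tmp_path / "run", acq2d)

    def test_nonzero_exit_is_script_error(self, tmp_path, acq2d, config2d_plain):
        _, nus_file, sched_file, cfg_file = self._inputs(tmp_path, acq2d, config2d_plain)
        script = self._script(tmp_path, "import sys\nsys.exit(3)\n")
        with pytest.raises(ScriptError, match="exited 3"):
            run_external_reconstruction(script, nus_file, sched_file, cfg_file,
                                        tmp_path / "run", acq2d)
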