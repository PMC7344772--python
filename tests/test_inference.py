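"""RMSE fitting, calibration/quantification recovery and LOD estimation."""

import math
import warnings

import numpy as np
import pytest

import telisim as ts
from telisim.errors import DataError
from telisim.inference import (
    calibrate,
    estimate_lod,
    quantify,
    rmse,
)
from telisim.reaction_transport import KineticParams
from telisim.synthetic_data import NoiseModel, generate_signal
from telisim.thermal_readout import SignalTrace
from telisim.units import FMOL


def trace(voltage, dt=0.01):
    v = np.asarray(voltage, dtype=float)
    return SignalTrace(times=np.arange(len(v)) * dt, voltage=v)


class TestRMSE:
    def test_identical_traces_zero(self):
        y = trace([0, 1e-6, 2e-6, 1e-6])
        assert rmse(y, y, mask_start=0.0) == 0.0

    def test_hand_evaluated_example(self):
        # residuals (3, 4) uV -> sqrt((9+16)/2) = 3.5355 uV
        y = trace([0.0, 0.0])
        yp = trace([3e-6, 4e-6])
        assert rmse(y, yp, mask_start=0.0) == pytest.approx(3.5355e-6,
                                                            rel=1e-4)

    def test_constant_offset(self):
        y = trace(np.linspace(0, 5e-6, 20))
        yp = trace(y.voltage + 0.7e-6)
        assert rmse(y, yp, mask_start=0.0) == pytest.approx(0.7e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = trace(rng.normal(0, 1e-6, 40))
        b = trace(rng.normal(0, 1e-6, 40))
        assert rmse(a, b, 0.1) == pytest.approx(rmse(b, a, 0.1))

    def test_mask_excludes_artifact_window(self):
        y = trace(np.zeros(50))
        spoiled = y.voltage.copy()
        spoiled[:10] = 50e-6  # artifact inside [0, 0.1) s
        yp = trace(spoiled)
        assert rmse(y, yp, mask_start=0.1) == 0.0
        assert rmse(y, yp, mask_start=0.0) > 0.0

    def test_errors(self):
        y = trace(np.zeros(10))
        with pytest.raises(DataError):
            rmse(y, trace(np.zeros(12)), 0.1)
        with pytest.raises(DataError):
            rmse(y, trace(np.zeros(10), dt=0.02), 0.1)
        with pytest.raises(DataError):
            rmse(y, y, mask_start=10.0)  # nothing left


class TestCalibrate:
    def test_noiseless_self_consistency(self, fast_fm):
        """A trace generated at a grid node is recovered exactly, with
        (near-)zero RMSE, and the truth node beats every other node."""
        kcat_grid = np.geomspace(5e4, 8e5, 7)
        inf_grid = np.geomspace(0.5, 32, 5)
        truth = KineticParams(Ea=2.5 * FMOL, kcat=float(kcat_grid[3]),
                              InF=float(inf_grid[2]))
        sig = fast_fm.run(truth, 10.0).signal
        res = calibrate(sig, 2.5 * FMOL, kcat_grid, inf_grid, fast_fm, 10.0,
                        base=truth)
        assert res.kcat_hat == pytest.approx(truth.kcat)
        assert res.InF_hat == pytest.approx(truth.InF)
        assert res.rmse_min <= 1e-9
        i, j = res.surface.argmin()
        assert np.all(res.surface.values >= res.surface.values[i, j])
        assert not res.boundary_hit

    def test_boundary_hit_warns(self, fast_fm):
        kcat_grid = np.geomspace(1e4, 5e4, 3)  # truth above the range
        inf_grid = np.array([1.0, 4.0])
        truth = KineticParams(Ea=2.5 * FMOL, kcat=2.6e5, InF=4.0)
        sig = fast_fm.run(truth, 10.0).signal
        with pytest.warns(UserWarning, match="boundary"):
            res = calibrate(sig, 2.5 * FMOL, kcat_grid, inf_grid, fast_fm,
                            10.0, base=truth)
        assert res.boundary_hit

    def test_empty_grid_rejected(self, fast_fm):
        sig = trace(np.zeros(10), dt=0.02)
        with pytest.raises(ValueError):
            calibrate(sig, 1 * FMOL, [], [1.0], fast_fm, 10.0)

    def test_noisy_recovery_inactivation_dominant(self, fast_fm):
        """In a regime where the enzyme dies mid-run (tiny Ea*InF), both
        kcat and InF shape the trace and the grid search recovers each
        within one grid cell in nearly all noisy replicates."""
        kcat_grid = np.geomspace(1e5, 6e5, 5)
        inf_grid = np.geomspace(0.005, 0.08, 5)
        truth = KineticParams(Ea=0.05 * FMOL, kcat=float(kcat_grid[2]),
                              InF=float(inf_grid[2]))
        noise = NoiseModel(sigma=0.05e-6, artifact_amplitude=50e-6)
        hits_k = hits_i = 0
        n_rep = 10
        for seed in range(n_rep):
            sig = generate_signal(truth, 10.0,
                                  NoiseModel(sigma=noise.sigma, seed=seed,
                                             artifact_amplitude=50e-6),
                                  fast_fm)
            res = calibrate(sig, truth.Ea, kcat_grid, inf_grid, fast_fm,
                            10.0, base=truth)
            ik = np.argmin(np.abs(np.log(kcat_grid) - np.log(res.kcat_hat)))
            ii = np.argmin(np.abs(np.log(inf_grid) - np.log(res.InF_hat)))
            hits_k += abs(ik - 2) <= 1
            hits_i += abs(ii - 2) <= 1
        assert hits_k >= 9
        assert hits_i >= 8


class TestQuantify:
    def test_noiseless_self_consistency(self, fast_fm):
        ea_grid = np.geomspace(0.05 * FMOL, 5 * FMOL, 13)
        truth = KineticParams(Ea=float(ea_grid[7]), kcat=2.6e5, InF=4.0)
        sig = fast_fm.run(truth, 10.0).signal
        res = quantify(sig, truth.kcat, truth.InF, ea_grid, fast_fm, 10.0,
                       base=truth)
        assert res.Ea_hat == truth.Ea
        assert res.rmse_min <= 1e-9
        assert not res.boundary_hit

    def test_flat_zero_signal_hits_lower_boundary(self, fast_fm):
        n = fast_fm.n_steps + 1
        flat = SignalTrace(times=fast_fm.times.copy(), voltage=np.zeros(n))
        ea_grid = np.geomspace(0.05 * FMOL, 5 * FMOL, 9)
        with pytest.warns(UserWarning, match="boundary"):
            res = quantify(flat, 2.6e5, 4.0, ea_grid, fast_fm, 10.0)
        assert res.Ea_hat == ea_grid[0]
        assert res.boundary_hit


class TestEstimateLOD:
    def test_identity_mean_line_returns_sigma(self):
        # mean response identical to truth, equal per-level SD sigma
        sigma = 0.3e-15
        det = {1e-15: [1e-15 - sigma, 1e-15 + sigma],
               2e-15: [2e-15 - sigma, 2e-15 + sigma]}
        res = estimate_lod(det)
        sd = np.std([-sigma, sigma], ddof=1)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-22)
        assert res.lod == pytest.approx(sd, rel=1e-9)

    def test_zero_noise_unbiased_gives_zero(self):
        det = {1e-15: [1e-15, 1e-15], 2e-15: [2e-15, 2e-15]}
        assert estimate_lod(det).lod == 0.0

    def test_lod_scales_linearly_with_sd(self):
        def build(s):
            return {1e-15: [1e-15 - s, 1e-15 + s],
                    2e-15: [2e-15 - s, 2e-15 + s],
                    3e-15: [3e-15 - s, 3e-15 + s]}
        l1 = estimate_lod(build(0.1e-15)).lod
        l2 = estimate_lod(build(0.2e-15)).lod
        assert l2 == pytest.approx(2 * l1, rel=1e-9)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        det = {lv: list(rng.normal(lv, 0.1 * lv, 5))
               for lv in (1e-15, 1.5e-15, 2e-15)}
        a = estimate_lod(det)
        shuffled = {lv: list(reversed(v)) for lv, v in reversed(det.items())}
        b = estimate_lod(shuffled)
        assert a.lod == pytest.approx(b.lod)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_lod({1e-15: [1e-15, 1e-15]})  # single level
        with pytest.raises(ValueError):
            estimate_lod({1e-15: [1e-15], 2e-15: [2e-15]})  # single reps
        with pytest.raises(ValueError):
            # non-increasing mean response
            estimate_lod({1e-15: [2e-15, 2.1e-15], 2e-15: [1e-15, 0.9e-15]})
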