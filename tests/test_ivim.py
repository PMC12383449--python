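"""Biexponential model evaluation and voxelwise fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivimid import (
    BValueScheme,
    DEFAULT_SCHEME,
    FitConfig,
    FitResult,
    IVIMParameters,
    apply_f_exclusion,
    fit_ivim_volume,
    fit_ivim_voxel,
    ivim_signal,
)


class TestSignalModel:
    def test_unity_at_b_zero(self, gm_params):
        assert ivim_signal(gm_params, 1.0, 0.0) == pytest.approx(1.0)

    def test_monoexponential_limit(self):
        p = IVIMParameters(d=1.0e-3, d_star=0.07, f=0.0)
        assert ivim_signal(p, 1.0, 1000.0) == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_direct_arithmetic(self, gm_params):
        # 0.15*e^-4 + 0.85*e^-0.16, evaluated independently
        expected = 0.15 * np.exp(-200 * 0.02) + 0.85 * np.exp(-200 * 0.8e-3)
        assert ivim_signal(gm_params, 1.0, 200.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.7271, abs=5e-5)

    def test_scales_with_s0(self, gm_params):
        assert ivim_signal(gm_params, 250.0, 100.0) == pytest.approx(
            250.0 * ivim_signal(gm_params, 1.0, 100.0)
        )

    def test_domain_errors(self, gm_params):
        with pytest.raises(ValueError):
            ivim_signal(gm_params, 1.0, -5.0)
        with pytest.raises(ValueError):
            ivim_signal(gm_params, 0.0, 100.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        d=st.floats(1e-4, 3e-3),
        d_star=st.floats(4e-3, 0.3),
        f=st.floats(0.0, 1.0),
    )
    def test_signal_strictly_decreasing_in_b(self, d, d_star, f):
        p = IVIMParameters(d=d, d_star=d_star, f=f)
        b = np.linspace(0, 1500, 40)
        s = ivim_signal(p, 1.0, b)
        assert np.all(np.diff(s) < 0)


class TestScheme:
    def test_default_scheme(self, scheme):
        assert len(scheme) == 12
        assert scheme.values[0] == 0.0 and scheme.values[-1] == 1500.0

    @pytest.mark.parametrize(
        "values",
        [
            (0, 10, 25),                 # too short
            (10, 25, 50, 100),           # missing b=0
            (0, 10, 10, 50),             # not strictly increasing
            (0, -10, 25, 50),            # negative
        ],
    )
    def test_invalid_schemes_rejected(self, values):
        with pytest.raises(ValueError):
            BValueScheme(values)

    def test_bval_file_round_trip(self, tmp_path, scheme):
        p = tmp_path / "dwi.bval"
        p.write_text(" ".join(str(v) for v in scheme.values) + "\n")
        assert BValueScheme.from_file(p).values == scheme.values


class TestVoxelFit:
    def test_noiseless_recovery_within_one_percent(self, scheme, gm_params):
        sig = ivim_signal(gm_params, 1.0, scheme.as_array())
        res = fit_ivim_voxel(sig, scheme)
        assert res.converged and res.valid
        assert res.params.d == pytest.approx(gm_params.d, rel=0.01)
        assert res.params.d_star == pytest.approx(gm_params.d_star, rel=0.01)
        assert res.params.f == pytest.approx(gm_params.f, rel=0.01)

    def test_monoexponential_input_gives_zero_f(self, scheme):
        truth = IVIMParameters(d=1.0e-3, d_star=0.02, f=0.0)
        sig = ivim_signal(truth, 1.0, scheme.as_array())
        res = fit_ivim_voxel(sig, scheme)
        assert res.params.f <= 0.01
        assert res.params.d == pytest.approx(1.0e-3, rel=0.01)

    def test_constant_signal_fits_zero_decay(self, scheme):
        res = fit_ivim_voxel(np.ones(len(scheme)), scheme)
        assert res.params.d == pytest.approx(0.0, abs=1e-6)
        assert res.params.f == pytest.approx(0.0, abs=1e-3)

    def test_residual_not_worse_than_truth(self, scheme, gm_params, rng):
        """Fit optimality: on noiseless data the fitted residual cannot
        exceed the residual at the generating parameters."""
        sig = ivim_signal(gm_params, 1.0, scheme.as_array())
        res = fit_ivim_voxel(sig, scheme)
        assert res.residual_norm <= 1e-8  # truth residual is 0

    def test_residual_not_worse_than_grid_starts(self, scheme, gm_params, rng):
        sig = ivim_signal(gm_params, 1.0, scheme.as_array())
        sig = sig + rng.normal(0, 0.02, sig.shape)
        sig[0] = abs(sig[0])
        res = fit_ivim_voxel(sig, scheme)
        cfg = FitConfig()
        norm = sig / sig[0]
        b = scheme.as_array()
        for ds in cfg.d_star_grid:
            for d0 in (0.5e-3, 1e-3, 2e-3):
                for f0 in (0.05, 0.1, 0.2):
                    grid = ivim_signal(IVIMParameters(d=d0, d_star=ds, f=f0), 1.0, b)
                    # solver started from its own best grid point; any
                    # candidate start can only be worse or equal
                    assert res.residual_norm <= np.sum((grid - norm) ** 2) + 1e-8

    def test_zero_signal_rejected(self, scheme):
        with pytest.raises(ValueError):
            fit_ivim_voxel(np.zeros(len(scheme)), scheme)

    def test_length_mismatch_rejected(self, scheme):
        with pytest.raises(ValueError):
            fit_ivim_voxel(np.ones(5), scheme)


class TestFExclusion:
    def _result(self, f):
        return FitResult(
            params=IVIMParameters(d=1e-3, d_star=0.02, f=f),
            s0=1.0, residual_norm=0.0, converged=True,
        )

    @pytest.mark.parametrize(
        "f,expected_valid",
        [(0.35, False), (-0.01, False), (0.15, True), (0.0, True), (0.3, True)],
    )
    def test_exclusion_band(self, f, expected_valid):
        out = apply_f_exclusion(self._result(f))
        assert out.valid is expected_valid
        assert out.params.f == f  # parameters untouched


class TestVolumeFit:
    def test_homogeneous_phantom_identical_parameters(self, scheme, gm_params):
        sig = ivim_signal(gm_params, 1.0, scheme.as_array())
        vol = np.broadcast_to(sig, (4, 4, 1, len(scheme))).copy()
        fit = fit_ivim_volume(vol, scheme)
        assert np.allclose(fit.d, fit.d[0, 0, 0])
        assert np.allclose(fit.f, fit.f[0, 0, 0])

    def test_two_region_phantom_recovered(self, scheme):
        truths = {
            1: IVIMParameters(d=0.8e-3, d_star=0.02, f=0.15),
            2: IVIMParameters(d=0.7e-3, d_star=0.01, f=0.08),
        }
        labels = np.ones((4, 4, 1), dtype=int)
        labels[2:] = 2
        vol = np.empty((4, 4, 1, len(scheme)))
        for lab, p in truths.items():
            vol[labels == lab] = ivim_signal(p, 1.0, scheme.as_array())
        fit = fit_ivim_volume(vol, scheme)
        for lab, p in truths.items():
            sel = labels == lab
            assert fit.d[sel].mean() == pytest.approx(p.d, rel=0.02)
            assert fit.d_star[sel].mean() == pytest.approx(p.d_star, rel=0.02)
            assert fit.f[sel].mean() == pytest.approx(p.f, rel=0.02)

    def test_mask_contract_and_conservation(self, scheme, gm_params):
        sig = ivim_signal(gm_params, 1.0, scheme.as_array())
        vol = np.broadcast_to(sig, (4, 4, 1, len(scheme))).copy()
        mask = np.zeros((4, 4, 1), dtype=bool)
        mask[:2] = True  # exactly half
        fit = fit_ivim_volume(vol, scheme, mask=mask)
        assert fit.n_masked == 8
        assert np.isnan(fit.d[~mask]).all()
        assert fit.n_valid + fit.n_excluded + fit.n_masked == mask.size

    def test_shape_mismatches_rejected(self, scheme):
        with pytest.raises(ValueError):
            fit_ivim_volume(np.ones((4, 4, 1, 5)), scheme)
        with pytest.raises(ValueError):
            fit_ivim_volume(
                np.ones((4, 4, 1, len(scheme))), scheme, mask=np.ones((2, 2, 1), bool)
            )
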