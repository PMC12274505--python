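"""Force-curve analysis: baseline, contact point, stiffness, adhesion,
per-cell aggregation."""

import numpy as np
import pandas as pd
import pytest

from ecmorph import synthgen as sg
from ecmorph.containers import ForceCurve
from ecmorph.force import (
    NoContactError,
    adhesion_metrics,
    aggregate_cells,
    find_contact_point,
    first_slope_stiffness,
    fit_baseline,
)


def _curve(**kwargs):
    seed = kwargs.pop("seed", 0)
    cfg = sg.SynthConfig(seed=seed, curve=sg.CurveSpec(**kwargs))
    return sg.make_force_curve(cfg)


class TestBaseline:
    def test_zero_baseline(self):
        curve, _ = _curve(contact_nm=500.0, slope_pn_per_nm=0.05)
        fit = fit_baseline(curve, "approach")
        assert fit.intercept_pn == pytest.approx(0.0, abs=1e-12)
        assert fit.slope_pn_per_nm == pytest.approx(0.0, abs=1e-15)
        assert fit.noise_sd_pn == pytest.approx(0.0, abs=1e-12)

    def test_tilted_baseline_recovered_exactly(self):
        curve, _ = _curve(
            contact_nm=500.0, slope_pn_per_nm=0.05,
            baseline_pn=3.0, baseline_tilt_pn_per_nm=0.002,
        )
        fit = fit_baseline(curve, "approach")
        assert fit.intercept_pn == pytest.approx(3.0, abs=1e-9)
        assert fit.slope_pn_per_nm == pytest.approx(0.002, rel=1e-9)
        assert fit.noise_sd_pn == pytest.approx(0.0, abs=1e-9)

    def test_noise_sd_estimate_within_20_percent(self):
        sds = []
        for seed in range(100):
            curve, _ = _curve(seed=seed, contact_nm=500.0, noise_sd_pn=5.0)
            sds.append(fit_baseline(curve, "approach").noise_sd_pn)
        assert np.mean(sds) == pytest.approx(5.0, rel=0.2)

    def test_too_few_baseline_samples(self):
        curve, _ = _curve(n_samples=60)
        with pytest.raises(ValueError, match="10 samples"):
            fit_baseline(curve, "approach", fraction=0.05)


class TestContactPoint:
    def test_flat_curve_raises_no_contact(self):
        curve, _ = _curve(slope_pn_per_nm=0.0)
        with pytest.raises(NoContactError):
            find_contact_point(curve)

    def test_noiseless_ramp_contact_exact_on_grid(self):
        # contact at 500 nm lies on the 4 nm sample grid
        curve, _ = _curve(contact_nm=500.0, slope_pn_per_nm=0.05, ramp_nm=2000.0, n_samples=501)
        assert find_contact_point(curve) == pytest.approx(500.0, abs=1e-6)

    def test_noisy_recovery_within_50_nm(self):
        errors = []
        for seed in range(100):
            curve, _ = _curve(
                seed=seed, contact_nm=500.0, slope_pn_per_nm=0.05, noise_sd_pn=5.0
            )
            try:
                errors.append(find_contact_point(curve) - 500.0)
            except NoContactError:
                pass  # rare: noise keeps the run below threshold
        assert len(errors) >= 95
        assert np.median(np.abs(errors)) < 50.0


class TestStiffness:
    def test_noiseless_slope_exact(self):
        curve, _ = _curve(contact_nm=500.0, slope_pn_per_nm=0.05, ramp_nm=2000.0, n_samples=501)
        res = first_slope_stiffness(curve)
        assert res.slope_pn_per_nm == pytest.approx(0.05, rel=1e-6)
        assert res.residual_rms_pn < 1e-9

    def test_translation_invariance(self):
        curve, _ = _curve(contact_nm=500.0, slope_pn_per_nm=0.05, ramp_nm=2000.0, n_samples=501)
        base = first_slope_stiffness(curve).slope_pn_per_nm
        for shift in (-300.0, 300.0):
            shifted = ForceCurve(
                curve.approach + [shift, 0.0], curve.retract + [shift, 0.0], curve.meta
            )
            assert first_slope_stiffness(shifted).slope_pn_per_nm == pytest.approx(base, rel=1e-9)

    def test_no_cell_propagates_no_contact(self):
        curve, _ = _curve(slope_pn_per_nm=0.0)
        with pytest.raises(NoContactError):
            first_slope_stiffness(curve)

    def test_mean_recovery_at_moderate_noise(self):
        slopes = []
        for seed in range(100):
            curve, _ = _curve(seed=seed, contact_nm=1000.0, slope_pn_per_nm=0.05, noise_sd_pn=5.0)
            slopes.append(first_slope_stiffness(curve, window_nm=200.0).slope_pn_per_nm)
        assert np.mean(slopes) == pytest.approx(0.05, rel=0.02)


class TestAdhesion:
    def test_no_negative_forces_means_zero(self):
        curve, _ = _curve(contact_nm=500.0, slope_pn_per_nm=0.05)
        res = adhesion_metrics(curve)
        assert res.max_pulling_force_pn == 0.0
        assert res.adhesion_energy_J == 0.0

    def test_triangular_dip_closed_form(self, triangle_dip_curve):
        curve, truth = triangle_dip_curve
        res = adhesion_metrics(curve)
        assert res.max_pulling_force_pn == pytest.approx(200.0, rel=5e-3)
        assert res.adhesion_energy_J == pytest.approx(truth.data["adhesion_energy_J"], rel=5e-3)

    @pytest.mark.parametrize("offset", [-50.0, 50.0, 500.0])
    def test_energy_invariant_under_force_offsets(self, triangle_dip_curve, offset):
        curve, _ = triangle_dip_curve
        base = adhesion_metrics(curve).adhesion_energy_J
        shifted = ForceCurve(
            curve.approach + [0.0, offset], curve.retract + [0.0, offset], curve.meta
        )
        assert adhesion_metrics(shifted).adhesion_energy_J == pytest.approx(base, rel=1e-9)

    def test_dip_below_noise_band_gives_zero_energy(self):
        curve, _ = _curve(
            seed=5, contact_nm=500.0, noise_sd_pn=5.0,
            dip_depth_pn=10.0, dip_width_nm=400.0,
        )
        res = adhesion_metrics(curve, k_sigma=3.0)
        # dip depth 10 pN (2 sigma) stays inside the 15 pN band
        assert res.adhesion_energy_J == pytest.approx(0.0, abs=1e-19)

    def test_metrics_monotone_in_dip_depth(self):
        forces, energies = [], []
        for depth in (0.0, 50.0, 100.0, 200.0, 400.0):
            curve, _ = _curve(
                contact_nm=500.0, dip_depth_pn=depth,
                dip_width_nm=400.0 if depth else 0.0,
            )
            res = adhesion_metrics(curve)
            forces.append(res.max_pulling_force_pn)
            energies.append(res.adhesion_energy_J)
        assert np.all(np.diff(forces) >= 0)
        assert np.all(np.diff(energies) >= 0)


class TestAggregation:
    def test_identical_curves_mean(self):
        rows = [{"cell_id": "c1", "value": 2.5}] * 6
        out = aggregate_cells(rows, "value", min_curves=6)
        assert out.loc[0, "mean"] == 2.5
        assert bool(out.loc[0, "included"])

    def test_undersampled_cell_flagged(self):
        rows = [{"cell_id": "c1", "value": 1.0}] * 5
        out = aggregate_cells(rows, "value", min_curves=6)
        assert not bool(out.loc[0, "included"])

    def test_recovers_known_cell_means(self):
        rng = np.random.default_rng(0)
        true_means = {f"cell{i}": 0.02 + 0.01 * i for i in range(20)}
        rows = [
            {"cell_id": cid, "value": rng.normal(mu, 0.002)}
            for cid, mu in true_means.items()
            for _ in range(10)
        ]
        out = aggregate_cells(rows, "value", min_curves=6).set_index("cell_id")
        for cid, mu in true_means.items():
            assert out.loc[cid, "mean"] == pytest.approx(mu, abs=3 * 0.002 / np.sqrt(10))

    def test_unknown_cell_id_raises(self):
        rows = [{"cell_id": "c1", "value": 1.0}] * 6
        with pytest.raises(KeyError, match="c1"):
            aggregate_cells(rows, "value", group_labels={"other": "WT"})


def test_pipeline_on_tsv_roundtrip(tmp_path):
    """Analysis results survive the TSV round trip bit-exactly."""
    from ecmorph import io

    cfg = sg.SynthConfig(
        seed=9,
        curve=sg.CurveSpec(
            contact_nm=500.0, slope_pn_per_nm=0.1, noise_sd_pn=2.0,
            dip_depth_pn=150.0, dip_width_nm=300.0, cell_id="cellA",
        ),
    )
    curve, _ = sg.make_force_curve(cfg)
    path = io.write_force_curve(curve, tmp_path / "c.tsv")
    back = io.read_force_curve(path)
    assert back.meta["cell_id"] == "cellA"
    a, b = adhesion_metrics(curve), adhesion_metrics(back)
    assert b.adhesion_energy_J == pytest.approx(a.adhesion_energy_J, rel=1e-12)
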