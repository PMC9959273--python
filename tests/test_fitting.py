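"""DLVO estimation pipeline: log-linear fit, fixed-kappa re-fit, limit
distances and replicate aggregation."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from chiralloid import (
    DLVOForceModel,
    DLVOParameters,
    ProbeGeometry,
    TailPolicy,
    aggregate_pairs,
    extract_limit_distance,
    limit_distance,
    loglinear_fit,
    refit_fixed_kappa,
    summarize_pairs,
)
from chiralloid.synthetic import ForceCurveSpec, gen_force_curve


class TestFreeFit:
    def test_recovers_cnc_cnc_parameters(self, cnc_params, make_noiseless_curve):
        res = loglinear_fit(make_noiseless_curve(cnc_params))
        assert res.kappa == pytest.approx(0.04125, rel=1e-3)
        assert res.z_const == pytest.approx(9.305e-3, rel=1e-3)
        assert res.r_squared > 0.999999

    def test_recovers_paas_cnc_parameters(self, all_pair_params, make_noiseless_curve):
        res = loglinear_fit(make_noiseless_curve(all_pair_params["PAAS-CNC"]))
        assert res.kappa == pytest.approx(0.03966, rel=1e-3)
        assert res.z_const == pytest.approx(11.17e-3, rel=1e-3)

    def test_recovers_every_pair_to_point_one_percent(
        self, all_pair_params, make_noiseless_curve
    ):
        for label, params in all_pair_params.items():
            res = loglinear_fit(make_noiseless_curve(params))
            assert res.kappa == pytest.approx(params.kappa, rel=1e-3), label
            assert res.z_const == pytest.approx(params.z_const, rel=1e-3), label

    def test_agrees_with_nonlinear_least_squares_oracle(
        self, cnc_params, make_noiseless_curve
    ):
        """Dual route: OLS on the log tail vs scipy curve_fit of the full model."""
        curve = make_noiseless_curve(cnc_params)
        res = loglinear_fit(curve)
        lo, hi = res.tail_range
        mask = (curve.distance >= lo) & (curve.distance <= hi)
        d, f = curve.distance[mask], curve.force[mask]
        r = 5000.0

        def full_model(d, kappa, z):
            return kappa * r * z * np.exp(-kappa * d) - 3.6e-21 * r / (6 * d**2) * 1e18

        (k_nls, z_nls), _ = curve_fit(full_model, d, f, p0=[0.03, 5e-3])
        assert res.kappa == pytest.approx(k_nls, rel=5e-3)
        assert res.z_const == pytest.approx(z_nls, rel=5e-3)

    def test_noise_bias_small_over_replicates(self, cnc_params):
        seeds = np.random.SeedSequence(20230415).generate_state(100) % (2**31)
        ks, zs = [], []
        for s in seeds:
            c = gen_force_curve(ForceCurveSpec(params=cnc_params, noise_sd=2e-3,
                                               seed=int(s)))
            res = loglinear_fit(c)
            ks.append(res.kappa)
            zs.append(res.z_const)
        assert abs(np.mean(ks) / cnc_params.kappa - 1) < 0.02
        assert abs(np.mean(zs) / cnc_params.z_const - 1) < 0.05

    def test_from_dataframe(self, cnc_params, make_noiseless_curve):
        df = make_noiseless_curve(cnc_params).to_frame()
        res = DLVOForceModel.from_dataframe(df).fit()
        assert res.kappa == pytest.approx(cnc_params.kappa, rel=1e-3)

    def test_summary_mentions_estimates(self, cnc_params, make_noiseless_curve):
        text = loglinear_fit(make_noiseless_curve(cnc_params)).summary()
        assert "kappa" in text and "0.04125" in text

    def test_degenerate_tail_rejected(self, cnc_params):
        c = gen_force_curve(ForceCurveSpec(params=cnc_params, noise_sd=0.0,
                                           contact_artifact_amplitude=0.0))
        with pytest.raises(ValueError):
            DLVOForceModel(c, tail_policy=TailPolicy(d_min=1e4)).fit()


class TestFixedKappaRefit:
    def test_self_consistent_with_free_fit(self, cnc_params, make_noiseless_curve):
        curve = make_noiseless_curve(cnc_params)
        free = loglinear_fit(curve)
        refit = refit_fixed_kappa(curve, free.kappa)
        assert refit.kappa == free.kappa  # exact, by construction
        assert refit.z_const == pytest.approx(free.z_const, rel=1e-9)

    def test_misspecified_kappa_degrades_fit(self, make_noiseless_curve):
        truth = DLVOParameters(kappa=0.05, z_const=8e-3, hamaker=3.6e-21,
                               geometry=ProbeGeometry(5000.0))
        curve = make_noiseless_curve(truth)
        free = loglinear_fit(curve)
        wrong = refit_fixed_kappa(curve, 0.04125)
        assert wrong.z_const != pytest.approx(truth.z_const, rel=1e-3)
        assert wrong.r_squared < free.r_squared

    def test_z_ordering_preserved_across_pairs(self, all_pair_params, make_noiseless_curve):
        """Re-fitting all pairs at the reference kappa keeps the Z ranking:
        strongest repulsion for PAAS-CNC, weakest for the most-loaded composite."""
        z_fixed = {
            label: refit_fixed_kappa(make_noiseless_curve(p), 0.04125).z_const
            for label, p in all_pair_params.items()
        }
        ranked = sorted(z_fixed, key=z_fixed.get)
        assert ranked[-1] == "PAAS-CNC"
        assert ranked[0] == "CNC/COS_3.0-CNC/COS_3.0"


class TestLimitDistanceExtraction:
    def test_analytic_mode_delegates_to_forward_model(self, cnc_params, make_noiseless_curve):
        res = loglinear_fit(make_noiseless_curve(cnc_params))
        assert extract_limit_distance(res) == pytest.approx(
            limit_distance(res.params), rel=1e-12
        )

    def test_empirical_within_two_spacings_of_analytic(self, cnc_params):
        c = gen_force_curve(ForceCurveSpec(params=cnc_params, d_range=(2.0, 200.0),
                                           n_points=400, noise_sd=0.0,
                                           contact_artifact_amplitude=0.0))
        spacing = c.distance[1] - c.distance[0]
        emp = extract_limit_distance(c, mode="empirical")
        ana = extract_limit_distance(c, mode="analytic")
        assert abs(emp - ana) <= 2 * spacing

    def test_vanishing_threshold_escapes_bracket(self, cnc_params, make_noiseless_curve):
        res = loglinear_fit(make_noiseless_curve(cnc_params))
        with pytest.raises(ValueError):
            res.limit_distance(slope_threshold=1e-30)

    def test_unreachable_threshold_on_data(self, cnc_params):
        c = gen_force_curve(ForceCurveSpec(params=cnc_params, d_range=(150.0, 200.0),
                                           n_points=64, noise_sd=0.0,
                                           contact_artifact_amplitude=0.0))
        with pytest.raises(ValueError, match="slope"):
            extract_limit_distance(c, slope_threshold=10.0, mode="empirical")


class TestAggregation:
    def test_single_curve_sd_zero(self, cnc_params, make_noiseless_curve):
        res = loglinear_fit(make_noiseless_curve(cnc_params))
        s = aggregate_pairs([res])
        assert s.n_curves == 1
        assert s.limit_distance_sd == 0.0

    def test_identical_curves_zero_spread(self, cnc_params, make_noiseless_curve):
        r1 = loglinear_fit(make_noiseless_curve(cnc_params))
        r2 = loglinear_fit(make_noiseless_curve(cnc_params))
        s = aggregate_pairs([r1, r2])
        assert s.kappa_mean == pytest.approx(r1.kappa)
        assert s.kappa_sd == pytest.approx(0.0, abs=1e-15)

    def test_mixed_labels_rejected(self, all_pair_params, make_noiseless_curve):
        r1 = loglinear_fit(make_noiseless_curve(all_pair_params["CNC-CNC"],
                                                pair_label="CNC-CNC"))
        r2 = loglinear_fit(make_noiseless_curve(all_pair_params["PAAS-CNC"],
                                                pair_label="PAAS-CNC"))
        with pytest.raises(ValueError, match="mixed"):
            aggregate_pairs([r1, r2])

    def test_summary_table_schema(self, all_pair_params, make_noiseless_curve, reference_table):
        results = []
        for label, p in all_pair_params.items():
            for _ in range(2):
                results.append(loglinear_fit(make_noiseless_curve(p, pair_label=label)))
        zeta = {
            row.pair_label: (row.zeta_probe_mV, row.zeta_substrate_mV)
            for row in reference_table.itertuples()
        }
        table = summarize_pairs(results, zeta_by_pair=zeta)
        assert list(table.columns) == [
            "pair_label", "zeta_probe_mV", "zeta_substrate_mV",
            "limit_distance_nm", "limit_distance_sd_nm",
            "kappa_per_nm", "z_nN", "n_curves",
        ]
        assert len(table) == 7
        assert (table.n_curves == 2).all()

    def test_limit_distance_increases_with_z_at_fixed_kappa(self):
        """Across a dilution-style series with shared kappa, larger Z pushes
        the flat-slope point outward."""
        lds = [
            limit_distance(DLVOParameters(kappa=0.045, z_const=z, hamaker=3.6e-21,
                                          geometry=ProbeGeometry(5000.0)))
            for z in (6e-3, 8e-3, 10e-3)
        ]
        assert lds == sorted(lds)
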