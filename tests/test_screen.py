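import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trajscreen import (
    ScreenConfig,
    bh_adjust,
    fit_pair_with_fallback,
    make_cohort,
    results_to_frame,
    run_screen,
    within_patient_mean_spearman,
)
from trajscreen.errors import ConfigError, DataError, DomainError
from trajscreen.simulate import (
    Association,
    SyntheticConfig,
    VariableSpec,
    default_echo_variables,
    protein_spec,
    screen_config,
    spline_coefs_for_changes,
)

from conftest import prepared_cohort


class TestBhAdjust:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_nan_excluded_and_reinserted(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        # family size m=2, not 3
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant_and_dominates_p(self, ps):
        p = np.asarray(ps)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(p[perm]), q[perm])
        # monotone in the order statistics
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


def _means_cohort(protein_means, echo_means):
    rows = []
    for i, (pm, em) in enumerate(zip(protein_means, echo_means)):
        rows.append((f"P{i}", 1.0, "prot", "protein", pm))
        rows.append((f"P{i}", 3.0, "av", "echo", em))
    meas = pd.DataFrame(rows, columns=["patient_id", "time_months", "variable_id", "variable_type", "value"])
    cov = pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(len(protein_means))],
        "age_years": 60.0, "sex": "male",
    })
    return make_cohort(meas, cov)


class TestWithinPatientMeanSpearman:
    @pytest.mark.parametrize(
        "pm, em, expected",
        [
            ([1, 2, 3], [10, 20, 30], 1.0),
            ([1, 2, 3], [30, 20, 10], -1.0),
            # 1 - 6*sum(d^2)/(n(n^2-1)): sum(d^2)=4 -> 0.8, sum(d^2)=6 -> 0.7
            ([1, 2, 3, 4, 5], [1, 3, 2, 5, 4], 0.8),
            ([1, 2, 3, 4, 5], [1, 3, 4, 2, 5], 0.7),
        ],
    )
    def test_worked_rank_examples(self, pm, em, expected):
        ds = _means_cohort(pm, em)
        rho, _, n = within_patient_mean_spearman(ds, "prot", "av")
        assert rho == pytest.approx(expected, abs=1e-12)
        assert n == len(pm)

    def test_too_few_complete_patients(self):
        ds = _means_cohort([1, 2], [5, 6])
        with pytest.raises(DataError):
            within_patient_mean_spearman(ds, "prot", "av")


def _sparse_protein_cohort(n_times_protein):
    """Cohort whose protein has only `n_times_protein` distinct visit times."""
    times_p = [1.0, 3.0][:n_times_protein]
    echo = default_echo_variables()[0]
    rows = []
    rng = np.random.default_rng(0)
    for i in range(60):
        for t in times_p:
            rows.append((f"P{i}", t, "prot", "protein", float(np.exp(rng.normal(7, 0.5)))))
        for t in (0.0, 3.0, 12.0):
            rows.append((f"P{i}", t, "av", "echo", float(rng.normal(22 + 0.3 * t, 5))))
    meas = pd.DataFrame(rows, columns=["patient_id", "time_months", "variable_id", "variable_type", "value"])
    cov = pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(60)],
        "age_years": rng.uniform(40, 80, 60), "sex": "male",
    })
    from trajscreen import apply_design_filters, log_transform_proteins
    return apply_design_filters(log_transform_proteins(make_cohort(meas, cov)))


class TestFallbackLadder:
    def test_rich_data_uses_top_ladder_entry(self):
        times = (0.0, 2.0, 6.0, 12.0)
        ptimes = (1.0, 3.0, 6.0, 12.0)
        echo = VariableSpec(
            "av", "echo", times, 20.0,
            spline_coefs_for_changes(times, 3.0, 5.0), 0.05, -1.0,
            "intercept_spline2", (5.0, 1.5, 0.4), 2.0,
        )
        prot = VariableSpec(
            "prot", "protein", ptimes, 7.0,
            spline_coefs_for_changes(ptimes, -0.1, -0.3), 0.0, 0.0,
            "intercept_spline2", (0.6, 0.15, 0.04), 0.3,
        )
        cfg = SyntheticConfig(
            echo_vars=(echo,), proteins=(prot,),
            associations=(Association("prot", "av", 0.5),),
            n_patients=200, missingness=0.0, seed=21,
        )
        ds, _ = prepared_cohort(cfg, 21)
        res = fit_pair_with_fallback(ds, "prot", "av", seed=21)
        assert res.converged
        assert (res.structure_protein, res.structure_echo) == ("RI+splines", "RI+splines")
        assert res.lrt.df == 9

    def test_two_protein_times_never_spline_on_protein_side(self):
        ds = _sparse_protein_cohort(2)
        res = fit_pair_with_fallback(ds, "prot", "av", seed=0)
        assert res.structure_protein in ("RI", "RI+slope")

    def test_single_visit_data_never_converges(self):
        ds = _sparse_protein_cohort(1)
        # echo side also reduced to a single visit per patient
        m = ds.measurements
        m = m[(m["variable_type"] == "protein") | (m["time_months"] == 3.0)].reset_index(drop=True)
        from dataclasses import replace
        ds1 = replace(ds, measurements=m)
        res = fit_pair_with_fallback(ds1, "prot", "av", seed=0)
        assert not res.converged
        assert res.lrt is None


@pytest.fixture(scope="module")
def small_screen():
    cfg = screen_config(n_proteins=8, n_true=2, rho=0.7, n_patients=120)
    ds, truth = prepared_cohort(cfg, 5)
    results = run_screen(
        ds, ["LVEDV"], [p.name for p in cfg.proteins],
        config=ScreenConfig(ladder=(("intercept", "intercept"),)), seed=5,
    )
    return cfg, ds, results


class TestRunScreen:

    def test_one_result_per_pair_with_fdr(self, small_screen):
        cfg, ds, results = small_screen
        assert len(results) == 8
        conv = [r for r in results if r.converged]
        for r in conv:
            assert r.fdr_q >= r.lrt.p_value - 1e-12

    def test_empty_id_lists_rejected(self, small_screen):
        _, ds, _ = small_screen
        with pytest.raises(ConfigError):
            run_screen(ds, [], ["PROT001"])

    def test_deterministic_and_order_independent(self, small_screen):
        cfg, ds, results = small_screen
        ids = [p.name for p in cfg.proteins]
        sc = ScreenConfig(ladder=(("intercept", "intercept"),))
        again = run_screen(ds, ["LVEDV"], ids, config=sc, seed=5)
        reversed_ = run_screen(ds, ["LVEDV"], ids[::-1], config=sc, seed=5)
        t0 = results_to_frame(results).to_csv()
        assert results_to_frame(again).to_csv() == t0
        assert results_to_frame(reversed_).to_csv() == t0

    def test_per_echo_families(self):
        cfg = screen_config(n_proteins=4, n_true=1, rho=0.7, n_patients=100)
        # add a second echo variable so two BH families exist
        from dataclasses import replace as dreplace
        echo2 = dreplace(default_echo_variables()[0], name="AV2")
        cfg = dreplace(cfg, echo_vars=cfg.echo_vars + (echo2,))
        ds, _ = prepared_cohort(cfg, 6)
        results = run_screen(
            ds, ["LVEDV", "AV2"], [p.name for p in cfg.proteins],
            config=ScreenConfig(ladder=(("intercept", "intercept"),)), seed=6,
        )
        assert len(results) == 8
        for echo_id in ("LVEDV", "AV2"):
            fam = [r for r in results if r.echo_id == echo_id and r.converged]
            p = np.array([r.lrt.p_value for r in fam])
            q = bh_adjust(p)
            np.testing.assert_allclose([r.fdr_q for r in fam], q)
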