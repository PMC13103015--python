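import copy
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import approx_fprime

from trajscreen import (
    OutcomeSpec,
    assemble_design,
    assemble_pair_design,
    fit_model,
    fit_pair,
    lrt_cross_block,
    make_cohort,
    marginal_loglik,
    pair_spec_from_data,
)
from trajscreen.bivariate import PairModelSpec, _default_start, _nll_and_grad, _profiled_nll
from trajscreen.errors import NumericalError, StateError, VariableLookupError
from trajscreen.benchmarks import loglik_oracle_check
from trajscreen.simulate import pair_config

from conftest import prepared_cohort


def _both_outcome_cohort():
    rows = []
    for t in (1.0, 3.0, 12.0):
        rows.append(("P1", t, "prot_a", "protein", 2.0 + 0.1 * t))
    for t in (0.0, 3.0, 12.0):
        rows.append(("P1", t, "av", "echo", 20.0 + t))
    for t in (0.0, 3.0, 12.0):
        rows.append(("P2", t, "av", "echo", 22.0 + t))
    meas = pd.DataFrame(rows, columns=["patient_id", "time_months", "variable_id", "variable_type", "value"])
    cov = pd.DataFrame({"patient_id": ["P1", "P2"], "age_years": [55.0, 60.0], "sex": ["male", "female"]})
    return make_cohort(meas, cov)


class TestAssembly:
    def test_stacked_dimensions_ri_ri(self):
        ds = _both_outcome_cohort()
        spec = pair_spec_from_data(ds, "prot_a", "av", "intercept", "intercept", "full")
        design = assemble_pair_design(ds, "prot_a", "av", spec)
        g1 = [g for g in design.groups if "P1" in g.patient_ids][0]
        assert g1.y.shape == (1, 6)
        assert g1.Z.shape == (6, 2)
        # outcome-indicator random columns: protein rows load only column 0
        np.testing.assert_array_equal(g1.Z[:3], [[1, 0]] * 3)
        np.testing.assert_array_equal(g1.Z[3:], [[0, 1]] * 3)

    def test_single_outcome_patient_has_zero_protein_columns(self):
        ds = _both_outcome_cohort()
        spec = pair_spec_from_data(ds, "prot_a", "av", "intercept", "intercept", "full")
        design = assemble_pair_design(ds, "prot_a", "av", spec)
        g2 = [g for g in design.groups if "P2" in g.patient_ids][0]
        assert g2.y.shape[1] == 3
        assert np.all(g2.Z[:, 0] == 0)  # no protein random loading

    def test_unknown_variable_raises(self):
        ds = _both_outcome_cohort()
        with pytest.raises(VariableLookupError):
            pair_spec_from_data(ds, "prot_a", "nope", "intercept", "intercept")


class TestMarginalLoglik:
    def test_single_standard_normal_observation(self):
        meas = pd.DataFrame(
            [("P1", 0.0, "av", "echo", 0.0)],
            columns=["patient_id", "time_months", "variable_id", "variable_type", "value"],
        )
        cov = pd.DataFrame({"patient_id": ["P1"], "age_years": [60.0], "sex": ["male"]})
        ds = make_cohort(meas, cov)
        design = assemble_design(ds, [OutcomeSpec("av", "intercept", None, "none")])
        ll = marginal_loglik(design, np.zeros(design.p), [1.0], np.zeros((1, 1)))
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_row_permutation_invariance(self, ri_pair_cohort):
        ds, _ = ri_pair_cohort
        spec = pair_spec_from_data(ds, "PROT1", "LVEDV", "intercept", "intercept", "full")
        design = assemble_pair_design(ds, "PROT1", "LVEDV", spec)
        rng = np.random.default_rng(0)
        Xs = np.concatenate([g.X.reshape(-1, design.p) for g in design.groups])
        ys = np.concatenate([g.y.ravel() for g in design.groups])
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)  # sane magnitudes
        D = np.array([[0.3, 0.1], [0.1, 0.5]])
        ll = marginal_loglik(design, beta, [0.2, 0.4], D)
        permuted = copy.deepcopy(design)
        g = permuted.groups[0]
        perm = rng.permutation(g.Z.shape[0])
        g.Z[:] = g.Z[perm]
        g.X[:] = g.X[:, perm, :]
        g.y[:] = g.y[:, perm]
        g.row_outcome[:] = g.row_outcome[perm]
        ll_perm = marginal_loglik(permuted, beta, [0.2, 0.4], D)
        assert ll_perm == pytest.approx(ll, rel=1e-10, abs=1e-9)

    def test_matches_dense_multivariate_normal(self):
        res = loglik_oracle_check(n_instances=5, seed=3)
        assert res["max_abs_diff"] < 1e-8

    def test_non_psd_rejected(self, ri_pair_cohort):
        ds, _ = ri_pair_cohort
        spec = pair_spec_from_data(ds, "PROT1", "LVEDV", "intercept", "intercept", "full")
        design = assemble_pair_design(ds, "PROT1", "LVEDV", spec)
        with pytest.raises(NumericalError):
            marginal_loglik(design, np.zeros(design.p), [1.0, 1.0], np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestGradient:
    @pytest.mark.parametrize("constraint", ["full", "block_diagonal"])
    def test_analytic_matches_finite_difference(self, constraint):
        cfg = pair_config(n_patients=25, rho=0.5, missingness=0.1,
                          structure_E="intercept_slope", seed=7)
        ds, _ = prepared_cohort(cfg, 7)
        spec = pair_spec_from_data(ds, "PROT1", "LVEDV", "intercept", "intercept_slope", constraint)
        design = assemble_pair_design(ds, "PROT1", "LVEDV", spec)
        theta = _default_start(design, constraint) + 0.05
        _, grad = _nll_and_grad(theta, design, constraint)
        grad_num = approx_fprime(theta, lambda t: _profiled_nll(t, design, constraint), 1e-6)
        np.testing.assert_allclose(grad, grad_num, rtol=1e-3, atol=1e-4)


class TestFitAndLrt:
    def test_recovers_cross_correlation(self):
        cfg = pair_config(n_patients=500, rho=0.6, missingness=0.0, seed=9)
        ds, _ = prepared_cohort(cfg, 9)
        spec_null = pair_spec_from_data(ds, "PROT1", "LVEDV", "intercept", "intercept", "block_diagonal")
        design = assemble_pair_design(ds, "PROT1", "LVEDV", spec_null)
        fit_null = fit_pair(design, spec_null)
        spec_full = pair_spec_from_data(ds, "PROT1", "LVEDV", "intercept", "intercept", "full")
        fit_full = fit_pair(design, spec_full, init=fit_null)
        assert fit_full.converged
        assert abs(fit_full.cross_correlation - 0.6) < 0.08

    def test_nesting_and_block_structure(self, ri_pair_cohort):
        ds, _ = ri_pair_cohort
        spec_null = pair_spec_from_data(ds, "PROT1", "LVEDV", "intercept", "intercept", "block_diagonal")
        design = assemble_pair_design(ds, "PROT1", "LVEDV", spec_null)
        fit_null = fit_pair(design, spec_null)
        spec_full = pair_spec_from_data(ds, "PROT1", "LVEDV", "intercept", "intercept", "full")
        fit_full = fit_pair(design, spec_full, init=fit_null)
        assert fit_full.loglik >= fit_null.loglik - 1e-6
        assert fit_null.D[0, 1] == 0.0  # off-block exactly zero under the constraint
        lrt = lrt_cross_block(fit_full, fit_null, spec_full)
        assert lrt.statistic >= 0
        assert lrt.df == 1

    @pytest.mark.parametrize(
        "sP, sE, df",
        [("intercept", "intercept", 1), ("intercept_spline2", "intercept_slope", 6)],
    )
    def test_lrt_degrees_of_freedom(self, sP, sE, df):
        spec = PairModelSpec(sP, sE, None, None, "full") if sP != "intercept_spline2" else None
        if spec is None:
            from trajscreen import make_spline_spec
            sp = make_spline_spec([1, 3, 12], df=2)
            spec = PairModelSpec(sP, sE, sp, sp, "full")
        assert spec.q_P * spec.q_E == df

    def test_chi2_reference_quantile(self):
        # 3.8415 is the 95% point of chi2_1
        assert stats.chi2.sf(3.8415, 1) == pytest.approx(0.0500, abs=5e-5)

    def test_lrt_requires_convergence(self, ri_pair_cohort):
        ds, _ = ri_pair_cohort
        spec = pair_spec_from_data(ds, "PROT1", "LVEDV", "intercept", "intercept", "full")
        design = assemble_pair_design(ds, "PROT1", "LVEDV", spec)
        good = fit_pair(design, spec)
        bad = copy.deepcopy(good)
        bad.converged = False
        with pytest.raises(StateError):
            lrt_cross_block(good, bad, spec)

    def test_reparameterized_spline_basis_leaves_loglik_unchanged(self, ri_pair_cohort):
        ds, _ = ri_pair_cohort
        spec = pair_spec_from_data(ds, "PROT1", "LVEDV", "intercept", "intercept", "full")
        design = assemble_pair_design(ds, "PROT1", "LVEDV", spec)
        fit = fit_pair(design, spec)
        T = np.array([[2.0, -1.0], [0.5, 3.0]])  # invertible map of the echo spline columns
        design2 = copy.deepcopy(design)
        for g in design2.groups:
            g.X[:, :, 8:10] = g.X[:, :, 8:10] @ T
        fit2 = fit_pair(design2, spec, init=fit)
        assert abs(fit2.loglik - fit.loglik) < 1e-6

    def test_scale_equivariance_of_lrt(self, ri_pair_cohort):
        ds, _ = ri_pair_cohort
        c = 3.7

        def fits(dataset):
            spec_n = pair_spec_from_data(dataset, "PROT1", "LVEDV", "intercept", "intercept", "block_diagonal")
            d = assemble_pair_design(dataset, "PROT1", "LVEDV", spec_n)
            fn = fit_pair(d, spec_n)
            spec_f = pair_spec_from_data(dataset, "PROT1", "LVEDV", "intercept", "intercept", "full")
            ff = fit_pair(d, spec_f, init=fn)
            return fn, ff, lrt_cross_block(ff, fn, spec_f)

        _, ff1, lrt1 = fits(ds)
        from dataclasses import replace
        meas = ds.measurements.copy()
        echo = meas["variable_type"] == "echo"
        meas.loc[echo, "value"] *= c
        _, ff2, lrt2 = fits(replace(ds, measurements=meas))
        assert np.sqrt(ff2.sigma2_E) == pytest.approx(c * np.sqrt(ff1.sigma2_E), rel=1e-4)
        assert lrt2.statistic == pytest.approx(lrt1.statistic, abs=1e-4 * (1 + lrt1.statistic))

    def test_single_visit_slope_flagged(self):
        rows = []
        for i in range(30):
            rows.append((f"P{i}", 1.0, "prot_a", "protein", 2.0 + 0.1 * i))
            rows.append((f"P{i}", 3.0, "av", "echo", 20.0 + i))
        meas = pd.DataFrame(rows, columns=["patient_id", "time_months", "variable_id", "variable_type", "value"])
        cov = pd.DataFrame(
            {"patient_id": [f"P{i}" for i in range(30)], "age_years": 60.0, "sex": "male"}
        )
        ds = make_cohort(meas, cov)
        spec = pair_spec_from_data(ds, "prot_a", "av", "intercept_slope", "intercept", "full")
        design = assemble_pair_design(ds, "prot_a", "av", spec)
        fit = fit_model(design, "full", restarts=0, maxiter=100)
        # slope variance is unidentifiable with one visit: either flagged
        # non-converged or collapsed to the boundary
        assert (not fit.converged) or fit.D[1, 1] < 1e-6


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_matches_nlme_reference_fit(ri_pair_cohort, tmp_path):
    """Full and null ML log-likelihoods agree with nlme::lme on the same data.

    The reference fit stacks the two outcomes with outcome-specific
    fixed effects, a pdSymm/pdDiag random-intercept pair and
    per-outcome residual variances (varIdent) — the standard R route
    to this bivariate model.
    """
    cfg = pair_config(n_patients=60, rho=0.6, missingness=0.0, seed=11)
    ds, _ = prepared_cohort(cfg, 11)
    spec_f = pair_spec_from_data(ds, "PROT1", "LVEDV", "intercept", "intercept", "full")
    spec_n = pair_spec_from_data(ds, "PROT1", "LVEDV", "intercept", "intercept", "block_diagonal")
    design = assemble_pair_design(ds, "PROT1", "LVEDV", spec_f)
    fn = fit_pair(design, spec_n)
    ff = fit_pair(design, spec_f, init=fn)

    from trajscreen.splines import evaluate_basis
    m = ds.measurements.merge(ds.covariates, on="patient_id")
    m["sexind"] = (m["sex"] == "female").astype(int)
    isP = (m["variable_type"] == "protein").to_numpy(float)
    bP = evaluate_basis(spec_f.spline_P, m["time_months"].to_numpy())
    bE = evaluate_basis(spec_f.spline_E, m["time_months"].to_numpy())
    df = pd.DataFrame({
        "pid": m["patient_id"], "y": m["value"], "out": np.where(isP == 1, "P", "E"),
        "iP": isP, "iE": 1 - isP,
        "aP": isP * m["age_years"], "aE": (1 - isP) * m["age_years"],
        "sP": isP * m["sexind"], "sE": (1 - isP) * m["sexind"],
        "n1P": isP * bP[:, 0], "n2P": isP * bP[:, 1],
        "n1E": (1 - isP) * bE[:, 0], "n2E": (1 - isP) * bE[:, 1],
    })
    csv = tmp_path / "biv.csv"
    df.to_csv(csv, index=False)
    rcode = f'''
    suppressMessages(library(nlme))
    d <- read.csv("{csv}")
    fx <- y ~ -1 + iP + aP + sP + n1P + n2P + iE + aE + sE + n1E + n2E
    ctl <- lmeControl(maxIter=200, msMaxIter=200, opt="optim")
    full <- lme(fx, random=list(pid=pdSymm(~ -1 + iP + iE)),
                weights=varIdent(form=~1|out), data=d, method="ML", control=ctl)
    null <- lme(fx, random=list(pid=pdDiag(~ -1 + iP + iE)),
                weights=varIdent(form=~1|out), data=d, method="ML", control=ctl)
    cat(sprintf("%.8f %.8f", logLik(full), logLik(null)))
    '''
    out = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True, check=True)
    ll_full_r, ll_null_r = map(float, out.stdout.split())
    assert ff.loglik == pytest.approx(ll_full_r, abs=5e-3)
    assert fn.loglik == pytest.approx(ll_null_r, abs=5e-3)
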