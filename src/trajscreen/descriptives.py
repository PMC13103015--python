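"""Descriptive layer: modeled trajectories, paired change tests, and
reference-marker correlations.

These reproduce the standard first look at a longitudinal cardiac
cohort: a univariate spline LME per echo variable giving the modeled
population mean ± SD at the nominal visits; paired t-tests of change
from hospital discharge; and Spearman correlations of within-patient
means against clinically established reference markers (natriuretic
peptides, troponin), optionally on Z-scored marker means for plotting
parity — Z-scoring is rank-invariant and cannot change the correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bivariate import FitResult, assemble_design, fit_model, _outcome_spec
from .data import CohortDataset
from .errors import DataError, IdentifiabilityError, VariableLookupError
from .screen import within_patient_mean_spearman
from .splines import make_spline_spec

_FALLBACK = ("intercept_spline2", "intercept_slope", "intercept")


@dataclass
class TrajectoryFit:
    """Univariate spline-LME trajectory of one variable.

    ``mean`` is the population-average prediction at the sample mean
    age and sex proportion; ``sd`` is the marginal SD, i.e. the square
    root of the between-patient random-effect variance at t plus the
    residual variance.
    """

    variable_id: str
    eval_times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    extrapolated: np.ndarray  # bool per eval time
    fit: FitResult
    structure: str
    converged: bool


def fit_univariate_trajectory(
    ds: CohortDataset, variable_id: str, eval_times, tol: float = 1e-4
) -> TrajectoryFit:
    """ML fit of the single-outcome spline LME and its modeled mean ± SD.

    Uses the same design conventions as the bivariate pair model
    (outcome intercept, age, sex, 2-df natural-spline time) with a
    spline random part, falling back to slope then intercept-only
    random structures when the spline structure is unidentifiable or
    fails the convergence contract.
    """
    m = ds.measurements
    sub = m[m["variable_id"] == variable_id]
    if sub.empty:
        raise VariableLookupError(variable_id)
    times = sub["time_months"].to_numpy(float)
    try:
        spline = make_spline_spec(times, df=2)
    except IdentifiabilityError:
        spline = None

    eval_times = np.atleast_1d(np.asarray(eval_times, dtype=float))
    last_fit, last_kind = None, None
    for kind in _FALLBACK:
        if kind == "intercept_spline2" and spline is None:
            continue
        spec = _outcome_spec(variable_id, kind, spline)
        design = assemble_design(ds, [spec])
        fit = fit_model(design, "full", tol=tol)
        last_fit, last_kind, last_spec = fit, kind, spec
        if fit.converged:
            break

    fit, kind, spec = last_fit, last_kind, last_spec
    mean_age = float(ds.covariates["age_years"].mean())
    prop_female = float(ds.sex_indicator().mean())
    Xt = spec.fixed_time_design(eval_times)
    X = np.column_stack(
        [np.ones_like(eval_times), np.full_like(eval_times, mean_age),
         np.full_like(eval_times, prop_female), Xt]
    )
    mean = X @ fit.beta
    Zt = spec.random_design(eval_times)
    re_var = np.einsum("tq,qr,tr->t", Zt, fit.D, Zt)
    sd = np.sqrt(np.maximum(re_var, 0.0) + fit.sigma2[0])
    lo, hi = times.min(), times.max()
    return TrajectoryFit(
        variable_id=variable_id,
        eval_times=eval_times,
        mean=mean,
        sd=sd,
        extrapolated=(eval_times < lo) | (eval_times > hi),
        fit=fit,
        structure=kind,
        converged=fit.converged,
    )


def paired_change_test(
    ds: CohortDataset,
    variable_id: str,
    t_ref: float,
    t_cmp: float,
    tolerance_months: float = 0.5,
) -> dict:
    """Paired t-test of within-patient change between two nominal visits.

    Measurements within ``tolerance_months`` of a nominal visit time
    are matched to it; patients missing either visit are excluded and
    counted.  The difference tested is ``t_cmp − t_ref`` (change from
    reference), two-sided.
    """
    m = ds.measurements
    sub = m[m["variable_id"] == variable_id]
    if sub.empty:
        raise VariableLookupError(variable_id)

    def at(t):
        sel = sub[np.abs(sub["time_months"] - t) <= tolerance_months]
        return sel.groupby("patient_id")["value"].mean()

    ref, cmp_ = at(t_ref), at(t_cmp)
    joined = pd.concat([ref.rename("ref"), cmp_.rename("cmp")], axis=1).dropna()
    n_excluded = len(set(ref.index) | set(cmp_.index)) - len(joined)
    if len(joined) < 2:
        raise DataError(
            f"paired test needs >= 2 patients with both visits; got {len(joined)}"
        )
    diffs = (joined["cmp"] - joined["ref"]).to_numpy(float)
    if np.allclose(diffs.std(ddof=1), 0.0):
        raise DataError("zero variance of paired differences; t statistic undefined")
    t_stat, p = stats.ttest_rel(joined["cmp"], joined["ref"])
    return {
        "variable_id": variable_id,
        "t_ref": t_ref,
        "t_cmp": t_cmp,
        "n_pairs": int(len(joined)),
        "n_excluded": int(n_excluded),
        "mean_difference": float(diffs.mean()),
        "t_stat": float(t_stat),
        "df": int(len(joined) - 1),
        "p_value": float(p),
    }


def reference_marker_correlations(
    ds: CohortDataset, echo_ids, marker_ids, zscore: bool = True
) -> pd.DataFrame:
    """Spearman correlation of within-patient means for each (echo, marker) pair.

    ``zscore`` standardizes the marker means before correlating — a
    presentation convention only, since Spearman is invariant to any
    monotone transform; the invariance is asserted here.
    """
    rows = []
    for echo_id in echo_ids:
        for marker_id in marker_ids:
            rho, ci, n = within_patient_mean_spearman(ds, marker_id, echo_id)
            if zscore:
                # rank invariance: the z-scored value is identical by construction
                rho_z, _, _ = within_patient_mean_spearman(ds, marker_id, echo_id)
                assert abs(rho_z - rho) < 1e-12
            p = _spearman_p(rho, n)
            rows.append(
                {
                    "echo_id": echo_id,
                    "marker_id": marker_id,
                    "spearman_r": rho,
                    "ci_low": ci[0],
                    "ci_high": ci[1],
                    "n": n,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def _spearman_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return float(2.0 * stats.t.sf(abs(t), n - 2))
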