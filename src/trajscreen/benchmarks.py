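"""Simulation studies validating the screening machinery.

Each function here closes a loop the method depends on: the structured
marginal likelihood against a dense multivariate-normal evaluation,
type-I error calibration of the cross-block likelihood-ratio test,
recovery of the generating parameters, and screen-level FDR/recall.
They are consumed by the test suite and by ``scripts/acceptance.py``;
none of them is needed for ordinary use of the package.

All randomness flows from a single base seed through deterministic
per-replicate children, so every study is exactly reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .bivariate import assemble_pair_design, fit_pair, lrt_cross_block, marginal_loglik, pair_spec_from_data
from .data import apply_design_filters, log_transform_proteins
from .screen import ScreenConfig, fit_pair_with_fallback, run_screen
from .simulate import generate_cohort, make_null_config, pair_config, screen_config

_RI_LADDER = (("intercept", "intercept"),)


def _child_seed(base: int, i: int) -> int:
    return int((base * 1000003 + 7919 * i + 1) % (2**31 - 1))


def _prepared_pair_cohort(cfg, seed):
    ds, truth = generate_cohort(cfg, seed=seed)
    ds = apply_design_filters(log_transform_proteins(ds))
    return ds, truth


def loglik_oracle_check(n_instances: int = 50, seed: int = 0) -> dict:
    """Structured vs dense multivariate-normal log-likelihood.

    Builds small two-outcome designs (3 patients, ≤ 4 observations
    each) from tiny simulated cohorts, draws random parameter points
    with a random positive-definite D, and compares the pattern-batched
    evaluation against a direct per-patient dense normal density.
    Returns the maximum absolute discrepancy over all instances.
    """
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for i in range(n_instances):
        structure = ["intercept", "intercept_slope"][i % 2]
        cfg = pair_config(n_patients=3, rho=0.0, structure_P="intercept",
                          structure_E=structure, seed=_child_seed(seed, i))
        ds, _ = _prepared_pair_cohort(cfg, _child_seed(seed, i))
        spec = pair_spec_from_data(ds, "PROT1", "LVEDV", "intercept", structure, "full")
        design = assemble_pair_design(ds, "PROT1", "LVEDV", spec)
        q = design.q_total
        A = rng.normal(size=(q, q))
        D = A @ A.T + 0.1 * np.eye(q)
        beta = rng.normal(size=design.p)
        sigma2 = rng.uniform(0.5, 2.0, size=2)

        ll_structured = marginal_loglik(design, beta, sigma2, D)
        ll_dense = 0.0
        for g in design.groups:
            V = g.Z @ D @ g.Z.T + np.diag(sigma2[g.row_outcome])
            for j in range(g.y.shape[0]):
                mu = g.X[j] @ beta
                ll_dense += stats.multivariate_normal.logpdf(g.y[j], mean=mu, cov=V)
        max_diff = max(max_diff, abs(ll_structured - ll_dense))
    return {"max_abs_diff": float(max_diff), "n_instances": n_instances}


def null_calibration(
    n_reps: int = 500,
    n_patients: int = 150,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical type-I error of the cross-block LRT under the null.

    Cohorts are generated with a block-diagonal random-effects
    covariance (random intercepts on both sides, complete 3-visit
    grids); the rejection rate at ``alpha`` should sit near ``alpha``.
    """
    base = pair_config(n_patients=n_patients, rho=0.6, missingness=0.0)
    cfg = make_null_config(base)
    rejections, converged = 0, 0
    for i in range(n_reps):
        ds, _ = _prepared_pair_cohort(cfg, _child_seed(seed, i))
        res = fit_pair_with_fallback(
            ds, "PROT1", "LVEDV", ladder=_RI_LADDER, seed=_child_seed(seed, i)
        )
        if res.converged:
            converged += 1
            if res.lrt.p_value < alpha:
                rejections += 1
    rate = rejections / converged if converged else np.nan
    return {
        "rejection_rate": float(rate),
        "n_reps": n_reps,
        "n_converged": converged,
        "alpha": alpha,
    }


def parameter_recovery(
    n_reps: int = 100,
    n_patients: int = 300,
    rho: float = 0.6,
    seed: int = 0,
) -> dict:
    """Recovery of the generating parameters from repeated fits.

    Reports the median absolute error of the estimated cross-intercept
    correlation, and the relative error of the replicate-averaged
    fixed-effect and residual-variance estimates against the generating
    values (averaging across replicates isolates bias from sampling
    noise).
    """
    cfg = pair_config(n_patients=n_patients, rho=rho, missingness=0.0)
    rho_hats, sigma2_hats, beta_hats = [], [], []
    truth_beta = truth_sigma2 = None
    for i in range(n_reps):
        ds, truth = _prepared_pair_cohort(cfg, _child_seed(seed, i))
        res = fit_pair_with_fallback(
            ds, "PROT1", "LVEDV", ladder=_RI_LADDER, seed=_child_seed(seed, i)
        )
        if not res.converged:
            continue
        fit = res.fit_full
        rho_hats.append(fit.cross_correlation)
        sigma2_hats.append(fit.sigma2.copy())
        beta_hats.append(fit.beta.copy())
        truth_beta = np.concatenate([truth.beta["PROT1"], truth.beta["LVEDV"]])
        truth_sigma2 = np.array([truth.sigma2["PROT1"], truth.sigma2["LVEDV"]])
    rho_hats = np.asarray(rho_hats)
    beta_mean = np.mean(beta_hats, axis=0)
    sigma2_mean = np.mean(sigma2_hats, axis=0)
    beta_rel = np.abs(beta_mean - truth_beta) / np.abs(truth_beta)
    sigma2_rel = np.abs(sigma2_mean - truth_sigma2) / truth_sigma2
    return {
        "rho_true": rho,
        "median_abs_rho_error": float(np.median(np.abs(rho_hats - rho))),
        "mean_rho_hat": float(rho_hats.mean()),
        "max_rel_error_beta": float(beta_rel.max()),
        "max_rel_error_sigma2": float(sigma2_rel.max()),
        "n_converged": int(len(rho_hats)),
        "n_reps": n_reps,
    }


def screen_fdr_study(
    n_seeds: int = 20,
    n_proteins: int = 100,
    n_true: int = 10,
    rho: float = 0.7,
    n_patients: int = 250,
    q_threshold: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical FDR and recall of the full screen on synthetic cohorts.

    ``n_true`` proteins couple to the echo variable at cross-intercept
    correlation ``rho``; the remainder are null.  Discoveries are pairs
    with BH q below ``q_threshold``; the false-discovery proportion and
    recall are averaged over independently generated cohorts.
    """
    cfg = screen_config(
        n_proteins=n_proteins, n_true=n_true, rho=rho, n_patients=n_patients
    )
    true_set = {a.protein for a in cfg.associations}
    screen_cfg = ScreenConfig(ladder=_RI_LADDER)
    fdps, recalls = [], []
    for s in range(n_seeds):
        ds, _ = _prepared_pair_cohort(cfg, _child_seed(seed, s))
        results = run_screen(
            ds, ["LVEDV"], [p.name for p in cfg.proteins], config=screen_cfg,
            seed=_child_seed(seed, s),
        )
        discovered = {
            r.protein_id for r in results if r.fdr_q is not None and r.fdr_q < q_threshold
        }
        n_disc = len(discovered)
        false_disc = len(discovered - true_set)
        fdps.append(false_disc / n_disc if n_disc else 0.0)
        recalls.append(len(discovered & true_set) / len(true_set))
    return {
        "empirical_fdr": float(np.mean(fdps)),
        "recall": float(np.mean(recalls)),
        "n_seeds": n_seeds,
        "n_proteins": n_proteins,
        "n_true": n_true,
    }
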