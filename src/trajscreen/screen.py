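"""Proteome-wide screen of trajectory associations.

For each (protein, echo) pair the screen walks a fallback ladder of
random-effect structures, fits the full and block-diagonal bivariate
models at the first structure for which both satisfy the convergence
contract, tests the cross-outcome covariance block by likelihood ratio,
and finally applies Benjamini–Hochberg FDR control within each echo
variable's family of converged pairs.  Because random spline effects do
not offer a sign, the direction of each association is summarized by
the Spearman correlation between within-patient means of the two
variables.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bivariate import (
    FitResult,
    LrtResult,
    PairModelSpec,
    assemble_pair_design,
    fit_pair,
    lrt_cross_block,
    pair_spec_from_data,
    structure_dim,
)
from .data import CohortDataset
from .errors import ConfigError, DataError, DomainError, NumericalError, StateError
from .splines import make_spline_spec
from .errors import IdentifiabilityError

logger = logging.getLogger(__name__)

#: Default fallback ladder: start with the richest structure on both
#: sides, reduce (protein side first within a tier) until the
#: intercept-only/intercept-only floor.
DEFAULT_LADDER: tuple[tuple[str, str], ...] = (
    ("intercept_spline2", "intercept_spline2"),
    ("intercept_spline2", "intercept_slope"),
    ("intercept_slope", "intercept_spline2"),
    ("intercept_slope", "intercept_slope"),
    ("intercept_spline2", "intercept"),
    ("intercept", "intercept_spline2"),
    ("intercept_slope", "intercept"),
    ("intercept", "intercept_slope"),
    ("intercept", "intercept"),
)

_STRUCTURE_LABEL = {
    "intercept": "RI",
    "intercept_slope": "RI+slope",
    "intercept_spline2": "RI+splines",
}


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable knobs of :func:`run_screen`."""

    ladder: tuple[tuple[str, str], ...] = DEFAULT_LADDER
    fdr_family: str = "per-echo"  # 'per-echo' | 'pooled'
    alpha: float = 0.05
    tol: float = 1e-4
    restarts: int = 2
    maxiter: int = 500

    def __post_init__(self):
        for sp, se in self.ladder:
            structure_dim(sp)
            structure_dim(se)
        if self.fdr_family not in ("per-echo", "pooled"):
            raise ConfigError(f"unknown fdr_family {self.fdr_family!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")


@dataclass
class PairTestResult:
    """Outcome of screening one (protein, echo) pair."""

    protein_id: str
    echo_id: str
    structure_protein: str
    structure_echo: str
    lrt: LrtResult | None
    converged: bool
    fdr_q: float | None = None
    spearman_of_means: float | None = None
    spearman_ci: tuple[float, float] | None = None
    fit_full: FitResult | None = None
    fit_null: FitResult | None = None

    @property
    def p_value(self) -> float | None:
        return self.lrt.p_value if self.lrt is not None else None


def _pair_rng(base_seed: int, protein_id: str, echo_id: str) -> np.random.Generator:
    """Per-pair rng independent of processing order (stable CRC mix)."""
    tag = zlib.crc32(f"{protein_id}|{echo_id}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([base_seed & 0x7FFFFFFF, tag]))


def _structure_feasible(ds: CohortDataset, variable_id: str, kind: str) -> bool:
    """Cheap identifiability pre-check for a random-effect structure.

    A structure of dimension q needs at least q distinct observation
    times across the cohort and at least one patient with more than q
    observations of the variable (otherwise the subject-level variances
    cannot be separated from the residual variance).
    """
    m = ds.measurements
    sub = m[m["variable_id"] == variable_id]
    if sub.empty:
        return False
    q = structure_dim(kind)
    if sub["time_months"].nunique() < q:
        return False
    if int(sub.groupby("patient_id").size().max()) <= q:
        return False
    if kind == "intercept_spline2":
        try:
            make_spline_spec(sub["time_months"].to_numpy(float), df=2)
        except IdentifiabilityError:
            return False
    return True


def fit_pair_with_fallback(
    ds: CohortDataset,
    protein_id: str,
    echo_id: str,
    ladder=DEFAULT_LADDER,
    config: ScreenConfig | None = None,
    seed: int = 0,
) -> PairTestResult:
    """Walk the fallback ladder; LRT at the first structure where both
    the full and the block-diagonal fits meet the convergence contract.

    Candidates whose structures are not identifiable from the observed
    visit grid (e.g. spline random effects with < 3 distinct times) are
    skipped before any optimization.  If no candidate converges, the
    pair is reported with ``converged=False`` and no test.
    """
    cfg = config or ScreenConfig(ladder=tuple(tuple(s) for s in ladder))
    rng = _pair_rng(seed, protein_id, echo_id)
    tried: list[tuple[str, str]] = []
    for structure_P, structure_E in cfg.ladder:
        if not _structure_feasible(ds, protein_id, structure_P):
            continue
        if not _structure_feasible(ds, echo_id, structure_E):
            continue
        tried.append((structure_P, structure_E))
        t0 = time.perf_counter()
        try:
            spec_null = pair_spec_from_data(
                ds, protein_id, echo_id, structure_P, structure_E, "block_diagonal"
            )
            design = assemble_pair_design(ds, protein_id, echo_id, spec_null)
            fit_null = fit_pair(
                design, spec_null, tol=cfg.tol, restarts=cfg.restarts, rng=rng,
                maxiter=cfg.maxiter,
            )
            spec_full = pair_spec_from_data(
                ds, protein_id, echo_id, structure_P, structure_E, "full"
            )
            fit_full = fit_pair(
                design, spec_full, init=fit_null, tol=cfg.tol, restarts=cfg.restarts,
                rng=rng, maxiter=cfg.maxiter,
            )
        except (NumericalError, DataError, IdentifiabilityError) as e:
            logger.debug("pair (%s, %s) structure %s/%s failed: %s",
                         protein_id, echo_id, structure_P, structure_E, e)
            continue
        if fit_null.converged and fit_full.converged:
            lrt = lrt_cross_block(fit_full, fit_null, spec_full)
            logger.info(
                "pair (%s, %s): structures %s/%s, LRT=%.3f df=%d p=%.3g (%.2fs)",
                protein_id, echo_id, _STRUCTURE_LABEL[structure_P],
                _STRUCTURE_LABEL[structure_E], lrt.statistic, lrt.df, lrt.p_value,
                time.perf_counter() - t0,
            )
            return PairTestResult(
                protein_id=protein_id,
                echo_id=echo_id,
                structure_protein=_STRUCTURE_LABEL[structure_P],
                structure_echo=_STRUCTURE_LABEL[structure_E],
                lrt=lrt,
                converged=True,
                fit_full=fit_full,
                fit_null=fit_null,
            )
    last = tried[-1] if tried else ("intercept", "intercept")
    logger.warning("pair (%s, %s): no ladder candidate converged", protein_id, echo_id)
    return PairTestResult(
        protein_id=protein_id,
        echo_id=echo_id,
        structure_protein=_STRUCTURE_LABEL[last[0]],
        structure_echo=_STRUCTURE_LABEL[last[1]],
        lrt=None,
        converged=False,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values.

    NaN entries (pairs without a test) are excluded from the family and
    re-inserted as NaN; the family size m counts only finite p-values.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise DomainError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if finite.sum():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def within_patient_mean_spearman(
    ds: CohortDataset, protein_id: str, echo_id: str
) -> tuple[float, tuple[float, float], int]:
    """Spearman correlation of within-patient means, with Fisher-z 95% CI.

    Per patient, the mean of the available (log-scale) protein values
    and the mean of the available echo values; correlation across
    patients observed on both.  The confidence interval applies the
    Fisher z transform to the rank correlation with standard error
    ``1/sqrt(n - 3)``.
    """
    m = ds.measurements
    pm = (
        m[m["variable_id"] == protein_id].groupby("patient_id")["value"].mean()
    )
    em = m[m["variable_id"] == echo_id].groupby("patient_id")["value"].mean()
    joined = pd.concat([pm.rename("p"), em.rename("e")], axis=1).dropna()
    n = len(joined)
    if n < 3:
        raise DataError(
            f"need >= 3 patients with both {protein_id} and {echo_id}; got {n}"
        )
    rho = float(stats.spearmanr(joined["p"], joined["e"]).statistic)
    if n > 3 and abs(rho) < 1:
        z = np.arctanh(rho)
        half = 1.959963984540054 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    else:
        ci = (np.nan, np.nan)
    return rho, ci, n


def run_screen(
    ds: CohortDataset,
    echo_ids,
    protein_ids,
    config: ScreenConfig | None = None,
    seed: int = 0,
) -> list[PairTestResult]:
    """Screen every (protein, echo) pair and control the FDR.

    Pairs are fitted independently with order-independent per-pair
    seeding, so the result list is deterministic given the dataset,
    config and seed regardless of scheduling.  BH is applied within
    each echo variable's family over the converged pairs (or pooled
    across echo variables if configured); non-converged pairs carry no
    p-value and do not enter the family.
    """
    cfg = config or ScreenConfig()
    echo_ids = list(echo_ids)
    protein_ids = list(protein_ids)
    if not echo_ids or not protein_ids:
        raise ConfigError("need at least one echo id and one protein id")

    # the null model for a given echo structure is shared across all pairs
    # with that echo variable; warm starts come from it pair by pair anyway,
    # so the work loop is embarrassingly parallel by contract.
    results: list[PairTestResult] = []
    for echo_id in echo_ids:
        for protein_id in protein_ids:
            r = fit_pair_with_fallback(
                ds, protein_id, echo_id, ladder=cfg.ladder, config=cfg, seed=seed
            )
            try:
                rho, ci, _ = within_patient_mean_spearman(ds, protein_id, echo_id)
                r.spearman_of_means, r.spearman_ci = rho, ci
            except DataError:
                r.spearman_of_means, r.spearman_ci = None, None
            results.append(r)

    if cfg.fdr_family == "pooled":
        families = {None: results}
    else:
        families = {}
        for r in results:
            families.setdefault(r.echo_id, []).append(r)
    for fam in families.values():
        p = np.array(
            [r.p_value if r.p_value is not None else np.nan for r in fam], dtype=float
        )
        q = bh_adjust(p)
        for r, qi in zip(fam, q):
            r.fdr_q = float(qi) if np.isfinite(qi) else None
    return results
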