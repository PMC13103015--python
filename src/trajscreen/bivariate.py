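"""Bivariate linear mixed-effects model for one (biomarker, outcome) pair.

For patient ``i``, outcome ``k`` (P = log-protein, E = echocardiographic
variable) and visit time ``t`` the model is

    y_ik(t) = x_ik(t)' beta_k + z_ik(t)' b_ik + eps_ik(t)

where ``x`` holds an outcome-specific intercept, age, a sex indicator
(female = 1) and a 2-df natural-spline basis of time; ``z`` is the
outcome's random-effect design (random intercept; intercept + slope; or
intercept + 2-df spline); ``b_i = (b_iP, b_iE) ~ N(0, D)`` and
``eps_ik(t) ~ N(0, sigma_k^2)`` independent of everything else.

Under the *full* model ``D`` is an unstructured positive-definite
matrix of dimension ``q_P + q_E``, so the protein's and the outcome's
subject-level trajectory deviations may be correlated.  Under the
*null* model ``D`` is block-diagonal — the two trajectories share no
subject-level information.  The association test is the likelihood
ratio between the two, referred to a chi-squared distribution with
``q_P × q_E`` degrees of freedom (the number of cross-covariances set
to zero; these are interior points of the parameter space, so no
boundary mixture is needed).

Estimation is maximum likelihood.  Fixed effects are profiled out of
the marginal likelihood by generalized least squares; ``D`` is
parameterized through the log-Cholesky factorization (log diagonal,
free off-diagonal) so the optimization is smooth and unconstrained.
Patients sharing an observation pattern (same visit times per outcome)
share a marginal covariance, which the likelihood exploits by batching
the triangular solves per pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .data import CohortDataset
from .errors import (
    DataError,
    IdentifiabilityError,
    NumericalError,
    StateError,
    VariableLookupError,
)
from .splines import SplineBasisSpec, evaluate_basis, make_spline_spec

#: random-effect structure kinds and their dimension q
STRUCTURE_DIMS = {"intercept": 1, "intercept_slope": 2, "intercept_spline2": 3}

_LOG_BOUND = 15.0  # bound on log-scale parameters; keeps exp() finite
_COND_LIMIT = 1e10  # condition-number ceiling of D in the convergence contract


def structure_dim(kind: str) -> int:
    try:
        return STRUCTURE_DIMS[kind]
    except KeyError:
        raise IdentifiabilityError(f"unknown random-effect structure {kind!r}") from None


@dataclass(frozen=True)
class OutcomeSpec:
    """One outcome block of a (possibly multivariate) mixed model."""

    variable_id: str
    structure: str  # 'intercept' | 'intercept_slope' | 'intercept_spline2'
    spline: SplineBasisSpec | None = None  # basis for fixed (and spline-random) time terms
    fixed_time: str = "spline"  # 'spline' | 'linear' | 'none'

    def __post_init__(self):
        structure_dim(self.structure)
        if self.structure == "intercept_spline2" and self.spline is None:
            raise IdentifiabilityError(
                f"structure 'intercept_spline2' for {self.variable_id} needs a spline spec"
            )
        if self.fixed_time == "spline" and self.spline is None:
            raise IdentifiabilityError(
                f"fixed spline time effect for {self.variable_id} needs a spline spec"
            )

    @property
    def q(self) -> int:
        return structure_dim(self.structure)

    @property
    def n_fixed(self) -> int:
        n_time = {"spline": self.spline.df if self.spline else 0, "linear": 1, "none": 0}[
            self.fixed_time
        ]
        return 3 + n_time  # intercept, age, sex + time columns

    def fixed_names(self) -> list[str]:
        names = ["intercept", "age", "sex"]
        if self.fixed_time == "spline":
            names += [f"ns{i + 1}" for i in range(self.spline.df)]
        elif self.fixed_time == "linear":
            names += ["time"]
        return [f"{self.variable_id}:{n}" for n in names]

    def random_design(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        cols = [np.ones_like(t)]
        if self.structure == "intercept_slope":
            cols.append(t)
        elif self.structure == "intercept_spline2":
            cols.extend(evaluate_basis(self.spline, t).T)
        return np.column_stack(cols)

    def fixed_time_design(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.fixed_time == "spline":
            return evaluate_basis(self.spline, t)
        if self.fixed_time == "linear":
            return t[:, None]
        return np.empty((t.size, 0))


@dataclass(frozen=True)
class PairModelSpec:
    """Definition of the bivariate model for one (protein, echo) pair."""

    structure_P: str
    structure_E: str
    spline_P: SplineBasisSpec | None = None
    spline_E: SplineBasisSpec | None = None
    covariance_constraint: str = "full"  # 'full' | 'block_diagonal'

    def __post_init__(self):
        if self.covariance_constraint not in ("full", "block_diagonal"):
            raise IdentifiabilityError(
                f"unknown covariance constraint {self.covariance_constraint!r}"
            )

    @property
    def q_P(self) -> int:
        return structure_dim(self.structure_P)

    @property
    def q_E(self) -> int:
        return structure_dim(self.structure_E)


@dataclass
class PatternGroup:
    """All patients sharing one observation pattern (visit times per outcome)."""

    Z: np.ndarray  # (m, q_total) random-effect design
    X: np.ndarray  # (n_g, m, p) fixed design per patient
    y: np.ndarray  # (n_g, m) responses
    row_outcome: np.ndarray  # (m,) outcome index of each stacked row
    patient_ids: list


@dataclass
class Design:
    """Per-pattern stacked design bundle for a 1- or 2-outcome LMM."""

    groups: list[PatternGroup]
    outcome_specs: list[OutcomeSpec]
    beta_names: list[str]
    n_obs: int
    n_patients: int

    @property
    def q_blocks(self) -> list[int]:
        return [o.q for o in self.outcome_specs]

    @property
    def q_total(self) -> int:
        return sum(self.q_blocks)

    @property
    def p(self) -> int:
        return len(self.beta_names)

    @property
    def n_out(self) -> int:
        return len(self.outcome_specs)


@dataclass
class FitResult:
    """Maximum-likelihood fit of a (possibly constrained) LMM.

    ``D`` is the random-effects covariance over all outcome blocks;
    under the block-diagonal constraint its cross-outcome entries are
    exactly zero.  ``cov_beta`` is the GLS covariance of the fixed
    effects at the ML variance parameters.
    """

    beta: np.ndarray
    beta_names: list[str]
    sigma2: np.ndarray  # per-outcome residual variances
    D: np.ndarray
    q_blocks: list[int]
    loglik: float
    converged: bool
    n_iter: int
    gradient_norm: float
    constraint: str
    cov_beta: np.ndarray | None = None

    def _block_slice(self, k: int) -> slice:
        start = sum(self.q_blocks[:k])
        return slice(start, start + self.q_blocks[k])

    @property
    def sigma2_P(self) -> float:
        return float(self.sigma2[0])

    @property
    def sigma2_E(self) -> float:
        return float(self.sigma2[-1])

    @property
    def D_P(self) -> np.ndarray:
        s = self._block_slice(0)
        return self.D[s, s]

    @property
    def D_E(self) -> np.ndarray:
        s = self._block_slice(len(self.q_blocks) - 1)
        return self.D[s, s]

    @property
    def D_cross(self) -> np.ndarray:
        """Cross-outcome covariance block (q_P x q_E)."""
        sP, sE = self._block_slice(0), self._block_slice(1)
        return self.D[sP, sE]

    @property
    def cross_correlation(self) -> float:
        """Correlation between the two random intercepts."""
        iP, iE = 0, self.q_blocks[0]
        denom = np.sqrt(self.D[iP, iP] * self.D[iE, iE])
        if denom <= 0:
            return np.nan
        return float(self.D[iP, iE] / denom)


@dataclass(frozen=True)
class LrtResult:
    """Likelihood-ratio test of the cross-outcome covariance block."""

    statistic: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------


def _per_patient_tables(ds: CohortDataset, variable_ids: list[str]):
    m = ds.measurements
    sub = m[m["variable_id"].isin(variable_ids)]
    out: dict = {}
    for (pid, vid), grp in sub.groupby(["patient_id", "variable_id"], sort=True):
        g = grp.sort_values("time_months")
        out.setdefault(pid, {})[vid] = (
            g["time_months"].to_numpy(float),
            g["value"].to_numpy(float),
        )
    return out


def assemble_design(ds: CohortDataset, outcome_specs: list[OutcomeSpec]) -> Design:
    """Stack responses and build per-pattern design matrices.

    Every patient with at least one observation of at least one outcome
    contributes; rows are ordered by outcome block, then time.  Patients
    observed on only one outcome carry no cross-block information but
    still sharpen the within-block estimates.
    """
    ids = [o.variable_id for o in outcome_specs]
    present = set(ds.measurements["variable_id"].unique())
    for vid in ids:
        if vid not in present:
            raise VariableLookupError(vid)

    tables = _per_patient_tables(ds, ids)
    if not tables:
        raise DataError("no usable patients for the requested variables")

    cov = ds.covariates.set_index("patient_id")
    sex = ds.sex_indicator()

    q_offsets = np.cumsum([0] + [o.q for o in outcome_specs])
    p_offsets = np.cumsum([0] + [o.n_fixed for o in outcome_specs])
    p_total = int(p_offsets[-1])
    q_total = int(q_offsets[-1])
    beta_names = [n for o in outcome_specs for n in o.fixed_names()]

    # group patients by observation pattern
    buckets: dict = {}
    for pid in sorted(tables):
        per_var = tables[pid]
        key = tuple(tuple(per_var[vid][0]) if vid in per_var else () for vid in ids)
        buckets.setdefault(key, []).append(pid)

    groups: list[PatternGroup] = []
    n_obs = 0
    for key, pids in sorted(buckets.items()):
        m_rows = sum(len(tk) for tk in key)
        if m_rows == 0:
            continue
        Z = np.zeros((m_rows, q_total))
        template = np.zeros((m_rows, p_total))
        row_outcome = np.zeros(m_rows, dtype=int)
        age_cols, sex_cols = [], []
        r = 0
        for k, (o, tk) in enumerate(zip(outcome_specs, key)):
            tk = np.asarray(tk, dtype=float)
            nk = tk.size
            if nk == 0:
                continue
            rows = slice(r, r + nk)
            row_outcome[rows] = k
            Z[rows, q_offsets[k] : q_offsets[k] + o.q] = o.random_design(tk)
            base = p_offsets[k]
            template[rows, base] = 1.0  # intercept
            template[rows, base + 1] = 1.0  # age placeholder
            template[rows, base + 2] = 1.0  # sex placeholder
            tcols = o.fixed_time_design(tk)
            if tcols.shape[1]:
                template[rows, base + 3 : base + 3 + tcols.shape[1]] = tcols
            age_cols.append(base + 1)
            sex_cols.append(base + 2)
            r += nk
        n_g = len(pids)
        factor = np.ones((n_g, p_total))
        ages = cov.loc[pids, "age_years"].to_numpy(float)
        sexes = sex.loc[pids].to_numpy(float)
        for c in age_cols:
            factor[:, c] = ages
        for c in sex_cols:
            factor[:, c] = sexes
        X = template[None, :, :] * factor[:, None, :]
        y = np.empty((n_g, m_rows))
        for j, pid in enumerate(pids):
            vals = []
            for vid, tk in zip(ids, key):
                if len(tk):
                    vals.append(tables[pid][vid][1])
            y[j] = np.concatenate(vals)
        groups.append(PatternGroup(Z=Z, X=X, y=y, row_outcome=row_outcome, patient_ids=pids))
        n_obs += n_g * m_rows

    return Design(
        groups=groups,
        outcome_specs=outcome_specs,
        beta_names=beta_names,
        n_obs=n_obs,
        n_patients=sum(len(g.patient_ids) for g in groups),
    )


def pair_spec_from_data(
    ds: CohortDataset,
    protein_id: str,
    echo_id: str,
    structure_P: str = "intercept",
    structure_E: str = "intercept",
    covariance_constraint: str = "full",
) -> PairModelSpec:
    """Build a :class:`PairModelSpec` with knots placed from the observed times.

    Knots are per-variable (the protein and echo visit grids differ):
    boundary at the min/max observed times, interior at the median with
    multiplicity.
    """
    m = ds.measurements

    def times_of(vid):
        t = m.loc[m["variable_id"] == vid, "time_months"].to_numpy(float)
        if t.size == 0:
            raise VariableLookupError(vid)
        return t

    def maybe_spline(t):
        try:
            return make_spline_spec(t, df=2)
        except IdentifiabilityError:
            return None

    return PairModelSpec(
        structure_P=structure_P,
        structure_E=structure_E,
        spline_P=maybe_spline(times_of(protein_id)),
        spline_E=maybe_spline(times_of(echo_id)),
        covariance_constraint=covariance_constraint,
    )


def _outcome_spec(variable_id: str, structure: str, spline) -> OutcomeSpec:
    if spline is not None:
        fixed_time = "spline"
    else:
        fixed_time = "linear"
        if structure == "intercept_spline2":
            raise IdentifiabilityError(
                f"spline random effects for {variable_id} need a valid spline spec"
            )
    return OutcomeSpec(variable_id, structure, spline, fixed_time)


def assemble_pair_design(
    ds: CohortDataset, protein_id: str, echo_id: str, spec: PairModelSpec
) -> Design:
    """Stacked two-outcome design for one (protein, echo) pair."""
    specs = [
        _outcome_spec(protein_id, spec.structure_P, spec.spline_P),
        _outcome_spec(echo_id, spec.structure_E, spec.spline_E),
    ]
    return assemble_design(ds, specs)


def split_design(design: Design) -> list[Design]:
    """Decompose a multi-outcome design into independent per-outcome designs.

    Exact under a block-diagonal D with independent residuals: the joint
    likelihood factorizes over outcomes, so the null model can be fitted
    one outcome at a time.
    """
    singles = []
    for k, o in enumerate(design.outcome_specs):
        qs = slice(sum(design.q_blocks[:k]), sum(design.q_blocks[: k + 1]))
        p_off = np.cumsum([0] + [s.n_fixed for s in design.outcome_specs])
        ps = slice(int(p_off[k]), int(p_off[k + 1]))
        buckets: dict = {}
        for g in design.groups:
            rows = np.flatnonzero(g.row_outcome == k)
            if rows.size == 0:
                continue
            Zk = g.Z[np.ix_(rows, range(qs.start, qs.stop))]
            key = (tuple(map(tuple, np.round(Zk, 12))),)
            ent = buckets.setdefault(
                key, {"Z": Zk, "X": [], "y": [], "pids": [], "Xt": g.X[:, rows, ps]}
            )
            ent["X"].append(g.X[:, rows, ps])
            ent["y"].append(g.y[:, rows])
            ent["pids"].extend(g.patient_ids)
        groups = []
        n_obs = 0
        for ent in buckets.values():
            X = np.concatenate(ent["X"], axis=0)
            y = np.concatenate(ent["y"], axis=0)
            groups.append(
                PatternGroup(
                    Z=ent["Z"],
                    X=X,
                    y=y,
                    row_outcome=np.zeros(ent["Z"].shape[0], dtype=int),
                    patient_ids=ent["pids"],
                )
            )
            n_obs += y.size
        singles.append(
            Design(
                groups=groups,
                outcome_specs=[o],
                beta_names=o.fixed_names(),
                n_obs=n_obs,
                n_patients=sum(len(g.patient_ids) for g in groups),
            )
        )
    return singles


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------

_LOG_2PI = np.log(2.0 * np.pi)


def _gather_terms(design: Design, sigma2: np.ndarray, D: np.ndarray):
    """Accumulate logdet, X'V^-1X, X'V^-1y and y'V^-1y over all patients."""
    p = design.p
    A = np.zeros((p, p))
    c = np.zeros(p)
    yy = 0.0
    logdet = 0.0
    N = 0
    for g in design.groups:
        m = g.Z.shape[0]
        V = g.Z @ D @ g.Z.T
        V[np.diag_indices(m)] += sigma2[g.row_outcome]
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError as e:
            raise NumericalError(
                f"marginal covariance not positive definite (m={m}, "
                f"min diag {V.diagonal().min():.3e})"
            ) from e
        n_g = g.y.shape[0]
        logdet += n_g * 2.0 * np.log(np.diagonal(L)).sum()
        Xw = solve_triangular(
            L, g.X.transpose(1, 0, 2).reshape(m, n_g * p), lower=True, check_finite=False
        ).reshape(m, n_g, p)
        yw = solve_triangular(L, g.y.T, lower=True, check_finite=False)
        A += np.einsum("mnp,mnq->pq", Xw, Xw, optimize=True)
        c += np.einsum("mnp,mn->p", Xw, yw, optimize=True)
        yy += float((yw**2).sum())
        N += n_g * m
    return A, c, yy, logdet, N


def marginal_loglik(design: Design, beta, sigma2, D) -> float:
    """Marginal log-likelihood at explicit parameter values.

    Sum over patients of the log density of the stacked response under
    ``N(X_i beta, Z_i D Z_i' + R_i)`` with ``R_i`` diagonal holding the
    outcome-matched residual variances, evaluated through per-pattern
    Cholesky factorizations.
    """
    beta = np.asarray(beta, dtype=float)
    sigma2 = np.atleast_1d(np.asarray(sigma2, dtype=float))
    D = np.asarray(D, dtype=float)
    if not np.all(sigma2 > 0):
        raise NumericalError("residual variances must be positive")
    if not np.allclose(D, D.T, atol=1e-10):
        raise NumericalError("D must be symmetric")
    eig = np.linalg.eigvalsh((D + D.T) / 2.0)
    if eig.min() < -1e-8:
        raise NumericalError(f"D not positive semidefinite (min eigenvalue {eig.min():.3e})")
    A, c, yy, logdet, N = _gather_terms(design, sigma2, D)
    quad = yy - 2.0 * c @ beta + beta @ A @ beta
    return -0.5 * (N * _LOG_2PI + logdet + quad)


# ---------------------------------------------------------------------------
# parameterization and fitting
# ---------------------------------------------------------------------------


def _n_chol_params(q_blocks: list[int], constraint: str) -> int:
    if constraint == "full":
        q = sum(q_blocks)
        return q * (q + 1) // 2
    return sum(q * (q + 1) // 2 for q in q_blocks)


def _unpack(theta: np.ndarray, q_blocks: list[int], n_out: int, constraint: str):
    sigma2 = np.exp(2.0 * theta[:n_out])
    q = sum(q_blocks)
    L = np.zeros((q, q))
    idx = n_out
    if constraint == "full":
        for i in range(q):
            for j in range(i + 1):
                L[i, j] = np.exp(theta[idx]) if i == j else theta[idx]
                idx += 1
    else:
        off = 0
        for qb in q_blocks:
            for i in range(qb):
                for j in range(i + 1):
                    L[off + i, off + j] = np.exp(theta[idx]) if i == j else theta[idx]
                    idx += 1
            off += qb
    return sigma2, L


def _pack(sigma2: np.ndarray, L: np.ndarray, q_blocks: list[int], constraint: str) -> np.ndarray:
    theta = [0.5 * np.log(s) for s in sigma2]
    q = sum(q_blocks)
    if constraint == "full":
        for i in range(q):
            for j in range(i + 1):
                theta.append(np.log(max(L[i, j], 1e-8)) if i == j else L[i, j])
    else:
        off = 0
        for qb in q_blocks:
            for i in range(qb):
                for j in range(i + 1):
                    v = L[off + i, off + j]
                    theta.append(np.log(max(v, 1e-8)) if i == j else v)
            off += qb
    return np.asarray(theta)


def _profiled_nll(theta, design: Design, constraint: str, want_beta: bool = False):
    n_out = design.n_out
    sigma2, L = _unpack(theta, design.q_blocks, n_out, constraint)
    D = L @ L.T
    # a large finite penalty (not inf) keeps line searches usable
    penalty = 1e12
    try:
        A, c, yy, logdet, N = _gather_terms(design, sigma2, D)
    except NumericalError:
        return (penalty, None, None) if want_beta else penalty
    try:
        beta = np.linalg.solve(A, c)
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(A, c, rcond=None)
    quad = yy - 2.0 * c @ beta + beta @ A @ beta
    nll = 0.5 * (N * _LOG_2PI + logdet + quad)
    if not np.isfinite(nll):
        nll = penalty
    if want_beta:
        return nll, beta, A
    return nll


def _nll_and_grad(theta, design: Design, constraint: str):
    """Profiled negative log-likelihood and its analytic gradient.

    The gradient is exact at the profiled beta-hat by the envelope
    theorem: d nll / d theta = 0.5 * tr(M dV/dtheta) summed over
    patients, with ``M = V^-1 - V^-1 r r' V^-1`` accumulated per
    observation pattern.  For the log-Cholesky parameters of D the
    trace reduces to entries of (Z'MZ) L; for the log residual SDs it
    is the diagonal of M restricted to the outcome's rows.
    """
    n_out = design.n_out
    sigma2, L = _unpack(theta, design.q_blocks, n_out, constraint)
    D = L @ L.T
    penalty = 1e12
    p = design.p
    q = design.q_total

    cache = []
    A = np.zeros((p, p))
    c = np.zeros(p)
    yy = 0.0
    logdet = 0.0
    N = 0
    for g in design.groups:
        m = g.Z.shape[0]
        V = g.Z @ D @ g.Z.T
        V[np.diag_indices(m)] += sigma2[g.row_outcome]
        try:
            LV = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return penalty, np.zeros_like(theta)
        n_g = g.y.shape[0]
        logdet += n_g * 2.0 * np.log(np.diagonal(LV)).sum()
        Xw = solve_triangular(
            LV, g.X.transpose(1, 0, 2).reshape(m, n_g * p), lower=True, check_finite=False
        ).reshape(m, n_g, p)
        yw = solve_triangular(LV, g.y.T, lower=True, check_finite=False)
        A += np.einsum("mnp,mnq->pq", Xw, Xw, optimize=True)
        c += np.einsum("mnp,mn->p", Xw, yw, optimize=True)
        yy += float((yw**2).sum())
        N += n_g * m
        cache.append((g, LV, Xw, yw))

    try:
        beta = np.linalg.solve(A, c)
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(A, c, rcond=None)
    quad = yy - 2.0 * c @ beta + beta @ A @ beta
    nll = 0.5 * (N * _LOG_2PI + logdet + quad)
    if not np.isfinite(nll):
        return penalty, np.zeros_like(theta)

    Gsum = np.zeros((q, q))
    diag_by_outcome = np.zeros(n_out)
    for g, LV, Xw, yw in cache:
        m = g.Z.shape[0]
        n_g = g.y.shape[0]
        rw = yw - np.einsum("mnp,p->mn", Xw, beta, optimize=True)  # (m, n_g)
        S = rw @ rw.T  # sum of whitened residual outer products
        W = solve_triangular(LV, np.eye(m), lower=True, check_finite=False)
        Vinv = W.T @ W
        P = W.T @ (S @ W)  # V^-1 (sum r r') V^-1  via whitened S
        M = n_g * Vinv - P
        Gsum += g.Z.T @ M @ g.Z
        Mdiag = np.diagonal(M)
        for k in range(n_out):
            diag_by_outcome[k] += Mdiag[g.row_outcome == k].sum()

    grad = np.zeros_like(np.asarray(theta, dtype=float))
    grad[:n_out] = sigma2 * diag_by_outcome  # d/d log sigma_k (x2 sigma chain /2)
    GL = Gsum @ L
    idx = n_out
    if constraint == "full":
        for i in range(q):
            for j in range(i + 1):
                grad[idx] = GL[i, j] * (L[i, j] if i == j else 1.0)
                idx += 1
    else:
        off = 0
        for qb in design.q_blocks:
            for i in range(qb):
                for j in range(i + 1):
                    a, b = off + i, off + j
                    grad[idx] = GL[a, b] * (L[a, b] if a == b else 1.0)
                    idx += 1
            off += qb
    return nll, grad


def _default_start(design: Design, constraint: str) -> np.ndarray:
    """Moment-based start: split each outcome's variance between the
    random intercept and the residual; small variances for slope/spline
    dimensions scaled by their design-column magnitudes."""
    n_out = design.n_out
    var_k = np.ones(n_out)
    for k in range(n_out):
        vals = np.concatenate(
            [g.y[:, g.row_outcome == k].ravel() for g in design.groups if (g.row_outcome == k).any()]
        )
        v = float(np.var(vals)) if vals.size > 1 else 1.0
        var_k[k] = max(v, 1e-6)
    sigma2 = var_k / 2.0
    q_blocks = design.q_blocks
    L = np.zeros((sum(q_blocks), sum(q_blocks)))
    off = 0
    for k, qb in enumerate(q_blocks):
        zcols = np.concatenate(
            [g.Z[g.row_outcome == k, off : off + qb] for g in design.groups], axis=0
        )
        scale = np.maximum(np.mean(zcols**2, axis=0), 1e-2)
        for j in range(qb):
            L[off + j, off + j] = np.sqrt(var_k[k] / (2.0 * qb * scale[j]))
        off += qb
    return _pack(sigma2, L, q_blocks, constraint)


def _bounds(n_params: int, n_out: int, q_blocks, constraint) -> list[tuple]:
    bounds: list[tuple] = [(-_LOG_BOUND, _LOG_BOUND)] * n_out
    q = sum(q_blocks)
    if constraint == "full":
        for i in range(q):
            for j in range(i + 1):
                bounds.append((-_LOG_BOUND, _LOG_BOUND) if i == j else (-1e6, 1e6))
    else:
        for qb in q_blocks:
            for i in range(qb):
                for j in range(i + 1):
                    bounds.append((-_LOG_BOUND, _LOG_BOUND) if i == j else (-1e6, 1e6))
    return bounds


def _optimize(design, constraint, theta0, tol, maxiter):
    res = optimize.minimize(
        _nll_and_grad,
        theta0,
        args=(design, constraint),
        jac=True,
        method="L-BFGS-B",
        bounds=_bounds(len(theta0), design.n_out, design.q_blocks, constraint),
        options={"maxiter": maxiter, "maxfun": 20 * maxiter, "ftol": 1e-11, "gtol": 1e-6},
    )
    relgrad = float(np.max(np.abs(res.jac))) / (1.0 + abs(float(res.fun)))
    return res, relgrad


def _result_from(res, relgrad, design, constraint, tol) -> FitResult:
    sigma2, L = _unpack(res.x, design.q_blocks, design.n_out, constraint)
    D = L @ L.T
    nll, beta, A = _profiled_nll(res.x, design, constraint, want_beta=True)
    if beta is None:
        raise NumericalError("optimum lies in a numerically invalid region")
    loglik = -float(nll)
    eig = np.linalg.eigvalsh(D)
    cond = eig.max() / max(eig.min(), 1e-300) if eig.max() > 0 else np.inf
    converged = bool(
        res.success and np.isfinite(loglik) and relgrad < tol and cond < _COND_LIMIT
    )
    try:
        cov_beta = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        cov_beta = None
    return FitResult(
        beta=beta,
        beta_names=design.beta_names,
        sigma2=sigma2,
        D=D,
        q_blocks=design.q_blocks,
        loglik=loglik,
        converged=converged,
        n_iter=int(res.nit),
        gradient_norm=relgrad,
        constraint=constraint,
        cov_beta=cov_beta,
    )


def fit_model(
    design: Design,
    constraint: str = "full",
    init: np.ndarray | FitResult | None = None,
    tol: float = 1e-4,
    restarts: int = 2,
    rng: np.random.Generator | None = None,
    maxiter: int = 500,
) -> FitResult:
    """Maximize the ML marginal likelihood of a stacked LMM.

    ``init`` may be a packed parameter vector or a previous
    :class:`FitResult` (e.g. the block-diagonal fit warm-starting the
    full fit).  On failure of the convergence contract, up to
    ``restarts`` randomly perturbed starts are tried; the best point
    found is always returned, with ``converged`` reporting whether any
    start met the contract.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if isinstance(init, FitResult):
        L = np.linalg.cholesky(init.D + 1e-10 * np.eye(init.D.shape[0]))
        theta0 = _pack(init.sigma2, L, design.q_blocks, constraint)
    elif init is not None:
        theta0 = np.asarray(init, dtype=float)
    else:
        theta0 = _default_start(design, constraint)

    best: FitResult | None = None
    for attempt in range(restarts + 1):
        start = theta0 if attempt == 0 else theta0 + rng.normal(0.0, 0.3, size=theta0.shape)
        try:
            res, relgrad = _optimize(design, constraint, start, tol, maxiter)
        except (NumericalError, np.linalg.LinAlgError):
            continue
        fit = _result_from(res, relgrad, design, constraint, tol)
        if best is None or (fit.converged and not best.converged) or (
            fit.converged == best.converged and fit.loglik > best.loglik
        ):
            best = fit
        if best.converged:
            break
    if best is None:
        raise NumericalError("all optimization starts failed with numerical errors")
    return best


def fit_pair(
    design: Design,
    spec: PairModelSpec,
    init: np.ndarray | FitResult | None = None,
    tol: float = 1e-4,
    restarts: int = 2,
    rng: np.random.Generator | None = None,
    maxiter: int = 500,
) -> FitResult:
    """Fit the bivariate pair model under the spec's covariance constraint.

    Under the block-diagonal constraint the joint likelihood factorizes
    over the two outcomes, so the null model is fitted as two
    independent single-outcome models and reassembled — exactly
    equivalent to the joint constrained optimization and considerably
    better behaved.
    """
    if spec.covariance_constraint == "block_diagonal":
        singles = split_design(design)
        fits = [
            fit_model(d, "full", None, tol, restarts, rng, maxiter) for d in singles
        ]
        q = design.q_total
        D = np.zeros((q, q))
        off = 0
        for f, qb in zip(fits, design.q_blocks):
            D[off : off + qb, off : off + qb] = f.D
            off += qb
        p_sizes = [len(f.beta) for f in fits]
        cov_beta = None
        if all(f.cov_beta is not None for f in fits):
            cov_beta = np.zeros((sum(p_sizes), sum(p_sizes)))
            o = 0
            for f, psz in zip(fits, p_sizes):
                cov_beta[o : o + psz, o : o + psz] = f.cov_beta
                o += psz
        return FitResult(
            beta=np.concatenate([f.beta for f in fits]),
            beta_names=design.beta_names,
            sigma2=np.array([float(f.sigma2[0]) for f in fits]),
            D=D,
            q_blocks=design.q_blocks,
            loglik=sum(f.loglik for f in fits),
            converged=all(f.converged for f in fits),
            n_iter=sum(f.n_iter for f in fits),
            gradient_norm=max(f.gradient_norm for f in fits),
            constraint="block_diagonal",
            cov_beta=cov_beta,
        )
    return fit_model(design, "full", init, tol, restarts, rng, maxiter)


def lrt_cross_block(fit_full: FitResult, fit_null: FitResult, spec: PairModelSpec) -> LrtResult:
    """Likelihood-ratio test that the cross-outcome covariance block is zero.

    ``statistic = 2 (l_full - l_null)``, clamped at zero (warning if
    more negative than optimizer noise allows), with ``q_P * q_E``
    degrees of freedom.
    """
    if not (fit_full.converged and fit_null.converged):
        raise StateError("both fits must satisfy the convergence contract before the LRT")
    stat = 2.0 * (fit_full.loglik - fit_null.loglik)
    if stat < -1e-6 * (1.0 + abs(fit_null.loglik)):
        raise NumericalError(
            f"full-model loglik {fit_full.loglik:.6f} below null {fit_null.loglik:.6f}; "
            "nesting violated beyond optimizer tolerance"
        )
    if stat < 0:
        warnings.warn("LRT statistic slightly negative; clamped to 0", RuntimeWarning)
        stat = 0.0
    df = spec.q_P * spec.q_E
    p = float(stats.chi2.sf(stat, df))
    return LrtResult(statistic=float(stat), df=df, p_value=p)
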