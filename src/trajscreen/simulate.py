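"""Synthetic post-MI cohort generator with known ground truth.

The generator draws cohorts from exactly the statistical structure the
screening pipeline assumes: per-patient random trajectories for
log-scale proteins and for echocardiographic variables, subject-level
random effects whose intercepts may be correlated across a designated
(protein, echo) pair, age and sex fixed effects, Gaussian residual
noise, asynchronous visit grids (echo at 0/3/12 months, proteins at
1/3/12 — no baseline protein draw), and visit-level missingness.

Protein values are emitted on the raw, exponentiated
relative-fluorescence-like scale so the pipeline's log-transform step
is exercised end to end.  The generating parameters and the realized
random effects are returned as a :class:`SyntheticTruth` that fitting
code never sees — it exists only so recovery tests can close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from .bivariate import structure_dim
from .data import CohortDataset, make_cohort
from .errors import ConfigError
from .splines import evaluate_basis, make_spline_spec


@dataclass(frozen=True)
class VariableSpec:
    """Generating parameters for one longitudinal variable.

    ``spline_coefs`` are coefficients on the 2-df natural-spline basis
    built from ``times`` (boundary knots at min/max, interior at the
    median), i.e. the same basis the fitting code will construct, so
    fixed-effect recovery is parameter-for-parameter.  ``re_sd`` gives
    the standard deviations of the random-effect dimensions implied by
    ``structure`` (intercept; intercept+slope; intercept+2-df spline).
    """

    name: str
    var_type: str  # 'protein' | 'echo'
    times: tuple[float, ...]
    intercept: float
    spline_coefs: tuple[float, float]
    age_effect: float
    sex_effect: float
    structure: str  # random-effect structure kind
    re_sd: tuple[float, ...]
    sigma: float

    def __post_init__(self):
        q = structure_dim(self.structure)
        if len(self.re_sd) != q:
            raise ConfigError(
                f"{self.name}: structure {self.structure!r} needs {q} re_sd entries, "
                f"got {len(self.re_sd)}"
            )
        if any(s < 0 for s in self.re_sd) or self.sigma <= 0:
            raise ConfigError(f"{self.name}: standard deviations must be non-negative")
        if self.var_type == "protein" and 0.0 in self.times:
            raise ConfigError(
                f"{self.name}: protein variables are never measured at t=0 "
                "(acute-phase exclusion)"
            )
        if len(set(self.times)) < 3:
            raise ConfigError(f"{self.name}: need >= 3 distinct visit times")


@dataclass(frozen=True)
class Association:
    """Correlation rho between a protein's and an echo variable's random intercepts."""

    protein: str
    echo: str
    rho: float

    def __post_init__(self):
        if not -1.0 < self.rho < 1.0:
            raise ConfigError(f"rho must be in (-1, 1), got {self.rho}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a synthetic cohort."""

    echo_vars: tuple[VariableSpec, ...]
    proteins: tuple[VariableSpec, ...]
    associations: tuple[Association, ...] = ()
    n_patients: int = 246
    missingness: float = 0.05
    missingness_level: str = "visit"  # 'visit' (per patient x time x modality) | 'measurement'
    age_range: tuple[float, float] = (40.0, 80.0)
    female_prop: float = 0.19
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if not 0.0 <= self.missingness < 1.0:
            raise ConfigError("missingness must be in [0, 1)")
        if self.missingness_level not in ("visit", "measurement"):
            raise ConfigError(f"unknown missingness_level {self.missingness_level!r}")
        names = [v.name for v in self.echo_vars + self.proteins]
        if len(set(names)) != len(names):
            raise ConfigError("variable names must be unique")
        echo_names = {v.name for v in self.echo_vars}
        prot_names = {v.name for v in self.proteins}
        seen = set()
        for a in self.associations:
            if a.protein not in prot_names or a.echo not in echo_names:
                raise ConfigError(f"association references unknown variables: {a}")
            if a.protein in seen:
                raise ConfigError(f"protein {a.protein} appears in more than one association")
            seen.add(a.protein)


@dataclass
class SyntheticTruth:
    """Generating parameters and realized random effects of a cohort.

    Kept strictly outside the fitting code paths; consumed only by
    recovery tests and simulation studies.
    """

    config: SyntheticConfig
    beta: dict  # name -> [intercept, age, sex, ns1, ns2]
    sigma2: dict  # name -> residual variance
    re_sd: dict  # name -> per-dimension random-effect SDs
    rho: dict  # (protein, echo) -> generating cross-correlation
    random_effects: dict  # name -> (n_patients, q) realized effects
    ages: np.ndarray = field(default_factory=lambda: np.empty(0))
    sex_female: np.ndarray = field(default_factory=lambda: np.empty(0))


def make_null_config(cfg: SyntheticConfig) -> SyntheticConfig:
    """Zero every cross-outcome correlation, leaving all variances untouched."""
    null_assoc = tuple(replace(a, rho=0.0) for a in cfg.associations)
    return replace(cfg, associations=null_assoc)


def _random_design(spec: VariableSpec, t: np.ndarray, basis: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(t)]
    if spec.structure == "intercept_slope":
        cols.append(t)
    elif spec.structure == "intercept_spline2":
        cols.extend(basis.T)
    return np.column_stack(cols)


def generate_cohort(
    cfg: SyntheticConfig, seed: int | None = None
) -> tuple[CohortDataset, SyntheticTruth]:
    """Draw one cohort; byte-for-byte deterministic given config and seed.

    Ages are Uniform over ``age_range``; sex is Bernoulli(``female_prop``)
    for female.  Echo random effects are drawn first; each associated
    protein's random intercept is then drawn conditionally on its echo
    partner's so the pair's intercepts have correlation ``rho`` (all
    other random-effect dimensions are mutually independent).  Protein
    trajectories are simulated on the natural-log scale and exponentiated
    before output.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_patients
    pids = np.array([f"P{i + 1:04d}" for i in range(n)])
    ages = rng.uniform(*cfg.age_range, size=n)
    female = (rng.random(n) < cfg.female_prop).astype(float)

    assoc_by_protein = {a.protein: a for a in cfg.associations}
    echo_specs = {v.name: v for v in cfg.echo_vars}

    # random effects: echo first, then proteins (conditionally for associated ones)
    b: dict[str, np.ndarray] = {}
    for v in cfg.echo_vars:
        b[v.name] = rng.normal(0.0, 1.0, size=(n, len(v.re_sd))) * np.asarray(v.re_sd)
    for v in cfg.proteins:
        raw = rng.normal(0.0, 1.0, size=(n, len(v.re_sd)))
        eff = raw * np.asarray(v.re_sd)
        a = assoc_by_protein.get(v.name)
        if a is not None and a.rho != 0.0:
            e_spec = echo_specs[a.echo]
            sd_p0, sd_e0 = v.re_sd[0], e_spec.re_sd[0]
            cond_mean = a.rho * (sd_p0 / sd_e0) * b[a.echo][:, 0]
            eff[:, 0] = cond_mean + raw[:, 0] * sd_p0 * np.sqrt(1.0 - a.rho**2)
        b[v.name] = eff

    beta_truth, sigma2_truth, re_sd_truth = {}, {}, {}
    frames = []
    for v in cfg.echo_vars + cfg.proteins:
        t = np.asarray(v.times, dtype=float)
        spec = make_spline_spec(np.tile(t, n if n > 1 else 2), df=2)
        basis = evaluate_basis(spec, t)  # (T, 2)
        Zt = _random_design(v, t, basis)  # (T, q)
        fixed_t = basis @ np.asarray(v.spline_coefs)  # (T,)
        mean = (
            v.intercept
            + v.age_effect * ages[:, None]
            + v.sex_effect * female[:, None]
            + fixed_t[None, :]
        )
        values = mean + b[v.name] @ Zt.T + rng.normal(0.0, v.sigma, size=(n, t.size))
        if v.var_type == "protein":
            values = np.exp(values)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.repeat(pids, t.size),
                    "time_months": np.tile(t, n),
                    "variable_id": v.name,
                    "variable_type": v.var_type,
                    "value": values.ravel(),
                }
            )
        )
        beta_truth[v.name] = np.array(
            [v.intercept, v.age_effect, v.sex_effect, *v.spline_coefs]
        )
        sigma2_truth[v.name] = v.sigma**2
        re_sd_truth[v.name] = tuple(v.re_sd)

    meas = pd.concat(frames, ignore_index=True)

    if cfg.missingness > 0:
        if cfg.missingness_level == "visit":
            visits = meas[["patient_id", "time_months", "variable_type"]].drop_duplicates()
            visits = visits.sort_values(list(visits.columns)).reset_index(drop=True)
            drop = rng.random(len(visits)) < cfg.missingness
            dropped = visits[drop]
            key = ["patient_id", "time_months", "variable_type"]
            meas = meas.merge(dropped.assign(_drop=True), on=key, how="left")
            meas = meas[meas["_drop"].isna()].drop(columns="_drop").reset_index(drop=True)
        else:
            keep = rng.random(len(meas)) >= cfg.missingness
            meas = meas[keep].reset_index(drop=True)

    cov = pd.DataFrame(
        {
            "patient_id": pids,
            "age_years": ages,
            "sex": np.where(female == 1.0, "female", "male"),
        }
    )
    ds = make_cohort(meas, cov, protein_log_applied=False)
    truth = SyntheticTruth(
        config=cfg,
        beta=beta_truth,
        sigma2=sigma2_truth,
        re_sd=re_sd_truth,
        rho={(a.protein, a.echo): a.rho for a in cfg.associations},
        random_effects=b,
        ages=ages,
        sex_female=female,
    )
    return ds, truth


# ---------------------------------------------------------------------------
# canned configurations
# ---------------------------------------------------------------------------

ECHO_TIMES = (0.0, 3.0, 12.0)
PROTEIN_TIMES = (1.0, 3.0, 12.0)


def spline_coefs_for_changes(
    times, change_mid: float, change_end: float
) -> tuple[float, float]:
    """Coefficients on the 2-df basis giving stated mean changes from the
    first visit to the middle and last visit."""
    t = np.asarray(times, dtype=float)
    spec = make_spline_spec(np.tile(t, 2), df=2)
    B = evaluate_basis(spec, t)
    M = B[[1, 2]] - B[0]
    sol = np.linalg.solve(M, np.array([change_mid, change_end]))
    return float(sol[0]), float(sol[1])


def default_echo_variables() -> tuple[VariableSpec, ...]:
    """Three echo variables whose population curves qualitatively mimic
    post-MI remodeling: atrial volume and end-diastolic volume rising
    then flattening, ejection fraction recovering."""

    def ev(name, base, d3, d12, age_eff, sex_eff, ri_sd, slope_sd, sigma):
        c = spline_coefs_for_changes(ECHO_TIMES, d3, d12)
        # intercept chosen so the population mean at discharge (mean age 60,
        # 19% female) sits at `base`
        icpt = base - 60.0 * age_eff - 0.19 * sex_eff
        return VariableSpec(
            name=name,
            var_type="echo",
            times=ECHO_TIMES,
            intercept=icpt,
            spline_coefs=c,
            age_effect=age_eff,
            sex_effect=sex_eff,
            structure="intercept_slope",
            re_sd=(ri_sd, slope_sd),
            sigma=sigma,
        )

    return (
        ev("AV", 20.5, 4.1, 4.9, 0.05, -1.0, 5.0, 0.30, 3.0),
        ev("LVEDV", 52.3, 7.1, 10.0, 0.20, -4.0, 12.0, 0.60, 7.0),
        ev("LVEF", 49.3, 4.6, 5.9, -0.05, 1.0, 7.0, 0.30, 4.5),
    )


def protein_spec(
    name: str,
    intercept: float = 7.0,
    spline_coefs: tuple[float, float] = (0.0, 0.0),
    age_effect: float = 0.0,
    sex_effect: float = 0.0,
    structure: str = "intercept",
    re_sd: tuple[float, ...] = (0.5,),
    sigma: float = 0.35,
) -> VariableSpec:
    """A log-normal protein on the relative-fluorescence scale (ln RFU ~ 7)."""
    return VariableSpec(
        name=name,
        var_type="protein",
        times=PROTEIN_TIMES,
        intercept=intercept,
        spline_coefs=spline_coefs,
        age_effect=age_effect,
        sex_effect=sex_effect,
        structure=structure,
        re_sd=re_sd,
        sigma=sigma,
    )


def pair_config(
    n_patients: int = 246,
    rho: float = 0.6,
    missingness: float = 0.0,
    structure_P: str = "intercept",
    structure_E: str = "intercept",
    seed: int = 0,
) -> SyntheticConfig:
    """One protein paired with one LVEDV-like echo variable.

    Used by calibration and recovery studies; random-intercept-only
    structures by default keep the cross-block a single correlation.
    """
    re_sd_E = {"intercept": (12.0,), "intercept_slope": (12.0, 0.6), "intercept_spline2": (12.0, 1.2, 0.25)}[structure_E]
    re_sd_P = {"intercept": (0.5,), "intercept_slope": (0.5, 0.03), "intercept_spline2": (0.5, 0.06, 0.012)}[structure_P]
    echo = replace(
        default_echo_variables()[1], structure=structure_E, re_sd=re_sd_E
    )
    prot = protein_spec(
        "PROT1",
        spline_coefs=spline_coefs_for_changes(PROTEIN_TIMES, -0.10, -0.25),
        age_effect=0.03,
        sex_effect=0.30,
        structure=structure_P,
        re_sd=re_sd_P,
    )
    assoc = (Association("PROT1", echo.name, rho),) if rho != 0.0 else ()
    return SyntheticConfig(
        echo_vars=(echo,),
        proteins=(prot,),
        associations=assoc,
        n_patients=n_patients,
        missingness=missingness,
        seed=seed,
    )


def screen_config(
    n_proteins: int = 100,
    n_true: int = 10,
    rho: float = 0.7,
    n_patients: int = 250,
    missingness: float = 0.05,
    seed: int = 0,
) -> SyntheticConfig:
    """A screening study: one echo variable, ``n_true`` proteins whose
    random intercepts correlate with it at ``rho``, the rest null."""
    if n_true > n_proteins:
        raise ConfigError("n_true cannot exceed n_proteins")
    echo = default_echo_variables()[1]
    rng = np.random.default_rng(1234)  # fixed: protein parameter diversity, not sampling
    proteins = []
    for i in range(n_proteins):
        proteins.append(
            protein_spec(
                f"PROT{i + 1:03d}",
                intercept=float(rng.uniform(5.5, 9.0)),
                spline_coefs=spline_coefs_for_changes(
                    PROTEIN_TIMES, float(rng.normal(0, 0.08)), float(rng.normal(0, 0.15))
                ),
                age_effect=float(rng.normal(0.0, 0.01)),
                sex_effect=float(rng.normal(0.0, 0.15)),
                re_sd=(float(rng.uniform(0.3, 0.7)),),
                sigma=float(rng.uniform(0.2, 0.5)),
            )
        )
    assoc = tuple(Association(proteins[i].name, echo.name, rho) for i in range(n_true))
    return SyntheticConfig(
        echo_vars=(echo,),
        proteins=tuple(proteins),
        associations=assoc,
        n_patients=n_patients,
        missingness=missingness,
        seed=seed,
    )


def demo_config(n_patients: int = 246, seed: int = 0) -> SyntheticConfig:
    """Small realistic cohort: 3 echo variables, 12 proteins, 3 of them
    (natriuretic-peptide-like) coupled to the echo trajectories."""
    echo = default_echo_variables()
    proteins = [
        protein_spec("NTproBNP", intercept=8.0, re_sd=(0.8,), sigma=0.4,
                     spline_coefs=spline_coefs_for_changes(PROTEIN_TIMES, -0.2, -0.5)),
        protein_spec("BNP", intercept=7.2, re_sd=(0.7,), sigma=0.4,
                     spline_coefs=spline_coefs_for_changes(PROTEIN_TIMES, -0.15, -0.4)),
        protein_spec("hsTnT", intercept=5.5, re_sd=(0.6,), sigma=0.35,
                     spline_coefs=spline_coefs_for_changes(PROTEIN_TIMES, -0.3, -0.6)),
    ] + [protein_spec(f"NULL{i + 1:02d}") for i in range(9)]
    assoc = (
        Association("NTproBNP", "AV", 0.5),
        Association("BNP", "LVEDV", 0.45),
        Association("hsTnT", "LVEF", -0.4),
    )
    return SyntheticConfig(
        echo_vars=echo,
        proteins=tuple(proteins),
        associations=assoc,
        n_patients=n_patients,
        seed=seed,
    )
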