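"""Synthetic case-control cohorts with calibrated rank-correlation structure.

The generator emulates a two-group (Parkinson's disease vs control)
observational cohort: demographics (age, gender), statin use, fasting
lipids (total and LDL cholesterol, mg/dL), clinical scores for the PD
arm only (UPDRS-III motor score, disease duration in years, levodopa
equivalent daily dose LEDD in mg), and per-ROI trimmed-mean R2* values
(s^-1) for the four nigrostriatal structures.

Generative model (Gaussian copula with covariate loadings)
----------------------------------------------------------
For each subject, exogenous covariates are drawn first: age ~ Normal,
gender and statin ~ Bernoulli with group-specific proportions.  Each
continuous outcome X_j then gets a standardised latent

    Z_j = a_j * age_std + g_j * gender_std + s_j * statin_std
          + sqrt(1 - a_j^2 - g_j^2 - s_j^2) * e_j,

where e ~ MVN(0, R_e) carries the *residual* correlation structure
beyond the covariates.  Because a Spearman rank-correlation target
rho_s between two jointly Gaussian variables corresponds to a Pearson
correlation of 2*sin(pi*rho_s/6), each target is converted through that
map before entering R_e; partial Spearman correlation adjusted for the
covariates then recovers the target rather than an attenuated value.

Targets stated conditional on the extended covariate set (age, gender,
statin + the three clinical scores) are back-solved into marginal R_e
entries through the Gaussian conditional-correlation identity, so the
six-covariate partial correlation hits the stated value.

Marginals are matched exactly by monotone quantile transforms: Gaussian
for age, lipids and R2*; gamma for UPDRS-III and LEDD and lognormal for
disease duration (non-negative, right-skewed), with moments matched to
the group mean/SD.  Monotone transforms leave Spearman correlations
untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

__all__ = [
    "LATENT_VARS",
    "ROI_VARS",
    "CLINICAL_VARS",
    "CorrTarget",
    "CohortSpec",
    "SubjectRecord",
    "spearman_to_latent",
    "default_cohort_spec",
    "simulate_cohort",
    "inject_outliers",
    "spec_from_yaml",
    "spec_to_yaml",
]

ROI_VARS = ("SN", "caudate", "putamen", "GP")
LIPID_VARS = ("total_chol", "ldl_chol")
CLINICAL_VARS = ("updrs3", "duration", "ledd")
LATENT_VARS = ROI_VARS + LIPID_VARS + CLINICAL_VARS

BASIC_COVARIATES = ("age", "gender", "statin")
EXTENDED_COVARIATES = BASIC_COVARIATES + CLINICAL_VARS


def spearman_to_latent(rho_s: float) -> float:
    """Pearson correlation of a bivariate normal whose Spearman rho is ``rho_s``.

    The population identity rho_s = (6/pi) * arcsin(rho_p / 2) inverts to
    rho_p = 2 * sin(pi * rho_s / 6).
    """
    if not abs(rho_s) < 1:
        raise ValueError("|rho_s| must be < 1")
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


@dataclass(frozen=True)
class CorrTarget:
    """One partial-Spearman target between two latent variables.

    ``covariate_set`` names the adjustment under which the target holds:
    ``basic`` = age + gender + statin; ``extended`` adds the three
    clinical scores.
    """

    var1: str
    var2: str
    rho_s: float
    covariate_set: Literal["basic", "extended"] = "basic"

    def __post_init__(self) -> None:
        for v in (self.var1, self.var2):
            if v not in LATENT_VARS:
                raise ValueError(f"unknown variable {v!r}")
        if self.var1 == self.var2:
            raise ValueError("target variables must differ")
        if not abs(self.rho_s) < 1:
            raise ValueError("correlation targets must lie in (-1, 1)")
        if self.covariate_set not in ("basic", "extended"):
            raise ValueError(f"unknown covariate set {self.covariate_set!r}")


# Group marginals: mean/SD per continuous field.  Controls carry no
# clinical scores (structurally missing).
_PD_MARGINALS = {
    "age": (60.7, 8.3),
    "total_chol": (195.0, 36.0),
    "ldl_chol": (123.0, 29.0),
    "updrs3": (23.4, 15.2),
    "duration": (4.2, 4.7),
    "ledd": (532.0, 395.0),
    "SN": (34.9, 5.7),
    "caudate": (22.3, 3.5),
    "putamen": (28.4, 4.7),
    "GP": (37.2, 6.0),
}
_CONTROL_MARGINALS = {
    "age": (59.6, 6.7),
    "total_chol": (201.0, 39.0),
    "ldl_chol": (121.0, 34.0),
    "SN": (30.4, 4.6),
    "caudate": (22.4, 2.6),
    "putamen": (27.3, 3.1),
    "GP": (35.6, 4.2),
}

# Marginal families for the quantile transform.  Gamma / lognormal keep
# clinical scores non-negative and right-skewed while matching mean/SD.
_FAMILY = {
    "updrs3": "gamma",
    "ledd": "gamma",
    "duration": "lognormal",
}

# Default PD-group partial-Spearman targets (basic covariate set).
_PD_TARGETS = (
    # ROI R2* vs lipids
    CorrTarget("SN", "total_chol", -0.429),
    CorrTarget("SN", "ldl_chol", -0.305),
    CorrTarget("caudate", "total_chol", -0.336),
    CorrTarget("caudate", "ldl_chol", -0.279),
    CorrTarget("putamen", "total_chol", -0.324),
    CorrTarget("putamen", "ldl_chol", -0.232),
    CorrTarget("GP", "total_chol", -0.376),
    CorrTarget("GP", "ldl_chol", -0.267),
    # ROI R2* vs clinical scores
    CorrTarget("SN", "updrs3", 0.355),
    CorrTarget("SN", "duration", 0.418),
    CorrTarget("SN", "ledd", 0.407),
    CorrTarget("caudate", "updrs3", 0.397),
    CorrTarget("caudate", "duration", 0.055),
    CorrTarget("caudate", "ledd", 0.266),
    CorrTarget("putamen", "updrs3", 0.431),
    CorrTarget("putamen", "duration", 0.144),
    CorrTarget("putamen", "ledd", 0.424),
    CorrTarget("GP", "updrs3", -0.142),
    CorrTarget("GP", "duration", -0.061),
    CorrTarget("GP", "ledd", 0.130),
    # lipids vs clinical scores
    CorrTarget("total_chol", "updrs3", -0.334),
    CorrTarget("total_chol", "duration", -0.175),
    CorrTarget("total_chol", "ledd", -0.052),
    CorrTarget("ldl_chol", "updrs3", -0.397),
    CorrTarget("ldl_chol", "duration", -0.062),
    CorrTarget("ldl_chol", "ledd", 0.040),
)

# Structural latent (Pearson) correlations not taken from any target:
# LDL is the major cholesterol fraction (strong lipid-lipid coupling);
# medication load grows with disease duration and severity; regional
# iron levels co-vary mildly across structures.  Applied to both groups.
_STRUCTURAL = {
    ("total_chol", "ldl_chol"): 0.85,
    ("updrs3", "duration"): 0.35,
    ("updrs3", "ledd"): 0.35,
    ("duration", "ledd"): 0.45,
    ("SN", "caudate"): 0.25,
    ("SN", "putamen"): 0.25,
    ("SN", "GP"): 0.25,
    ("caudate", "putamen"): 0.25,
    ("caudate", "GP"): 0.25,
    ("putamen", "GP"): 0.25,
}

# Standardised covariate loadings (age, gender[female=1], statin).  The
# study reports no covariate effect sizes; these are simulator
# conventions sized so that covariate adjustment visibly matters: iron
# accumulates with age, statin use lowers measured cholesterol, gender
# shifts lipids slightly.  Clinical scores carry no binary loadings so
# their latents stay exactly Gaussian for the quantile transform.
_LOADINGS = {
    "SN": {"age": 0.30, "gender": 0.10, "statin": 0.0},
    "caudate": {"age": 0.30, "gender": 0.10, "statin": 0.0},
    "putamen": {"age": 0.30, "gender": 0.10, "statin": 0.0},
    "GP": {"age": 0.30, "gender": 0.10, "statin": 0.0},
    "total_chol": {"age": 0.10, "gender": 0.15, "statin": -0.35},
    "ldl_chol": {"age": 0.10, "gender": 0.15, "statin": -0.35},
    "updrs3": {"age": 0.15, "gender": 0.0, "statin": 0.0},
    "duration": {"age": 0.10, "gender": 0.0, "statin": 0.0},
    "ledd": {"age": 0.10, "gender": 0.0, "statin": 0.0},
}


@dataclass(frozen=True)
class CohortSpec:
    n_pd: int = 40
    n_control: int = 29
    pd_marginals: dict = field(default_factory=lambda: dict(_PD_MARGINALS))
    control_marginals: dict = field(
        default_factory=lambda: dict(_CONTROL_MARGINALS)
    )
    female_prop: dict = field(
        default_factory=lambda: {"PD": 17 / 40, "control": 17 / 29}
    )
    statin_prop: dict = field(
        default_factory=lambda: {"PD": 9 / 40, "control": 6 / 29}
    )
    targets: tuple = _PD_TARGETS  # PD group; controls default to zero targets
    structural: dict = field(default_factory=lambda: dict(_STRUCTURAL))
    loadings: dict = field(default_factory=lambda: dict(_LOADINGS))
    seed: int = 0

    def group_vars(self, group: str) -> list[str]:
        marg = self.pd_marginals if group == "PD" else self.control_marginals
        return [v for v in LATENT_VARS if v in marg]


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    gender: str  # "F" / "M"
    statin: bool
    total_chol: float
    ldl_chol: float
    updrs3: float | None
    duration: float | None
    ledd: float | None
    roi_r2star: dict

    @classmethod
    def from_row(cls, row: pd.Series) -> "SubjectRecord":
        def opt(k):
            v = row.get(k, np.nan)
            return None if pd.isna(v) else float(v)

        return cls(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            age=float(row["age"]),
            gender=str(row["gender"]),
            statin=bool(row["statin"]),
            total_chol=float(row["total_chol"]),
            ldl_chol=float(row["ldl_chol"]),
            updrs3=opt("updrs3"),
            duration=opt("duration"),
            ledd=opt("ledd"),
            roi_r2star={r: float(row[f"r2star_{r}"]) for r in ROI_VARS},
        )


def _residual_matrix(spec: CohortSpec, group: str) -> tuple[np.ndarray, list[str]]:
    """Latent residual correlation matrix R_e for one group.

    Basic-set targets enter directly as 2*sin(pi*rho/6); extended-set
    targets are back-solved so that the partial correlation given the
    clinical trio (in addition to the exogenous covariates) equals the
    converted target.  Raises if the result is not positive definite.
    """
    vars_ = spec.group_vars(group)
    idx = {v: i for i, v in enumerate(vars_)}
    k = len(vars_)
    R = np.eye(k)

    def set_entry(a, b, val):
        if a in idx and b in idx:
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = val

    for (a, b), v in spec.structural.items():
        set_entry(a, b, v)
    targets = spec.targets if group == "PD" else ()
    basic = [t for t in targets if t.covariate_set == "basic"]
    extended = [t for t in targets if t.covariate_set == "extended"]
    for t in basic:
        set_entry(t.var1, t.var2, _solve_target_entry(spec, R, idx, [], t))
    for t in extended:
        clin = [c for c in CLINICAL_VARS if c in idx]
        val = _solve_target_entry(spec, R, idx, clin, t)
        set_entry(t.var1, t.var2, val)
    eig = np.linalg.eigvalsh(R)
    if eig.min() <= 1e-10:
        raise ValueError(
            f"implied latent residual correlation matrix for group {group!r} "
            f"is not positive definite (min eigenvalue {eig.min():.3g})"
        )
    return R, vars_


def _partial_from_corr(S: np.ndarray, x: int, y: int, z: list[int]) -> float:
    Szz = S[np.ix_(z, z)]
    sx = np.linalg.solve(Szz, S[x, z])
    sy = np.linalg.solve(Szz, S[y, z])
    qx, qy = S[x, z] @ sx, S[y, z] @ sy
    return float((S[x, y] - S[x, z] @ sy)
                 / np.sqrt((1 - qx) * (1 - qy)))


def _solve_target_entry(
    spec: CohortSpec, R: np.ndarray, idx: dict, clin: list[str], t: CorrTarget
) -> float:
    """Residual-matrix entry whose partial Spearman hits the target.

    The rank-based partial-correlation estimator converges to the partial
    correlation of the *uniform scores* (probability-integral transforms)
    of all variables — i.e. the partial computed from the pairwise
    Spearman correlation matrix — not to the Spearman of the Gaussian
    conditional law.  The two notions separate by up to a few hundredths
    once covariates correlate with the outcome pair (most visibly under
    the six-covariate extended adjustment), so the entry is found by
    root-solving the population value of the estimator given the
    covariates of the target's set (``clin`` empty for the basic set).
    2*sin(pi*rho/6) remains the underlying Gaussian-copula conversion
    inside the solve.  Binary covariates are treated as Gaussian here, a
    second-order approximation at the default (small) binary loadings.
    """
    from scipy.optimize import brentq

    outcomes = clin + [t.var1, t.var2]
    lam = np.array([
        [spec.loadings.get(v, {}).get(c, 0.0) for c in BASIC_COVARIATES]
        for v in outcomes
    ])  # (m, 3)
    resid_sd = np.sqrt(1.0 - (lam**2).sum(axis=1))
    m = len(outcomes)
    xi, yi = m - 2, m - 1  # positions of var1/var2 within `outcomes`
    Re_local = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            Re_local[i, j] = Re_local[j, i] = R[idx[outcomes[i]],
                                                idx[outcomes[j]]]

    def population_partial(r_entry: float) -> float:
        Re = Re_local.copy()
        Re[xi, yi] = Re[yi, xi] = r_entry
        # marginal latent Pearson matrix over (exog, outcomes)
        M = np.eye(3 + m)
        M[:3, 3:] = lam.T
        M[3:, :3] = lam
        M[3:, 3:] = lam @ lam.T + np.outer(resid_sd, resid_sd) * Re
        np.fill_diagonal(M, 1.0)
        S = (6.0 / np.pi) * np.arcsin(M / 2.0)  # Spearman scale
        np.fill_diagonal(S, 1.0)
        z = list(range(3 + len(clin)))
        return _partial_from_corr(S, 3 + xi, 3 + yi, z)

    try:
        return float(brentq(
            lambda r: population_partial(r) - t.rho_s, -0.995, 0.995,
            xtol=1e-10,
        ))
    except ValueError as e:
        raise ValueError(
            f"extended target ({t.var1}, {t.var2}, rho_s={t.rho_s}) has no "
            f"attainable residual correlation: {e}"
        ) from e


def _quantile_transform(u: np.ndarray, var: str, mean: float, sd: float) -> np.ndarray:
    """Map a standard-normal latent to the variable's marginal, monotonically."""
    family = _FAMILY.get(var, "gaussian")
    if family == "gaussian" or sd == 0:
        return mean + sd * u
    p = sps.norm.cdf(u)
    if family == "gamma":
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        return sps.gamma.ppf(p, a=shape, scale=scale)
    if family == "lognormal":
        s2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - s2 / 2
        return sps.lognorm.ppf(p, s=np.sqrt(s2), scale=np.exp(mu))
    raise ValueError(f"unknown marginal family {family!r}")


def _simulate_group(
    spec: CohortSpec, group: str, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    marg = spec.pd_marginals if group == "PD" else spec.control_marginals
    R, vars_ = _residual_matrix(spec, group)
    L = np.linalg.cholesky(R)
    age_mean, age_sd = marg["age"]
    age_std = rng.standard_normal(n)
    p_f = spec.female_prop[group]
    p_s = spec.statin_prop[group]
    female = rng.random(n) < p_f
    statin = rng.random(n) < p_s
    # standardised binary covariates (zero mean, unit variance)
    g_std = (female - p_f) / np.sqrt(p_f * (1 - p_f))
    s_std = (statin - p_s) / np.sqrt(p_s * (1 - p_s))
    e = rng.standard_normal((n, len(vars_))) @ L.T
    prefix = "PD" if group == "PD" else "C"
    out = {
        "subject_id": [f"{prefix}{i:04d}" for i in range(n)],
        "group": group,
        "age": age_mean + age_sd * age_std,
        "gender": np.where(female, "F", "M"),
        "statin": statin,
    }
    for j, var in enumerate(vars_):
        lam = spec.loadings.get(var, {})
        la = lam.get("age", 0.0)
        lg = lam.get("gender", 0.0)
        ls = lam.get("statin", 0.0)
        resid_var = 1.0 - la**2 - lg**2 - ls**2
        if resid_var <= 0:
            raise ValueError(f"loadings for {var!r} exceed unit variance")
        z = la * age_std + lg * g_std + ls * s_std + np.sqrt(resid_var) * e[:, j]
        mean, sd = marg[var]
        col = f"r2star_{var}" if var in ROI_VARS else var
        out[col] = _quantile_transform(z, var, mean, sd)
    df = pd.DataFrame(out)
    # structurally missing clinical scores
    for var in CLINICAL_VARS:
        if var not in vars_:
            df[var] = np.nan
    order = (
        ["subject_id", "group", "age", "gender", "statin"]
        + list(LIPID_VARS)
        + list(CLINICAL_VARS)
        + [f"r2star_{r}" for r in ROI_VARS]
    )
    return df[order]


def simulate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw a full two-group cohort; deterministic for a given spec + seed.

    Returns a tidy DataFrame, one row per subject; use
    :meth:`SubjectRecord.from_row` for typed access.
    """
    spec = spec or CohortSpec()
    if spec.n_pd < 0 or spec.n_control < 0:
        raise ValueError("group sizes must be non-negative")
    frames = []
    for gi, (group, n) in enumerate((("PD", spec.n_pd),
                                     ("control", spec.n_control))):
        if n == 0:
            continue
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), gi]))
        frames.append(_simulate_group(spec, group, n, rng))
    if not frames:
        raise ValueError("cohort has no subjects")
    return pd.concat(frames, ignore_index=True)


def default_cohort_spec(**overrides) -> CohortSpec:
    """The study-calibrated default spec (40 PD / 29 controls)."""
    return replace(CohortSpec(), **overrides) if overrides else CohortSpec()


def inject_outliers(
    records: pd.DataFrame,
    k_subjects: int,
    magnitude_sd: float,
    group: str | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Force ``k_subjects`` extreme total-cholesterol values.

    Each chosen subject's total cholesterol is set to its group's
    empirical mean + ``magnitude_sd`` * group SD (pre-injection), with
    LDL rescaled proportionally; injected rows are flagged in the
    ``chol_outlier_injected`` column.  ``k_subjects == 0`` returns the
    records unchanged (apart from the flag column).
    """
    if k_subjects > len(records):
        raise ValueError("k_subjects exceeds cohort size")
    df = records.copy()
    if "chol_outlier_injected" not in df:
        df["chol_outlier_injected"] = False
    if k_subjects == 0:
        return df
    pool = df if group is None else df[df["group"] == group]
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool.index.to_numpy(), size=k_subjects, replace=False)
    stats = df.groupby("group")["total_chol"].agg(["mean", "std"])
    for i in chosen:
        g = df.at[i, "group"]
        old = df.at[i, "total_chol"]
        new = stats.at[g, "mean"] + magnitude_sd * stats.at[g, "std"]
        df.at[i, "total_chol"] = new
        df.at[i, "ldl_chol"] = df.at[i, "ldl_chol"] * new / old
        df.at[i, "chol_outlier_injected"] = True
    return df


# ---------------------------------------------------------------------------
# YAML (de)serialisation of cohort specs
# ---------------------------------------------------------------------------

def spec_to_yaml(spec: CohortSpec, path: str | Path) -> None:
    doc = {
        "n_pd": spec.n_pd,
        "n_control": spec.n_control,
        "pd_marginals": {k: list(v) for k, v in spec.pd_marginals.items()},
        "control_marginals": {
            k: list(v) for k, v in spec.control_marginals.items()
        },
        "female_prop": dict(spec.female_prop),
        "statin_prop": dict(spec.statin_prop),
        "targets": [
            {"var1": t.var1, "var2": t.var2, "rho_s": t.rho_s,
             "covariate_set": t.covariate_set}
            for t in spec.targets
        ],
        "structural": {f"{a}|{b}": v for (a, b), v in spec.structural.items()},
        "loadings": {k: dict(v) for k, v in spec.loadings.items()},
        "seed": spec.seed,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def spec_from_yaml(path: str | Path) -> CohortSpec:
    doc = yaml.safe_load(Path(path).read_text())
    base = CohortSpec()
    return CohortSpec(
        n_pd=int(doc.get("n_pd", base.n_pd)),
        n_control=int(doc.get("n_control", base.n_control)),
        pd_marginals={
            k: tuple(v) for k, v in doc.get(
                "pd_marginals", base.pd_marginals).items()
        },
        control_marginals={
            k: tuple(v) for k, v in doc.get(
                "control_marginals", base.control_marginals).items()
        },
        female_prop=doc.get("female_prop", base.female_prop),
        statin_prop=doc.get("statin_prop", base.statin_prop),
        targets=tuple(
            CorrTarget(t["var1"], t["var2"], float(t["rho_s"]),
                       t.get("covariate_set", "basic"))
            for t in doc.get("targets", [])
        ) if "targets" in doc else base.targets,
        structural={
            tuple(k.split("|")): float(v)
            for k, v in doc.get(
                "structural",
                {f"{a}|{b}": v for (a, b), v in base.structural.items()},
            ).items()
        },
        loadings=doc.get("loadings", base.loadings),
        seed=int(doc.get("seed", 0)),
    )
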