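"""Longitudinal progression inference.

The study design is paired-eye and repeated-measure: both eyes of every
patient are measured at several visits.  Three estimators carry the
analysis:

* a linear mixed model (LMM) of metric vs age with random intercepts for
  patient and eye-within-patient, yielding the population progression
  rate (fixed slope, Wald 95% CI) and a likelihood-ratio test of the age
  effect;
* a continuous two-segment piecewise-linear ("hinge") regression whose
  breakpoint psi estimates the inflection age at which a metric starts
  to change, with a patient-resampling bootstrap CI;
* repeated-measures correlation (within-subject ANCOVA with common slope
  and subject-specific intercepts) for interocular and inter-metric
  relationships.

Rates are additionally normalised by each metric's dynamic range to make
them comparable across metrics, and Bonferroni correction controls the
family-wise error over the metric family.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .errors import EstimationError, UnderdeterminedError, ValidationError

HINGE_GRID_STEP = 0.1  # years
HINGE_BOOTSTRAP_REPS = 1000


# ---------------------------------------------------------------------------
# Linear mixed model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LMMFit:
    """Mixed-model progression fit for one metric."""

    slope: float
    slope_ci: tuple[float, float]
    slope_se: float
    intercept: float
    var_patient: float
    var_eye: float
    var_resid: float
    lrt_chi2: float
    lrt_p: float
    r2_marginal: float
    n_obs: int
    n_patients: int
    n_eyes: int
    converged: bool


def _prepare(df: pd.DataFrame, metric: str | None) -> pd.DataFrame:
    required = {"patient_id", "eye", "age_years", "value"}
    if metric is not None and "metric" in df.columns:
        df = df[df["metric"] == metric]
    if not required.issubset(df.columns):
        raise ValidationError(f"records need columns {sorted(required)}")
    df = df.dropna(subset=["value", "age_years"]).copy()
    df["eye_uid"] = df["patient_id"].astype(str) + ":" + df["eye"].astype(str)
    return df


def fit_lmm(records: pd.DataFrame, metric: str | None = None, min_visits: int = 2) -> LMMFit:
    """REML fit of ``value ~ age`` with patient and eye-within-patient
    random intercepts.

    Eyes with fewer than ``min_visits`` visits are dropped (longitudinal
    inclusion rule).  The age effect is tested by a likelihood-ratio test
    of full-ML fits with and without the age term (1 df); the Wald 95% CI
    uses the REML slope standard error.  ``r2_marginal`` is the
    fixed-effects (marginal) variance explained, i.e. var(X*beta) over
    total model variance.
    """
    df = _prepare(records, metric)
    visits = df.groupby("eye_uid")["age_years"].transform("nunique")
    df = df[visits >= min_visits]
    if df["age_years"].nunique() < 3:
        raise UnderdeterminedError("fewer than 3 distinct ages; slope not identifiable")
    df = df.reset_index(drop=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            "value ~ age_years",
            groups="patient_id",
            re_formula="1",
            vc_formula={"eye": "0 + C(eye_uid)"},
            data=df,
        )
        res = model.fit(reml=True, method=["lbfgs", "powell"])
        full_ml = model.fit(reml=False, method=["lbfgs", "powell"])
        null_model = MixedLM.from_formula(
            "value ~ 1",
            groups="patient_id",
            re_formula="1",
            vc_formula={"eye": "0 + C(eye_uid)"},
            data=df,
        )
        null_ml = null_model.fit(reml=False, method=["lbfgs", "powell"])
    slope = float(res.params["age_years"])
    se = float(res.bse["age_years"])
    z = stats.norm.ppf(0.975)
    chi2 = max(0.0, 2.0 * (full_ml.llf - null_ml.llf))
    var_patient = float(np.asarray(res.cov_re).ravel()[0])
    var_eye = float(res.vcomp[0]) if len(res.vcomp) else 0.0
    var_resid = float(res.scale)
    fixed = res.params["Intercept"] + slope * df["age_years"].to_numpy()
    var_fixed = float(np.var(fixed))
    denom = var_fixed + var_patient + var_eye + var_resid
    return LMMFit(
        slope=slope,
        slope_ci=(slope - z * se, slope + z * se),
        slope_se=se,
        intercept=float(res.params["Intercept"]),
        var_patient=var_patient,
        var_eye=var_eye,
        var_resid=var_resid,
        lrt_chi2=chi2,
        lrt_p=float(stats.chi2.sf(chi2, df=1)),
        r2_marginal=var_fixed / denom if denom > 0 else math.nan,
        n_obs=len(df),
        n_patients=df["patient_id"].nunique(),
        n_eyes=df["eye_uid"].nunique(),
        converged=bool(res.converged),
    )


# ---------------------------------------------------------------------------
# Hinge (piecewise-linear) regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HingeFit:
    """Continuous two-segment fit: breakpoint psi, slopes on each side."""

    psi: float
    psi_ci: tuple[float, float]
    pre_slope: float
    post_slope: float
    value_at_psi: float
    rss: float
    rss_line: float
    boundary: bool  # minimum at the edge of the candidate range
    n_obs: int


def _hinge_design(ages: np.ndarray, psi: float) -> np.ndarray:
    d = ages - psi
    return np.column_stack([np.ones_like(ages), np.minimum(d, 0.0), np.maximum(d, 0.0)])


def hinge_rss_profile(ages: np.ndarray, values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Profiled residual sum of squares over candidate breakpoints.

    Solves the 3-parameter normal equations for every grid psi in one
    batched pass; exploits that the two hinge basis columns
    min(age-psi, 0) and max(age-psi, 0) are pointwise orthogonal.
    """
    d = ages[None, :] - grid[:, None]  # (G, n)
    lo = np.minimum(d, 0.0)
    hi = np.maximum(d, 0.0)
    n = ages.size
    g = grid.size
    sl, sh = lo.sum(axis=1), hi.sum(axis=1)
    sll, shh = (lo * lo).sum(axis=1), (hi * hi).sum(axis=1)
    sly, shy = lo @ values, hi @ values
    sy, yty = values.sum(), values @ values
    xtx = np.zeros((g, 3, 3))
    # ridge jitter keeps degenerate grid points (no data on one side) solvable
    xtx[:, 0, 0] = n + 1e-10
    xtx[:, 0, 1] = xtx[:, 1, 0] = sl
    xtx[:, 0, 2] = xtx[:, 2, 0] = sh
    xtx[:, 1, 1] = sll + 1e-10
    xtx[:, 2, 2] = shh + 1e-10
    xty = np.stack([np.full(g, sy), sly, shy], axis=1)
    beta = np.linalg.solve(xtx, xty[..., None])[..., 0]
    return np.maximum(yty - np.einsum("gi,gi->g", beta, xty), 0.0)


def _fit_hinge_arrays(
    ages: np.ndarray, values: np.ndarray, grid_step: float
) -> tuple[float, np.ndarray, float, bool]:
    """Grid search + local quadratic refinement; returns
    (psi, beta, rss, boundary)."""
    distinct = np.unique(ages)
    lo, hi = distinct[1], distinct[-2]
    if hi <= lo:
        grid = np.array([0.5 * (distinct[0] + distinct[-1])])
    else:
        grid = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    rss = hinge_rss_profile(ages, values, grid)
    k = int(np.argmin(rss))
    psi = float(grid[k])
    boundary = k in (0, len(grid) - 1)
    if 0 < k < len(grid) - 1:
        # recompute the three bracketing RSS values from direct residuals:
        # the closed-form profile loses precision near an exact fit
        def _direct_rss(p: float) -> float:
            x = _hinge_design(ages, p)
            b, *_ = np.linalg.lstsq(x, values, rcond=None)
            return float(np.sum((values - x @ b) ** 2))

        r0, r1, r2 = (_direct_rss(grid[j]) for j in (k - 1, k, k + 1))
        denom = r0 - 2 * r1 + r2
        # near an exact fit the profile is V-shaped (kinked), not parabolic,
        # and quadratic interpolation would bias psi toward the shallower
        # side; keep the grid point when the minimum is orders of magnitude
        # below its neighbours
        if denom > 0 and r1 > 1e-4 * min(r0, r2):
            shift = 0.5 * (r0 - r2) / denom * grid_step
            psi = float(np.clip(psi + shift, grid[k - 1], grid[k + 1]))
    x = _hinge_design(ages, psi)
    beta, final_rss, *_ = np.linalg.lstsq(x, values, rcond=None)
    final_rss = float(np.sum((values - x @ beta) ** 2))
    return psi, beta, final_rss, boundary


def fit_hinge(
    records: pd.DataFrame,
    metric: str | None = None,
    grid_step: float = HINGE_GRID_STEP,
    n_boot: int = HINGE_BOOTSTRAP_REPS,
    seed: int | np.random.Generator | None = 0,
) -> HingeFit:
    """Fit the hinge model ``value = a + b0*min(age-psi,0) + b1*max(age-psi,0)``
    on pooled data.

    The breakpoint is profiled by grid search (default 0.1-year step over
    the interior of the observed age range) and refined by local
    quadratic interpolation of the RSS profile; the 95% CI comes from a
    case-resampling bootstrap over patients (percentile method, seeded).
    ``n_boot=0`` skips the bootstrap (CI = (nan, nan)).
    """
    df = _prepare(records, metric)
    ages = df["age_years"].to_numpy(dtype=float)
    values = df["value"].to_numpy(dtype=float)
    if np.unique(ages).size < 4:
        raise UnderdeterminedError("hinge fit needs at least 4 distinct ages")
    psi, beta, rss, boundary = _fit_hinge_arrays(ages, values, grid_step)
    line = np.polyfit(ages, values, 1)
    rss_line = float(np.sum((values - np.polyval(line, ages)) ** 2))
    ci = (math.nan, math.nan)
    if n_boot > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        patients = df["patient_id"].to_numpy()
        uniq = np.unique(patients)
        groups = {p: np.flatnonzero(patients == p) for p in uniq}
        draws = []
        for _ in range(n_boot):
            chosen = rng.choice(uniq, size=len(uniq), replace=True)
            idx = np.concatenate([groups[p] for p in chosen])
            a, v = ages[idx], values[idx]
            if np.unique(a).size < 4:
                continue
            draws.append(_fit_hinge_arrays(a, v, grid_step)[0])
        if len(draws) >= max(10, n_boot // 2):
            ci = tuple(np.percentile(draws, [2.5, 97.5]))
        else:
            raise EstimationError("bootstrap failed: too many degenerate resamples")
    return HingeFit(
        psi=psi,
        psi_ci=ci,
        pre_slope=float(beta[1]),
        post_slope=float(beta[2]),
        value_at_psi=float(beta[0]),
        rss=rss,
        rss_line=rss_line,
        boundary=boundary,
        n_obs=len(df),
    )


# ---------------------------------------------------------------------------
# Repeated-measures correlation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RmcorrResult:
    r: float
    ci: tuple[float, float]
    dof: int
    p: float
    n_subjects: int
    n_pairs: int


def rm_correlation(
    paired: pd.DataFrame, x: str = "x", y: str = "y", subject: str = "patient_id"
) -> RmcorrResult:
    """Within-subject correlation of two repeatedly measured series.

    Estimated by the ANCOVA decomposition (subject-specific intercepts,
    common slope); invariant to per-subject constant offsets in either
    series.  Subjects contributing a single complete visit are dropped
    with a warning.  CI by Fisher z on the error degrees of freedom.
    """
    df = paired.dropna(subset=[x, y]).copy()
    counts = df.groupby(subject)[x].count()
    singletons = counts[counts < 2].index
    if len(singletons):
        warnings.warn(f"dropping {len(singletons)} subject(s) with a single visit", stacklevel=2)
        df = df[~df[subject].isin(singletons)]
    if df[subject].nunique() < 3:
        raise UnderdeterminedError("repeated-measures correlation needs >= 3 subjects")
    res = pg.rm_corr(data=df, x=x, y=y, subject=subject)
    r = float(res["r"].iloc[0])
    dof = int(res["dof"].iloc[0])
    p = float(res["pval"].iloc[0])
    if dof > 2 and abs(r) < 1:
        z = math.atanh(r)
        se = 1.0 / math.sqrt(dof - 1)
        zc = stats.norm.ppf(0.975)
        ci = (math.tanh(z - zc * se), math.tanh(z + zc * se))
    else:
        ci = (math.nan, math.nan)
    return RmcorrResult(
        r=r, ci=ci, dof=dof, p=p, n_subjects=df[subject].nunique(), n_pairs=len(df)
    )


# ---------------------------------------------------------------------------
# Normalised rates, exclusions, multiplicity
# ---------------------------------------------------------------------------


def circle_sqrt_dynamic_range(diameter_mm: float) -> float:
    """Dynamic range of sqrt-AA for a circle: sqrt(pi * (d/2)^2) mm."""
    return math.sqrt(math.pi * (diameter_mm / 2.0) ** 2)


def default_dynamic_range(metric: str, **kwargs) -> float:
    """Default dynamic range per metric.

    sqrt-AA: the square root of the full circle area; EZ: the lateral
    scan extent (``scan_extent_um``); CRT / PR+RPE: the cohort baseline
    median (``baseline_median``); BCVA: the usable LogMAR span
    (``logmar_span``, default 1.5).
    """
    if metric == "sqrtAA_6mm":
        return circle_sqrt_dynamic_range(6.0)
    if metric == "sqrtAA_14mm":
        return circle_sqrt_dynamic_range(14.0)
    if metric in ("EZ_total", "EZ_nasal", "EZ_temporal"):
        return float(kwargs["scan_extent_um"])
    if metric in ("CRT", "PR_RPE"):
        return float(kwargs["baseline_median"])
    if metric == "BCVA_logMAR":
        return float(kwargs.get("logmar_span", 1.5))
    raise ValidationError(f"no default dynamic range for metric {metric!r}")


def normalized_rate(slope: float, dynamic_range: float) -> float:
    """Progression rate as percent of the metric's dynamic range per year:
    ``100 * |slope| / dynamic_range``."""
    if not dynamic_range > 0:
        raise ValidationError("dynamic range must be positive")
    return 100.0 * abs(slope) / dynamic_range


def filter_endstage_bcva(records: pd.DataFrame, flag_col: str = "end_stage") -> pd.DataFrame:
    """Drop end-stage (counting-fingers-or-worse) BCVA rows from
    progression inputs; such rows stay in descriptive tables upstream."""
    if flag_col not in records.columns:
        raise ValidationError(f"records lack the {flag_col!r} column")
    out = records[~records[flag_col].astype(bool)].copy()
    if out.empty and not records.empty:
        warnings.warn("all BCVA records are end-stage; progression input empty", stacklevel=2)
    return out


def bonferroni_adjust(p_values, family_size: int | None = None) -> np.ndarray:
    """Family-wise Bonferroni correction: ``min(1, p * m)``."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = family_size if family_size is not None else p.size
    if m < 1:
        raise ValidationError("family size must be >= 1")
    return np.minimum(1.0, p * m)
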