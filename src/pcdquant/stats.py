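"""Cohort statistics: adjusted group comparisons, sector contrasts,
univariate regressions, and dependent-correlation difference tests.

Group comparisons fit a linear mixed model with fixed group + covariates
(age, sex, axial length) and a subject-level random intercept to absorb the
inter-eye correlation; pairwise group contrasts are Bonferroni-corrected
over the number of pairs tested. Inference on the fixed effects uses
large-sample Wald z statistics. When every subject contributes a single
eye the random intercept is unidentifiable and the model degenerates to
ordinary least squares with the same fixed effects.

The difference between two dependent, non-overlapping correlations (e.g.
r(PCD_sup, RNFL_sup) vs r(PCD_inf, RNFL_inf) measured on the same eyes) is
tested with Dunn & Clark's (1969) Fisher-z statistic, using the
Pearson-Filon asymptotic covariance of the two correlations computed from
the full 4 x 4 intercorrelation matrix. If the intercorrelations are
unknown, the two correlations are conservatively treated as independent
and the result is flagged.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .errors import SchemaError, SingularDesignError
from .geometry import SECTORS

_SECTOR_COLS = {"superior": "pcd_sup_pct", "nasal": "pcd_nas_pct",
                "inferior": "pcd_inf_pct", "temporal": "pcd_temp_pct"}
_RNFL_COLS = {"superior": "rnfl_sup_um", "nasal": "rnfl_nas_um",
              "inferior": "rnfl_inf_um", "temporal": "rnfl_temp_um"}

DEFAULT_COVARIATES = ("age_years", "sex", "axial_length_mm")


@dataclass
class GroupComparison:
    """Pairwise adjusted group contrasts for one outcome."""

    outcome: str
    contrasts: pd.DataFrame      # group_a, group_b, estimate, se, z, ci_low, ci_high, p_raw, p_bonf
    covariates: tuple[str, ...]
    model: str                   # "mixed" or "ols"
    n_obs: int
    n_subjects: int
    bonferroni_family: int


@dataclass
class CorrelationComparison:
    """Dunn-Clark test of two dependent non-overlapping correlations."""

    r1: float
    r2: float
    difference: float
    n: int
    z: float
    p: float
    intercorrelations: dict[str, float] | None
    assumed_independent: bool = False


def _encode_sex(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "sex" in df.columns and df["sex"].dtype == object:
        df["sex"] = (df["sex"].astype(str).str.upper().str[0] == "F").astype(float)
    return df


def compare_groups(table: pd.DataFrame, outcome: str,
                   covariates: tuple[str, ...] = DEFAULT_COVARIATES,
                   bonferroni_family: int | None = None) -> GroupComparison:
    """Adjusted pairwise group differences for one outcome.

    Fits ``outcome ~ group + covariates`` with a subject-level random
    intercept (REML); every pair of groups present is contrasted and the
    raw two-sided p-values are Bonferroni-corrected over the family of
    pairs (configurable via ``bonferroni_family``).
    """
    needed = [outcome, "group", "subject_id", *covariates]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort table is missing columns: {missing}")
    df = _encode_sex(table).dropna(subset=needed).copy()
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise SingularDesignError("need at least two groups for a comparison")
    counts = df.groupby("group").size()
    small = counts[counts < 3]
    if len(small):
        raise SingularDesignError(f"groups with fewer than 3 eyes: {dict(small)}")
    for cov in covariates:
        if np.ptp(df[cov].astype(float).to_numpy()) == 0:
            raise SingularDesignError(f"covariate {cov!r} is constant")

    ref = groups[0]
    rhs = " + ".join([f"C(group, Treatment(reference={ref!r}))", *covariates])
    formula = f"{outcome} ~ {rhs}"
    one_eye = df.groupby("subject_id").size().max() == 1
    if one_eye:
        res = smf.ols(formula, data=df).fit()
        model = "ols"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.mixedlm(formula, data=df, groups=df["subject_id"]).fit(reml=True)
        model = "mixed"

    names = list(res.params.index)
    cov_params = np.asarray(res.cov_params())[:len(names), :len(names)]
    coef = {g: 0.0 for g in groups}
    vec = {g: np.zeros(len(names)) for g in groups}
    for g in groups:
        if g == ref:
            continue
        term = f"C(group, Treatment(reference={ref!r}))[T.{g}]"
        idx = names.index(term)
        coef[g] = float(res.params.iloc[idx])
        vec[g][idx] = 1.0

    pairs = list(itertools.combinations(groups, 2))
    m = bonferroni_family if bonferroni_family is not None else len(pairs)
    rows = []
    for a, b in pairs:
        contrast = vec[a] - vec[b]
        est = coef[a] - coef[b]
        se = float(np.sqrt(contrast @ cov_params @ contrast))
        z = est / se if se > 0 else np.inf * np.sign(est)
        p = float(2 * sps.norm.sf(abs(z)))
        rows.append({
            "group_a": a, "group_b": b, "estimate": est, "se": se, "z": z,
            "ci_low": est - 1.959963984540054 * se,
            "ci_high": est + 1.959963984540054 * se,
            "p_raw": p, "p_bonf": min(1.0, m * p),
        })
    return GroupComparison(
        outcome=outcome, contrasts=pd.DataFrame(rows), covariates=tuple(covariates),
        model=model, n_obs=len(df), n_subjects=df["subject_id"].nunique(),
        bonferroni_family=m)


def sector_contrasts(table: pd.DataFrame, group: str,
                     bonferroni_family: int = 6) -> pd.DataFrame:
    """Within-eye PCD differences across the six sector pairs for one group.

    For each pair of sectors the per-eye difference is tested against zero
    (paired t-test over eyes); p-values are Bonferroni-corrected for the six
    comparisons. Rows with missing sector values are dropped (a warning
    reports the count). A pair with all differences exactly zero gets p = 1.
    """
    cols = list(_SECTOR_COLS.values())
    missing = [c for c in cols + ["group"] if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort table is missing columns: {missing}")
    df = table[table["group"] == group]
    n_before = len(df)
    df = df.dropna(subset=cols)
    if len(df) < n_before:
        warnings.warn(f"dropped {n_before - len(df)} rows with missing sector values")
    rows = []
    for a, b in itertools.combinations(SECTORS, 2):
        d = (df[_SECTOR_COLS[a]] - df[_SECTOR_COLS[b]]).to_numpy(dtype=float)
        est = float(d.mean()) if len(d) else np.nan
        sd = float(d.std(ddof=1)) if len(d) > 1 else np.nan
        if len(d) > 1 and sd > 0:
            t, p = sps.ttest_1samp(d, 0.0)
            t, p = float(t), float(p)
        elif len(d) > 1 and est == 0.0:
            t, p = 0.0, 1.0     # identically zero differences
        else:
            t, p = np.inf * np.sign(est), 0.0
        rows.append({"sector_a": a, "sector_b": b, "estimate": est, "sd": sd,
                     "n": len(d), "t": t, "p_raw": p,
                     "p_bonf": min(1.0, bonferroni_family * p)})
    return pd.DataFrame(rows)


@dataclass
class UnivariateFit:
    """Simple least-squares regression summary (y on x)."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    r: float
    r2: float
    p: float
    n: int


def univariate_fit(table: pd.DataFrame, y: str, x: str) -> UnivariateFit:
    """Univariable linear regression of ``y`` on ``x`` with slope CI,
    R-squared and the (signed) Pearson correlation, r = sign(slope)·sqrt(R²)."""
    for col in (y, x):
        if col not in table.columns:
            raise SchemaError(f"cohort table is missing column {col!r}")
    df = table[[y, x]].dropna()
    if len(df) < 3:
        raise SingularDesignError(f"need >= 3 complete pairs for {y} ~ {x}, got {len(df)}")
    xv = df[x].to_numpy(dtype=float)
    if np.ptp(xv) == 0:
        raise SingularDesignError(f"predictor {x!r} has zero variance")
    res = sm.OLS(df[y].to_numpy(dtype=float), sm.add_constant(xv)).fit()
    ci = res.conf_int()[1]
    slope = float(res.params[1])
    r2 = float(res.rsquared)
    return UnivariateFit(
        slope=slope, intercept=float(res.params[0]),
        ci_low=float(ci[0]), ci_high=float(ci[1]),
        r=float(np.sign(slope) * np.sqrt(r2)) if slope != 0 else 0.0,
        r2=r2, p=float(res.pvalues[1]), n=len(df))


def _pearson_filon_cov(r_jk: float, r_hm: float, rc: dict[str, float]) -> float:
    """Asymptotic covariance (x n) between two non-overlapping correlations
    r_jk and r_hm of jointly normal variables (Pearson & Filon, 1898)."""
    r_jh, r_jm, r_kh, r_km = rc["r_jh"], rc["r_jm"], rc["r_kh"], rc["r_km"]
    return (0.5 * r_jk * r_hm * (r_jh ** 2 + r_jm ** 2 + r_kh ** 2 + r_km ** 2)
            + r_jh * r_km + r_jm * r_kh
            - (r_jk * (r_jh * r_jm + r_kh * r_km)
               + r_hm * (r_jh * r_kh + r_jm * r_km)))


def compare_dependent_correlations(r1: float, r2: float, n: int,
                                   intercorrelations: dict[str, float] | None = None
                                   ) -> CorrelationComparison:
    """Dunn & Clark's z for two dependent non-overlapping correlations.

    ``r1 = r(j, k)`` and ``r2 = r(h, m)`` are computed on the same ``n``
    sampling units with no shared variable. ``intercorrelations`` supplies
    the four cross-correlations ``r_jh, r_jm, r_kh, r_km``; without them,
    the two correlations are treated as independent, which overstates the
    variance of the difference whenever their true covariance is positive
    (a conservative default, flagged via ``assumed_independent``).
    """
    if n <= 3:
        raise ValueError(f"need n > 3 samples, got {n}")
    for name, r in (("r1", r1), ("r2", r2)):
        if abs(r) >= 1:
            raise ValueError(f"|{name}| must be < 1, got {r}")
    assumed_independent = intercorrelations is None
    if assumed_independent:
        c = 0.0
    else:
        keys = ("r_jh", "r_jm", "r_kh", "r_km")
        missing = [k for k in keys if k not in intercorrelations]
        if missing:
            raise ValueError(f"intercorrelations missing keys: {missing}")
        rc = {k: float(intercorrelations[k]) for k in keys}
        R = np.array([
            [1.0, r1, rc["r_jh"], rc["r_jm"]],
            [r1, 1.0, rc["r_kh"], rc["r_km"]],
            [rc["r_jh"], rc["r_kh"], 1.0, r2],
            [rc["r_jm"], rc["r_km"], r2, 1.0],
        ])
        if np.linalg.eigvalsh(R).min() < -1e-8:
            raise ValueError("intercorrelation matrix is not positive semidefinite")
        c = _pearson_filon_cov(r1, r2, rc) / ((1 - r1 ** 2) * (1 - r2 ** 2))
    c = float(np.clip(c, -0.999, 0.999))
    z = (np.arctanh(r1) - np.arctanh(r2)) * np.sqrt((n - 3) / (2.0 - 2.0 * c))
    p = float(2 * sps.norm.sf(abs(z)))
    return CorrelationComparison(
        r1=float(r1), r2=float(r2), difference=float(r1 - r2), n=int(n),
        z=float(z), p=p, intercorrelations=None if assumed_independent else rc,
        assumed_independent=assumed_independent)


def sector_correlation_difference(table: pd.DataFrame, sector_a: str, sector_b: str
                                  ) -> CorrelationComparison:
    """Compare r(PCD_a, RNFL_a) with r(PCD_b, RNFL_b) on one cohort table.

    Both correlations and the full intercorrelation structure are estimated
    from the same (complete-case) rows, then passed to
    :func:`compare_dependent_correlations` with n = number of eyes.
    """
    cols = [_SECTOR_COLS[sector_a], _RNFL_COLS[sector_a],
            _SECTOR_COLS[sector_b], _RNFL_COLS[sector_b]]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort table is missing columns: {missing}")
    df = table[cols].dropna()
    R = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
    # variable order: j = PCD_a, k = RNFL_a, h = PCD_b, m = RNFL_b
    return compare_dependent_correlations(
        r1=float(R[0, 1]), r2=float(R[2, 3]), n=len(df),
        intercorrelations={"r_jh": float(R[0, 2]), "r_jm": float(R[0, 3]),
                           "r_kh": float(R[1, 2]), "r_km": float(R[1, 3])})
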