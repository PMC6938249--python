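"""Coarticulation degree as a regression statistic, plus descriptive tests.

Coarticulation degree is the slope of normalized consonant-midpoint
dorsum position (peak_c_x) regressed on normalized vowel-midpoint
position (peak_v_x): 1 means the consonant fully anticipates the vowel's
lingual gesture, 0 means it is immune to it. The slope is estimated

* per speaker/consonant by closed-form OLS (:func:`slope_ols`), and
* pooled across children by a linear mixed model with
  slope-by-consonant and slope-by-cohort fixed interactions and random
  peak_v_x slopes by speaker (consonant-specific) and by word
  (:func:`fit_pooled_lmm`), from which pairwise cohort ("age") and
  consonant contrasts on the slope are read off.

Welch t tests and Pearson correlations for the behavioral descriptives
delegate to scipy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REFERENCE_CONSONANT = "b"
REFERENCE_COHORT = "K1"


class DegenerateFitError(ValueError):
    """Zero vowel variance: the coarticulation slope is undefined."""


class InsufficientDataError(ValueError):
    """Fewer pairs than the minimum required for a reported fit."""


@dataclass(frozen=True)
class SlopeFit:
    """One coarticulation-degree estimate (OLS of peak_c_x on peak_v_x)."""

    speaker_id: str  # or "pooled"
    consonant: str
    slope: float
    intercept: float
    slope_se: float
    n_tokens: int


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    kind: str  # welch_t | pearson_r

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p={self.p} outside [0, 1]")


@dataclass
class MixedModelResult:
    fixed_effects: pd.DataFrame      # term, estimate, std_error, t
    age_contrasts: pd.DataFrame      # comparison, estimate, std_error, t, p
    consonant_contrasts: pd.DataFrame
    vc_estimates: Dict[str, float]
    scale: float
    converged: bool
    singular: bool
    n_obs: int
    n_speakers: int
    n_words: int
    p_method: str


def slope_ols(pairs: Sequence[Tuple[float, float]], speaker_id: str = "pooled",
              consonant: str = "", min_tokens: int = 3) -> SlopeFit:
    """Closed-form OLS slope of consonant position on vowel position.

    slope = cov(v, c) / var(v); the standard error uses the usual
    residual-variance formula with n - 2 degrees of freedom.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (peak_v_x, peak_c_x)")
    n = arr.shape[0]
    if n < min_tokens:
        raise InsufficientDataError(f"need >= {min_tokens} pairs, got {n}")
    v, c = arr[:, 0], arr[:, 1]
    v_mean, c_mean = v.mean(), c.mean()
    sxx = float(((v - v_mean) ** 2).sum())
    if sxx == 0.0:
        raise DegenerateFitError("zero variance in peak_v_x")
    sxy = float(((v - v_mean) * (c - c_mean)).sum())
    slope = sxy / sxx
    intercept = c_mean - slope * v_mean
    resid = c - (intercept + slope * v)
    sigma2 = float((resid**2).sum()) / (n - 2) if n > 2 else 0.0
    se = float(np.sqrt(sigma2 / sxx))
    return SlopeFit(speaker_id, consonant, float(slope), float(intercept), se, n)


def pooled_consonant_slopes(table: pd.DataFrame, min_tokens: int = 3) -> pd.DataFrame:
    """Pooled OLS slope per consonant over all speakers' rows."""
    rows = []
    for consonant, grp in table.groupby("consonant", sort=True):
        fit = slope_ols(
            np.column_stack([grp["peak_v_x"], grp["peak_c_x"]]),
            speaker_id="pooled", consonant=str(consonant), min_tokens=min_tokens,
        )
        rows.append(fit.__dict__)
    return pd.DataFrame(rows)


def per_speaker_slopes(table: pd.DataFrame, min_tokens: int = 3) -> pd.DataFrame:
    """OLS slope per speaker x consonant; groups below ``min_tokens`` are skipped."""
    rows = []
    for (spk, consonant), grp in table.groupby(["speaker_id", "consonant"], sort=True):
        if len(grp) < min_tokens:
            logger.warning("skipping %s/%s: only %d tokens", spk, consonant, len(grp))
            continue
        try:
            fit = slope_ols(
                np.column_stack([grp["peak_v_x"], grp["peak_c_x"]]),
                speaker_id=str(spk), consonant=str(consonant), min_tokens=min_tokens,
            )
        except DegenerateFitError:
            logger.warning("skipping %s/%s: zero vowel variance", spk, consonant)
            continue
        rows.append(fit.__dict__)
    return pd.DataFrame(rows)


def welch_t(a: Iterable[float], b: Iterable[float]) -> TestResult:
    """Two-sided Welch t test with Welch-Satterthwaite degrees of freedom."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TestResult(0.0, float(a.size + b.size - 2), 1.0, "welch_t")
        raise DegenerateFitError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue), "welch_t")


def pearson_r(x: Iterable[float], y: Iterable[float]) -> TestResult:
    """Pearson product-moment correlation with two-sided p from the t transform."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("need n >= 3 paired values")
    if x.var() == 0.0 or y.var() == 0.0:
        raise DegenerateFitError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return TestResult(float(res.statistic), float(x.size - 2), float(res.pvalue), "pearson_r")


def _contrast_table(levels, names, params, cov, p_method, resid_df) -> pd.DataFrame:
    """Pairwise contrasts on slope coefficients given a coefficient map.

    ``names`` maps each non-reference level to its coefficient name; the
    reference level has an implicit zero coefficient.
    """
    idx = {nm: i for i, nm in enumerate(params.index)}
    rows = []
    k = len(params)
    for i, hi in enumerate(levels):
        for lo in levels[:i]:
            vec = np.zeros(k)
            if hi in names:
                vec[idx[names[hi]]] += 1.0
            if lo in names:
                vec[idx[names[lo]]] -= 1.0
            est = float(vec @ params.to_numpy())
            se = float(np.sqrt(vec @ cov @ vec))
            t = est / se if se > 0 else np.nan
            if p_method == "residual":
                p = float(2 * stats.t.sf(abs(t), resid_df)) if np.isfinite(t) else np.nan
            else:
                p = float(2 * stats.norm.sf(abs(t))) if np.isfinite(t) else np.nan
            rows.append(
                {"comparison": f"{hi}-{lo}", "estimate": est, "std_error": se, "t": t, "p": p}
            )
    return pd.DataFrame(rows, columns=["comparison", "estimate", "std_error", "t", "p"])


def fit_pooled_lmm(
    table: pd.DataFrame,
    reference_consonant: str = REFERENCE_CONSONANT,
    reference_cohort: str = REFERENCE_COHORT,
    p_method: str = "normal",
    include_word_slopes: bool = True,
) -> MixedModelResult:
    """Mixed model of normalized consonant position on vowel position.

    Fixed effects: peak_v_x crossed with consonant and with cohort (plus
    the marginal factors). Random effects: consonant-specific peak_v_x
    slopes by speaker and peak_v_x slopes by word (the C1+V pseudoword),
    fitted as independent variance components by REML (statsmodels
    MixedLM). Cohort and consonant contrasts on the coarticulation slope
    are reported with normal-approximation p-values by default
    (``p_method="residual"`` uses a t reference with n - p df).
    """
    from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec

    if p_method not in ("normal", "residual"):
        raise ValueError(f"unknown p_method {p_method!r}")
    df = table.reset_index(drop=True)
    consonants = sorted(df["consonant"].unique())
    cohorts = sorted(df["cohort"].unique())
    if reference_consonant in consonants:
        consonants = [reference_consonant] + [c for c in consonants if c != reference_consonant]
    if reference_cohort in cohorts:
        cohorts = [reference_cohort] + [c for c in cohorts if c != reference_cohort]
    v = df["peak_v_x"].to_numpy(float)
    y = df["peak_c_x"].to_numpy(float)
    n = len(df)

    cols = {"Intercept": np.ones(n)}
    cons_names, coh_names = {}, {}
    for c in consonants[1:]:
        cols[f"C[{c}]"] = (df["consonant"] == c).to_numpy(float)
    for g in cohorts[1:]:
        cols[f"cohort[{g}]"] = (df["cohort"] == g).to_numpy(float)
    cols["peak_v_x"] = v
    for c in consonants[1:]:
        nm = f"peak_v_x:C[{c}]"
        cols[nm] = v * (df["consonant"] == c).to_numpy(float)
        cons_names[c] = nm
    for g in cohorts[1:]:
        nm = f"peak_v_x:cohort[{g}]"
        cols[nm] = v * (df["cohort"] == g).to_numpy(float)
        coh_names[g] = nm
    exog = pd.DataFrame(cols)

    # variance components: all rows form one "group" so that the speaker and
    # word random slopes, which are crossed, can coexist
    speakers = sorted(df["speaker_id"].unique())
    words = sorted(df["word_id"].unique())
    spk_dum = pd.get_dummies(pd.Categorical(df["speaker_id"], categories=speakers)).to_numpy(float)
    word_dum = pd.get_dummies(pd.Categorical(df["word_id"], categories=words)).to_numpy(float)
    vc_names, vc_colnames, vc_mats = [], [], []
    for c in consonants:
        mask = (df["consonant"] == c).to_numpy(float)
        vc_names.append(f"spk_slope[{c}]")
        vc_colnames.append([[f"{s}:{c}" for s in speakers]])
        vc_mats.append([spk_dum * (mask * v)[:, None]])
    if include_word_slopes:
        vc_names.append("word_slope")
        vc_colnames.append([list(words)])
        vc_mats.append([word_dum * v[:, None]])
    vcs = VCSpec(vc_names, vc_colnames, vc_mats)

    model = MixedLM(
        y, exog, groups=np.zeros(n, dtype=int),
        exog_re=np.empty((n, 0)), exog_vc=vcs,
    )
    converged, singular = True, False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(reml=True, method="powell")
        except Exception:
            logger.warning("powell failed; retrying with lbfgs")
            res = model.fit(reml=True, method="lbfgs")
    converged = bool(getattr(res, "converged", True))
    for w in caught:
        msg = str(w.message).lower()
        if "singular" in msg or "boundary" in msg:
            singular = True
        if "converge" in msg or "convergence" in msg:
            converged = False
    if not converged:
        logger.warning("mixed model did not converge; fixed effects still reported")

    params = res.fe_params
    cov = np.asarray(res.cov_params())[: len(params), : len(params)]
    bse = np.sqrt(np.diag(cov))
    fixed = pd.DataFrame(
        {
            "term": list(params.index),
            "estimate": params.to_numpy(),
            "std_error": bse,
            "t": params.to_numpy() / bse,
        }
    )
    resid_df = n - len(params)
    if len(cohorts) < 2:
        logger.warning("only one cohort present; age contrasts skipped")
        age = pd.DataFrame(columns=["comparison", "estimate", "std_error", "t", "p"])
    else:
        age = _contrast_table(cohorts, coh_names, params, cov, p_method, resid_df)
    if len(consonants) < 2:
        cons = pd.DataFrame(columns=["comparison", "estimate", "std_error", "t", "p"])
    else:
        cons = _contrast_table(consonants, cons_names, params, cov, p_method, resid_df)

    vc_est = {nm: float(val) for nm, val in zip(vc_names, res.vcomp)}
    return MixedModelResult(
        fixed_effects=fixed,
        age_contrasts=age,
        consonant_contrasts=cons,
        vc_estimates=vc_est,
        scale=float(res.scale),
        converged=converged,
        singular=singular,
        n_obs=n,
        n_speakers=len(speakers),
        n_words=len(words),
        p_method=p_method,
    )


def age_contrasts(result: MixedModelResult) -> pd.DataFrame:
    """The pairwise cohort contrasts on the coarticulation slope."""
    return result.age_contrasts.copy()
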