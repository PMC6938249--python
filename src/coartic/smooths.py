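"""Penalized tensor-product smooth interactions and terrain-map grids.

For one consonantal context, the normalized consonant-midpoint dorsum
position is modeled as a smooth surface over (skill score, vowel
position):

    peak_c_x ~ intercept + f(score, peak_v_x)

f is a tensor-product smooth built from marginal cubic B-spline bases
(default rank 5 per margin) with exact integrated-squared-second-
derivative penalties. The tensor basis is reparametrized into a
functional ANOVA layout -- linear main effects, nonlinear main effects,
and a (linear + nonlinear) interaction block -- and every component
carries its own smoothing parameter, including full-rank shrinkage of
the penalty null space. Smoothing parameters are selected by restricted
maximum likelihood (REML; GCV optional).

Because the null space is itself shrinkable, the effective degrees of
freedom (edf) of the whole smooth approach 1 on data that are purely
linear in vowel position, and values above 1 signal nonlinearity -- the
reporting convention used throughout. Significance uses a
truncated-Wald F approximation on the smooth's coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)

MIN_ROWS = 50
MIN_VOWEL_SPAN = 0.5


class SmoothFitError(ValueError):
    """Data unsuitable for a tensor-smooth fit (constant score, too few rows...)."""


class ExtrapolationError(ValueError):
    """Prediction requested beyond the observed score range."""


class _Margin:
    """One marginal cubic B-spline basis with a curvature penalty.

    Exposes the margin reparametrized into a centered linear column and
    ``k - 2`` nonlinear columns scaled so the curvature penalty is the
    identity; together with a constant they span the original basis.
    """

    degree = 3

    def __init__(self, x: np.ndarray, k: int, domain: Optional[Tuple[float, float]] = None):
        if k < 4:
            raise SmoothFitError("marginal basis dimension must be >= 4")
        x = np.asarray(x, dtype=float)
        lo, hi = domain if domain is not None else (float(x.min()), float(x.max()))
        if not hi > lo:
            raise SmoothFitError("margin has zero range")
        self.lo, self.hi, self.k = lo, hi, k
        inner = np.linspace(lo, hi, k - self.degree + 1)
        self.knots = np.concatenate(
            [np.full(self.degree, lo), inner, np.full(self.degree, hi)]
        )
        self._spl = BSpline(self.knots, np.eye(k), self.degree, extrapolate=True)
        self._curv = self._spl.derivative(2)
        P = self._curvature_penalty()
        evals, evecs = np.linalg.eigh(P)
        tol = 1e-9 * evals.max()
        pen = evals > tol
        if pen.sum() != k - 2:  # curvature penalty annihilates exactly {1, x}
            raise SmoothFitError("unexpected curvature-penalty null space")
        self._U = evecs[:, pen] / np.sqrt(evals[pen])
        self.mid = 0.5 * (lo + hi)
        self.halfspan = 0.5 * (hi - lo)

    def _curvature_penalty(self) -> np.ndarray:
        # B'' of a cubic spline is piecewise linear, so per-interval Simpson
        # integrates the products exactly
        P = np.zeros((self.k, self.k))
        breaks = np.unique(self.knots)
        for a, b in zip(breaks[:-1], breaks[1:]):
            pts = np.array([a, 0.5 * (a + b), b])
            D = self._curv(pts)  # (3, k)
            w = (b - a) / 6.0 * np.array([1.0, 4.0, 1.0])
            P += (D * w[:, None]).T @ D
        return P

    def linear(self, x) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mid) / self.halfspan

    def nonlinear(self, x) -> np.ndarray:
        return self._spl(np.asarray(x, dtype=float)) @ self._U


@dataclass
class SmoothFit:
    """A fitted tensor-product smooth for one consonant and one score."""

    consonant: str
    score_name: str
    edf: float
    f_stat: float
    p: float
    score_edf: float
    score_f: float
    score_p: float
    smoothing_params: Dict[str, float]
    criterion: str
    basis_dims: Tuple[int, int]
    n_obs: int
    score_range: Tuple[float, float]
    vowel_range: Tuple[float, float]
    edf_by_term: Dict[str, float] = field(default_factory=dict)
    _margins: tuple = field(default=None, repr=False)
    _beta: np.ndarray = field(default=None, repr=False)
    _scales: np.ndarray = field(default=None, repr=False)

    def predict(self, score, vowel, allow_extrapolation: bool = False) -> np.ndarray:
        score = np.asarray(score, dtype=float)
        vowel = np.asarray(vowel, dtype=float)
        lo, hi = self.score_range
        if not allow_extrapolation and (score.min() < lo - 1e-12 or score.max() > hi + 1e-12):
            raise ExtrapolationError(
                f"score values outside the observed range [{lo}, {hi}]; "
                "pass allow_extrapolation=True to override"
            )
        X = _design(self._margins[0], self._margins[1], score, vowel)[0]
        return (X / self._scales) @ self._beta


@dataclass
class TerrainGrid:
    """Rectangular prediction grid of the fitted surface (a terrain map)."""

    consonant: str
    score_name: str
    score_grid: np.ndarray
    vowel_grid: np.ndarray
    values: np.ndarray  # (n_score, n_vowel)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.score_grid), len(self.vowel_grid)):
            raise ValueError("grid values must be (n_score, n_vowel)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite predictions on the grid")

    def to_frame(self) -> pd.DataFrame:
        s, v = np.meshgrid(self.score_grid, self.vowel_grid, indexing="ij")
        return pd.DataFrame(
            {
                "consonant": self.consonant,
                "score_name": self.score_name,
                "score": s.ravel(),
                "peak_v_x": v.ravel(),
                "predicted_peak_c_x": self.values.ravel(),
            }
        )


def _design(ms: "_Margin", mv: "_Margin", score: np.ndarray, vowel: np.ndarray):
    """Assemble the ANOVA-layout tensor design and its penalty structure.

    Returns (X, groups, weights): X has columns
    [1 | v_lin | s_lin | v_non | s_non | s_lin*v_lin | s_lin*v_non |
     s_non*v_lin | s_non (x) v_non]; ``groups`` maps each penalized column
    to its smoothing-parameter group, ``weights`` are per-column penalty
    weights (identity within group before column rescaling).
    """
    n = len(score)
    s_lin = ms.linear(score)
    v_lin = mv.linear(vowel)
    s_non = ms.nonlinear(score)
    v_non = mv.nonlinear(vowel)
    blocks = [
        ("intercept", np.ones((n, 1))),
        ("v_lin", v_lin[:, None]),
        ("s_lin", s_lin[:, None]),
        ("v_non", v_non),
        ("s_non", s_non),
        ("int_lin", (s_lin * v_lin)[:, None]),
        ("int_non", np.column_stack(
            [s_lin[:, None] * v_non, s_non * v_lin[:, None]]
            + [s_non[:, [i]] * v_non for i in range(s_non.shape[1])]
        )),
    ]
    X = np.column_stack([b for _, b in blocks])
    groups, weights = [], []
    for name, b in blocks:
        groups.extend([name] * b.shape[1])
        weights.extend([0.0 if name == "intercept" else 1.0] * b.shape[1])
    return X, np.array(groups), np.array(weights)


GROUPS = ("v_lin", "s_lin", "v_non", "s_non", "int_lin", "int_non")
SCORE_GROUPS = ("s_lin", "s_non", "int_lin", "int_non")


def _reml_criterion(rho, A, Xty, yty, dmat, group_idx, n, criterion):
    lam = np.exp(rho)
    d = dmat @ lam  # per-column penalty diagonal
    M = A + np.diag(d)
    try:
        L = np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        return 1e12
    beta = np.linalg.solve(M, Xty)
    rss = float(yty - 2 * beta @ Xty + beta @ A @ beta)
    pen = float(beta @ (d * beta))
    D = max(rss + pen, 1e-12 * yty)
    if criterion == "gcv":
        Ainv_half = np.linalg.solve(L, A)
        edf = float(np.trace(np.linalg.solve(L.T, Ainv_half)))
        return n * max(rss, 1e-12 * yty) / (n - edf) ** 2
    logdet_M = 2.0 * float(np.log(np.diag(L)).sum())
    logdet_S = float(np.sum(np.log(d[d > 0])))
    return (n - 1) * np.log(D) + logdet_M - logdet_S


def _truncated_wald(beta_b, V_b, edf_b, df2):
    """mgcv-style test of a smooth block: Wald on the top-edf eigendirections."""
    r = int(min(len(beta_b), max(1, round(edf_b))))
    evals, evecs = np.linalg.eigh(V_b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order][:r], evecs[:, order][:, :r]
    good = evals > 1e-12 * max(evals.max(), 1e-300)
    if not good.any():
        return 0.0, 1.0, r
    proj = evecs[:, good].T @ beta_b
    T = float(np.sum(proj**2 / evals[good]))
    F = T / r
    p = float(stats.f.sf(F, r, max(df2, 1.0)))
    return F, p, r


def fit_te_smooth(
    rows: pd.DataFrame,
    scores: Union[pd.DataFrame, Mapping[str, float], pd.Series],
    score_name: str = "composite_pa",
    k_score: int = 5,
    k_vowel: int = 5,
    criterion: str = "reml",
    per_speaker_intercept: bool = False,
) -> SmoothFit:
    """Fit peak_c_x ~ intercept + te(score, peak_v_x) for one consonant.

    Parameters
    ----------
    rows
        Analysis-table subset for a single consonant (columns speaker_id,
        peak_v_x, peak_c_x).
    scores
        Per-speaker skill values: a scores DataFrame containing
        ``score_name``, or a mapping/Series speaker_id -> value.
    criterion
        Smoothing-parameter selection: ``"reml"`` (default) or ``"gcv"``.
    per_speaker_intercept
        Adds fixed per-speaker intercept offsets (ridge-free); off by
        default.

    Notes
    -----
    The reported ``p`` tests the whole smooth; ``score_p`` tests only the
    score-involving components (score main effect + interaction), i.e.
    whether the skill score contributes at all beyond vowel position.
    """
    if criterion not in ("reml", "gcv"):
        raise ValueError(f"unknown criterion {criterion!r}")
    consonant = str(rows["consonant"].iloc[0]) if "consonant" in rows else ""
    if "consonant" in rows and rows["consonant"].nunique() > 1:
        raise SmoothFitError("rows must belong to a single consonant")
    if len(rows) < MIN_ROWS:
        raise SmoothFitError(f"need >= {MIN_ROWS} rows, got {len(rows)}")

    if isinstance(scores, pd.DataFrame):
        ser = scores.set_index("speaker_id")[score_name]
    elif isinstance(scores, pd.Series):
        ser = scores
    else:
        ser = pd.Series(dict(scores))
    score = rows["speaker_id"].map(ser).to_numpy(float)
    keep = np.isfinite(score)
    if not keep.all():
        logger.warning("dropping %d rows with missing %s", (~keep).sum(), score_name)
    rows = rows.loc[keep]
    score = score[keep]
    vowel = rows["peak_v_x"].to_numpy(float)
    y = rows["peak_c_x"].to_numpy(float)
    n = len(y)
    if n < MIN_ROWS:
        raise SmoothFitError(f"need >= {MIN_ROWS} usable rows, got {n}")
    if np.ptp(score) == 0.0:
        raise SmoothFitError("score is constant: no interaction estimable")
    if np.ptp(vowel) <= MIN_VOWEL_SPAN:
        raise SmoothFitError("vowel positions span too little of [0, 1]")

    ms = _Margin(score, k_score)
    mv = _Margin(vowel, k_vowel)
    X, groups, weights = _design(ms, mv, score, vowel)
    if per_speaker_intercept:
        spk = pd.get_dummies(rows["speaker_id"]).to_numpy(float)[:, 1:]
        X = np.column_stack([X, spk])
        groups = np.concatenate([groups, ["speaker"] * spk.shape[1]])
        weights = np.concatenate([weights, np.full(spk.shape[1], 1e-8)])

    # column rescaling for conditioning; penalty weights follow (w / s^2)
    scales = np.sqrt(np.mean(X**2, axis=0))
    scales[scales == 0] = 1.0
    Xs = X / scales
    w_adj = weights / scales**2 * np.mean(scales**2)

    group_names = list(GROUPS) + (["speaker"] if per_speaker_intercept else [])
    dmat = np.zeros((Xs.shape[1], len(group_names)))
    for j, g in enumerate(group_names):
        dmat[groups == g, j] = w_adj[groups == g]

    A = Xs.T @ Xs
    Xty = Xs.T @ y
    yty = float(y @ y)
    obj = lambda rho: _reml_criterion(rho, A, Xty, yty, dmat, groups, n, criterion)
    res = optimize.minimize(
        obj,
        x0=np.zeros(len(group_names)),
        method="Nelder-Mead",
        bounds=[(-18.0, 18.0)] * len(group_names),
        options={"maxiter": 3000, "xatol": 1e-3, "fatol": 1e-6},
    )
    lam = np.exp(res.x)
    d = dmat @ lam
    M = A + np.diag(d)
    beta = np.linalg.solve(M, Xty)
    Minv = np.linalg.inv(M)
    edf_cols = np.sum(Minv * A, axis=1)  # diag(Minv @ A)
    rss = float(yty - 2 * beta @ Xty + beta @ A @ beta)
    pen = float(beta @ (d * beta))
    sigma2 = max(rss + pen, 0.0) / max(n - 1, 1)
    Vb = sigma2 * Minv

    smooth_mask = np.isin(groups, GROUPS)
    edf_total = float(edf_cols.sum())
    edf_smooth = float(edf_cols[smooth_mask].sum())
    df2 = n - edf_total
    idx = np.flatnonzero(smooth_mask)
    F, p, _ = _truncated_wald(beta[idx], Vb[np.ix_(idx, idx)], edf_smooth, df2)
    sidx = np.flatnonzero(np.isin(groups, SCORE_GROUPS))
    edf_score = float(edf_cols[sidx].sum())
    sF, sp, _ = _truncated_wald(beta[sidx], Vb[np.ix_(sidx, sidx)], edf_score, df2)

    edf_by_term = {
        g: float(edf_cols[groups == g].sum()) for g in group_names
    }
    return SmoothFit(
        consonant=consonant,
        score_name=score_name,
        edf=edf_smooth,
        f_stat=F,
        p=p,
        score_edf=edf_score,
        score_f=sF,
        score_p=sp,
        smoothing_params={g: float(l) for g, l in zip(group_names, lam)},
        criterion=criterion,
        basis_dims=(k_score, k_vowel),
        n_obs=n,
        score_range=(ms.lo, ms.hi),
        vowel_range=(mv.lo, mv.hi),
        edf_by_term=edf_by_term,
        _margins=(ms, mv),
        _beta=beta,
        _scales=scales[: len(beta)] if not per_speaker_intercept else scales,
    )


def predict_grid(
    fit: SmoothFit,
    n_score: int = 25,
    n_vowel: int = 25,
    allow_extrapolation: bool = False,
    score_range: Optional[Tuple[float, float]] = None,
    vowel_range: Tuple[float, float] = (0.0, 1.0),
) -> TerrainGrid:
    """Predict the fitted surface on a rectangular (score x vowel) grid.

    The default grid spans the observed score range and [0, 1] in vowel
    position -- exactly what a terrain-map plot consumes. Requesting
    scores beyond the observed range raises unless
    ``allow_extrapolation`` is set.
    """
    if n_score < 2 or n_vowel < 2:
        raise ValueError("need n_score, n_vowel >= 2")
    lo, hi = score_range if score_range is not None else fit.score_range
    if not allow_extrapolation and (lo < fit.score_range[0] - 1e-12 or hi > fit.score_range[1] + 1e-12):
        raise ExtrapolationError(
            f"requested score range [{lo}, {hi}] exceeds observed {fit.score_range}"
        )
    sgrid = np.linspace(lo, hi, n_score)
    vgrid = np.linspace(*vowel_range, n_vowel)
    S, V = np.meshgrid(sgrid, vgrid, indexing="ij")
    vals = fit.predict(S.ravel(), V.ravel(), allow_extrapolation=allow_extrapolation)
    return TerrainGrid(fit.consonant, fit.score_name, sgrid, vgrid, vals.reshape(n_score, n_vowel))


def nonlinearity_report(fits: Sequence[SmoothFit]) -> pd.DataFrame:
    """Fits ordered by edf (descending), ties broken by consonant label.

    Reproduces the reporting format of per-consonant tensor-smooth
    tables: one row per consonant with edf, F, and p.
    """
    rows = [
        {
            "consonant": f.consonant,
            "score_name": f.score_name,
            "edf": f.edf,
            "f": f.f_stat,
            "p": f.p,
            "n_obs": f.n_obs,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows)
    df["_neg_edf"] = -df["edf"]
    df = df.sort_values(["_neg_edf", "consonant"], kind="mergesort").drop(columns="_neg_edf")
    return df.reset_index(drop=True)
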