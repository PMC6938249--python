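"""End-to-end pipeline: simulate -> validate -> extract -> score -> model -> report.

All stage outputs are plain CSV/JSON so other environments (R, spreadsheets)
can consume them; the whole run is a deterministic function of the config
and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contours import N_SPLINE_POINTS, build_analysis_table
from .models import fit_pooled_lmm, pearson_r, per_speaker_slopes, pooled_consonant_slopes, welch_t
from .scoring import COMPOSITE_MAX, N_ITEMS, summarize_scores
from .simulate import (
    COHORTS,
    DEFAULT_COHORT_SIZES,
    ConfigurationError,
    GesturalConfig,
    SimulatedDataset,
    _check_unknown,
    simulate_cohort,
)
from .smooths import SmoothFitError, fit_te_smooth, nonlinearity_report, predict_grid

logger = logging.getLogger(__name__)

RESULT_FILES = (
    "descriptives.csv",
    "welch_tests.csv",
    "correlations.csv",
    "slopes_pooled.csv",
    "slopes_by_speaker.csv",
    "age_contrasts.csv",
    "consonant_contrasts.csv",
    "smooth_summaries.csv",
    "report.json",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs are marked in the report."""


@dataclass
class ModelOptions:
    reference_consonant: str = "b"
    reference_cohort: str = "K1"
    p_method: str = "normal"  # normal | residual
    include_word_slopes: bool = True
    min_tokens: int = 3


@dataclass
class GamOptions:
    k_score: int = 5
    k_vowel: int = 5
    criterion: str = "reml"  # reml | gcv
    per_speaker_intercept: bool = False
    scores: Tuple[str, ...] = ("rhyme", "composite_pa", "vocabulary")
    n_score: int = 25
    n_vowel: int = 25


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    out_dir: str = "coartic_out"
    seed: int = 0
    input_dir: Optional[str] = None   # read dataset CSVs from here if simulate is off
    simulate: bool = True
    cohort_sizes: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COHORT_SIZES))
    simulator: GesturalConfig = field(default_factory=GesturalConfig)
    orientation: str = "anterior_low"
    model: ModelOptions = field(default_factory=ModelOptions)
    gam: GamOptions = field(default_factory=GamOptions)
    allow_extrapolation: bool = False
    write_dataset: bool = True

    def __post_init__(self) -> None:
        if self.orientation not in ("anterior_low", "anterior_high"):
            raise ConfigurationError(f"unknown orientation {self.orientation!r}")
        if not self.simulate and self.input_dir is None:
            raise ConfigurationError("simulator disabled but no input_dir given")

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        _check_unknown(d, cls, "RunConfig")
        if "simulator" in d and isinstance(d["simulator"], Mapping):
            d["simulator"] = GesturalConfig.from_dict(d["simulator"])
        for key, sub in (("model", ModelOptions), ("gam", GamOptions)):
            if key in d and isinstance(d[key], Mapping):
                sd = dict(d[key])
                _check_unknown(sd, sub, key)
                if key == "gam" and "scores" in sd:
                    sd["scores"] = tuple(sd["scores"])
                d[key] = sub(**sd)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulator"] = self.simulator.to_dict()
        return d

    def hash(self) -> str:
        d = self.to_dict()
        for key in ("out_dir", "input_dir", "write_dataset"):  # paths are not science
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_inputs(
    contours: pd.DataFrame, tokens: pd.DataFrame, scores: pd.DataFrame
) -> List[dict]:
    """Structural validation of the three input tables.

    Returns a machine-readable issue list; an empty list means the
    dataset is well-formed.
    """
    issues: List[dict] = []
    counts = contours.groupby(["token_id", "segment"]).size()
    for (tok, seg), cnt in counts.items():
        if cnt != N_SPLINE_POINTS:
            issues.append(
                {"issue": "contour_length", "token_id": str(tok), "segment": str(seg),
                 "detail": f"{cnt} points, expected {N_SPLINE_POINTS}"}
            )
    have = set(map(tuple, counts.index.tolist()))
    for tok in tokens["token_id"]:
        for seg in ("C1", "V"):
            if (tok, seg) not in have:
                issues.append(
                    {"issue": "missing_segment", "token_id": str(tok), "segment": seg,
                     "detail": "no contour for this segment"}
                )
    bad = ~contours["segment"].isin(["C1", "V"])
    if bad.any():
        issues.append(
            {"issue": "unknown_segment", "token_id": "", "segment": "",
             "detail": str(sorted(contours.loc[bad, "segment"].unique()))}
        )
    limits = {
        "rhyme": N_ITEMS,
        "onset_deletion": N_ITEMS,
        "phoneme_synthesis": N_ITEMS,
        "composite_pa": COMPOSITE_MAX,
    }
    for col, hi in limits.items():
        if col not in scores.columns:
            continue
        vals = pd.to_numeric(scores[col], errors="coerce")
        bad_rows = scores.loc[vals.notna() & ((vals < 0) | (vals > hi)), "speaker_id"]
        for spk in bad_rows:
            issues.append(
                {"issue": "score_out_of_range", "speaker_id": str(spk), "segment": "",
                 "detail": f"{col} outside [0, {hi}]"}
            )
    for frame, nm in ((tokens, "tokens"), (scores, "scores")):
        if "cohort" in frame.columns:
            bad_cohort = ~frame["cohort"].isin(COHORTS)
            if bad_cohort.any():
                issues.append(
                    {"issue": "unknown_cohort", "speaker_id": "", "segment": "",
                     "detail": f"{nm}: {sorted(frame.loc[bad_cohort, 'cohort'].unique())}"}
                )
    return issues


def _versions() -> Dict[str, str]:
    import scipy
    import statsmodels

    return {
        "coartic": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _holm(pvals: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    if len(pvals) == 0:
        return pvals
    return multipletests(pvals, method="holm")[1]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write results under ``config.out_dir``.

    Returns the run report (also written as ``report.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": int(config.seed),
        "config_hash": config.hash(),
        "versions": _versions(),
        "stages": {},
        "parameters": {
            "orientation": config.orientation,
            "reference_consonant": config.model.reference_consonant,
            "reference_cohort": config.model.reference_cohort,
            "p_method": config.model.p_method,
            "gam_criterion": config.gam.criterion,
            "gam_basis_dims": [config.gam.k_score, config.gam.k_vowel],
        },
    }

    # --- acquire data -----------------------------------------------------
    if config.simulate:
        ds = simulate_cohort(config.simulator, config.cohort_sizes, config.seed)
        if config.write_dataset:
            ds.write(out / "dataset")
    else:
        in_dir = Path(config.input_dir)
        for fname in ("contours.csv", "tokens.csv", "scores.csv"):
            if not (in_dir / fname).exists():
                raise PipelineError(f"missing input file: {in_dir / fname}")
        ds = SimulatedDataset(
            speakers=[],
            contours=pd.read_csv(in_dir / "contours.csv"),
            tokens=pd.read_csv(in_dir / "tokens.csv"),
            scores=pd.read_csv(in_dir / "scores.csv"),
            truth={},
        )
    report["stages"]["data"] = {
        "n_speakers": int(ds.tokens["speaker_id"].nunique()),
        "n_tokens": int(len(ds.tokens)),
        "n_contour_rows": int(len(ds.contours)),
        "simulated": bool(config.simulate),
    }

    # --- validate ---------------------------------------------------------
    issues = validate_inputs(ds.contours, ds.tokens, ds.scores)
    report["stages"]["validate"] = {"n_issues": len(issues), "issues": issues[:50]}
    if issues:
        raise PipelineError(f"input validation found {len(issues)} issues; see report")

    # --- extract ----------------------------------------------------------
    extract_report: dict = {}
    table = build_analysis_table(
        ds.contours, ds.tokens, orientation=config.orientation, run_report=extract_report
    )
    report["stages"]["extract"] = extract_report
    _write_csv(table, out / "analysis_table.csv")

    # --- behavioral descriptives -----------------------------------------
    desc = summarize_scores(ds.scores)
    _write_csv(desc, out / "descriptives.csv")
    tests, corrs = [], []
    cohorts = sorted(ds.scores["cohort"].dropna().unique())
    for task in ("rhyme", "composite_pa", "vocabulary"):
        for a, b in combinations(cohorts, 2):
            va = pd.to_numeric(ds.scores.loc[ds.scores.cohort == a, task], errors="coerce").dropna()
            vb = pd.to_numeric(ds.scores.loc[ds.scores.cohort == b, task], errors="coerce").dropna()
            if len(va) < 2 or len(vb) < 2:
                continue
            try:
                t = welch_t(va, vb)
            except ValueError:
                continue
            tests.append(
                {"task": task, "comparison": f"{a}-{b}", "t": t.statistic, "df": t.df, "p": t.p}
            )
    pairs = [
        ("onset_deletion", "phoneme_synthesis"),
        ("rhyme", "composite_pa"),
        ("composite_pa", "vocabulary"),
        ("rhyme", "vocabulary"),
    ]
    for a, b in pairs:
        sub = ds.scores[[a, b]].apply(pd.to_numeric, errors="coerce").dropna()
        if len(sub) < 3 or sub[a].var() == 0 or sub[b].var() == 0:
            continue
        r = pearson_r(sub[a], sub[b])
        corrs.append({"x": a, "y": b, "r": r.statistic, "df": r.df, "p": r.p, "n": len(sub)})
    _write_csv(pd.DataFrame(tests), out / "welch_tests.csv")
    _write_csv(pd.DataFrame(corrs), out / "correlations.csv")
    report["stages"]["score"] = {"n_welch": len(tests), "n_correlations": len(corrs)}

    # --- coarticulation slopes -------------------------------------------
    pooled = pooled_consonant_slopes(table, min_tokens=config.model.min_tokens)
    by_spk = per_speaker_slopes(table, min_tokens=config.model.min_tokens)
    _write_csv(pooled, out / "slopes_pooled.csv")
    _write_csv(by_spk, out / "slopes_by_speaker.csv")
    report["stages"]["slopes"] = {
        "pooled": {r["consonant"]: r["slope"] for _, r in pooled.iterrows()},
        "n_speaker_fits": int(len(by_spk)),
    }

    # --- mixed model ------------------------------------------------------
    lmm = fit_pooled_lmm(
        table,
        reference_consonant=config.model.reference_consonant,
        reference_cohort=config.model.reference_cohort,
        p_method=config.model.p_method,
        include_word_slopes=config.model.include_word_slopes,
    )
    _write_csv(lmm.age_contrasts, out / "age_contrasts.csv")
    _write_csv(lmm.consonant_contrasts, out / "consonant_contrasts.csv")
    _write_csv(lmm.fixed_effects, out / "lmm_fixed_effects.csv")
    report["stages"]["lmm"] = {
        "converged": lmm.converged,
        "singular": lmm.singular,
        "n_obs": lmm.n_obs,
        "n_speakers": lmm.n_speakers,
        "n_words": lmm.n_words,
        "vc_estimates": lmm.vc_estimates,
    }

    # --- tensor smooths + terrain grids ----------------------------------
    fits, failures = [], []
    for score_name in config.gam.scores:
        for consonant in sorted(table["consonant"].unique()):
            sub = table[table["consonant"] == consonant]
            try:
                fit = fit_te_smooth(
                    sub,
                    ds.scores,
                    score_name=score_name,
                    k_score=config.gam.k_score,
                    k_vowel=config.gam.k_vowel,
                    criterion=config.gam.criterion,
                    per_speaker_intercept=config.gam.per_speaker_intercept,
                )
            except SmoothFitError as exc:
                logger.warning("smooth %s/%s refused: %s", score_name, consonant, exc)
                failures.append({"score_name": score_name, "consonant": consonant, "error": str(exc)})
                continue
            fits.append(fit)
            grid = predict_grid(
                fit,
                n_score=config.gam.n_score,
                n_vowel=config.gam.n_vowel,
                allow_extrapolation=config.allow_extrapolation,
            )
            _write_csv(grid.to_frame(), out / f"terrain_grid_{score_name}_{consonant}.csv")
    summary_parts = []
    for score_name in config.gam.scores:
        part = nonlinearity_report([f for f in fits if f.score_name == score_name])
        if not part.empty:
            summary_parts.append(part)
    smooth_summary = (
        pd.concat(summary_parts, ignore_index=True) if summary_parts else pd.DataFrame()
    )
    if not smooth_summary.empty:
        smooth_summary["p_holm"] = _holm(smooth_summary["p"].to_numpy())
    _write_csv(smooth_summary, out / "smooth_summaries.csv")
    report["stages"]["gam"] = {
        "n_fits": len(fits),
        "n_refused": len(failures),
        "refused": failures,
        "edf": {f"{f.score_name}:{f.consonant}": f.edf for f in fits},
    }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")
    return report
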