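"""Tongue-dorsum feature extraction and per-speaker normalization.

Each segment midpoint (the consonant C1 or the vowel V of a CV pseudoword
token) is represented by a 100-point midsagittal contour in raw scanner
coordinates. The analysis variable is the horizontal (x) coordinate of the
contour's highest point -- the antero-posterior tongue-dorsum position.

Raw positions are normalized per speaker so that the most anterior dorsum
position observed at *vowel* midpoints maps to 0 and the most posterior to
1. Consonant-midpoint positions are passed through the same linear map and
may legitimately fall outside [0, 1]; they are not clamped, since
truncation would bias coarticulation slopes toward zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_SPLINE_POINTS = 100

Orientation = Literal["anterior_low", "anterior_high"]


class DataError(ValueError):
    """Malformed kinematic data (non-finite contour, missing segment...)."""


class DegenerateSpeakerError(ValueError):
    """Speaker whose vowel-midpoint positions have zero range."""


@dataclass
class TongueSpline:
    """One 100-point midsagittal tongue contour at a segment midpoint."""

    speaker_id: str
    token_id: str
    segment: str  # "C1" | "V"
    points: np.ndarray  # (100, 2) array of (x, y), x strictly monotone

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise DataError(f"{self.token_id}/{self.segment}: points must be (n, 2)")
        if pts.shape[0] != N_SPLINE_POINTS:
            raise DataError(
                f"{self.token_id}/{self.segment}: expected {N_SPLINE_POINTS} points, "
                f"got {pts.shape[0]}"
            )
        if not np.all(np.isfinite(pts)):
            raise DataError(f"{self.token_id}/{self.segment}: non-finite coordinates")
        dx = np.diff(pts[:, 0])
        if not (np.all(dx > 0) or np.all(dx < 0)):
            raise DataError(f"{self.token_id}/{self.segment}: x not strictly monotone")
        self.points = pts

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass(frozen=True)
class SpeakerNormalization:
    """Linear map sending a speaker's vowel-position range onto [0, 1]."""

    speaker_id: str
    v_min: float
    v_max: float

    def __post_init__(self) -> None:
        if not self.v_max > self.v_min:
            raise DegenerateSpeakerError(
                f"speaker {self.speaker_id}: vowel range is degenerate "
                f"(v_min={self.v_min}, v_max={self.v_max})"
            )

    def __call__(self, z):
        return (np.asarray(z, dtype=float) - self.v_min) / (self.v_max - self.v_min)


def extract_dorsum_peak(spline: TongueSpline) -> float:
    """x-coordinate of the contour's highest point.

    Ties at the maximal y are resolved by averaging the tied x values
    (symmetric and deterministic).
    """
    y = spline.y
    if not np.all(np.isfinite(y)):
        raise DataError(f"{spline.token_id}/{spline.segment}: non-finite y")
    ymax = y.max()
    tied = np.flatnonzero(y == ymax)
    return float(spline.x[tied].mean())


def fit_speaker_normalization(
    speaker_id: str, vowel_peaks: Iterable[float]
) -> SpeakerNormalization:
    """Fit the 0-1 normalization from a speaker's raw vowel-midpoint peaks."""
    peaks = np.asarray(list(vowel_peaks), dtype=float)
    if peaks.size < 2 or np.unique(peaks).size < 2:
        raise DegenerateSpeakerError(
            f"speaker {speaker_id}: need >= 2 distinct vowel-midpoint positions"
        )
    return SpeakerNormalization(speaker_id, float(peaks.min()), float(peaks.max()))


def _peaks_from_contours(contours, orientation: Orientation) -> pd.DataFrame:
    """Peak position per (token, segment), as a tidy frame.

    ``contours`` is either an iterable of :class:`TongueSpline` or a long
    DataFrame with columns speaker_id, token_id, segment, point_index, x, y.
    Under the ``anterior_high`` convention raw x decreases front-to-back;
    x is sign-flipped before anything else so that all internal math uses
    anterior = low.
    """
    sign = -1.0 if orientation == "anterior_high" else 1.0
    if isinstance(contours, pd.DataFrame):
        df = contours.sort_values(["token_id", "segment", "point_index"], kind="mergesort")
        keys = pd.MultiIndex.from_frame(df[["token_id", "segment"]])
        codes = keys.factorize()[0]
        counts = np.bincount(codes)
        if not np.all(counts == N_SPLINE_POINTS):
            bad = int(np.argmax(counts != N_SPLINE_POINTS))
            tok, seg = df.iloc[np.searchsorted(codes, bad)][["token_id", "segment"]]
            raise DataError(
                f"{tok}/{seg}: expected {N_SPLINE_POINTS} points, got {counts[bad]}"
            )
        y = df["y"].to_numpy(float).reshape(-1, N_SPLINE_POINTS)
        x = sign * df["x"].to_numpy(float).reshape(-1, N_SPLINE_POINTS)
        if not np.all(np.isfinite(y)):
            bad = int(np.argmax(~np.isfinite(y).all(axis=1)))
            tok, seg = df.iloc[bad * N_SPLINE_POINTS][["token_id", "segment"]]
            raise DataError(f"{tok}/{seg}: non-finite y")
        tied = y == y.max(axis=1, keepdims=True)  # tie rule: mean of tied x
        peak = (x * tied).sum(axis=1) / tied.sum(axis=1)
        head = df.iloc[:: N_SPLINE_POINTS]
        return pd.DataFrame(
            {
                "speaker_id": head["speaker_id"].to_numpy(),
                "token_id": head["token_id"].to_numpy(),
                "segment": head["segment"].to_numpy(),
                "peak_x": peak,
            }
        )
    recs = []
    for sp in contours:
        flipped = sp
        if sign < 0:
            flipped = TongueSpline(
                sp.speaker_id, sp.token_id, sp.segment,
                np.column_stack([sign * sp.x, sp.y]),
            )
        recs.append(
            {
                "speaker_id": sp.speaker_id,
                "token_id": sp.token_id,
                "segment": sp.segment,
                "peak_x": extract_dorsum_peak(flipped),
            }
        )
    return pd.DataFrame(recs)


def build_analysis_table(
    contours,
    tokens: pd.DataFrame,
    orientation: Orientation = "anterior_low",
    run_report: Optional[dict] = None,
) -> pd.DataFrame:
    """Assemble the per-token analysis table of normalized dorsum positions.

    Parameters
    ----------
    contours
        Iterable of :class:`TongueSpline`, or the long contour DataFrame
        written by the simulator (columns speaker_id, token_id, segment,
        point_index, x, y).
    tokens
        Token table keyed by ``token_id`` with columns speaker_id, cohort,
        consonant, vowel, rep.
    orientation
        Raw-x convention; ``anterior_low`` (default) means x grows
        front-to-back.
    run_report
        Optional dict to which drop counts are added.

    Returns
    -------
    DataFrame with one row per token: speaker_id, cohort, consonant,
    vowel, rep, word_id, peak_c_x_raw, peak_v_x_raw, peak_c_x, peak_v_x.
    Speakers with a degenerate (zero-range) vowel span are dropped with a
    logged warning and accounted for in ``run_report``.
    """
    peaks = _peaks_from_contours(contours, orientation)
    wide = peaks.pivot_table(index="token_id", columns="segment", values="peak_x")
    missing = [
        tok for tok in tokens["token_id"]
        if tok not in wide.index
        or "C1" not in wide.columns or "V" not in wide.columns
        or pd.isna(wide.loc[tok]).any()
    ]
    if missing:
        raise DataError(f"tokens missing a C1 or V contour: {missing[:5]}"
                        + ("..." if len(missing) > 5 else ""))

    table = tokens.copy()
    table["peak_c_x_raw"] = wide.loc[table["token_id"], "C1"].to_numpy()
    table["peak_v_x_raw"] = wide.loc[table["token_id"], "V"].to_numpy()
    table["word_id"] = table["consonant"].astype(str) + table["vowel"].astype(str)

    dropped_speakers = []
    out = []
    for spk, grp in table.groupby("speaker_id", sort=True):
        try:
            norm = fit_speaker_normalization(str(spk), grp["peak_v_x_raw"])
        except DegenerateSpeakerError as exc:
            logger.warning("dropping speaker %s: %s", spk, exc)
            dropped_speakers.append(str(spk))
            continue
        g = grp.copy()
        g["peak_c_x"] = norm(g["peak_c_x_raw"])
        g["peak_v_x"] = norm(g["peak_v_x_raw"])
        out.append(g)

    if run_report is not None:
        run_report["dropped_speakers"] = dropped_speakers
        run_report["n_tokens_in"] = int(len(table))
        run_report["n_rows_out"] = int(sum(len(g) for g in out))

    if not out:
        raise DataError("no speakers with a usable vowel range")
    cols = [
        "speaker_id", "cohort", "consonant", "vowel", "rep", "word_id",
        "peak_c_x_raw", "peak_v_x_raw", "peak_c_x", "peak_v_x",
    ]
    result = pd.concat(out, ignore_index=True)
    extra = [c for c in result.columns if c not in cols and c != "token_id"]
    return result[["token_id"] + cols + extra] if "token_id" in result else result[cols]
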