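"""Synthetic gestural data with known coarticulation ground truth.

The generator emulates the study design the analysis pipeline expects:
41 children in three cohorts (K1 n=10, K2 n=13, P1 n=18) each producing
3 consonants /b, d, g/ x 6 tense vowels /i, y, u, a, e, o/ x 6
repetitions of C1-V pseudowords, recorded as 100-point midsagittal
tongue contours at the consonant (C1) and vowel (V) midpoints, plus four
behavioral scores per child.

The articulatory model is gestural blending: in normalized gesture space
(0 = most anterior, 1 = most posterior dorsum position) the vowel
contour is centered on the vowel's dorsum target T_v, and the consonant
contour on the convex blend

    (1 - w) * D_c + w * T_v

where D_c is the consonant's own dorsum target and w in [0, 1] is the
coarticulation degree: w = 1 means full vocalic anticipation, w = 0 a
consonant immune to its vowel. Each consonant carries a base weight
w_max (its inverse coarticulatory resistance: alveolar /d/ low, labial
/b/ high), optionally reduced by the child's skill through a link
function -- the generative counterpart of the hypothesis that greater
phonological proficiency lowers coarticulation degree.

Per-speaker anatomy enters as an affine map of the normalized gesture
space into raw scanner coordinates; positional noise is added in
normalized space *before* that map, so ``noise_sd`` means the same
thing for every speaker.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .contours import N_SPLINE_POINTS, TongueSpline
from .scoring import N_ITEMS, SkillScores, scores_to_frame

COHORTS = ("K1", "K2", "P1")
DEFAULT_COHORT_SIZES: Dict[str, int] = {"K1": 10, "K2": 13, "P1": 18}


class DomainError(ValueError):
    """Argument outside the simulator's domain."""


class ConfigurationError(ValueError):
    """Invalid simulator configuration."""


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


def _check_unknown(d: Mapping, cls, name: str) -> None:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown keys in {name}: {sorted(unknown)}")


@dataclass
class ContourParams:
    """Shape of the synthetic tongue contour (a single Gaussian dorsum bump)."""

    bump_height: float = 10.0       # raw y units (mm-like)
    bump_sigma: float = 0.12        # bump width, normalized gesture units
    baseline: float = 0.0           # raw y offset
    y_noise_sd: float = 0.0         # optional additive measurement noise on y

    def __post_init__(self) -> None:
        if self.bump_sigma <= 0 or self.bump_height <= 0 or self.y_noise_sd < 0:
            raise ConfigurationError("contour params must be positive (y_noise_sd >= 0)")


@dataclass
class BehavioralParams:
    """Generative model of the four assessment scores.

    All tasks are driven by the child's latent ability. The two phonemic
    tasks (onset deletion, phoneme synthesis) share one phonemic latent
    factor so their scores correlate strongly across children
    (``target_corr`` documents the intended population correlation, which
    mirrors the strong inter-task correlation such batteries show);
    kindergarten cohorts sit at a phonemic floor, reflecting that
    phoneme-level manipulation emerges with literacy instruction.
    """

    rhyme_easiness: float = 1.8
    phonemic_easiness: float = 0.6
    phonemic_factor_sd: float = 0.8   # sd of the shared phonemic factor around ability
    task_noise_sd: float = 1.0        # task-specific deviation from the shared factor
    target_corr: float = 0.9          # intended corr(onset_deletion, phoneme_synthesis)
    floor_prob: float = 0.01          # per-item success probability at the phonemic floor
    floor_cohorts: Tuple[str, ...] = ("K1", "K2")
    vocab_easiness: float = 1.45
    vocab_slope: float = 0.6
    vocabulary_max: int = 36

    def __post_init__(self) -> None:
        if not (0.0 <= self.floor_prob <= 1.0):
            raise ConfigurationError("floor_prob must lie in [0, 1]")
        if self.vocabulary_max < 1:
            raise ConfigurationError("vocabulary_max must be >= 1")


@dataclass
class GesturalConfig:
    """Ground truth of the gestural-blending simulator.

    Dorsum targets follow the anterior-to-posterior vowel ordering
    /i, y, e, a, o, u/ and give /d/ an anterior target, /g/ a back one,
    and the labial /b/ -- which has no lingual constriction of its own --
    a neutral target with high base weight.
    """

    vowel_targets: Dict[str, float] = field(
        default_factory=lambda: {"i": 0.05, "y": 0.15, "e": 0.30, "a": 0.60, "o": 0.78, "u": 0.95}
    )
    consonant_targets: Dict[str, float] = field(
        default_factory=lambda: {"b": 0.50, "d": 0.20, "g": 0.70}
    )
    base_weights: Dict[str, float] = field(
        default_factory=lambda: {"b": 0.80, "d": 0.35, "g": 0.60}
    )
    skill_effect: float = 0.4        # gamma: maximal proportional reduction of w
    link: str = "none"               # none | linear | sigmoid
    link_midpoint: float = 0.5       # s0 of the sigmoid link
    link_steepness: float = 0.08     # tau of the sigmoid link
    noise_sd: float = 0.05           # positional noise, normalized gesture units
    reps: int = 6
    contour: ContourParams = field(default_factory=ContourParams)
    behavioral: BehavioralParams = field(default_factory=BehavioralParams)
    # per-cohort latent ability ~ Normal(mean, sd)
    cohort_ability: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"K1": (-1.0, 0.5), "K2": (-0.5, 0.5), "P1": (1.0, 0.5)}
    )
    anatomy_offset_range: Tuple[float, float] = (20.0, 40.0)  # raw x units
    anatomy_scale_range: Tuple[float, float] = (25.0, 35.0)   # raw x units, > 0
    skill_source: str = "latent"     # latent | composite_pa

    def __post_init__(self) -> None:
        for name, m in (
            ("vowel_targets", self.vowel_targets),
            ("consonant_targets", self.consonant_targets),
            ("base_weights", self.base_weights),
        ):
            for k, v in m.items():
                if not (0.0 <= float(v) <= 1.0):
                    raise ConfigurationError(f"{name}[{k}]={v} outside [0, 1]")
        if set(self.base_weights) != set(self.consonant_targets):
            raise ConfigurationError("base_weights and consonant_targets must share keys")
        if not (0.0 <= self.skill_effect <= 1.0):
            raise ConfigurationError("skill_effect (gamma) must lie in [0, 1]")
        if self.link not in ("none", "linear", "sigmoid"):
            raise ConfigurationError(f"unknown link {self.link!r}")
        if self.link_steepness <= 0:
            raise ConfigurationError("sigmoid steepness tau must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.reps < 1:
            raise ConfigurationError("reps must be >= 1")
        if self.anatomy_scale_range[0] <= 0:
            raise ConfigurationError("anatomy scale must be > 0")
        if self.skill_source not in ("latent", "composite_pa"):
            raise ConfigurationError(f"unknown skill_source {self.skill_source!r}")

    @property
    def consonants(self) -> Tuple[str, ...]:
        return tuple(self.consonant_targets)

    @property
    def vowels(self) -> Tuple[str, ...]:
        return tuple(self.vowel_targets)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort_ability"] = {k: list(v) for k, v in self.cohort_ability.items()}
        d["anatomy_offset_range"] = list(self.anatomy_offset_range)
        d["anatomy_scale_range"] = list(self.anatomy_scale_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GesturalConfig":
        d = dict(d)
        _check_unknown(d, cls, "GesturalConfig")
        if "contour" in d and isinstance(d["contour"], Mapping):
            _check_unknown(d["contour"], ContourParams, "contour")
            d["contour"] = ContourParams(**d["contour"])
        if "behavioral" in d and isinstance(d["behavioral"], Mapping):
            bd = dict(d["behavioral"])
            _check_unknown(bd, BehavioralParams, "behavioral")
            if "floor_cohorts" in bd:
                bd["floor_cohorts"] = tuple(bd["floor_cohorts"])
            d["behavioral"] = BehavioralParams(**bd)
        if "cohort_ability" in d:
            d["cohort_ability"] = {k: tuple(v) for k, v in d["cohort_ability"].items()}
        for key in ("anatomy_offset_range", "anatomy_scale_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SpeakerProfile:
    speaker_id: str
    cohort: str
    anatomy_offset: float
    anatomy_scale: float
    latent_ability: float

    def __post_init__(self) -> None:
        if self.anatomy_scale <= 0:
            raise ConfigurationError("anatomy_scale must be > 0")
        if self.cohort not in COHORTS:
            raise ConfigurationError(f"unknown cohort {self.cohort!r}")

    @property
    def skill(self) -> float:
        """Latent ability squashed onto [0, 1] for the skill -> w link."""
        return float(_logistic(self.latent_ability))


def coarticulation_weight(consonant: str, skill: float, config: GesturalConfig) -> float:
    """Ground-truth coarticulation degree w for a consonant at a skill level.

    w = w_max * (1 - gamma * g(skill)) clamped to [0, 1], with g the
    configured link: ``none`` g == 0, ``linear`` g(s) = s, ``sigmoid``
    g(s) = 1 / (1 + exp(-(s - s0) / tau)).
    """
    if consonant not in config.base_weights:
        raise DomainError(f"unknown consonant {consonant!r}")
    if not (0.0 <= skill <= 1.0):
        raise DomainError(f"skill {skill} outside [0, 1]")
    if config.link == "none":
        g = 0.0
    elif config.link == "linear":
        g = skill
    else:
        g = float(_logistic((skill - config.link_midpoint) / config.link_steepness))
    w = config.base_weights[consonant] * (1.0 - config.skill_effect * g)
    return float(min(1.0, max(0.0, w)))


def make_contour(
    speaker: SpeakerProfile,
    dorsum_pos: float,
    config: GesturalConfig,
    rng: np.random.Generator,
    token_id: str = "",
    segment: str = "",
) -> TongueSpline:
    """Generate one 100-point contour with a Gaussian bump at ``dorsum_pos``.

    The bump center receives additive positional noise (sd ``noise_sd``)
    in normalized gesture space and is then mapped through the speaker's
    anatomy transform; x is sampled on a uniform 100-point grid over the
    speaker's raw extent. With ``noise_sd = 0`` the y-maximum sits at the
    grid point nearest the requested position.
    """
    if not (0.0 <= dorsum_pos <= 1.0):
        raise DomainError(f"dorsum_pos {dorsum_pos} outside [0, 1]")
    center = dorsum_pos
    if config.noise_sd > 0:
        center = float(np.clip(center + rng.normal(0.0, config.noise_sd), 0.0, 1.0))
    grid = np.linspace(0.0, 1.0, N_SPLINE_POINTS)
    cp = config.contour
    y = cp.baseline + cp.bump_height * np.exp(-((grid - center) ** 2) / (2.0 * cp.bump_sigma**2))
    if cp.y_noise_sd > 0:
        y = y + rng.normal(0.0, cp.y_noise_sd, size=N_SPLINE_POINTS)
    x = speaker.anatomy_offset + speaker.anatomy_scale * grid
    return TongueSpline(speaker.speaker_id, token_id, segment, np.column_stack([x, y]))


def simulate_scores(
    speaker: SpeakerProfile, config: GesturalConfig, rng: np.random.Generator
) -> SkillScores:
    """Draw the four behavioral scores for one child.

    Rhyme: 12 Bernoulli items at p = logistic(ability + easiness).
    Onset deletion / phoneme synthesis: 12 items each at probabilities
    derived from one shared phonemic factor (plus small task-specific
    deviations), overridden by the floor probability in kindergarten
    cohorts. Vocabulary: binomial count increasing in ability.
    """
    if not np.isfinite(speaker.latent_ability):
        raise DomainError("latent_ability must be finite")
    b = config.behavioral
    p_rhyme = _logistic(speaker.latent_ability + b.rhyme_easiness)
    rhyme = int(rng.binomial(N_ITEMS, p_rhyme))

    phonemic_factor = speaker.latent_ability + rng.normal(0.0, b.phonemic_factor_sd)
    task_scores = []
    for _task in ("onset_deletion", "phoneme_synthesis"):
        p = _logistic(phonemic_factor + b.phonemic_easiness + rng.normal(0.0, b.task_noise_sd))
        if speaker.cohort in b.floor_cohorts:
            p = b.floor_prob
        task_scores.append(int(rng.binomial(N_ITEMS, p)))

    p_voc = _logistic(b.vocab_easiness + b.vocab_slope * speaker.latent_ability)
    vocabulary = int(rng.binomial(b.vocabulary_max, p_voc))
    return SkillScores(
        speaker_id=speaker.speaker_id,
        cohort=speaker.cohort,
        rhyme=rhyme,
        onset_deletion=task_scores[0],
        phoneme_synthesis=task_scores[1],
        vocabulary=vocabulary,
        vocabulary_max=b.vocabulary_max,
    )


@dataclass
class SimulatedDataset:
    """A complete simulated study: speakers, contours, scores, and the truth."""

    speakers: list  # of SpeakerProfile
    contours: pd.DataFrame  # long: speaker_id, cohort, token_id, consonant, vowel, rep, segment, point_index, x, y
    tokens: pd.DataFrame    # token_id, speaker_id, cohort, consonant, vowel, rep
    scores: pd.DataFrame    # one row per speaker
    truth: dict             # config + realized per-speaker skill and w

    def iter_splines(self):
        """Yield the contours as :class:`TongueSpline` objects."""
        for (tok, seg), grp in self.contours.groupby(["token_id", "segment"], sort=False):
            g = grp.sort_values("point_index")
            yield TongueSpline(
                g["speaker_id"].iloc[0], tok, seg,
                np.column_stack([g["x"].to_numpy(), g["y"].to_numpy()]),
            )

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.contours.to_csv(out / "contours.csv", index=False)
        self.tokens.to_csv(out / "tokens.csv", index=False)
        self.scores.to_csv(out / "scores.csv", index=False)
        speakers = [dataclasses.asdict(s) for s in self.speakers]
        with open(out / "truth.json", "w") as fh:
            json.dump({"speakers": speakers, **self.truth}, fh, indent=1, sort_keys=True)

    @classmethod
    def read(cls, in_dir) -> "SimulatedDataset":
        d = Path(in_dir)
        with open(d / "truth.json") as fh:
            truth = json.load(fh)
        speakers = [SpeakerProfile(**s) for s in truth.pop("speakers")]
        return cls(
            speakers=speakers,
            contours=pd.read_csv(d / "contours.csv"),
            tokens=pd.read_csv(d / "tokens.csv"),
            scores=pd.read_csv(d / "scores.csv"),
            truth=truth,
        )


def _speaker_rng(seed: int, cohort_index: int, within_index: int) -> np.random.Generator:
    # keyed substreams: a speaker's data does not depend on other cohort sizes
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(cohort_index, within_index))
    )


def simulate_cohort(
    config: Optional[GesturalConfig] = None,
    cohort_sizes: Optional[Mapping[str, int]] = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Simulate the full cross-sectional dataset.

    Every speaker contributes len(consonants) x len(vowels) x reps tokens,
    each with a C1 and a V contour. The dataset is a deterministic
    function of (config, cohort_sizes, seed).
    """
    config = config if config is not None else GesturalConfig()
    sizes = dict(cohort_sizes) if cohort_sizes is not None else dict(DEFAULT_COHORT_SIZES)
    if not sizes:
        raise ConfigurationError("cohort_sizes must not be empty")
    for c, n in sizes.items():
        if c not in COHORTS:
            raise ConfigurationError(f"unknown cohort {c!r}")
        if n < 1:
            raise ConfigurationError(f"cohort {c} size must be >= 1")

    speakers, all_scores, token_rows, contour_blocks = [], [], [], []
    realized = []
    grid = np.linspace(0.0, 1.0, N_SPLINE_POINTS)
    for ci, cohort in enumerate(c for c in COHORTS if c in sizes):
        mean, sd = config.cohort_ability[cohort]
        for si in range(sizes[cohort]):
            rng = _speaker_rng(seed, ci, si)
            profile = SpeakerProfile(
                speaker_id=f"{cohort}_{si + 1:02d}",
                cohort=cohort,
                anatomy_offset=float(rng.uniform(*config.anatomy_offset_range)),
                anatomy_scale=float(rng.uniform(*config.anatomy_scale_range)),
                latent_ability=float(rng.normal(mean, sd)),
            )
            speakers.append(profile)
            scores = simulate_scores(profile, config, rng)
            all_scores.append(scores)
            if config.skill_source == "composite_pa":
                comp = scores.composite_pa
                skill = 0.0 if comp is None else comp / 24.0
            else:
                skill = profile.skill
            weights = {
                c: coarticulation_weight(c, skill, config) for c in config.consonants
            }
            realized.append(
                {"speaker_id": profile.speaker_id, "skill": skill, "weights": weights}
            )
            for consonant in config.consonants:
                w = weights[consonant]
                d_c = config.consonant_targets[consonant]
                for vowel in config.vowels:
                    t_v = config.vowel_targets[vowel]
                    c_pos = (1.0 - w) * d_c + w * t_v
                    for rep in range(1, config.reps + 1):
                        token_id = f"{profile.speaker_id}_{consonant}{vowel}_{rep}"
                        token_rows.append(
                            {
                                "token_id": token_id,
                                "speaker_id": profile.speaker_id,
                                "cohort": cohort,
                                "consonant": consonant,
                                "vowel": vowel,
                                "rep": rep,
                            }
                        )
                        for segment, pos in (("C1", c_pos), ("V", t_v)):
                            sp = make_contour(
                                profile, pos, config, rng,
                                token_id=token_id, segment=segment,
                            )
                            contour_blocks.append(
                                (profile.speaker_id, cohort, token_id, consonant,
                                 vowel, rep, segment, sp.x, sp.y)
                            )

    n_pts = N_SPLINE_POINTS
    contours = pd.DataFrame(
        {
            "speaker_id": np.repeat([b[0] for b in contour_blocks], n_pts),
            "cohort": np.repeat([b[1] for b in contour_blocks], n_pts),
            "token_id": np.repeat([b[2] for b in contour_blocks], n_pts),
            "consonant": np.repeat([b[3] for b in contour_blocks], n_pts),
            "vowel": np.repeat([b[4] for b in contour_blocks], n_pts),
            "rep": np.repeat([b[5] for b in contour_blocks], n_pts),
            "segment": np.repeat([b[6] for b in contour_blocks], n_pts),
            "point_index": np.tile(np.arange(n_pts), len(contour_blocks)),
            "x": np.concatenate([b[7] for b in contour_blocks]),
            "y": np.concatenate([b[8] for b in contour_blocks]),
        }
    )
    truth = {
        "seed": int(seed),
        "cohort_sizes": sizes,
        "config": config.to_dict(),
        "realized": realized,
    }
    return SimulatedDataset(
        speakers=speakers,
        contours=contours,
        tokens=pd.DataFrame(token_rows),
        scores=scores_to_frame(all_scores),
        truth=truth,
    )


def sample_scores_population(
    config: Optional[GesturalConfig] = None, n: int = 2000, seed: int = 0
) -> pd.DataFrame:
    """Draw behavioral scores for ``n`` children from the default cohort mix.

    Cohort membership is sampled with probabilities proportional to the
    default cohort sizes; used for Monte-Carlo checks of the score model
    (e.g. the inter-task correlation of the two phonemic tasks).
    """
    config = config if config is not None else GesturalConfig()
    rng = np.random.default_rng(seed)
    names = list(DEFAULT_COHORT_SIZES)
    probs = np.array([DEFAULT_COHORT_SIZES[c] for c in names], dtype=float)
    probs /= probs.sum()
    out = []
    for i in range(n):
        cohort = names[rng.choice(len(names), p=probs)]
        mean, sd = config.cohort_ability[cohort]
        profile = SpeakerProfile(
            speaker_id=f"sim_{i}",
            cohort=cohort,
            anatomy_offset=30.0,
            anatomy_scale=30.0,
            latent_ability=float(rng.normal(mean, sd)),
        )
        out.append(simulate_scores(profile, config, rng))
    return scores_to_frame(out)
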