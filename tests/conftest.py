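import numpy as np
import pandas as pd
import pytest

from coartic import GesturalConfig, build_analysis_table, simulate_cohort

SMALL_SIZES = {"K1": 3, "K2": 3, "P1": 4}


@pytest.fixture(scope="session")
def small_config():
    """Reduced repetitions keep unit-test simulations fast."""
    return GesturalConfig(reps=2)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_cohort(small_config, SMALL_SIZES, seed=11)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    return build_analysis_table(small_dataset.contours, small_dataset.tokens)


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size study (41 speakers, 3x6x6 tokens each), default config."""
    return simulate_cohort(seed=1)


@pytest.fixture(scope="session")
def default_table(default_dataset):
    return build_analysis_table(default_dataset.contours, default_dataset.tokens)


def exact_blend_table(
    config: GesturalConfig = None,
    cohort_speakers=(("K1", 2), ("K2", 2), ("P1", 2)),
    reps: int = 2,
    slope_shift_by_cohort=None,
) -> pd.DataFrame:
    """Noise-free analysis table built directly from the gestural blend.

    Bypasses the contour layer (and hence its grid quantization): peak
    positions are the exact blend (1 - w) * D_c + w * T_v, normalized by
    the vowel-target range. Optionally adds a per-cohort extra slope
    (centered at vowel position 0.5) to inject a known cohort effect.
    """
    cfg = config if config is not None else GesturalConfig()
    vmin = min(cfg.vowel_targets.values())
    vmax = max(cfg.vowel_targets.values())
    norm = lambda z: (z - vmin) / (vmax - vmin)
    shift = dict(slope_shift_by_cohort or {})
    rows = []
    for cohort, nspk in cohort_speakers:
        for i in range(nspk):
            for c in cfg.consonants:
                w = cfg.base_weights[c]
                for v in cfg.vowels:
                    tv = cfg.vowel_targets[v]
                    cx = (1 - w) * cfg.consonant_targets[c] + w * tv
                    pv, pc = norm(tv), norm(cx)
                    pc = pc + shift.get(cohort, 0.0) * (pv - 0.5)
                    for rep in range(1, reps + 1):
                        rows.append(
                            {
                                "speaker_id": f"{cohort}_{i}",
                                "cohort": cohort,
                                "consonant": c,
                                "vowel": v,
                                "rep": rep,
                                "word_id": c + v,
                                "peak_v_x": pv,
                                "peak_c_x": pc,
                            }
                        )
    return pd.DataFrame(rows)
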