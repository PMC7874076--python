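"""Cohort-level workflows chaining the generator and the analysis stages."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import inference, prosody
from .coherence import CohortCoherence, compare_conditions
from .synthdyad import (
    CONDITION_SPEECH_DEFAULTS,
    SpeechGroundTruth,
    generate_speech,
    generate_turn_schedule,
)

__all__ = ["speech_cohort_measures", "coherence_screen"]


def speech_cohort_measures(
    n_dyads: int = 18,
    sample_rate: int = 8000,
    seed: int = 0,
    run_duration: float = 180.0,
    turn_duration: float = 15.0,
    truths: dict[str, SpeechGroundTruth] | None = None,
) -> pd.DataFrame:
    """Turn measures for a full audio cohort, z-scored within speaker.

    Every dyad debates once per condition; speaker sexes cycle through
    mixed/female/male pairings.  Audio is synthesized per turn, measured, and
    discarded, so memory stays flat.
    """
    truths = truths or CONDITION_SPEECH_DEFAULTS
    root = np.random.default_rng(seed)
    sexes = [("F", "M"), ("M", "F"), ("F", "F"), ("M", "M")]
    frames = []
    for d in range(n_dyads):
        s1, s2 = f"d{d:02d}s1", f"d{d:02d}s2"
        schedule = generate_turn_schedule(run_duration, turn_duration, s1, s2)
        sex_map = dict(zip((s1, s2), sexes[d % len(sexes)]))
        for condition, truth in truths.items():
            audio = generate_speech(
                schedule,
                truth,
                sample_rate=sample_rate,
                speaker_sex=sex_map,
                seed=int(root.integers(0, 2**31 - 1)),
            )
            frames.append(
                prosody.turn_measures(
                    audio,
                    schedule,
                    condition,
                    dyad_id=f"d{d:02d}",
                    debate_id=f"d{d:02d}-{condition}",
                    speaker_sex=sex_map,
                )
            )
    table = pd.concat(frames, ignore_index=True)
    return inference.zscore_by_speaker(table)


def coherence_screen(
    cohort: CohortCoherence,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Condition comparison for every unordered ROI pair of a cohort.

    Returns one row per pair with per-bin t/p and the consecutive-bin
    decision.
    """
    rows = []
    for rp in itertools.combinations_with_replacement(cohort.rois, 2):
        spectra = cohort.condition_spectra(rp)
        cmp_ = compare_conditions(spectra["agree"], spectra["disagree"], alpha=alpha)
        rows.append(
            {
                "roi_a": rp[0],
                "roi_b": rp[1],
                "mean_diff_bin1": cmp_.mean_diff[0],
                "mean_diff_bin2": cmp_.mean_diff[1],
                "mean_diff_bin3": cmp_.mean_diff[2],
                "p_bin1": cmp_.p[0],
                "p_bin2": cmp_.p[1],
                "p_bin3": cmp_.p[2],
                "decision": cmp_.decision,
            }
        )
    return pd.DataFrame(rows)
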