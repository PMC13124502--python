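"""Normative ratings of the 18 VR stimulus clips.

Pre-study panel ratings (nine-point Self-Assessment Manikin scale) for the
six positive, six neutral and six negative immersive video clips used as
emotion-elicitation stimuli. Valence runs from 1 (very unpleasant) to
9 (very pleasant), arousal from 1 (very calm) to 9 (very excited).

The table drives two things:

* :func:`emofuse.screening.categorize_video` — the selection thresholds
  (positive: valence > 7 and arousal > 6; negative: valence < 3 and
  arousal > 6; neutral: valence in [4, 6] and arousal < 4) can be checked
  against each clip's assigned category.
* default SAM-rating profiles of the synthetic generator, which pool the
  per-category means and standard deviations of this table.
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = ["video_norms", "pooled_sam_profile"]

# (video id, category, valence mean, valence sd, arousal mean, arousal sd)
_VIDEO_NORMS = [
    ("V01", "positive", 7.8, 0.6, 7.2, 0.8),
    ("V02", "positive", 8.1, 0.5, 6.5, 0.7),
    ("V03", "positive", 7.5, 0.7, 6.8, 0.9),
    ("V04", "positive", 7.9, 0.6, 7.5, 0.7),
    ("V05", "positive", 7.6, 0.8, 7.0, 0.8),
    ("V06", "positive", 7.7, 0.6, 6.2, 0.8),
    ("V07", "neutral", 5.1, 0.4, 3.2, 0.5),
    ("V08", "neutral", 5.3, 0.5, 3.5, 0.6),
    ("V09", "neutral", 5.0, 0.4, 3.1, 0.5),
    ("V10", "neutral", 4.9, 0.5, 2.8, 0.5),
    ("V11", "neutral", 5.4, 0.5, 3.3, 0.6),
    ("V12", "neutral", 5.2, 0.4, 3.4, 0.5),
    ("V13", "negative", 2.5, 0.5, 7.8, 0.7),
    ("V14", "negative", 2.3, 0.4, 7.5, 0.8),
    ("V15", "negative", 2.8, 0.6, 7.0, 0.8),
    ("V16", "negative", 2.1, 0.4, 8.0, 0.7),
    ("V17", "negative", 2.4, 0.5, 7.6, 0.8),
    ("V18", "negative", 2.6, 0.5, 7.4, 0.7),
]


def video_norms() -> pd.DataFrame:
    """Return the stimulus norm table, one row per clip."""
    return pd.DataFrame(
        _VIDEO_NORMS,
        columns=[
            "video_id",
            "category",
            "valence_mean",
            "valence_sd",
            "arousal_mean",
            "arousal_sd",
        ],
    )


def pooled_sam_profile(category: str) -> dict[str, float]:
    """Pool the norm table into per-category SAM rating parameters.

    Means are averaged across the six clips of the category; standard
    deviations are pooled as the root mean square of the per-clip SDs
    (within-clip spread only; between-clip mean differences are treated
    as part of the stimulus design, not rater noise).
    """
    rows = [r for r in _VIDEO_NORMS if r[1] == category]
    if not rows:
        raise ValueError(f"unknown stimulus category: {category!r}")
    n = len(rows)
    return {
        "valence_mean": sum(r[2] for r in rows) / n,
        "valence_sd": math.sqrt(sum(r[3] ** 2 for r in rows) / n),
        "arousal_mean": sum(r[4] for r in rows) / n,
        "arousal_sd": math.sqrt(sum(r[5] ** 2 for r in rows) / n),
    }
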