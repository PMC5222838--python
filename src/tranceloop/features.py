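"""Per-stimulus feature tables joining the continuous and categorical
complexity measures: cyclic information content, average Cloud Momentum,
and the three repetition variables of the underlying pattern."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .generation import GeneratedStimulus
from .patterns import repetition_features
from .spiral import SpiralConfig, average_cloud_momentum

__all__ = ["stimulus_features", "write_features", "read_features"]


def stimulus_features(
    stimuli: Sequence[GeneratedStimulus],
    spiral_cfg: SpiralConfig = SpiralConfig(),
) -> pd.DataFrame:
    """One row per stimulus: id, pattern, start chord, the 8 chord tokens,
    cyclic IC (bits/chord), average Cloud Momentum, and the categorical
    repetition features."""
    rows = []
    for i, s in enumerate(stimuli):
        feats = repetition_features(s.pattern)
        rows.append(
            {
                "stimulus_id": f"S{i + 1:03d}",
                "pattern": s.pattern.text(),
                "start_chord": s.start_chord.token(),
                "chords": " ".join(c.token() for c in s.chords),
                "cyclic_ic": s.cyclic_ic,
                "cloud_momentum": average_cloud_momentum(s.chords, spiral_cfg),
                "first_half_structure": feats.first_half_structure.value,
                "second_half_unique": feats.second_half_unique,
                "structural_overlap_count": feats.structural_overlap_count,
                "structural_overlap_level": feats.structural_overlap_level.value,
            }
        )
    return pd.DataFrame(rows)


def write_features(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
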