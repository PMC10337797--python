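"""CSV and config I/O for the rating pipeline.

The on-disk dialect is deliberately plain: UTF-8 comma-separated text with
a header row ``participant,block,stimulus,repetition,rating``, one record
per row, integer ratings.  Curve output mirrors
``n_stimuli,source_entropy_bits,mi_mean_bits,mi_sd_bits,n_participants``.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .infotheory import ValidationError
from .pipeline import (
    CapacityEstimate,
    MICurvePoint,
    RatingDataset,
    REQUIRED_COLUMNS,
    curve_to_frame,
)

__all__ = [
    "read_ratings_csv",
    "write_ratings_csv",
    "write_curve_csv",
    "read_curve_csv",
    "write_report",
    "load_config",
]


def read_ratings_csv(
    path, scale_min: int = 1, scale_max: int = 10,
    repetitions: int | None = None,
) -> RatingDataset:
    """Load and validate a long-format ratings CSV."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {','.join(REQUIRED_COLUMNS)}"
        )
    return RatingDataset(df[list(df.columns)], scale_min, scale_max,
                         repetitions)


def write_ratings_csv(dataset: RatingDataset, path) -> None:
    cols = [c for c in dataset.frame.columns]
    dataset.frame.to_csv(path, index=False, columns=cols)


def write_curve_csv(curve: Sequence[MICurvePoint], path) -> None:
    curve_to_frame(curve).to_csv(path, index=False)


def read_curve_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_report(
    path,
    capacity: CapacityEstimate,
    curve: Sequence[MICurvePoint],
    settings: dict | None = None,
) -> None:
    """JSON report: capacity estimate, fit diagnostics and the curve."""
    payload = {
        "capacity": asdict(capacity),
        "curve": [asdict(pt) for pt in curve],
        "settings": settings or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_config(path) -> dict:
    """Key-value config (YAML, which also accepts plain JSON).

    Recognized keys: scale_min, scale_max, repetitions, rounding
    ('half-even' | 'half-up'), mode ('plugin' | 'loo'), pooled (bool),
    include_origin (bool), seed, and the generator keys block_sizes,
    anchors, participants, sigma, participant_offset_sd.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a key-value mapping")
    return cfg
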