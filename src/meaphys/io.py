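"""CSV dialects used by the pipeline.

All times are seconds, 0-based from session start.  Schemas:

* ``spikes.csv``   — unit_id, spike_time_s
* ``events.csv``   — stimulus, onset_s, rep_index [, epoch]
* ``epochs.csv``   — label, start_s, end_s
* ``behavior.csv`` — animal_id, group, phase, zone_or_odor, duration_s
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

SCHEMAS: dict[str, list[str]] = {
    "spikes": ["unit_id", "spike_time_s"],
    "events": ["stimulus", "onset_s", "rep_index"],
    "epochs": ["label", "start_s", "end_s"],
    "behavior": ["animal_id", "group", "phase", "zone_or_odor", "duration_s"],
    "trajectory": ["t_s", "x_cm", "y_cm"],
}


class SchemaError(ValueError):
    """Raised when a CSV is missing required columns."""


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read one of the pipeline CSVs, validating its schema."""
    required = SCHEMAS[kind]
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - passthrough
        raise SchemaError(f"{path}: malformed CSV ({exc})") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing} for {kind!r} table"
        )
    return frame


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a pipeline table deterministically (no index, fixed float
    formatting)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.10g")
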