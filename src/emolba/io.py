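"""Trial-table I/O with row-level validation.

The canonical on-disk format is a long-format CSV, one row per trial. RTs
are stored in seconds throughout; every threshold in the pipeline is in
seconds too.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

REQUIRED_COLUMNS = (
    "participant_id",
    "block",
    "trial_index",
    "cue",
    "picture_id",
    "picture_norm",
    "report",
    "rt_s",
)

OPTIONAL_COLUMNS = (
    "censored",
    "search_target",
    "search_response",
    "search_rt_s",
)

_VOCAB = {
    "cue": {"color", "shape", "conjunction"},
    "report": {"pleasant", "unpleasant"},
    "search_target": {"present", "absent"},
    "search_response": {"present", "absent"},
}


class ValidationError(ValueError):
    """Schema violation; ``rows`` carries per-row messages."""

    def __init__(self, messages: list[str]):
        super().__init__(
            "trial table failed validation:\n  " + "\n  ".join(messages[:20])
            + ("" if len(messages) <= 20 else f"\n  ... {len(messages) - 20} more")
        )
        self.rows = messages


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table; returns it typed, or raises ValidationError."""
    problems: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise ValidationError([f"missing required columns: {missing}"])

    trials = trials.copy()
    trials["picture_norm"] = pd.to_numeric(trials["picture_norm"], errors="coerce")
    trials["rt_s"] = pd.to_numeric(trials["rt_s"], errors="coerce")

    for col, vocab in _VOCAB.items():
        if col not in trials.columns:
            continue
        bad = ~trials[col].isin(vocab)
        for row in trials.index[bad]:
            problems.append(f"row {row}: {col}={trials.at[row, col]!r} not in {sorted(vocab)}")

    bad_rt = ~(trials["rt_s"] > 0)
    for row in trials.index[bad_rt]:
        problems.append(f"row {row}: rt_s={trials.at[row, 'rt_s']!r} must be positive")

    bad_norm = ~trials["picture_norm"].between(1, 9)
    for row in trials.index[bad_norm]:
        problems.append(
            f"row {row}: picture_norm={trials.at[row, 'picture_norm']!r} outside [1, 9]"
        )

    if problems:
        raise ValidationError(problems)
    return trials


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV (extra columns preserved)."""
    return validate_trials(pd.read_csv(Path(path)))


def write_trials(trials: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, index=False)
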