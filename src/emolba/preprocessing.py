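"""Preregistered four-step exclusion pipeline with per-step audit counts.

Steps, applied strictly in this order:

1. drop participants whose aberrant-response proportion exceeds 50%
   (strictly; exactly 50% is retained);
2. drop pictures whose across-participant normative-response rate falls
   below 50% (strictly; exactly 50% is retained);
3. drop trials with RT >= 6.1 s or RT <= 200 ms (both inclusive);
4. within each participant x pleasantness x difficulty cell, drop trials
   with |z(RT)| > 3.5 (strictly), z computed from that cell's own moments.

Step 4's grouping is per participant and per combination of the two design
factors: grouping by literal picture would leave one trial per group. Cells
with fewer than two trials, or with zero RT variance, are skipped and
logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import code_response, cue_to_difficulty, norm_to_pleasantness

RT_SLOW_CUTOFF_S = 6.1
RT_FAST_CUTOFF_S = 0.200
Z_CUTOFF = 3.5
MAX_ABERRANT_PROP = 0.5
MIN_NORMATIVE_RATE = 0.5


class EmptyDataError(RuntimeError):
    """All trials were excluded; the attached report explains where."""

    def __init__(self, report: "PreprocessReport"):
        super().__init__("preprocessing removed every trial\n" + report.pretty())
        self.report = report


@dataclass
class PreprocessReport:
    """Ordered audit log of the exclusion pipeline."""

    steps: list[dict] = field(default_factory=list)
    n_input: int = 0
    n_output: int = 0
    notes: list[str] = field(default_factory=list)

    def add_step(self, name: str, n_before: int, n_excluded: int, **extra) -> None:
        pct = 100.0 * n_excluded / n_before if n_before else 0.0
        self.steps.append(
            {
                "step": name,
                "trials_before": int(n_before),
                "trials_excluded": int(n_excluded),
                "percent_of_remaining": round(pct, 4),
                **extra,
            }
        )

    def counts(self) -> dict[str, int]:
        return {s["step"]: s["trials_excluded"] for s in self.steps}

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "steps": self.steps,
            "notes": self.notes,
        }

    def pretty(self) -> str:
        lines = [f"input trials: {self.n_input}"]
        for s in self.steps:
            lines.append(
                f"  {s['step']}: excluded {s['trials_excluded']} trials "
                f"({s['percent_of_remaining']:.2f}% of {s['trials_before']} remaining)"
            )
        lines.append(f"output trials: {self.n_output}")
        return "\n".join(lines)


def ensure_coding(trials: pd.DataFrame) -> pd.DataFrame:
    """Attach response/pleasantness/difficulty codings derived from the raw columns."""
    out = trials.copy()
    if "response" not in out.columns:
        out["response"] = [
            code_response(n, r) for n, r in zip(out["picture_norm"], out["report"])
        ]
    if "pleasantness" not in out.columns:
        out["pleasantness"] = [norm_to_pleasantness(n) for n in out["picture_norm"]]
    if "difficulty" not in out.columns:
        out["difficulty"] = [cue_to_difficulty(c) for c in out["cue"]]
    return out


def filter_participants(trials: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Step 1: remove participants responding aberrantly on >50% of trials."""
    aberr = trials.groupby("participant_id")["response"].apply(
        lambda s: np.mean(s == "aberrant")
    )
    bad = sorted(aberr.index[aberr > MAX_ABERRANT_PROP])
    kept = trials[~trials["participant_id"].isin(bad)]
    return kept, bad


def filter_pictures(trials: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Step 2: remove pictures whose normative-response rate fell below 50%."""
    norm_rate = trials.groupby("picture_id")["response"].apply(
        lambda s: np.mean(s == "normative")
    )
    bad = sorted(norm_rate.index[norm_rate < MIN_NORMATIVE_RATE])
    kept = trials[~trials["picture_id"].isin(bad)]
    return kept, bad


def filter_rt_window(trials: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Step 3: remove RT outliers outside (200 ms, 6.1 s), both cutoffs inclusive."""
    bad = (trials["rt_s"] >= RT_SLOW_CUTOFF_S) | (trials["rt_s"] <= RT_FAST_CUTOFF_S)
    return trials[~bad], int(bad.sum())


def filter_zscore(
    trials: pd.DataFrame, z_cutoff: float = Z_CUTOFF
) -> tuple[pd.DataFrame, int, list[str]]:
    """Step 4: remove |z(RT)| > cutoff within participant x pleasantness x difficulty."""
    skipped: list[str] = []
    keep = np.ones(len(trials), dtype=bool)
    rts = trials["rt_s"].to_numpy()
    groups = trials.groupby(["participant_id", "pleasantness", "difficulty"]).indices
    for key, idx in groups.items():
        if len(idx) < 2:
            skipped.append(f"cell {key}: fewer than 2 trials, skipped")
            continue
        cell = rts[idx]
        sd = cell.std(ddof=1)
        if sd == 0:
            skipped.append(f"cell {key}: zero RT variance, skipped")
            continue
        z = (cell - cell.mean()) / sd
        keep[idx[np.abs(z) > z_cutoff]] = False
    n_excluded = int((~keep).sum())
    return trials[keep], n_excluded, skipped


def preprocess(
    trials: pd.DataFrame, config: dict | None = None
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Run steps 1-4 in order and return the surviving trials plus the audit report."""
    report = PreprocessReport(n_input=len(trials))
    trials = ensure_coding(trials)

    n = len(trials)
    trials, bad_participants = filter_participants(trials)
    report.add_step(
        "participants_gt50pct_aberrant",
        n,
        n - len(trials),
        excluded_participants=list(map(str, bad_participants)),
        n_participants_excluded=len(bad_participants),
    )

    n = len(trials)
    trials, bad_pictures = filter_pictures(trials)
    report.add_step(
        "pictures_lt50pct_normative",
        n,
        n - len(trials),
        excluded_pictures=list(map(str, bad_pictures)),
        n_pictures_excluded=len(bad_pictures),
    )

    n = len(trials)
    trials, n_rt = filter_rt_window(trials)
    report.add_step("rt_window_200ms_6.1s", n, n_rt)

    n = len(trials)
    z_cutoff = (config or {}).get("z_cutoff", Z_CUTOFF)
    trials, n_z, skipped = filter_zscore(trials, z_cutoff)
    report.add_step("zscore_gt3.5_per_cell", n, n_z)
    report.notes.extend(skipped)

    report.n_output = len(trials)
    if report.n_output == 0:
        raise EmptyDataError(report)
    return trials.reset_index(drop=True), report
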