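"""Synthetic experiments with the statistical structure the analysis assumes.

:func:`gen_dataset` emulates the experimental design: a 2 (picture
pleasantness) x 2 (anticipated search difficulty) within-subject layout
delivered in identically structured blocks of 60 trials (30 pleasant / 30
unpleasant pictures; the three search cues 20/20/20, crossed with valence
10 per combination), with picture valence norms drawn uniformly from
[2, 4] (negative) and [5.5, 6.5] (positive) and each picture shown once
per participant. Emotion responses are generated from the hierarchical
two-accumulator LBA: subject-level parameters are truncated-Normal draws
around configurable population locations, and per-trial choice/RT come
from the race simulator. Default generating drift rates are the reported
cell means (normative: unpleasant-easy 2.942, unpleasant-difficult 3.172,
pleasant-easy 2.239, pleasant-difficult 2.148; aberrant: pleasant 0.742,
unpleasant 0.017) with A = 2, B = 2, t0 = 0.3 and population scale 0.2.

:func:`inject_contaminants` adds bookkept contaminants that trigger each
preprocessing filter; :func:`make_preprocess_fixture` builds a bounded-RT
table on which the injected counts are exactly recoverable.
:func:`gen_search_data` adds manipulation-check visual-search columns.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import CELLS, report_for_choice
from .lba import simulate_trials

#: generating population locations for the core model (drift cell means are
#: the reported estimates; A, B, t0 are the estimation-default central values)
DEFAULT_TRUTH_LOC: dict[str, float] = {
    "A": 2.0,
    "t0": 0.3,
    **{f"B[{p},{d}]": 2.0 for p, d in CELLS},
    "mean_v.normative[unpleasant,easy]": 2.942,
    "mean_v.normative[unpleasant,difficult]": 3.172,
    "mean_v.normative[pleasant,easy]": 2.239,
    "mean_v.normative[pleasant,difficult]": 2.148,
    "mean_v.aberrant[unpleasant,easy]": 0.017,
    "mean_v.aberrant[unpleasant,difficult]": 0.017,
    "mean_v.aberrant[pleasant,easy]": 0.742,
    "mean_v.aberrant[pleasant,difficult]": 0.742,
}

DEFAULT_POPULATION_SCALE = 0.2

#: generating locations for null-structured data (no cell effects; subjects
#: share one B and one drift pair across all four cells)
DEFAULT_NULL_TRUTH_LOC: dict[str, float] = {
    "A": 2.0,
    "B": 2.0,
    "t0": 0.3,
    "mean_v.normative": 2.0,
    "mean_v.aberrant": 0.5,
}

#: manipulation-check generating values (seconds / error proportions)
SEARCH_RT_MEAN_S = {"color": 1.131, "shape": 1.449, "conjunction": 1.832}
SEARCH_ERROR_RATE = {"color": 0.137, "shape": 0.135, "conjunction": 0.139}
SEARCH_RT_CV = 0.35  # lognormal SD as a fraction of the mean

_CUES = ("color", "shape", "conjunction")


@dataclass(frozen=True)
class GeneratorConfig:
    n_participants: int = 64
    blocks: int = 4
    trials_per_block: int = 60
    negative_norm_range: tuple[float, float] = (2.0, 4.0)
    positive_norm_range: tuple[float, float] = (5.5, 6.5)
    population_loc: dict = field(default_factory=lambda: dict(DEFAULT_TRUTH_LOC))
    population_scale: float = DEFAULT_POPULATION_SCALE
    drift_convention: str = "truncated"
    model: str = "core"  # parameter structure of the generating truth:
    # "core" draws cell-split B and drifts, "null" shares them across cells

    def __post_init__(self):
        if self.trials_per_block % 12 != 0:
            raise ValueError(
                "trials_per_block must be divisible by 12 "
                "(2 valences x 3 cues, balanced)"
            )
        if self.model == "null" and self.population_loc == DEFAULT_TRUTH_LOC:
            object.__setattr__(
                self, "population_loc", dict(DEFAULT_NULL_TRUTH_LOC)
            )
        from .design import get_model

        names = get_model(self.model).param_names
        missing = [n for n in names if n not in self.population_loc]
        if missing:
            raise ValueError(
                f"population_loc is missing {missing} for model {self.model!r}"
            )


@dataclass
class GeneratingTruth:
    """The parameters actually used, persisted alongside the data."""

    population_loc: dict[str, float]
    population_scale: dict[str, float]
    subject_params: pd.DataFrame  # participants x core-model parameters
    config: dict

    def cell_drift(self, kind: str, pleasantness: str, difficulty: str) -> float:
        return self.population_loc[f"mean_v.{kind}[{pleasantness},{difficulty}]"]

    def to_json(self) -> str:
        return json.dumps(
            {
                "population_loc": self.population_loc,
                "population_scale": self.population_scale,
                "subject_params": self.subject_params.to_dict(orient="index"),
                "config": self.config,
            },
            indent=2,
            default=str,
        )


def _block_design(config: GeneratorConfig, rng) -> pd.DataFrame:
    """Balanced block x cue x valence skeleton with picture slots.

    Each picture is seen once per participant, so the picture pool size
    equals the number of trials; valence is balanced within blocks and each
    cue precedes equally many pleasant and unpleasant pictures (the
    counterbalancing constraints).
    """
    n_trials = config.blocks * config.trials_per_block
    per_combo = config.trials_per_block // 6  # cue x valence per block
    rows = []
    for block in range(1, config.blocks + 1):
        combos = [
            (cue, val) for cue in _CUES for val in ("unpleasant", "pleasant")
        ] * per_combo
        rng.shuffle(combos)
        for cue, val in combos:
            rows.append({"block": block, "cue": cue, "valence": val})
    df = pd.DataFrame(rows)
    df["trial_index"] = np.arange(n_trials)
    return df


def _make_pictures(config: GeneratorConfig, rng) -> pd.DataFrame:
    n_trials = config.blocks * config.trials_per_block
    n_each = n_trials // 2
    neg = rng.uniform(*config.negative_norm_range, size=n_each)
    pos = rng.uniform(*config.positive_norm_range, size=n_each)
    return pd.DataFrame(
        {
            "picture_id": [f"NEG{i:03d}" for i in range(n_each)]
            + [f"POS{i:03d}" for i in range(n_each)],
            "picture_norm": np.concatenate([neg, pos]),
            "valence": ["unpleasant"] * n_each + ["pleasant"] * n_each,
        }
    )


def draw_subject_params(config: GeneratorConfig, rng) -> np.ndarray:
    """One subject's free-parameter vector (under the generating model's
    structure) from the population truncated-Normal distributions."""
    from .design import get_model
    from .hierfit import _truncnorm_draw

    spec = get_model(config.model)
    names = spec.param_names
    loc = np.array([config.population_loc[n] for n in names])
    lb = spec.lower_bounds()
    if config.population_scale == 0:
        return loc.copy()
    return _truncnorm_draw(rng, loc, config.population_scale, lb, len(names))


def gen_dataset(
    config: GeneratorConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, GeneratingTruth]:
    """Generate a full synthetic experiment and its generating truth."""
    from .design import get_model

    config = config or GeneratorConfig()
    gen_spec = get_model(config.model)
    rng = np.random.default_rng(seed)
    pictures = _make_pictures(config, rng)

    names = gen_spec.param_names
    subject_rows = {}
    frames = []
    for i in range(config.n_participants):
        pid = f"S{i + 1:03d}"
        theta = draw_subject_params(config, rng)
        subject_rows[pid] = theta
        cell_params = gen_spec.expand_subject_params(theta)

        design = _block_design(config, rng)
        # assign each picture once, matching valence slots
        assigned = []
        for val in ("unpleasant", "pleasant"):
            pool = pictures[pictures["valence"] == val].sample(
                frac=1.0, random_state=rng.integers(2**31)
            )
            assigned.append(
                pd.concat(
                    [
                        design[design["valence"] == val].reset_index(drop=True),
                        pool[["picture_id", "picture_norm"]].reset_index(drop=True),
                    ],
                    axis=1,
                )
            )
        trials = (
            pd.concat(assigned).sort_values("trial_index").reset_index(drop=True)
        )

        # simulate the race cell by cell
        rts = np.empty(len(trials))
        reports = np.empty(len(trials), dtype=object)
        censored = np.zeros(len(trials), dtype=bool)
        for cell in CELLS:
            pleas, diff = cell
            mask = (trials["valence"] == pleas) & (
                trials["cue"].map({"color": "easy", "shape": "easy", "conjunction": "difficult"})
                == diff
            )
            idx = np.flatnonzero(mask.to_numpy())
            if len(idx) == 0:
                continue
            sims = simulate_trials(
                cell_params[cell], len(idx), rng=rng,
                convention=config.drift_convention,
            )
            for j, sim in zip(idx, sims):
                rts[j] = sim.rt
                censored[j] = sim.censored
                reports[j] = report_for_choice(
                    trials["picture_norm"].iloc[j], sim.choice
                )
        trials["participant_id"] = pid
        trials["report"] = reports
        trials["rt_s"] = rts
        trials["censored"] = censored
        frames.append(trials)

    data = pd.concat(frames, ignore_index=True)
    data = data.rename(columns={"valence": "pleasantness"})
    cols = [
        "participant_id", "block", "trial_index", "cue", "picture_id",
        "picture_norm", "report", "rt_s", "censored",
    ]
    truth = GeneratingTruth(
        population_loc=dict(config.population_loc),
        population_scale={n: config.population_scale for n in names},
        subject_params=pd.DataFrame.from_dict(
            subject_rows, orient="index", columns=names
        ),
        config=asdict(config),
    )
    return data[cols], truth


# ---------------------------------------------------------------------------
# preprocessing fixture and contaminants


def make_preprocess_fixture(
    n_participants: int = 16,
    blocks: int = 4,
    trials_per_block: int = 60,
    seed: int = 0,
) -> pd.DataFrame:
    """Clean trial table for exercising the exclusion pipeline.

    Responses are all normative and RTs are uniform on [0.8, 2.0] s, whose
    bounded spread guarantees |z| < 3.5 within every design cell — so every
    later exclusion is attributable to an injected contaminant.
    """
    config = GeneratorConfig(
        n_participants=n_participants, blocks=blocks, trials_per_block=trials_per_block
    )
    rng = np.random.default_rng(seed)
    pictures = _make_pictures(config, rng)
    frames = []
    for i in range(n_participants):
        pid = f"S{i + 1:03d}"
        design = _block_design(config, rng)
        assigned = []
        for val in ("unpleasant", "pleasant"):
            pool = pictures[pictures["valence"] == val].sample(
                frac=1.0, random_state=rng.integers(2**31)
            )
            assigned.append(
                pd.concat(
                    [
                        design[design["valence"] == val].reset_index(drop=True),
                        pool[["picture_id", "picture_norm"]].reset_index(drop=True),
                    ],
                    axis=1,
                )
            )
        trials = pd.concat(assigned).sort_values("trial_index").reset_index(drop=True)
        trials["participant_id"] = pid
        trials["report"] = np.where(
            trials["valence"] == "unpleasant", "unpleasant", "pleasant"
        )
        trials["rt_s"] = rng.uniform(0.8, 2.0, size=len(trials))
        frames.append(trials)
    data = pd.concat(frames, ignore_index=True).rename(columns={"valence": "pleasantness"})
    return data[
        ["participant_id", "block", "trial_index", "cue", "picture_id",
         "picture_norm", "report", "rt_s"]
    ]


@dataclass
class InjectionLog:
    """Bookkeeping of injected contaminants, keyed like the preprocessing
    report's step names so the round trip can be checked count for count."""

    counts: dict[str, int]
    bad_participants: list[str]
    bad_pictures: list[str]


def _flip_report(report: str) -> str:
    return "pleasant" if report == "unpleasant" else "unpleasant"


def inject_contaminants(
    trials: pd.DataFrame,
    n_bad_participants: int = 0,
    n_bad_pictures: int = 0,
    n_fast: int = 0,
    n_slow: int = 0,
    n_z_outliers: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, InjectionLog]:
    """Add contaminants that trigger each preprocessing filter, with exact
    bookkeeping. Designed for :func:`make_preprocess_fixture` tables (bounded
    RTs, all-normative responses)."""
    rng = np.random.default_rng(seed)
    trials = trials.copy().reset_index(drop=True)
    good_participants = sorted(trials["participant_id"].unique())
    trials_per_participant = int(
        trials.groupby("participant_id").size().iloc[0]
    )

    # -- step 1 bait: extra participants responding 70% aberrantly
    bad_pids = []
    frames = [trials]
    template = trials[trials["participant_id"] == good_participants[0]]
    for i in range(n_bad_participants):
        pid = f"BAD{i + 1:02d}"
        bad_pids.append(pid)
        t = template.copy()
        t["participant_id"] = pid
        n_flip = math.ceil(0.7 * len(t))
        flip_idx = rng.choice(len(t), size=n_flip, replace=False)
        reports = t["report"].to_numpy(copy=True)
        reports[flip_idx] = [_flip_report(r) for r in reports[flip_idx]]
        t["report"] = reports
        t["rt_s"] = rng.uniform(0.8, 2.0, size=len(t))
        frames.append(t)
    trials = pd.concat(frames, ignore_index=True)

    # -- step 2 bait: pictures flipped to aberrant for 60% of good participants
    all_pictures = sorted(trials["picture_id"].unique())
    bad_pictures = list(
        rng.choice(all_pictures, size=n_bad_pictures, replace=False)
    )
    n_flip_participants = math.ceil(0.6 * len(good_participants))
    for pic in bad_pictures:
        flip_p = rng.choice(
            good_participants, size=n_flip_participants, replace=False
        )
        mask = (trials["picture_id"] == pic) & trials["participant_id"].isin(flip_p)
        trials.loc[mask, "report"] = [
            _flip_report(r) for r in trials.loc[mask, "report"]
        ]

    # pool of trials eligible for RT contamination: good participants on
    # retained pictures (so each injected trial survives to its own step)
    eligible = trials.index[
        trials["participant_id"].isin(good_participants)
        & ~trials["picture_id"].isin(bad_pictures)
    ].to_numpy()
    picked = rng.choice(eligible, size=n_fast + n_slow, replace=False)
    fast_idx, slow_idx = picked[:n_fast], picked[n_fast:]
    trials.loc[fast_idx, "rt_s"] = rng.uniform(0.05, 0.15, size=n_fast)
    trials.loc[slow_idx, "rt_s"] = rng.uniform(6.1, 7.5, size=n_slow)

    # -- step 4 bait: one extreme (but sub-6.1 s) RT in distinct design cells
    from .design import cue_to_difficulty, norm_to_pleasantness

    work = trials.loc[
        trials.index.isin(eligible) & ~trials.index.isin(picked)
    ].copy()
    work["pleasantness"] = [norm_to_pleasantness(n) for n in work["picture_norm"]]
    work["difficulty"] = [cue_to_difficulty(c) for c in work["cue"]]
    cells = list(work.groupby(["participant_id", "pleasantness", "difficulty"]).indices.items())
    rng.shuffle(cells)
    if n_z_outliers > len(cells):
        raise ValueError("not enough design cells for the requested z outliers")
    for key, rel_idx in cells[:n_z_outliers]:
        abs_idx = work.index.to_numpy()[rel_idx]
        target = rng.choice(abs_idx)
        others = trials.loc[abs_idx[abs_idx != target], "rt_s"]
        val = others.mean() + 6.0 * others.std(ddof=1)
        trials.loc[target, "rt_s"] = min(val, 6.0)

    log = InjectionLog(
        counts={
            "participants_gt50pct_aberrant": n_bad_participants
            * trials_per_participant,
            "pictures_lt50pct_normative": n_bad_pictures * len(good_participants),
            "rt_window_200ms_6.1s": n_fast + n_slow,
            "zscore_gt3.5_per_cell": n_z_outliers,
        },
        bad_participants=bad_pids,
        bad_pictures=[str(p) for p in bad_pictures],
    )
    return trials.reset_index(drop=True), log


# ---------------------------------------------------------------------------
# manipulation-check columns


def gen_search_data(trials: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Add visual-search task columns emulating the manipulation check.

    Search RTs are lognormal with condition means 1131 / 1449 / 1832 ms
    (color / shape / conjunction) and SD = 0.35 x mean; error rates are
    approximately equal across conditions (~0.14), so difficulty shows in
    speed, not accuracy.
    """
    rng = np.random.default_rng(seed)
    out = trials.copy()
    n = len(out)
    target = np.where(rng.uniform(size=n) < 0.5, "present", "absent")
    rts = np.empty(n)
    errors = np.zeros(n, dtype=bool)
    for cue in _CUES:
        mask = (out["cue"] == cue).to_numpy()
        k = int(mask.sum())
        mean = SEARCH_RT_MEAN_S[cue]
        sigma2 = np.log1p(SEARCH_RT_CV**2)
        mu = np.log(mean) - sigma2 / 2.0
        rts[mask] = rng.lognormal(mu, np.sqrt(sigma2), size=k)
        errors[mask] = rng.uniform(size=k) < SEARCH_ERROR_RATE[cue]
    response = np.where(
        errors,
        np.where(target == "present", "absent", "present"),
        target,
    )
    out["search_target"] = target
    out["search_response"] = response
    out["search_rt_s"] = rts
    return out
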