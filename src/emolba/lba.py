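"""Linear ballistic accumulator: closed-form finishing-time distributions,
the two-accumulator defective likelihood, and a trial simulator.

The LBA describes a two-choice decision as a race between accumulators. On
each trial accumulator ``i`` starts at ``start_i ~ Uniform(0, A)``, gathers
evidence linearly at rate ``drift_i ~ Normal(mean_v_i, sv)`` (drawn once per
trial; the trajectory itself is noiseless), and responds when it reaches the
boundary ``b = A + B``. The first accumulator to finish controls the
response; observed RT is the winning finishing time plus the non-decision
time ``t0``.

Two conventions for negative sampled drifts are supported:

``"truncated"`` (default)
    drifts are truncated to positive values and each accumulator's
    finishing-time distribution is renormalised by ``Phi(mean_v / sv)``, so
    every trial terminates — matching a task in which a response always
    occurred within the response window.
``"defective"``
    negative drifts never finish; each accumulator's CDF saturates at
    ``Phi(mean_v / sv)`` and a trial on which both drifts are negative is
    censored.

This module is the scipy-based reference implementation used by the public
API and by tests; the DE-MCMC sampler calls the equivalent numba kernels in
:mod:`emolba._fast`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import norm

DriftConvention = Literal["truncated", "defective"]

#: per-trial log-density floor applied before summation
LOG_FLOOR = -700.0

#: default simulation censoring horizon (s) — the on-screen response window
RESPONSE_WINDOW_S = 8.0

_A_EPS = 1e-6


class ParameterDomainError(ValueError):
    """Raised when LBA parameters violate their domain (A<0, B<=0, sv<=0, t0<0)."""


@dataclass(frozen=True)
class AccumulatorParams:
    """Parameters of a single LBA accumulator.

    A : start-point range upper bound (evidence units, >= 0)
    B : boundary offset above A (evidence units, > 0); boundary b = A + B
    mean_v : mean drift rate (evidence units / s)
    sv : across-trial drift standard deviation (evidence units / s, > 0)
    t0 : non-decision time (s, >= 0)
    """

    A: float
    B: float
    mean_v: float
    sv: float = 1.0
    t0: float = 0.3

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ParameterDomainError(f"A must be >= 0, got {self.A}")
        if self.B <= 0:
            raise ParameterDomainError(f"B must be > 0, got {self.B}")
        if self.sv <= 0:
            raise ParameterDomainError(f"sv must be > 0, got {self.sv}")
        if self.t0 < 0:
            raise ParameterDomainError(f"t0 must be >= 0, got {self.t0}")

    @property
    def b(self) -> float:
        """Absolute boundary b = A + B (structurally > A)."""
        return self.A + self.B


@dataclass(frozen=True)
class CellParams:
    """Normative/aberrant accumulator pair for one design cell.

    A, t0 and sv are shared between the two accumulators; only the mean
    drift rates (and, in principle, B) may differ.
    """

    normative: AccumulatorParams
    aberrant: AccumulatorParams

    def __post_init__(self) -> None:
        for name in ("A", "t0", "sv"):
            if getattr(self.normative, name) != getattr(self.aberrant, name):
                raise ParameterDomainError(
                    f"{name} must be shared between the two accumulators"
                )

    @classmethod
    def make(
        cls,
        A: float,
        B: float,
        mean_v_normative: float,
        mean_v_aberrant: float,
        sv: float = 1.0,
        t0: float = 0.3,
    ) -> "CellParams":
        base = AccumulatorParams(A=A, B=B, mean_v=mean_v_normative, sv=sv, t0=t0)
        return cls(normative=base, aberrant=replace(base, mean_v=mean_v_aberrant))

    def as_row(self) -> np.ndarray:
        """Kernel layout: [A, b, v_normative, v_aberrant, sv, t0]."""
        n = self.normative
        return np.array(
            [n.A, n.b, n.mean_v, self.aberrant.mean_v, n.sv, n.t0], dtype=float
        )


@dataclass(frozen=True)
class ChoiceRT:
    """One simulated or observed emotion-report outcome."""

    choice: Literal["normative", "aberrant"]
    rt: float
    censored: bool = False
    cell: object = None  # optional design-cell label

    def __post_init__(self) -> None:
        if self.choice not in ("normative", "aberrant"):
            raise ValueError(f"unknown choice {self.choice!r}")


def _termination_prob(acc: AccumulatorParams) -> float:
    return float(ndtr(acc.mean_v / acc.sv))


def finish_time_cdf(
    t, acc: AccumulatorParams, convention: DriftConvention = "truncated"
):
    """P(accumulator finishes by decision time ``t``).

    Closed form for start ~ Uniform(0, A), drift ~ Normal(mean_v, sv).
    Under the defective convention the limit at infinity is
    ``Phi(mean_v / sv)``; under truncation it is 1.
    """
    t = np.asarray(t, dtype=float)
    A, b, v, sv = acc.A, acc.b, acc.mean_v, acc.sv
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = t * sv
        if A < _A_EPS:
            F = np.where(t > 0, ndtr((t * v - b) / np.where(ts > 0, ts, 1.0)), 0.0)
        else:
            z1 = (b - A - t * v) / ts
            z2 = (b - t * v) / ts
            F = (
                1.0
                + (b - A - t * v) / A * ndtr(z1)
                - (b - t * v) / A * ndtr(z2)
                + ts / A * (norm.pdf(z1) - norm.pdf(z2))
            )
            F = np.where(t > 0, F, 0.0)
    F = np.clip(F, 0.0, 1.0)
    if convention == "truncated":
        F = F / _termination_prob(acc)
        F = np.clip(F, 0.0, 1.0)
    return F if F.ndim else float(F)


def finish_time_pdf(
    t, acc: AccumulatorParams, convention: DriftConvention = "truncated"
):
    """Finishing-time density at decision time ``t`` (0 for t <= 0)."""
    t = np.asarray(t, dtype=float)
    A, b, v, sv = acc.A, acc.b, acc.mean_v, acc.sv
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = np.where(t > 0, t * sv, 1.0)
        if A < _A_EPS:
            z = (t * v - b) / ts
            f = b / (t * ts) * norm.pdf(z)
        else:
            z1 = (b - A - t * v) / ts
            z2 = (b - t * v) / ts
            f = (-v * ndtr(z1) + sv * norm.pdf(z1) + v * ndtr(z2) - sv * norm.pdf(z2)) / A
    f = np.where(t > 0, np.clip(f, 0.0, np.inf), 0.0)
    if convention == "truncated":
        f = f / _termination_prob(acc)
    return f if f.ndim else float(f)


def defective_density(
    trial: ChoiceRT, cell: CellParams, convention: DriftConvention = "truncated"
) -> float:
    """Joint likelihood density of (choice, RT) for one trial.

    f_winner(rt - t0) * (1 - F_loser(rt - t0)); 0 whenever rt <= t0.
    Integrated over RT this gives the choice probability, not 1 — hence
    "defective".
    """
    if trial.choice == "normative":
        winner, loser = cell.normative, cell.aberrant
    else:
        winner, loser = cell.aberrant, cell.normative
    td = trial.rt - winner.t0
    if td <= 0:
        return 0.0
    fw = finish_time_pdf(td, winner, convention)
    Fl = finish_time_cdf(td, loser, convention)
    return float(max(fw * (1.0 - Fl), 0.0))


def dataset_loglik(
    trials: Iterable[ChoiceRT],
    params,
    convention: DriftConvention = "truncated",
) -> float:
    """Sum of log defective densities over trials.

    ``params`` is either a single :class:`CellParams` applied to every trial
    or a mapping from each trial's ``cell`` label to its :class:`CellParams`.
    Zero-density trials contribute the floor ``LOG_FLOOR`` instead of -inf.
    """
    total = 0.0
    for trial in trials:
        if isinstance(params, CellParams):
            cell = params
        else:
            try:
                cell = params[trial.cell]
            except KeyError:
                raise KeyError(f"trial cell label {trial.cell!r} has no parameters")
        dens = defective_density(trial, cell, convention)
        total += max(np.log(dens) if dens > 0 else LOG_FLOOR, LOG_FLOOR)
    return float(total)


def _draw_drifts(rng, n, mean_v, sv, convention):
    if convention == "truncated":
        lo = ndtr(-mean_v / sv)  # mass below zero
        u = rng.uniform(lo, 1.0, size=n)
        return mean_v + sv * ndtri(u)
    return rng.normal(mean_v, sv, size=n)


def simulate_trials(
    cell: CellParams,
    n: int,
    rng=None,
    convention: DriftConvention = "truncated",
    censor_at: float = RESPONSE_WINDOW_S,
) -> list[ChoiceRT]:
    """Simulate ``n`` trials of the two-accumulator race.

    Trials whose winning RT exceeds ``censor_at`` (or on which no
    accumulator terminates, under the defective convention) are flagged
    censored rather than dropped; their recorded rt is ``censor_at``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    out: list[ChoiceRT] = []
    accs = (cell.normative, cell.aberrant)
    starts = np.stack([rng.uniform(0.0, a.A if a.A > 0 else 1e-12, size=n) for a in accs])
    drifts = np.stack(
        [_draw_drifts(rng, n, a.mean_v, a.sv, convention) for a in accs]
    )
    with np.errstate(divide="ignore"):
        times = np.where(
            drifts > 0, (np.array([[a.b] for a in accs]) - starts) / drifts, np.inf
        )
    winners = np.argmin(times, axis=0)
    t0 = cell.normative.t0
    for i in range(n):
        w = winners[i]
        tw = times[w, i]
        rt = t0 + tw
        if not np.isfinite(tw) or rt > censor_at:
            out.append(
                ChoiceRT(choice=("normative", "aberrant")[w], rt=censor_at, censored=True)
            )
        else:
            out.append(ChoiceRT(choice=("normative", "aberrant")[w], rt=float(rt)))
    return out


def response_probability(
    cell: CellParams,
    choice: Literal["normative", "aberrant"] = "normative",
    convention: DriftConvention = "truncated",
) -> float:
    """P(choice) by quadrature of the defective density over decision time."""
    from scipy.integrate import quad

    trial_t0 = cell.normative.t0

    def integrand(td):
        return defective_density(
            ChoiceRT(choice=choice, rt=trial_t0 + td), cell, convention
        )

    val, _ = quad(integrand, 0, np.inf, limit=200)
    return float(val)
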