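"""Convergence diagnostics (Gelman-Rubin) and model comparison
(participant-summed deviance information criterion).

The Gelman-Rubin statistic here is the classic two-part potential scale
reduction factor computed from whole chains, matching the era's toolchain;
``split=True`` halves each chain first (the modern variant, more sensitive
to within-chain trends).

DIC for one participant uses that participant's subject-level draws only:
DIC = Dbar + pD with Dbar the posterior mean deviance (-2 log-likelihood of
the participant's trials) and pD = Dbar - D(posterior-mean parameters).
Model comparison sums DIC over participants; lower wins, and the
conventional 6-point difference is reported as the "real difference" bar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _fast
from .hierfit import PosteriorFit, SubjectData

#: a summed-DIC gap at or above this is conventionally a real difference
DIC_REAL_DIFFERENCE = 6.0


def gelman_rubin(chains: np.ndarray, split: bool = False) -> float:
    """Classic potential scale reduction factor for one parameter.

    ``chains``: (n_chains, n_draws). Returns NaN (with a warning) when the
    within-chain variance is zero in every chain.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 2:
        raise ValueError("need >= 2 chains with >= 2 draws each")
    if split:
        half = chains.shape[1] // 2
        chains = np.vstack([chains[:, :half], chains[:, half : 2 * half]])
    m, n = chains.shape
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = chains.mean(axis=1).var(ddof=1)
    if W == 0:
        warnings.warn("zero within-chain variance in all chains; R-hat undefined")
        return float("nan")
    var_hat = (n - 1) / n * W + (1.0 + 1.0 / m) * B_over_n
    return float(np.sqrt(var_hat / W))


def max_rhat_per_participant(fit: PosteriorFit, split: bool = False) -> pd.Series:
    """Largest R-hat over a participant's subject-level parameters."""
    out = {}
    for s, pid in enumerate(fit.subject_ids):
        vals = [
            gelman_rubin(fit.theta[:, :, s, i], split=split)
            for i in range(len(fit.param_names))
        ]
        out[pid] = np.nanmax(vals)
    return pd.Series(out, name="max_rhat")


def dic_from_draws(loglik_draws: np.ndarray, loglik_at_mean: float) -> float:
    """DIC = Dbar + pD with pD = Dbar - D(posterior-mean parameters)."""
    dbar = float(-2.0 * np.asarray(loglik_draws).mean())
    pd_ = dbar - (-2.0 * float(loglik_at_mean))
    return dbar + pd_


def dic_participant(fit: PosteriorFit, data: list[SubjectData], participant) -> float:
    """DIC for one participant from the stored subject-level draws."""
    s = fit.subject_ids.index(participant)
    ll = fit.loglik[:, :, s].ravel()
    theta_bar = fit.pooled_theta().mean(axis=0)[s]
    sd = data[s]
    ll_at_mean = _fast.subject_loglik(
        fit.spec.expand_many(theta_bar)[0],
        sd.rt,
        sd.resp,
        sd.cell,
        fit.config.drift_convention == "truncated",
    )
    if not np.isfinite(ll_at_mean):
        raise ValueError(
            f"non-finite deviance at posterior mean for participant {participant}"
        )
    return dic_from_draws(ll, float(ll_at_mean))


@dataclass
class ComparisonResult:
    """Participant-summed DIC comparison between two fitted models."""

    per_participant: pd.DataFrame  # columns: one per model name
    summed: dict[str, float]
    difference: float  # DIC(model_b) - DIC(model_a), positive favors model_a
    preferred: str
    real_difference: bool  # |difference| >= 6

    def to_dict(self) -> dict:
        return {
            "summed_dic": self.summed,
            "difference": self.difference,
            "preferred": self.preferred,
            "real_difference": self.real_difference,
            "threshold": DIC_REAL_DIFFERENCE,
        }


def compare_models(
    fit_a: PosteriorFit, fit_b: PosteriorFit, data: list[SubjectData]
) -> ComparisonResult:
    """Compare two fits of the same data by participant-summed DIC."""
    if fit_a.fingerprint != fit_b.fingerprint:
        raise ValueError("fits were not computed on identical data")
    if fit_a.subject_ids != fit_b.subject_ids:
        raise ValueError("participant sets differ between fits")
    names = [fit_a.model, fit_b.model]
    if names[0] == names[1]:
        names = [f"{names[0]}_a", f"{names[1]}_b"]
    rows = {}
    for name, fit in zip(names, (fit_a, fit_b)):
        rows[name] = [dic_participant(fit, data, pid) for pid in fit.subject_ids]
    table = pd.DataFrame(rows, index=fit_a.subject_ids)
    summed = {name: float(table[name].sum()) for name in table.columns}
    diff = summed[names[1]] - summed[names[0]]
    preferred = names[0] if diff >= 0 else names[1]
    if diff == 0:
        preferred = "tie"
    return ComparisonResult(
        per_participant=table,
        summed=summed,
        difference=float(diff),
        preferred=preferred,
        real_difference=abs(diff) >= DIC_REAL_DIFFERENCE,
    )
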