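"""Default-prior Bayes-factor inference on fitted parameters.

Two families are provided, both reimplementations of the standard
default-prior tests:

* :func:`jzs_paired_bf` — the JZS paired t-test Bayes factor (Cauchy prior
  on standardized effect size, default scale sqrt(2)/2), by one-dimensional
  numerical integration over the g mixing parameter.
* :func:`rm_banova_bf` — a 2x2 repeated-measures Bayesian ANOVA over the
  default-prior linear-model set {subject-only; +factor1; +factor2; +both;
  +both+interaction}. Effects use projected orthonormal sum-to-zero
  contrasts with one g per term (fixed-effect prior scale 0.5, random
  subject scale 1.0, g ~ InvGamma(1/2, r^2/2)); marginal likelihoods are
  computed by Monte-Carlo integration over g with a reported numerical
  error. Main-effect BFs compare each one-factor model against the
  subject-only base; the interaction BF compares the full model against
  the main-effects-only model.

Input is a complete participants x cells table of per-subject posterior
means of one fitted parameter (the two-stage workflow: model fit first,
ANOVA on the point summaries after).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.special import gammaln, logsumexp

DEFAULT_T_SCALE = np.sqrt(2.0) / 2.0
DEFAULT_FIXED_SCALE = 0.5
DEFAULT_RANDOM_SCALE = 1.0


@dataclass(frozen=True)
class BFResult:
    """A Bayes factor with its model pair and numerical-error estimate."""

    bf10: float
    model1: str
    model0: str
    prior_scales: dict
    error: float  # proportional numerical error on bf10
    n: int

    def __post_init__(self):
        if not self.bf10 > 0:
            raise ValueError("BF10 must be positive")

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


def percent_change(m_high: float, m_low: float) -> float:
    """Percent increase of m_high over m_low on a ratio-scale parameter,
    reported to 2 decimals."""
    if m_low <= 0:
        raise ValueError("percent change needs a positive baseline (ratio scale)")
    return round(100.0 * (m_high - m_low) / m_low, 2)


def _invgamma_half_logpdf(g, r):
    # g ~ InvGamma(1/2, r^2/2)  <=>  sqrt(g) has a half-Cauchy(r) scale role
    return (
        0.5 * np.log(r * r / 2.0)
        - gammaln(0.5)
        - 1.5 * np.log(g)
        - r * r / (2.0 * g)
    )


def jzs_paired_bf(differences, scale: float = DEFAULT_T_SCALE) -> BFResult:
    """JZS Bayes factor for a paired/one-sample t design.

    ``differences`` are the per-subject paired differences; BF10 favors a
    nonzero standardized effect with Cauchy(scale) prior.
    """
    x = np.asarray(differences, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: t statistic undefined")
    t = x.mean() / (sd / np.sqrt(n))
    nu = n - 1

    log_h0 = -(nu + 1) / 2.0 * np.log1p(t * t / nu)

    def integrand(g):
        log_h1 = (
            -0.5 * np.log1p(n * g)
            - (nu + 1) / 2.0 * np.log1p(t * t / ((1.0 + n * g) * nu))
            + _invgamma_half_logpdf(g, scale)
        )
        return np.exp(log_h1 - log_h0)

    val, err = quad(integrand, 0.0, np.inf, limit=400)
    return BFResult(
        bf10=float(val),
        model1="effect (JZS Cauchy prior)",
        model0="no effect",
        prior_scales={"effect": scale},
        error=float(err / val) if val > 0 else np.inf,
        n=n,
    )


# ---------------------------------------------------------------------------
# repeated-measures BANOVA


def _sum_zero_contrast(levels: int) -> np.ndarray:
    """Orthonormal basis of the sum-to-zero subspace (levels x levels-1)."""
    center = np.eye(levels) - np.ones((levels, levels)) / levels
    vals, vecs = np.linalg.eigh(center)
    return vecs[:, vals > 0.5]


def banova_design(n_subjects: int):
    """Design-matrix columns for the 2x2 within-subject layout.

    Returns dict term -> (N x k_term) matrix, rows ordered subject-major
    with the 4 cells in the order (factor1 level x factor2 level):
    (a1,b1), (a1,b2), (a2,b1), (a2,b2).
    """
    q2 = _sum_zero_contrast(2)  # (2,1)
    qs = _sum_zero_contrast(n_subjects)  # (S, S-1)
    ones_s = np.ones((n_subjects, 1))
    ones_2 = np.ones((2, 1))
    # cell-level factors replicated over subjects
    xa = np.kron(ones_s, np.kron(q2, ones_2))  # factor 1
    xb = np.kron(ones_s, np.kron(ones_2, q2))  # factor 2
    xab = np.kron(ones_s, np.kron(q2, q2))
    xs = np.kron(qs, np.ones((4, 1)))
    return {"subject": xs, "f1": xa, "f2": xb, "f1:f2": xab}


def _log_marginal_batch(y, X, term_cols, g_draws):
    """log m(y | g) for a batch of g draws, via the k-dim Woodbury identity.

    X: (N, k); term_cols: per-column term index into g vectors;
    g_draws: (n_mc, n_terms). Constant factors shared across models cancel
    in Bayes-factor ratios and are omitted.
    """
    N, k = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    Xt1 = X.T @ np.ones(N)
    yty = float(y @ y)
    one_y = float(y.sum())

    g_cols = g_draws[:, term_cols]  # (n_mc, k)
    sq = np.sqrt(g_cols)
    W = np.eye(k)[None] + sq[:, :, None] * XtX[None] * sq[:, None, :]
    sign, logdet = np.linalg.slogdet(W)
    rhs = np.stack(
        [sq * Xty[None, :], sq * Xt1[None, :]], axis=-1
    )  # (n_mc, k, 2)
    sol = np.linalg.solve(W, rhs)
    yVy = yty - np.einsum("mk,mk->m", sq * Xty[None, :], sol[:, :, 0])
    oVy = one_y - np.einsum("mk,mk->m", sq * Xty[None, :], sol[:, :, 1])
    oVo = N - np.einsum("mk,mk->m", sq * Xt1[None, :], sol[:, :, 1])
    q = yVy - oVy * oVy / oVo
    return -0.5 * logdet - 0.5 * np.log(oVo) - (N - 1) / 2.0 * np.log(q)


def _model_log_evidence(y, terms, scales, rng, n_mc):
    """Monte-Carlo log evidence (up to shared constants) and its SE."""
    names = list(terms)
    X = np.hstack([terms[t] for t in names])
    term_cols = np.concatenate(
        [np.full(terms[t].shape[1], i) for i, t in enumerate(names)]
    )
    # g ~ InvGamma(1/2, r^2/2): draw as (r^2/2) / Gamma(1/2) variate
    gam = rng.gamma(0.5, 1.0, size=(n_mc, len(names)))
    r2 = np.array([scales[t] ** 2 for t in names])
    g = (r2 / 2.0) / gam
    logm = _log_marginal_batch(y, X, term_cols, g)
    lse = logsumexp(logm)
    log_ev = lse - np.log(n_mc)
    w = np.exp(logm - logm.max())
    rel_se = w.std(ddof=1) / (w.mean() * np.sqrt(n_mc))
    return float(log_ev), float(rel_se)


def rm_banova_bf(
    table: pd.DataFrame,
    fixed_scale: float = DEFAULT_FIXED_SCALE,
    random_scale: float = DEFAULT_RANDOM_SCALE,
    n_mc: int = 100_000,
    seed: int = 0,
    factor_names: tuple[str, str] = ("pleasantness", "difficulty"),
) -> dict[str, BFResult]:
    """2x2 repeated-measures BANOVA on a participants x cells table.

    ``table`` columns must be the 4 cells ordered
    (f1level1.f2level1, f1level1.f2level2, f1level2.f2level1,
    f1level2.f2level2) — e.g. the output of
    :meth:`emolba.hierfit.PosteriorFit.banova_table`.
    Returns BFResults keyed by the two factor names and "interaction".
    """
    values = np.asarray(table, dtype=float)
    if values.ndim != 2 or values.shape[1] != 4:
        raise ValueError("table must be participants x 4 cells")
    if np.isnan(values).any():
        raise ValueError("table has missing cells")
    S = values.shape[0]
    if S < 2:
        raise ValueError("need at least 2 participants")
    y = values.reshape(-1)
    # standardize for the g-prior scale convention (BF is scale invariant)
    y = (y - y.mean()) / y.std(ddof=1)

    design = banova_design(S)
    scales = {
        "subject": random_scale,
        "f1": fixed_scale,
        "f2": fixed_scale,
        "f1:f2": fixed_scale,
    }
    model_terms = {
        "base": ["subject"],
        "f1": ["subject", "f1"],
        "f2": ["subject", "f2"],
        "main": ["subject", "f1", "f2"],
        "full": ["subject", "f1", "f2", "f1:f2"],
    }
    ev, se = {}, {}
    for name, terms in model_terms.items():
        # seed by model structure, not name: the two one-factor models then
        # share g draws, so relabelling the factors swaps their BFs exactly
        rng = np.random.default_rng([seed, len(terms)])
        ev[name], se[name] = _model_log_evidence(
            y, {t: design[t] for t in terms}, scales, rng, n_mc
        )

    def make(num, den, label):
        return BFResult(
            bf10=float(np.exp(ev[num] - ev[den])),
            model1=num,
            model0=den,
            prior_scales={"fixed": fixed_scale, "random": random_scale},
            error=se[num] + se[den],
            n=S,
        )

    f1, f2 = factor_names
    return {
        f1: make("f1", "base", f1),
        f2: make("f2", "base", f2),
        "interaction": make("full", "main", "interaction"),
    }


def banova_report(
    table: pd.DataFrame,
    factor_names: tuple[str, str] = ("pleasantness", "difficulty"),
    t_scale: float = DEFAULT_T_SCALE,
    **kwargs,
) -> dict:
    """BANOVA plus the follow-up paired t-tests at each level of factor 2.

    Mirrors the result structure of the drift-rate analyses: main effects,
    interaction, then a paired Bayes t-test between the two factor-2 levels
    within each level of factor 1.
    """
    bfs = rm_banova_bf(table, factor_names=factor_names, **kwargs)
    values = np.asarray(table, dtype=float)
    followups = {}
    # columns: (f1a,f2a), (f1a,f2b), (f1b,f2a), (f1b,f2b)
    for i, f1_level in enumerate(("level1", "level2")):
        name = table.columns[2 * i].split(".")[0]
        diffs = values[:, 2 * i + 1] - values[:, 2 * i]
        try:
            followups[name] = jzs_paired_bf(diffs, scale=t_scale)
        except ValueError:
            followups[name] = None
    return {
        "banova": bfs,
        "paired_tests": followups,
        "cell_means": dict(zip(table.columns, np.round(values.mean(axis=0), 4))),
    }
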