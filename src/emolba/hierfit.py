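"""Hierarchical Bayesian estimation of LBA parameters by DE-MCMC.

Model structure
---------------
Subject-level parameter vectors ``theta_s`` (5 free parameters under the
null model, 14 under the core model) follow truncated-Normal population
distributions on the natural scale::

    theta_s[d] ~ Normal(loc[d], scale[d])  truncated to the support
    loc[d]     ~ Normal(prior_loc[d], prior_sd[d])  truncated to the support
    scale[d]   ~ HalfNormal(1)

with the location priors taken from the estimation defaults in
:data:`emolba.design.PRIOR_TABLE`. A, B and t0 are bounded below by 0; the
drift means are unbounded.

Sampling
--------
Differential-evolution MCMC: many interacting chains, each holding the full
state (all subjects' theta plus the population location/scale). Each
iteration performs one Metropolis block update per subject (proposal =
current + gamma * (difference of two other chains' states) + small jitter,
gamma = 2.38 / sqrt(2 d)) conditional on that chain's population state,
then one joint block update of (loc, scale) conditional on the subjects.
During burn-in, a migration step occasionally lets a random cyclic subset
of chains exchange subject states, which protects against stuck outlier
chains. Draws after burn-in are thinned before storage.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr, ndtri

from . import _fast
from .design import CELLS, CELL_INDEX, ModelSpec, get_model
from .preprocessing import ensure_coding

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings. Defaults are the full-scale profile; see DESK_CONFIG
    for the scaled-down profile used in development-sized runs."""

    n_chains: int = 42
    n_burn: int = 1000
    n_sample: int = 8000
    thin: int = 12
    seed: int = 0
    jitter_sd: float = 1e-3
    migration_prob: float = 0.20  # burn-in only
    subject_sweeps: int = 4  # DE sweeps per subject block per iteration
    phi_sweeps: int = 3  # population block updates per iteration (cheap)
    init: str = "map"  # "map": start chains near per-subject penalized-
    # likelihood modes; "prior": overdispersed prior draws
    drift_convention: str = "truncated"

    def __post_init__(self):
        for name in ("n_chains", "n_burn", "n_sample", "thin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_chains < 4:
            raise ValueError("DE-MCMC needs at least 4 chains")


#: scaled-down profile for development-sized runs
DESK_CONFIG = SamplerConfig(n_chains=24, n_burn=500, n_sample=1500, thin=3)
#: full-scale profile
PAPER_CONFIG = SamplerConfig()


@dataclass
class SubjectData:
    """One participant's trials in kernel-ready arrays."""

    participant_id: object
    rt: np.ndarray        # float64, seconds
    resp: np.ndarray      # int64: 0 normative, 1 aberrant
    cell: np.ndarray      # int64 index into design.CELLS

    @property
    def n_trials(self) -> int:
        return len(self.rt)


class InitializationError(RuntimeError):
    pass


def prepare_subject_data(trials: pd.DataFrame) -> list[SubjectData]:
    """Split a coded trial table into per-subject kernel arrays."""
    trials = ensure_coding(trials)
    out = []
    for pid, grp in trials.groupby("participant_id", sort=True):
        cells = [
            CELL_INDEX[(p, d)] for p, d in zip(grp["pleasantness"], grp["difficulty"])
        ]
        out.append(
            SubjectData(
                participant_id=pid,
                rt=np.ascontiguousarray(grp["rt_s"].to_numpy(dtype=np.float64)),
                resp=np.ascontiguousarray(
                    (grp["response"] == "aberrant").to_numpy(dtype=np.int64)
                ),
                cell=np.ascontiguousarray(np.array(cells, dtype=np.int64)),
            )
        )
    return out


def data_fingerprint(data: list[SubjectData]) -> str:
    h = hashlib.sha256()
    for s in data:
        h.update(str(s.participant_id).encode())
        h.update(s.rt.tobytes())
        h.update(s.resp.tobytes())
        h.update(s.cell.tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# densities


def truncnorm_logpdf(x, loc, scale, lower):
    """Elementwise log density of Normal(loc, scale) truncated below at
    ``lower`` (-inf = untruncated). Broadcasts; -inf outside support."""
    x, loc, scale, lower = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (x, loc, scale, lower))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - loc) / scale
        lp = -np.log(scale) - 0.5 * z * z - _LOG_SQRT_2PI
        bounded = np.isfinite(lower)
        if np.any(bounded):
            # log(1 - Phi((lower - loc)/scale)) = log_ndtr((loc - lower)/scale)
            alpha = np.where(bounded, (loc - lower) / scale, np.inf)
            lp = lp - np.where(bounded, log_ndtr(alpha), 0.0)
        lp = np.where((x < lower) | (scale <= 0), -np.inf, lp)
    return lp


def halfnorm_logpdf(x, scale=1.0):
    x = np.asarray(x, dtype=float)
    lp = 0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (x / scale) ** 2
    return np.where(x > 0, lp, -np.inf)


def _truncnorm_draw(rng, loc, sd, lower, size):
    """Inverse-CDF draw from Normal(loc, sd) truncated below at lower."""
    loc, sd, lower = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (loc, sd, lower))
    )
    u = rng.uniform(size=size)
    lo = np.where(np.isfinite(lower), ndtr((lower - loc) / sd), 0.0)
    return loc + sd * ndtri(lo + u * (1.0 - lo - 1e-12))


def log_posterior(theta, phi_loc, phi_scale, data, spec, drift_convention="truncated"):
    """Joint log density of subject parameters + population state given data.

    theta: (n_subjects, n_free); phi_loc/phi_scale: (n_free,). Returns -inf
    outside the support. Used as the sampler's target and checkable against
    an independent recomputation.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    lb = spec.lower_bounds()
    mu0, sd0 = spec.prior_loc_sd()
    truncated = drift_convention == "truncated"

    hyper = truncnorm_logpdf(phi_loc, mu0, sd0, lb).sum() + halfnorm_logpdf(
        phi_scale
    ).sum()
    if not np.isfinite(hyper):
        return -np.inf
    subj_prior = truncnorm_logpdf(theta, phi_loc, phi_scale, lb).sum()
    if not np.isfinite(subj_prior):
        return -np.inf
    cellpars = spec.expand_many(theta)
    ll = 0.0
    for s, sd in enumerate(data):
        ll += _fast.subject_loglik(cellpars[s], sd.rt, sd.resp, sd.cell, truncated)
    if not np.isfinite(ll):
        return -np.inf
    return float(ll + subj_prior + hyper)


def _subject_map(sd_, spec, mu0, sd0, lb, truncated):
    """Crude penalized-likelihood mode for one subject (chain init only)."""
    from scipy.optimize import minimize

    def neg(theta):
        if np.any(theta[np.isfinite(lb)] <= lb[np.isfinite(lb)]):
            return 1e12
        ll = _fast.subject_loglik(
            spec.expand_many(theta)[0], sd_.rt, sd_.resp, sd_.cell, truncated
        )
        if not np.isfinite(ll):
            return 1e12
        pen = 0.5 * np.sum(((theta - mu0) / sd0) ** 2)
        return -(ll - pen)

    res = minimize(
        neg, mu0, method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-3, "fatol": 1e-2},
    )
    return res.x


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class PosteriorFit:
    """MCMC draws at subject and population level, plus bookkeeping.

    Array shapes: theta (chains, draws, subjects, params);
    phi_loc / phi_scale (chains, draws, params);
    loglik (chains, draws, subjects) — the data log-likelihood of each
    stored subject state, used for DIC.
    """

    model: str
    param_names: tuple[str, ...]
    subject_ids: list
    theta: np.ndarray
    phi_loc: np.ndarray
    phi_scale: np.ndarray
    loglik: np.ndarray
    config: SamplerConfig
    fingerprint: str
    runtime_s: float = 0.0

    @property
    def spec(self) -> ModelSpec:
        return get_model(self.model)

    @property
    def n_subjects(self) -> int:
        return self.theta.shape[2]

    def pooled_theta(self) -> np.ndarray:
        """(chains*draws, subjects, params)."""
        c, d, s, p = self.theta.shape
        return self.theta.reshape(c * d, s, p)

    def pooled_phi_loc(self) -> np.ndarray:
        c, d, p = self.phi_loc.shape
        return self.phi_loc.reshape(c * d, p)

    def population_means(self) -> dict[str, float]:
        pooled = self.pooled_phi_loc()
        return {n: float(pooled[:, i].mean()) for i, n in enumerate(self.param_names)}

    def population_ci(self, prob: float = 0.95) -> dict[str, tuple[float, float]]:
        pooled = self.pooled_phi_loc()
        a = 100 * (1 - prob) / 2
        return {
            n: tuple(np.percentile(pooled[:, i], [a, 100 - a]))
            for i, n in enumerate(self.param_names)
        }

    def subject_posterior_means(self) -> pd.DataFrame:
        pooled = self.pooled_theta().mean(axis=0)  # (subjects, params)
        return pd.DataFrame(pooled, index=self.subject_ids, columns=self.param_names)

    def rhat(self, split: bool = False) -> pd.DataFrame:
        """Gelman-Rubin statistic for every population and subject parameter."""
        from .diagnostics import gelman_rubin

        rows = []
        for i, n in enumerate(self.param_names):
            rows.append(("population", n, gelman_rubin(self.phi_loc[:, :, i], split=split)))
        for s, pid in enumerate(self.subject_ids):
            for i, n in enumerate(self.param_names):
                rows.append(
                    (str(pid), n, gelman_rubin(self.theta[:, :, s, i], split=split))
                )
        return pd.DataFrame(rows, columns=["level", "parameter", "rhat"])

    def max_rhat(self, split: bool = False) -> float:
        r = self.rhat(split=split)["rhat"]
        return float(np.nanmax(r.to_numpy()))

    def summary(self) -> pd.DataFrame:
        pooled = self.pooled_phi_loc()
        ci = self.population_ci()
        rows = []
        for i, n in enumerate(self.param_names):
            lo, hi = ci[n]
            rows.append(
                {
                    "parameter": n,
                    "mean": pooled[:, i].mean(),
                    "sd": pooled[:, i].std(ddof=1),
                    "ci2.5": lo,
                    "ci97.5": hi,
                }
            )
        return pd.DataFrame(rows)

    def banova_table(self, base_param: str) -> pd.DataFrame:
        """Participants x design cells table of posterior means for one
        cell-split parameter — the input to the BANOVA stage."""
        if base_param not in self.spec.split:
            raise ValueError(f"{base_param!r} is not cell-split in model {self.model!r}")
        means = self.subject_posterior_means()
        cols = {}
        for p, d in CELLS:
            cols[f"{p}.{d}"] = means[f"{base_param}[{p},{d}]"].to_numpy()
        return pd.DataFrame(cols, index=means.index)

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(
            path / "draws.npz",
            theta=self.theta,
            phi_loc=self.phi_loc,
            phi_scale=self.phi_scale,
            loglik=self.loglik,
        )
        manifest = {
            "model": self.model,
            "param_names": list(self.param_names),
            "subject_ids": [str(s) for s in self.subject_ids],
            "config": asdict(self.config),
            "fingerprint": self.fingerprint,
        }  # runtime intentionally omitted: manifests are reproducible byte for byte
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path) -> "PosteriorFit":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        arrs = np.load(path / "draws.npz")
        return cls(
            model=manifest["model"],
            param_names=tuple(manifest["param_names"]),
            subject_ids=manifest["subject_ids"],
            theta=arrs["theta"],
            phi_loc=arrs["phi_loc"],
            phi_scale=arrs["phi_scale"],
            loglik=arrs["loglik"],
            config=SamplerConfig(**manifest["config"]),
            fingerprint=manifest["fingerprint"],
            runtime_s=manifest.get("runtime_s", 0.0),
        )


# ---------------------------------------------------------------------------
# sampler


def _pick_pairs(rng, m):
    """For each chain pick two distinct other chains (DE difference pair)."""
    r1 = np.empty(m, dtype=np.int64)
    r2 = np.empty(m, dtype=np.int64)
    for c in range(m):
        a, b = rng.choice(m - 1, size=2, replace=False)
        r1[c] = a if a < c else a + 1
        r2[c] = b if b < c else b + 1
    return r1, r2


def sample_posterior(
    data,
    spec: ModelSpec | str,
    config: SamplerConfig = DESK_CONFIG,
    progress: bool = False,
) -> PosteriorFit:
    """Fit the hierarchical LBA model to preprocessed, coded trials.

    ``data`` is either a coded trial DataFrame or a list of
    :class:`SubjectData`. Deterministic under a fixed ``config.seed``.
    """
    if isinstance(spec, str):
        spec = get_model(spec)
    if isinstance(data, pd.DataFrame):
        data = prepare_subject_data(data)
    if len(data) < 2:
        raise ValueError("hierarchical estimation needs at least 2 subjects")

    rng = np.random.default_rng(config.seed)
    truncated = config.drift_convention == "truncated"
    m = config.n_chains
    S = len(data)
    d = spec.n_free
    lb = spec.lower_bounds()
    mu0, sd0 = spec.prior_loc_sd()
    gamma_s = 2.38 / np.sqrt(2.0 * d)
    gamma_p = 2.38 / np.sqrt(2.0 * 2 * d)
    gamma_f = 2.38 / np.sqrt(2.0 * (S * d + 2 * d))

    t_start = time.time()

    # ---- initialization
    theta = np.empty((m, S, d))
    cur_ll = np.empty((m, S))
    if config.init == "map":
        # start every chain in a small cloud around each subject's
        # penalized-likelihood mode; the ensemble then only has to mix
        # locally instead of first collapsing from prior dispersion
        maps = np.empty((S, d))
        for s, sd_ in enumerate(data):
            maps[s] = _subject_map(sd_, spec, mu0, sd0, lb, truncated)
        phi_loc = maps.mean(axis=0) + rng.normal(0.0, 0.02, size=(m, d))
        phi_scale = np.clip(
            maps.std(axis=0, ddof=1) + np.abs(rng.normal(0.0, 0.02, size=(m, d))),
            0.05,
            None,
        )
        phi_loc = np.where(
            np.isfinite(lb), np.maximum(phi_loc, lb + 1e-3), phi_loc
        )
    else:
        phi_loc = _truncnorm_draw(rng, mu0, sd0, lb, (m, d))
        phi_scale = np.clip(np.abs(rng.normal(0.0, 1.0, size=(m, d))), 0.05, None)
    for s, sd_ in enumerate(data):
        for c in range(m):
            ok = False
            for _ in range(200):
                if config.init == "map":
                    cand = maps[s] + rng.normal(0.0, 0.05, size=d)
                    cand = np.where(np.isfinite(lb), np.maximum(cand, lb + 1e-4), cand)
                else:
                    cand = _truncnorm_draw(rng, mu0, sd0, lb, d)
                ll = _fast.subject_loglik(
                    spec.expand_many(cand)[0], sd_.rt, sd_.resp, sd_.cell, truncated
                )
                if np.isfinite(ll):
                    theta[c, s] = cand
                    cur_ll[c, s] = ll
                    ok = True
                    break
            if not ok:
                raise InitializationError(
                    f"could not initialize chain {c} for subject {sd_.participant_id}"
                )

    def subj_prior(th, loc, scale):
        # th, loc, scale: (m, d) -> (m,)
        return truncnorm_logpdf(th, loc, scale, lb).sum(axis=1)

    def phi_target_dim(th, loc, scale):
        """Per-dimension population target for chains' states ``th``
        (k, S, d) under (loc, scale) (k, d). Conditional on theta the
        (loc_d, scale_d) pairs are independent across d, so each dimension
        is a valid 2-parameter Metropolis block."""
        t1 = truncnorm_logpdf(th, loc[:, None, :], scale[:, None, :], lb).sum(axis=1)
        t2 = truncnorm_logpdf(loc, mu0, sd0, lb)
        t3 = halfnorm_logpdf(scale)
        return t1 + t2 + t3

    iA = spec.param_names.index("A")
    iB = [i for i, n in enumerate(spec.param_names) if n.startswith("B")]

    n_stored = config.n_sample // config.thin
    out_theta = np.empty((m, n_stored, S, d))
    out_loc = np.empty((m, n_stored, d))
    out_scale = np.empty((m, n_stored, d))
    out_ll = np.empty((m, n_stored, S))
    store_i = 0

    total_iter = config.n_burn + config.n_sample
    for it in range(total_iter):
        burn = it < config.n_burn

        # ---- subject block updates (several DE sweeps with randomized
        # step scale; the difference vector tracks the posterior's
        # correlation structure, the scale draw avoids periodic moves)
        for s, sd_ in enumerate(data):
            for sweep in range(config.subject_sweeps):
                r1, r2 = _pick_pairs(rng, m)
                # crossover: every other sweep updates a random subset of
                # dimensions with a correspondingly larger step, which
                # beats the d-dimensional random-walk scaling on weakly
                # coupled coordinates
                if sweep % 2 == 1:
                    mask = rng.uniform(size=d) < rng.choice((0.3, 0.6))
                    if not mask.any():
                        mask[rng.integers(d)] = True
                    g = 2.38 / np.sqrt(2.0 * mask.sum()) * rng.uniform(0.5, 1.0)
                else:
                    mask = np.ones(d, dtype=bool)
                    g = gamma_s * rng.uniform(0.5, 1.0)
                step = (
                    g * (theta[r1, s, :] - theta[r2, s, :])
                    + rng.normal(0.0, config.jitter_sd, size=(m, d))
                ) * mask
                prop = theta[:, s, :] + step
                ll_prop = _fast.chains_loglik(
                    spec.expand_many(prop), sd_.rt, sd_.resp, sd_.cell, truncated
                )
                logr = (
                    ll_prop
                    + subj_prior(prop, phi_loc, phi_scale)
                    - cur_ll[:, s]
                    - subj_prior(theta[:, s, :], phi_loc, phi_scale)
                )
                acc = np.log(rng.uniform(size=m)) < logr
                theta[acc, s, :] = prop[acc]
                cur_ll[acc, s] = ll_prop[acc]

        # ---- migration (burn-in only): cyclic subject-state exchange
        if burn and rng.uniform() < config.migration_prob:
            k = int(rng.integers(2, max(3, m // 2)))
            sel = rng.choice(m, size=k, replace=False)
            src = np.roll(sel, 1)
            for s in range(S):
                pr_dst = subj_prior(theta[sel, s, :], phi_loc[sel], phi_scale[sel])
                pr_src = subj_prior(theta[src, s, :], phi_loc[sel], phi_scale[sel])
                logr = cur_ll[src, s] + pr_src - cur_ll[sel, s] - pr_dst
                acc = np.log(rng.uniform(size=k)) < logr
                theta[sel[acc], s, :] = theta[src[acc], s, :]
                cur_ll[sel[acc], s] = cur_ll[src[acc], s]

        # ---- population block updates: one (loc_d, scale_d) pair per
        # dimension, proposed for all dimensions at once and accepted
        # independently (the blocks factorize conditional on theta)
        for _ in range(config.phi_sweeps):
            r1, r2 = _pick_pairs(rng, m)
            g = gamma_p * rng.uniform(0.5, 1.0)
            prop_loc = (
                phi_loc
                + g * (phi_loc[r1] - phi_loc[r2])
                + rng.normal(0.0, config.jitter_sd, size=(m, d))
            )
            prop_scale = (
                phi_scale
                + g * (phi_scale[r1] - phi_scale[r2])
                + rng.normal(0.0, config.jitter_sd, size=(m, d))
            )
            logr = phi_target_dim(theta, prop_loc, prop_scale) - phi_target_dim(
                theta, phi_loc, phi_scale
            )
            acc = np.log(rng.uniform(size=(m, d))) < logr
            phi_loc[acc] = prop_loc[acc]
            phi_scale[acc] = prop_scale[acc]

        # ---- start-point ridge move: per subject, shift A while shifting
        # every B oppositely so each boundary b = A + B stays fixed. The
        # likelihood constrains b tightly but A only weakly, and A is
        # shared across cells, so this is the slowest direction for
        # coordinate-blocked proposals; a symmetric 1-d move along it
        # mixes the (A, B) trade-off directly.
        for s, sd_ in enumerate(data):
            for _ in range(2):
                delta = rng.normal(0.0, rng.uniform(0.05, 0.3), size=m)
                prop = theta[:, s, :].copy()
                prop[:, iA] += delta
                for i in iB:
                    prop[:, i] -= delta
                ll_prop = _fast.chains_loglik(
                    spec.expand_many(prop), sd_.rt, sd_.resp, sd_.cell, truncated
                )
                logr = (
                    ll_prop
                    + subj_prior(prop, phi_loc, phi_scale)
                    - cur_ll[:, s]
                    - subj_prior(theta[:, s, :], phi_loc, phi_scale)
                )
                acc = np.log(rng.uniform(size=m)) < logr
                theta[acc, s, :] = prop[acc]
                cur_ll[acc, s] = ll_prop[acc]

        # ---- hierarchical ridge move: the same A-vs-B exchange applied to
        # every subject and the population locations at once (all
        # boundaries b stay fixed). This mixes the collective trade-off
        # that individual-subject moves cross only diffusively.
        delta = rng.normal(0.0, rng.uniform(0.05, 0.3), size=m)
        prop_theta = theta.copy()
        prop_theta[:, :, iA] += delta[:, None]
        for i in iB:
            prop_theta[:, :, i] -= delta[:, None]
        prop_loc = phi_loc.copy()
        prop_loc[:, iA] += delta
        for i in iB:
            prop_loc[:, i] -= delta
        ll_prop = np.empty((m, S))
        for s, sd_ in enumerate(data):
            ll_prop[:, s] = _fast.chains_loglik(
                spec.expand_many(prop_theta[:, s, :]), sd_.rt, sd_.resp, sd_.cell, truncated
            )
        t_prop = ll_prop.sum(axis=1) + phi_target_dim(
            prop_theta, prop_loc, phi_scale
        ).sum(axis=1)
        t_cur = cur_ll.sum(axis=1) + phi_target_dim(theta, phi_loc, phi_scale).sum(axis=1)
        acc = np.log(rng.uniform(size=m)) < t_prop - t_cur
        theta[acc] = prop_theta[acc]
        phi_loc[acc] = prop_loc[acc]
        cur_ll[acc] = ll_prop[acc]

        # ---- full-state DE move: shift every subject's theta and the
        # population state together along a between-chain difference.
        # Needed because shrinkage couples all subjects to the chain's
        # (A, t0, B) region, a ridge that blockwise moves cross only slowly.
        r1, r2 = _pick_pairs(rng, m)
        g = gamma_f * rng.uniform(0.5, 1.0)
        jit = config.jitter_sd
        prop_theta = theta + g * (theta[r1] - theta[r2]) + rng.normal(0.0, jit, theta.shape)
        prop_loc = phi_loc + g * (phi_loc[r1] - phi_loc[r2]) + rng.normal(0.0, jit, (m, d))
        prop_scale = (
            phi_scale + g * (phi_scale[r1] - phi_scale[r2]) + rng.normal(0.0, jit, (m, d))
        )
        ll_prop = np.empty((m, S))
        for s, sd_ in enumerate(data):
            ll_prop[:, s] = _fast.chains_loglik(
                spec.expand_many(prop_theta[:, s, :]), sd_.rt, sd_.resp, sd_.cell, truncated
            )
        t_prop = (
            ll_prop.sum(axis=1)
            + phi_target_dim(prop_theta, prop_loc, prop_scale).sum(axis=1)
        )
        t_cur = (
            cur_ll.sum(axis=1)
            + phi_target_dim(theta, phi_loc, phi_scale).sum(axis=1)
        )
        acc = np.log(rng.uniform(size=m)) < t_prop - t_cur
        theta[acc] = prop_theta[acc]
        phi_loc[acc] = prop_loc[acc]
        phi_scale[acc] = prop_scale[acc]
        cur_ll[acc] = ll_prop[acc]

        # ---- population migration (burn-in only): chains adopt another
        # chain's (loc_d, scale_d), judged under their own subjects
        if burn and rng.uniform() < config.migration_prob:
            k = int(rng.integers(2, max(3, m // 2)))
            sel = rng.choice(m, size=k, replace=False)
            src = np.roll(sel, 1)
            loc_src, scale_src = phi_loc[src].copy(), phi_scale[src].copy()
            t_dst = phi_target_dim(theta[sel], phi_loc[sel], phi_scale[sel])
            t_src = phi_target_dim(theta[sel], loc_src, scale_src)
            acc = np.log(rng.uniform(size=(k, d))) < t_src - t_dst
            phi_loc[sel] = np.where(acc, loc_src, phi_loc[sel])
            phi_scale[sel] = np.where(acc, scale_src, phi_scale[sel])

        # ---- storage
        if not burn:
            j = it - config.n_burn + 1
            if j % config.thin == 0 and store_i < n_stored:
                out_theta[:, store_i] = theta
                out_loc[:, store_i] = phi_loc
                out_scale[:, store_i] = phi_scale
                out_ll[:, store_i] = cur_ll
                store_i += 1
        if progress and (it + 1) % 200 == 0:
            print(f"  iter {it + 1}/{total_iter}", flush=True)

    return PosteriorFit(
        model=spec.name,
        param_names=spec.param_names,
        subject_ids=[s.participant_id for s in data],
        theta=out_theta,
        phi_loc=out_loc,
        phi_scale=out_scale,
        loglik=out_ll,
        config=config,
        fingerprint=data_fingerprint(data),
        runtime_s=time.time() - t_start,
    )
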