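"""Numba kernels for the LBA likelihood.

These are the hot loops used by the DE-MCMC sampler. The public, scipy-based
reference implementations live in :mod:`emolba.lba`; tests cross-check the two.
"""

import math

import numpy as np
from numba import njit

SQRT2 = math.sqrt(2.0)
INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)
LOG_FLOOR = -700.0  # per-trial log-density floor before summation
_A_EPS = 1e-6  # below this, use the fixed-start-point limit forms


@njit(cache=True, fastmath=True)
def _phi(x):
    return INV_SQRT2PI * math.exp(-0.5 * x * x)


@njit(cache=True, fastmath=True)
def _Phi(x):
    return 0.5 * (1.0 + math.erf(x / SQRT2))


@njit(cache=True, fastmath=True)
def lba_cdf_raw(t, A, b, v, sv):
    """Defective finishing-time CDF (negative drifts never finish)."""
    if t <= 0.0:
        return 0.0
    ts = t * sv
    if ts < 1e-12:
        return 0.0
    if A < _A_EPS:
        # start point pinned at 0: P(finish <= t) = P(drift >= b/t)
        return _Phi((t * v - b) / ts)
    z1 = (b - A - t * v) / ts
    z2 = (b - t * v) / ts
    F = (
        1.0
        + (b - A - t * v) / A * _Phi(z1)
        - (b - t * v) / A * _Phi(z2)
        + ts / A * (_phi(z1) - _phi(z2))
    )
    if F < 0.0:
        return 0.0
    if F > 1.0:
        return 1.0
    return F


@njit(cache=True, fastmath=True)
def lba_pdf_raw(t, A, b, v, sv):
    """Defective finishing-time density."""
    if t <= 0.0:
        return 0.0
    ts = t * sv
    if ts < 1e-12:
        return 0.0
    if A < _A_EPS:
        z = (t * v - b) / ts
        return b / (t * ts) * _phi(z)
    z1 = (b - A - t * v) / ts
    z2 = (b - t * v) / ts
    f = (-v * _Phi(z1) + sv * _phi(z1) + v * _Phi(z2) - sv * _phi(z2)) / A
    return f if f > 0.0 else 0.0


@njit(cache=True, fastmath=True)
def defective_density_raw(td, A, b, v_win, v_lose, sv, truncated):
    """Joint density of (choice, decision time td): winner pdf x loser survivor.

    Under the truncated convention each accumulator's distribution is
    renormalised by P(drift > 0) so every trial terminates.
    """
    if td <= 0.0:
        return 0.0
    fw = lba_pdf_raw(td, A, b, v_win, sv)
    Fl = lba_cdf_raw(td, A, b, v_lose, sv)
    if truncated:
        pw = _Phi(v_win / sv)
        pl = _Phi(v_lose / sv)
        if pw < 1e-300 or pl < 1e-300:
            return 0.0
        fw = fw / pw
        Fl = Fl / pl
        if Fl > 1.0:
            Fl = 1.0
    dens = fw * (1.0 - Fl)
    return dens if dens > 0.0 else 0.0


@njit(cache=True, fastmath=True)
def _trial_logdens(rt, resp, A, b, vn, va, sv, t0, truncated):
    if resp == 0:
        dens = defective_density_raw(rt - t0, A, b, vn, va, sv, truncated)
    else:
        dens = defective_density_raw(rt - t0, A, b, va, vn, sv, truncated)
    if dens < 1e-304:
        return LOG_FLOOR
    lg = math.log(dens)
    return lg if lg > LOG_FLOOR else LOG_FLOOR


@njit(cache=True, fastmath=True)
def subject_loglik(cellpars, rt, resp, cell, truncated):
    """Log-likelihood of one subject's trials under per-cell LBA parameters.

    cellpars: (n_cells, 6) columns [A, b, v_norm, v_aberrant, sv, t0].
    resp: 0 = normative response, 1 = aberrant.
    """
    total = 0.0
    for i in range(rt.shape[0]):
        k = cell[i]
        A = cellpars[k, 0]
        b = cellpars[k, 1]
        if A < 0.0 or b <= A or cellpars[k, 4] <= 0.0 or cellpars[k, 5] < 0.0:
            return -np.inf
        total += _trial_logdens(
            rt[i], resp[i], A, b, cellpars[k, 2], cellpars[k, 3],
            cellpars[k, 4], cellpars[k, 5], truncated,
        )
    return total


@njit(cache=True, fastmath=True)
def chains_loglik(cellpars, rt, resp, cell, truncated):
    """subject_loglik evaluated for a stack of parameter states.

    cellpars: (n_states, n_cells, 6); returns (n_states,).
    """
    m = cellpars.shape[0]
    out = np.empty(m)
    for c in range(m):
        out[c] = subject_loglik(cellpars[c], rt, resp, cell, truncated)
    return out
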