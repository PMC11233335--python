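"""Closed-form LBA distributions against Monte-Carlo, quadrature and
finite-difference oracles, plus the defective-likelihood contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import kstest, norm

from emolba.lba import (
    AccumulatorParams,
    CellParams,
    ChoiceRT,
    ParameterDomainError,
    dataset_loglik,
    defective_density,
    finish_time_cdf,
    finish_time_pdf,
    response_probability,
    simulate_trials,
)

from conftest import lba_param_grid


def mc_cdf(t_grid, acc, n=200_000, seed=0):
    """Monte-Carlo finishing-time CDF oracle (defective convention)."""
    r = np.random.default_rng(seed)
    start = r.uniform(0, max(acc.A, 1e-12), size=n)
    drift = r.normal(acc.mean_v, acc.sv, size=n)
    with np.errstate(divide="ignore"):
        times = np.where(drift > 0, (acc.b - start) / drift, np.inf)
    est = np.array([(times <= t).mean() for t in t_grid])
    se = np.sqrt(est * (1 - est) / n)
    return est, se


class TestFinishTimeCdf:
    def test_zero_at_t0_and_monotone(self, typical_acc):
        assert finish_time_cdf(0.0, typical_acc) == 0.0
        ts = np.linspace(0.01, 10, 300)
        vals = finish_time_cdf(ts, typical_acc)
        assert np.all(np.diff(vals) >= -1e-12)
        assert np.all((vals >= 0) & (vals <= 1))

    def test_degenerate_start_point_half(self):
        # A -> 0 with b = 1, v = 1, sv = 1 at t = 1: Phi(0) = 1/2
        acc = AccumulatorParams(A=1e-9, B=1.0, mean_v=1.0, sv=1.0, t0=0.0)
        assert finish_time_cdf(1.0, acc, "defective") == pytest.approx(0.5, abs=1e-6)

    def test_limits_by_convention(self, typical_acc):
        # the limit is approached as P(0 < drift < b/t) ~ phi(v/sv) * b/t
        big = 1e6
        assert finish_time_cdf(big, typical_acc, "truncated") == pytest.approx(1.0, abs=1e-5)
        assert finish_time_cdf(big, typical_acc, "defective") == pytest.approx(
            norm.cdf(typical_acc.mean_v / typical_acc.sv), abs=1e-5
        )

    def test_matches_monte_carlo_oracle(self):
        acc = AccumulatorParams(A=1.0, B=1.0, mean_v=2.0, sv=1.0, t0=0.0)
        t_grid = [0.3, 0.6, 1.0, 2.0, 4.0]
        est, se = mc_cdf(t_grid, acc, n=1_000_000, seed=42)
        closed = finish_time_cdf(np.array(t_grid), acc, "defective")
        assert np.all(np.abs(closed - est) < 3 * se + 1e-6)

    @pytest.mark.parametrize("p", lba_param_grid())
    def test_oracle_equivalence_grid(self, p):
        acc = AccumulatorParams(A=p["A"], B=p["B"], mean_v=p["vn"], sv=p["sv"], t0=0.0)
        t_grid = [0.5, 1.5, 3.0]
        est, se = mc_cdf(t_grid, acc, n=100_000, seed=7)
        closed = finish_time_cdf(np.array(t_grid), acc, "defective")
        assert np.all(np.abs(closed - est) < 3 * se + 1e-3)

    def test_degenerate_limit_of_small_A(self):
        # as A -> 0 the cdf converges to the fixed-start form
        fixed = lambda t, b, v, sv: norm.cdf((t * v - b) / (t * sv))
        for A in (1e-7, 1e-9):
            acc = AccumulatorParams(A=A, B=2.0, mean_v=1.5, sv=1.0, t0=0.0)
            for t in (0.5, 1.0, 3.0):
                assert finish_time_cdf(t, acc, "defective") == pytest.approx(
                    fixed(t, acc.b, 1.5, 1.0), abs=1e-4
                )


class TestFinishTimePdf:
    def test_zero_at_origin(self, typical_acc):
        assert finish_time_pdf(0.0, typical_acc) == 0.0
        assert finish_time_pdf(-1.0, typical_acc) == 0.0

    def test_matches_cdf_finite_differences(self, typical_acc):
        h = 1e-4
        for t in (0.2, 0.5, 1.0, 2.0):
            num = (
                finish_time_cdf(t + h, typical_acc) - finish_time_cdf(t - h, typical_acc)
            ) / (2 * h)
            assert finish_time_pdf(t, typical_acc) == pytest.approx(num, abs=1e-5)

    def test_integrates_to_termination_probability(self, typical_acc):
        total, _ = quad(lambda t: finish_time_pdf(t, typical_acc, "defective"), 0, np.inf)
        assert total == pytest.approx(norm.cdf(typical_acc.mean_v), abs=1e-6)
        total_t, _ = quad(lambda t: finish_time_pdf(t, typical_acc, "truncated"), 0, np.inf)
        assert total_t == pytest.approx(1.0, abs=1e-6)


class TestParameterDomain:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(A=-0.1, B=1), dict(A=1, B=0.0), dict(A=1, B=1, sv=0.0), dict(A=1, B=1, t0=-0.1)],
    )
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(ParameterDomainError):
            AccumulatorParams(mean_v=1.0, **{"sv": 1.0, "t0": 0.3, **kwargs})

    def test_cell_requires_shared_nuisance_parameters(self):
        a = AccumulatorParams(A=1, B=1, mean_v=2, t0=0.3)
        b = AccumulatorParams(A=1, B=1, mean_v=1, t0=0.4)
        with pytest.raises(ParameterDomainError):
            CellParams(normative=a, aberrant=b)


class TestDefectiveDensity:
    def test_zero_when_rt_within_nondecision_time(self, typical_cell):
        t0 = typical_cell.normative.t0
        assert defective_density(ChoiceRT("normative", t0 - 0.01), typical_cell) == 0.0
        assert defective_density(ChoiceRT("normative", t0), typical_cell) == 0.0

    def test_identical_accumulators_split_evenly(self):
        cell = CellParams.make(A=1.5, B=1.5, mean_v_normative=2.0, mean_v_aberrant=2.0)
        p_norm = response_probability(cell, "normative")
        p_ab = response_probability(cell, "aberrant")
        assert p_norm == pytest.approx(p_ab, abs=1e-6)
        assert p_norm == pytest.approx(0.5, abs=1e-4)

    @pytest.mark.parametrize("convention", ["truncated", "defective"])
    @pytest.mark.parametrize("p", lba_param_grid())
    def test_normalization(self, p, convention):
        cell = CellParams.make(
            A=p["A"], B=p["B"], mean_v_normative=p["vn"],
            mean_v_aberrant=p["va"], sv=p["sv"], t0=p["t0"],
        )
        total = response_probability(cell, "normative", convention) + response_probability(
            cell, "aberrant", convention
        )
        if convention == "defective":
            # non-termination: both drifts negative
            total += norm.cdf(-p["vn"] / p["sv"]) * norm.cdf(-p["va"] / p["sv"])
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_matches_simulator(self, typical_cell):
        """Choice probabilities and the winning-RT distribution agree with
        10^5 simulated races (KS distance < 0.01)."""
        n = 100_000
        trials = simulate_trials(typical_cell, n, rng=123, censor_at=np.inf)
        rts = np.array([t.rt for t in trials])
        choices = np.array([t.choice == "normative" for t in trials])
        p_norm = response_probability(typical_cell, "normative")
        assert choices.mean() == pytest.approx(p_norm, abs=4 * np.sqrt(0.25 / n) + 2e-3)

        # conditional RT distribution of normative responses
        t0 = typical_cell.normative.t0
        grid = np.linspace(t0, 12.0, 4000)
        dens = np.array(
            [defective_density(ChoiceRT("normative", t), typical_cell) for t in grid]
        )
        cdf_grid = np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))
        cdf_grid = np.concatenate([[0.0], cdf_grid]) / p_norm
        stat = kstest(rts[choices], lambda x: np.interp(x, grid, cdf_grid)).statistic
        assert stat < 0.01

    def test_simulated_mean_rt_matches_quadrature(self, typical_cell):
        n = 100_000
        trials = simulate_trials(typical_cell, n, rng=5, censor_at=np.inf)
        sim_mean = np.mean([t.rt for t in trials])
        t0 = typical_cell.normative.t0
        integrand = lambda t, c: t * defective_density(ChoiceRT(c, t), typical_cell)
        quad_mean = sum(
            quad(integrand, t0, np.inf, args=(c,), limit=200)[0]
            for c in ("normative", "aberrant")
        )
        assert sim_mean == pytest.approx(quad_mean, rel=0.01)


class TestSimulator:
    def test_all_rts_exceed_t0(self, typical_cell, rng):
        trials = simulate_trials(typical_cell, 500, rng=rng)
        assert all(t.rt > typical_cell.normative.t0 for t in trials)

    def test_symmetric_race_is_fair(self):
        cell = CellParams.make(A=2, B=2, mean_v_normative=1.5, mean_v_aberrant=1.5)
        trials = simulate_trials(cell, 100_000, rng=9)
        p = np.mean([t.choice == "normative" for t in trials])
        assert abs(p - 0.5) < 3 * np.sqrt(0.25 / 100_000)

    def test_deterministic_under_seed(self, typical_cell):
        a = simulate_trials(typical_cell, 100, rng=77)
        b = simulate_trials(typical_cell, 100, rng=77)
        assert [(t.rt, t.choice) for t in a] == [(t.rt, t.choice) for t in b]

    def test_censoring_flags_slow_trials(self):
        cell = CellParams.make(A=2, B=6, mean_v_normative=0.6, mean_v_aberrant=0.1)
        trials = simulate_trials(cell, 2000, rng=3, censor_at=8.0)
        censored = [t for t in trials if t.censored]
        assert censored, "slow race should censor some trials at 8 s"
        assert all(t.rt == 8.0 for t in censored)
        assert all(t.rt <= 8.0 for t in trials)

    def test_defective_convention_censors_nonterminating_races(self):
        cell = CellParams.make(A=1, B=1, mean_v_normative=-3.0, mean_v_aberrant=-3.0)
        trials = simulate_trials(cell, 200, rng=4, convention="defective")
        assert all(t.censored for t in trials)


class TestDatasetLoglik:
    def test_empty_is_zero(self, typical_cell):
        assert dataset_loglik([], typical_cell) == 0.0

    def test_single_trial_additivity(self, typical_cell):
        trial = ChoiceRT("normative", 1.2)
        single = dataset_loglik([trial], typical_cell)
        assert single == pytest.approx(
            np.log(defective_density(trial, typical_cell)), abs=1e-12
        )
        assert dataset_loglik([trial, trial], typical_cell) == pytest.approx(
            2 * single, abs=1e-12
        )

    def test_unmapped_cell_raises(self, typical_cell):
        trial = ChoiceRT("normative", 1.2, cell="somewhere")
        with pytest.raises(KeyError):
            dataset_loglik([trial], {"elsewhere": typical_cell})

    def test_generating_parameters_beat_perturbed(self, typical_cell):
        """Log-likelihood at the generating parameters exceeds a +1 drift
        perturbation in >= 95/100 replicate datasets."""
        perturbed = CellParams.make(A=2.0, B=2.0, mean_v_normative=4.0, mean_v_aberrant=0.5)
        wins = 0
        for rep in range(100):
            trials = simulate_trials(typical_cell, 100, rng=1000 + rep)
            if dataset_loglik(trials, typical_cell) > dataset_loglik(trials, perturbed):
                wins += 1
        assert wins >= 95


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    v_lo=st.floats(0.5, 3.0),
    bump=st.floats(0.1, 2.0),
)
def test_normative_probability_monotone_in_drift(v_lo, bump):
    base = CellParams.make(A=2, B=2, mean_v_normative=v_lo, mean_v_aberrant=0.5)
    more = CellParams.make(A=2, B=2, mean_v_normative=v_lo + bump, mean_v_aberrant=0.5)
    assert response_probability(more, "normative") >= response_probability(
        base, "normative"
    ) - 1e-9
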