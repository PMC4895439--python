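"""Kinetic Monte Carlo generator: dwell statistics, protocols, determinism."""

import numpy as np
import pytest
from scipy import stats

import mechpath as mp
from mechpath.simulate import ParameterError


def equal_rate_network(n=6, alpha0=1.0, dx=0.2, gain=3.0):
    return mp.UnfoldingNetwork(
        elements=tuple(
            mp.Element(f"e{i}", gain, alpha0=alpha0, dx=dx) for i in range(n)
        )
    )


def chain_network(alphas, gain=4.3, dx=0.2):
    els = tuple(
        mp.Element(f"e{i}", gain, alpha0=a, dx=dx) for i, a in enumerate(alphas)
    )
    pres = {f"e{i}": (f"e{i-1}",) for i in range(1, len(alphas))}
    return mp.UnfoldingNetwork(elements=els, prerequisites=pres)


class TestDefaultNetwork:
    def test_six_elements_with_three_nm_steps_at_calibration_force(self, csp_network):
        assert len(csp_network.elements) == 6
        gains = csp_network.extension_gains_at(40.0)
        for g in gains.values():
            assert g == pytest.approx(19.0 / 6.0, abs=1e-9)
        assert csp_network.total_length_at(40.0) == pytest.approx(19.0, abs=1e-9)

    def test_total_length_increases_with_force(self, csp_network):
        # unfolded-chain elasticity: slight growth of the total with force
        assert (
            csp_network.total_length_at(20.0)
            < csp_network.total_length_at(40.0)
            < csp_network.total_length_at(60.0)
            < csp_network.total_length_at(80.0)
        )

    def test_single_element_single_step(self, single_element_network):
        assert len(single_element_network.elements) == 1
        path = mp.gillespie_clamp(single_element_network, 40.0, seed=0)
        assert len(path.elements) == 1 and path.completed

    @pytest.mark.parametrize("kw", [{"n_elements": 0}, {"total_length": -1.0}])
    def test_invalid_parameters(self, kw):
        with pytest.raises(ParameterError):
            mp.default_network(**kw)

    def test_cyclic_dependency_rejected(self):
        els = tuple(mp.Element(f"e{i}", 3.0, 1.0, 0.2) for i in range(2))
        with pytest.raises(ParameterError, match="cyclic"):
            mp.UnfoldingNetwork(
                elements=els, prerequisites={"e0": ("e1",), "e1": ("e0",)}
            )


class TestGillespieClamp:
    def test_single_element_dwell_mean_is_inverse_bell_rate(self):
        net = equal_rate_network(n=1, alpha0=0.5, dx=0.3)
        F = 30.0
        rate = 0.5 * np.exp(30.0 * 0.3 / mp.KT_ROOM)
        rng = np.random.default_rng(1)
        dwells = np.array(
            [mp.gillespie_clamp(net, F, rng).times[0] for _ in range(30000)]
        )
        se = dwells.std(ddof=1) / np.sqrt(dwells.size)
        assert abs(dwells.mean() - 1.0 / rate) < 3 * se

    def test_dwell_distribution_is_exponential(self):
        # Kolmogorov-Smirnov against the analytic total rate, alpha = 0.01
        net = equal_rate_network(n=3, alpha0=0.8, dx=0.2)
        F = 20.0
        total = 3 * 0.8 * np.exp(20.0 * 0.2 / mp.KT_ROOM)
        rng = np.random.default_rng(2)
        first_dwells = np.array(
            [mp.gillespie_clamp(net, F, rng).times[0] for _ in range(10000)]
        )
        ks = stats.kstest(first_dwells, "expon", args=(0, 1.0 / total))
        assert ks.pvalue > 0.01

    def test_strict_chain_forces_order(self):
        net = chain_network([2.0, 1.0, 3.0, 1.5])
        for s in range(20):
            path = mp.gillespie_clamp(net, 40.0, seed=s)
            assert path.elements == ["e0", "e1", "e2", "e3"]

    def test_equal_independent_rates_visit_all_orderings(self):
        # 6 exchangeable elements: every one of the 720 orderings has
        # probability 1/720, so 50k paths cover them all (miss prob ~ 1e-27)
        net = equal_rate_network(n=6)
        rng = np.random.default_rng(3)
        seen = {tuple(mp.gillespie_clamp(net, 10.0, rng).elements) for _ in range(50000)}
        assert len(seen) == 720

    def test_mfpt_matches_absorption_time_of_markov_chain(self):
        # oracle: expected absorption time by recursion over the 2^n subset
        # lattice, E[T_S] = 1/R_S + sum_i (r_i/R_S) E[T_{S+i}]
        alphas = [0.9, 0.5, 1.7, 0.25, 1.1]
        dx = 0.2
        F = 25.0
        rates = np.array(alphas) * np.exp(F * dx / mp.KT_ROOM)
        n = len(alphas)
        expect = {}
        for size in range(n, -1, -1):
            for mask in range(1 << n):
                if bin(mask).count("1") != size:
                    continue
                folded = [i for i in range(n) if not (mask >> i) & 1]
                if not folded:
                    expect[mask] = 0.0
                    continue
                R = rates[folded].sum()
                expect[mask] = 1.0 / R + sum(
                    rates[i] / R * expect[mask | (1 << i)] for i in folded
                )
        analytic = expect[0]
        net = mp.UnfoldingNetwork(
            elements=tuple(
                mp.Element(f"e{i}", 3.0, alpha0=a, dx=dx) for i, a in enumerate(alphas)
            )
        )
        rng = np.random.default_rng(4)
        fpts = np.array(
            [mp.gillespie_clamp(net, F, rng).times[-1] for _ in range(4000)]
        )
        se = fpts.std(ddof=1) / np.sqrt(fpts.size)
        assert abs(fpts.mean() - analytic) < 3 * se

    def test_negative_force_rejected(self):
        with pytest.raises(ParameterError):
            mp.gillespie_clamp(equal_rate_network(), -1.0, seed=0)


class TestSimulateClamp:
    def test_noiseless_single_element_staircase(self):
        net = mp.default_network(n_elements=1)
        cfg = mp.SimConfig(force=40.0, duration=30.0, noise_sd=0.0)
        trace, path = mp.simulate_clamp(net, cfg, seed=5)
        levels = np.unique(trace.extension)
        assert levels.size == 2
        assert levels[0] == 0.0
        assert levels[1] == pytest.approx(net.total_length_at(40.0), abs=1e-9)

    def test_zero_rates_flat_trace(self):
        net = mp.UnfoldingNetwork(
            elements=(mp.Element("e", 19.0, alpha0=0.0, dx=0.2),)
        )
        cfg = mp.SimConfig(force=40.0, duration=2.0, noise_sd=0.0)
        trace, path = mp.simulate_clamp(net, cfg, seed=0)
        assert np.all(trace.extension == 0.0)
        assert trace.meta["truncated"] is True

    def test_truncation_flagged(self, csp_network):
        cfg = mp.SimConfig(force=20.0, duration=0.05, noise_sd=0.0)
        trace, path = mp.simulate_clamp(csp_network, cfg, seed=6)
        assert trace.meta["truncated"] == (not path.completed)

    def test_levels_non_decreasing_within_pulse(self, csp_network):
        cfg = mp.SimConfig(force=40.0, duration=10.0, noise_sd=0.0)
        trace, _ = mp.simulate_clamp(csp_network, cfg, seed=7)
        assert np.all(np.diff(trace.extension) >= 0)

    def test_fingerprint_appended(self, csp_network):
        cfg = mp.SimConfig(force=40.0, duration=2.0, include_fingerprint=True)
        trace, _ = mp.simulate_clamp(csp_network, cfg, seed=8)
        assert trace.force.max() == pytest.approx(150.0)
        assert trace.duration > 2.0


class TestSimulateRamp:
    def test_most_probable_unfolding_force_matches_analytic_mode(self):
        # single Bell barrier under a linear ramp: the first-passage force
        # density peaks at F* = (kT/dx) ln(r dx / (alpha0 kT))
        alpha0, dx, r = 0.05, 0.4, 100.0
        net = mp.UnfoldingNetwork(
            elements=(mp.Element("e", 19.0, alpha0=alpha0, dx=dx),)
        )
        rng = np.random.default_rng(9)
        forces = np.array(
            [
                min(r * mp.gillespie_ramp(net, r, rng).times[0], 300.0)
                for _ in range(10000)
            ]
        )
        kde = stats.gaussian_kde(forces)
        grid = np.linspace(forces.min(), forces.max(), 500)
        f_star_emp = grid[np.argmax(kde(grid))]
        f_star = (mp.KT_ROOM / dx) * np.log(r * dx / (alpha0 * mp.KT_ROOM))
        assert abs(f_star_emp - f_star) < 2.0

    def test_unfolding_force_increases_with_ramp_rate(self):
        net = mp.UnfoldingNetwork(
            elements=(mp.Element("e", 19.0, alpha0=0.05, dx=0.3),)
        )
        rng = np.random.default_rng(10)
        f20 = np.array(
            [min(20.0 * mp.gillespie_ramp(net, 20.0, rng).times[0], 300.0)
             for _ in range(2000)]
        )
        f800 = np.array(
            [min(800.0 * mp.gillespie_ramp(net, 800.0, rng).times[0], 300.0)
             for _ in range(2000)]
        )
        # stochastic dominance at the quartiles
        for q in (0.25, 0.5, 0.75):
            assert np.quantile(f800, q) > np.quantile(f20, q)

    def test_zero_rates_reach_cap_without_steps(self):
        net = mp.UnfoldingNetwork(
            elements=(mp.Element("e", 19.0, alpha0=0.0, dx=0.2),)
        )
        cfg = mp.SimConfig(
            protocol="ramp", force=None, ramp_rate=100.0, duration=4.0, noise_sd=0.0
        )
        trace, path = mp.simulate_ramp(net, cfg, seed=0)
        assert len(path.elements) == 0
        assert trace.force.max() == pytest.approx(300.0)
        assert np.all(trace.extension == 0.0)


class TestSimulateExtension:
    def test_no_unfolding_single_wlc_branch(self):
        net = mp.UnfoldingNetwork(
            elements=(mp.Element("e", 19.0, alpha0=0.0, dx=0.2),)
        )
        cfg = mp.SimConfig(
            protocol="extension", force=None, pull_speed=400.0, duration=0.09,
            noise_sd=0.0,
        )
        trace, path = mp.simulate_extension(net, cfg, seed=0)
        assert len(path.elements) == 0
        p = mp.WLCParams(Lc=cfg.handle_contour, rho=net.rho)
        x = np.minimum(trace.extension, 0.995 * cfg.handle_contour)
        np.testing.assert_allclose(trace.force, mp.wlc_force(x, p), rtol=1e-9)

    def test_single_domain_sawtooth_and_contour_increment(self):
        # one 19 nm-contour element: a force peak, relaxation, and a
        # post-unfolding WLC branch whose fitted contour length exceeds the
        # initial one by the configured gain (within 5%)
        net = mp.UnfoldingNetwork(
            elements=(mp.Element("e", 19.0, alpha0=0.07, dx=0.2),)
        )
        cfg = mp.SimConfig(
            protocol="extension", force=None, pull_speed=400.0, duration=0.14,
            noise_sd=0.0, sampling_rate=4000.0,
        )
        trace, path = mp.simulate_extension(net, cfg, seed=3)
        assert len(path.elements) == 1
        i_unfold = int(path.times[0] * cfg.sampling_rate) + 1
        # force drops at the unfolding event
        assert trace.force[i_unfold] < trace.force[i_unfold - 1]
        post = slice(i_unfold + 5, None)
        fit, _ = mp.fit_wlc(trace.extension[post], trace.force[post], rho=net.rho)
        increment = fit.Lc - cfg.handle_contour
        assert increment == pytest.approx(19.0, rel=0.05)


class TestEnsemble:
    def test_bit_reproducible_for_fixed_seed(self, csp_network):
        cfg = mp.SimConfig(force=40.0, n_traces=5, duration=3.0)
        tr1, gt1 = mp.generate_ensemble(csp_network, cfg, seed=42)
        tr2, gt2 = mp.generate_ensemble(csp_network, cfg, seed=42)
        for a, b in zip(tr1, tr2):
            np.testing.assert_array_equal(a.extension, b.extension)
        assert gt1.events.equals(gt2.events)

    def test_trace_count(self, csp_network):
        cfg = mp.SimConfig(force=40.0, n_traces=57, duration=0.5, noise_sd=0.0)
        traces, _ = mp.generate_ensemble(csp_network, cfg, seed=1)
        assert len(traces) == 57

    def test_ground_truth_step_lengths_conserve_total(self, csp_network):
        cfg = mp.SimConfig(force=40.0, n_traces=20, duration=15.0, noise_sd=0.0)
        _, gt = mp.generate_ensemble(csp_network, cfg, seed=2)
        done = gt.traces[~gt.traces["censored"].astype(bool)]
        total = csp_network.total_length_at(40.0)
        for _, row in done.iterrows():
            steps = gt.events.loc[
                gt.events["trace_id"] == row["trace_id"], "step_length"
            ]
            assert steps.sum() == pytest.approx(row["total_length"], abs=1e-9)
            assert row["total_length"] == pytest.approx(total, abs=1e-9)

    def test_multiplicity_spans_zero_to_four_at_forty_pn(self, csp_network):
        # heterogeneous unfolding: 0-4 resolvable intermediates at 40 pN
        rng = np.random.default_rng(11)
        counts = np.array(
            [
                mp.observed_multiplicity(
                    mp.gillespie_clamp(csp_network, 40.0, rng, t_max=10.0), 0.05
                )
                for _ in range(400)
            ]
        )
        assert counts.min() == 0
        assert counts.max() == 4
        assert np.unique(counts).size >= 4

    def test_nonsequential_orderings_after_nucleation(self, csp_network):
        rng = np.random.default_rng(12)
        orders = set()
        for _ in range(200):
            path = mp.gillespie_clamp(csp_network, 40.0, rng)
            assert path.elements[0] == "s5"  # nucleation is always first
            orders.add(tuple(path.elements[1:]))
        assert len(orders) > 5  # downstream order is stochastic
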