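"""MFPT rate fits, network reconstruction, and the pathway test."""

import numpy as np
import pandas as pd
import pytest

import mechpath as mp
from mechpath.kinetics import rate_vs_force, sequential_pathway_test

EVENT_COLS = [
    "trace_id",
    "step_index",
    "step_length",
    "cumulative_length",
    "dwell_before",
    "force_at_step",
    "t_step",
]


def table_from_rows(trace_rows, event_rows=None):
    events = pd.DataFrame(event_rows or [], columns=EVENT_COLS)
    return mp.EventTable(events=events, traces=pd.DataFrame(trace_rows))


def trace_row(tid, force, n_steps, fpt, censored=False):
    return {
        "trace_id": tid,
        "protocol": "clamp",
        "force_condition": force,
        "n_steps": n_steps,
        "n_intermediates": max(n_steps - 1, 0),
        "total_length": 19.0,
        "first_passage_time": fpt,
        "censored": censored,
    }


class TestRateVsForce:
    def test_two_point_log_linear_exact(self):
        # exact rates 1 and e at 10 / 20 pN: slope 1/10, intercept -1
        rows = [trace_row(f"a{i}", 10.0, 1, 1.0) for i in range(6)]
        rows += [trace_row(f"b{i}", 20.0, 1, np.exp(-1.0)) for i in range(6)]
        fit = rate_vs_force(table_from_rows(rows))
        assert fit.slope == pytest.approx(0.1, abs=1e-12)
        assert fit.intercept == pytest.approx(-1.0, abs=1e-12)
        assert fit.alpha0 == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_force_independent_rates_give_zero_dx(self):
        rng = np.random.default_rng(0)
        rows = []
        for F in (20.0, 40.0, 60.0):
            fpts = rng.exponential(2.0, 400)
            rows += [
                trace_row(f"F{F:g}_{i}", F, 1, fpt) for i, fpt in enumerate(fpts)
            ]
        fit = rate_vs_force(table_from_rows(rows))
        assert abs(fit.dx_eff) < 3 * abs(fit.slope_se) * fit.kT + 0.02

    def test_censored_traces_excluded_and_reported(self):
        rows = [trace_row(f"a{i}", 10.0, 1, 1.0) for i in range(6)]
        rows += [trace_row("a_c", 10.0, 1, np.nan, censored=True)]
        rows += [trace_row(f"b{i}", 20.0, 1, 0.5) for i in range(6)]
        fit = rate_vs_force(table_from_rows(rows))
        assert fit.censored_fraction[0] == pytest.approx(1 / 7)
        assert fit.n_uncensored[0] == 6

    def test_sparse_condition_dropped_with_warning(self):
        rows = [trace_row(f"a{i}", 10.0, 1, 1.0) for i in range(6)]
        rows += [trace_row(f"b{i}", 20.0, 1, 0.5) for i in range(6)]
        rows += [trace_row("c0", 30.0, 1, 0.2)]
        with pytest.warns(UserWarning, match="dropped"):
            fit = rate_vs_force(table_from_rows(rows))
        assert fit.forces.tolist() == [10.0, 20.0]

    def test_single_condition_rejected(self):
        rows = [trace_row(f"a{i}", 10.0, 1, 1.0) for i in range(6)]
        with pytest.raises(ValueError):
            rate_vs_force(table_from_rows(rows))

    def test_parameter_recovery_single_barrier(self, single_element_network):
        # ensembles from a one-barrier Bell generator: the zero-force rate
        # is recovered within its fitted 95% confidence interval
        rows = []
        root = np.random.SeedSequence(99)
        for F, ss in zip((20.0, 40.0, 60.0, 80.0), root.spawn(4)):
            rng = np.random.default_rng(ss)
            for i in range(400):
                path = mp.gillespie_clamp(single_element_network, F, rng)
                rows.append(trace_row(f"F{F:g}_{i}", F, 1, float(path.times[-1])))
        fit = rate_vs_force(table_from_rows(rows))
        lo, hi = fit.alpha0_ci95
        assert lo <= 0.07 <= hi
        assert fit.dx_eff == pytest.approx(0.2, abs=0.05)


def event_row(tid, idx, length, cum, dwell, t):
    return {
        "trace_id": tid,
        "step_index": idx,
        "step_length": length,
        "cumulative_length": cum,
        "dwell_before": dwell,
        "force_at_step": 40.0,
        "t_step": t,
    }


@pytest.fixture
def small_solution():
    """Clusters around 3 nm (C1) and 16 nm (C2)."""
    rng = np.random.default_rng(1)
    data = np.concatenate((rng.normal(3.0, 0.3, 50), rng.normal(16.0, 0.4, 50)))
    return mp.kmeans(data, k=2, n_replicas=50, seed=2)


class TestLabelStates:
    def test_single_step_trace_is_n_to_u(self, small_solution):
        table = table_from_rows(
            [trace_row("a", 40.0, 1, 2.0)],
            [event_row("a", 0, 16.0, 16.0, 2.0, 2.0)],
        )
        seqs = mp.label_states(table, small_solution)
        assert seqs[0].states == ["N", "U"]

    def test_two_step_trace_routes_through_first_cluster(self, small_solution):
        table = table_from_rows(
            [trace_row("a", 40.0, 2, 3.0)],
            [
                event_row("a", 0, 3.1, 3.1, 1.0, 1.0),
                event_row("a", 1, 16.0, 19.1, 2.0, 3.0),
            ],
        )
        seqs = mp.label_states(table, small_solution)
        assert seqs[0].states == ["N", "C1", "U"]

    def test_unassignable_step_marked_outlier(self, small_solution):
        table = table_from_rows(
            [trace_row("a", 40.0, 2, 3.0)],
            [
                event_row("a", 0, 9.0, 9.0, 1.0, 1.0),  # far from both clusters
                event_row("a", 1, 16.0, 25.0, 2.0, 3.0),
            ],
        )
        seqs = mp.label_states(table, small_solution)
        assert seqs[0].states == ["N", "outlier", "U"]
        assert seqs[0].n_outliers == 1

    def test_five_step_trace_has_four_intermediates(self, small_solution):
        events = [
            event_row("a", i, 3.1, 3.1 * (i + 1), 0.5, 0.5 * (i + 1))
            for i in range(5)
        ]
        table = table_from_rows([trace_row("a", 40.0, 5, 2.5)], events)
        seqs = mp.label_states(table, small_solution)
        assert len(seqs[0].states) == 6  # N + 4 intermediates + U
        assert seqs[0].states[1:-1] == ["C1"] * 4


class TestBuildNetwork:
    def test_out_of_native_counts_equal_trace_count(self, small_solution):
        rows, events = [], []
        for i in range(8):
            rows.append(trace_row(f"t{i}", 40.0, 1, 1.0))
            events.append(event_row(f"t{i}", 0, 16.0, 16.0, 1.0, 1.0))
        for i in range(8, 13):
            rows.append(trace_row(f"t{i}", 40.0, 2, 2.0))
            events.append(event_row(f"t{i}", 0, 3.0, 3.0, 1.0, 1.0))
            events.append(event_row(f"t{i}", 1, 16.0, 19.0, 1.0, 2.0))
        net = mp.build_network(
            mp.label_states(table_from_rows(rows, events), small_solution),
            small_solution,
        )
        out_of_n = net.counts[
            (net.counts["origin"] == "N") & np.isclose(net.counts["force"], 40.0)
        ]["count"].sum()
        assert out_of_n == 13

    def test_all_single_step_traces_only_n_to_u(self, small_solution):
        rows = [trace_row(f"t{i}", 40.0, 1, 1.0) for i in range(5)]
        events = [event_row(f"t{i}", 0, 16.0, 16.0, 1.0, 1.0) for i in range(5)]
        net = mp.build_network(
            mp.label_states(table_from_rows(rows, events), small_solution)
        )
        assert set(zip(net.counts["origin"], net.counts["destiny"])) == {("N", "U")}
        assert net.counts["count"].sum() == 5

    def test_strict_chain_generator_yields_adjacent_transitions(self):
        # forced order + cumulative labelling: only C_i -> C_{i+1} appears
        net = mp.UnfoldingNetwork(
            elements=tuple(
                mp.Element(f"e{i}", 4.7, alpha0=0.5, dx=0.2) for i in range(4)
            ),
            prerequisites={f"e{i}": (f"e{i-1}",) for i in range(1, 4)},
        )
        rng = np.random.default_rng(3)
        rows, events = [], []
        z = net.fractional_extension(40.0)
        for i in range(40):
            path = mp.gillespie_clamp(net, 40.0, rng)
            rows.append(trace_row(f"t{i}", 40.0, 4, float(path.times[-1])))
            cum = 0.0
            prev = 0.0
            for j, t in enumerate(path.times):
                cum += 4.7 * z
                events.append(event_row(f"t{i}", j, 4.7 * z, cum, t - prev, t))
                prev = t
        data = np.array([e["cumulative_length"] for e in events])
        sol = mp.kmeans(data, k=4, n_replicas=50, seed=4)
        seqs = mp.label_states(table_from_rows(rows, events), sol, mode="cumulative")
        network = mp.build_network(seqs, sol)
        for _, row in network.counts.iterrows():
            if row["origin"].startswith("C") and row["destiny"].startswith("C"):
                a = int(row["origin"][1:])
                b = int(row["destiny"][1:])
                assert b == a + 1


class TestConnectivityRule:
    def _network(self, lengths):
        counts = pd.DataFrame(columns=["force", "origin", "destiny", "count"])
        occ = pd.DataFrame(columns=["force", "state", "count"])
        return mp.KineticNetwork(counts=counts, occurrences=occ, lengths=lengths)

    def test_short_long_pair_allowed(self):
        net = self._network({"N": 0.0, "C1": 3.0, "C5": 16.0})
        report = mp.check_connectivity_rule(net, L_total=19.0)
        assert ("C1", "C5") in report["allowed_pairs"]
        assert ("C5", "C1") in report["allowed_pairs"]

    def test_long_long_pair_flagged(self):
        counts = pd.DataFrame(
            [{"force": 40.0, "origin": "C5", "destiny": "C4", "count": 1}]
        )
        occ = pd.DataFrame(columns=["force", "state", "count"])
        net = mp.KineticNetwork(
            counts=counts,
            occurrences=occ,
            lengths={"N": 0.0, "C4": 13.0, "C5": 16.0},
        )
        report = mp.check_connectivity_rule(net, L_total=19.0)
        assert ("C5", "C4") in report["observed_violations"]

    def test_empty_network_empty_report(self):
        report = mp.check_connectivity_rule(self._network({"N": 0.0}), 19.0)
        assert report["allowed_pairs"] == []
        assert report["observed_violations"] == []


class TestHeterogeneityProfile:
    def test_all_single_step_means_zero(self):
        rows = [trace_row(f"t{i}", F, 1, 1.0) for F in (20.0, 40.0) for i in range(4)]
        prof = mp.heterogeneity_profile(table_from_rows(rows))
        assert np.allclose(prof["mean_intermediates"], 0.0)

    def test_counts_capped_at_four_plus(self):
        rows = [trace_row("a", 40.0, 7, 1.0), trace_row("b", 40.0, 3, 1.0)]
        prof = mp.heterogeneity_profile(table_from_rows(rows))
        assert prof.loc[0, "m4+"] == 1
        assert prof.loc[0, "m2"] == 1

    def test_force_modulation_of_default_generator(self, csp_network):
        # the emulated heterogeneity profile: more resolvable intermediates
        # at 40 pN than at 20 pN
        means = {}
        for F in (20.0, 40.0):
            rng = np.random.default_rng(17)
            counts = [
                mp.observed_multiplicity(
                    mp.gillespie_clamp(csp_network, F, rng, t_max=10.0), 0.05
                )
                for _ in range(250)
            ]
            means[F] = np.mean(counts)
        assert means[40.0] > means[20.0] + 0.5


class TestSequentialPathwayTest:
    def test_tail_detection_bounds(self):
        # a dwell must reach ~3 mean lifetimes to be seen when single-step
        # unfolding dominates: P = e^-3 < 0.05; two independent such dwells:
        # e^-6 < 0.05^2
        p1 = mp.tail_detection_probability(3.0, 1.0)
        assert p1 == pytest.approx(np.exp(-3), abs=1e-12)
        assert p1 < 0.05
        assert p1**2 == pytest.approx(np.exp(-6), abs=1e-12)
        assert p1**2 < 0.05**2

    def test_analytic_bounds_in_report(self):
        rows = [trace_row(f"t{i}", 40.0, 1, 1.0) for i in range(25)]
        report = sequential_pathway_test(
            table_from_rows(rows), t_res=0.05, n_mc=100, seed=0
        )
        assert report.analytic_bounds[2] == pytest.approx(0.0025)
        assert report.analytic_bounds[4] == pytest.approx(0.05**4)

    def test_insufficient_data_verdict(self):
        rows = [trace_row(f"t{i}", 40.0, 1, 1.0) for i in range(10)]
        report = sequential_pathway_test(
            table_from_rows(rows), t_res=0.05, n_mc=100, seed=0
        )
        assert report.verdict == "insufficient data"

    def test_rejects_multi_pathway_generator(self, csp_network):
        # bimodal multiplicity (fast sweeps + deep traps) cannot be matched
        # by any strict sequential chain
        rng = np.random.default_rng(23)
        rows = []
        for i in range(200):
            path = mp.gillespie_clamp(csp_network, 40.0, rng, t_max=10.0)
            m = mp.observed_multiplicity(path, 0.05)
            rows.append(trace_row(f"t{i}", 40.0, m + 1, 1.0))
        report = sequential_pathway_test(
            table_from_rows(rows), t_res=0.05, n_mc=500, seed=1
        )
        assert report.verdict == "sequential rejected"
        assert report.mc_pvalue < 0.01

    def test_type_i_control_under_true_sequential_chain(self):
        # data truly generated by a sequential chain with mostly
        # sub-resolution dwells: false rejection rate at the 0.01 level
        # stays within the nominal 5% over seeded datasets
        chain = mp.UnfoldingNetwork(
            elements=tuple(
                mp.Element(f"e{i}", 4.3, alpha0=a, dx=0.2)
                for i, a in enumerate([3.0, 8.0, 5.0, 12.0, 6.0, 9.0])
            ),
            prerequisites={f"e{i}": (f"e{i-1}",) for i in range(1, 6)},
        )
        rejections = 0
        n_datasets = 50
        for ds in range(n_datasets):
            rng = np.random.default_rng(np.random.SeedSequence([ds, 55]))
            rows = []
            for i in range(100):
                path = mp.gillespie_clamp(chain, 40.0, rng)
                m = mp.observed_multiplicity(path, 0.05)
                rows.append(trace_row(f"t{i}", 40.0, m + 1, 1.0))
            report = sequential_pathway_test(
                table_from_rows(rows), t_res=0.05, n_mc=300, seed=ds
            )
            rejections += report.verdict == "sequential rejected"
        assert rejections <= max(1, int(0.05 * n_datasets))
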