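"""MFPT rate analysis, kinetic-network reconstruction and the pathway test.

Three analyses act on the detected-event tables:

* **Rate versus force** -- the mean first-passage time (MFPT) to complete
  unfolding is averaged per clamp force (censored traces excluded, fraction
  reported); the average unfolding rate alpha(F) = 1/MFPT follows a near
  log-linear force dependence, so a weighted least-squares fit of
  ln alpha vs F yields the extrapolated zero-force rate alpha0 =
  exp(intercept) and an effective transition-state distance
  dx_eff = slope * kT.

* **Kinetic network** -- each detected step is labelled by its length
  cluster; a trace with steps (l1 .. ln) is read as the state sequence
  N -> C(l1) -> ... -> C(l_{n-1}) -> U (the final step completes unfolding).
  Transition counts per force reconstruct the empirical state graph, and the
  connectivity rule L(C_origin) + L(C_destiny) <= L(total) is audited over
  intermediate pairs (N and U are exempt: their lengths are 0 and ~L_total).

* **Sequential-pathway test** -- under a single sequential pathway whose
  intermediates are mostly too short-lived to detect, each intermediate is
  seen only when its exponential dwell falls in the distribution tail
  (probability p = exp(-t_res/tau) < 0.05 when t_res exceeds 3 mean
  lifetimes), so observing m intermediates has probability <= p**m.  The
  Monte Carlo version fits the per-stage detection probabilities of a strict
  sequential chain to the observed intermediate-multiplicity histogram
  (Poisson-binomial maximum likelihood) and measures goodness of fit by
  parametric bootstrap; a multiplicity histogram outside the reach of any
  sequential chain (e.g. simultaneous excesses of zero- and
  many-intermediate traces) rejects the sequential model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .cluster import ClusterSolution
from .trace import EventTable
from .wlc import KT_ROOM

__all__ = [
    "RateFit",
    "KineticNetwork",
    "StateSequence",
    "SequentialTestReport",
    "rate_vs_force",
    "label_states",
    "build_network",
    "check_connectivity_rule",
    "heterogeneity_profile",
    "sequential_pathway_test",
    "tail_detection_probability",
]


# ---------------------------------------------------------------------------
# MFPT rate analysis
# ---------------------------------------------------------------------------


@dataclass
class RateFit:
    """Result of the log-linear fit of inverse-MFPT rates versus force."""

    forces: np.ndarray  # pN
    alpha: np.ndarray  # 1/s, inverse MFPT per force
    alpha_se: np.ndarray  # 1/s, standard error of alpha
    n_uncensored: np.ndarray
    censored_fraction: np.ndarray
    slope: float  # 1/pN
    intercept: float  # ln(1/s)
    slope_se: float
    intercept_se: float
    alpha0: float  # 1/s, exp(intercept)
    alpha0_ci95: tuple  # 1/s
    dx_eff: float  # nm, slope * kT
    kT: float = KT_ROOM


def rate_vs_force(
    table: EventTable,
    kT: float = KT_ROOM,
    min_traces: int = 5,
) -> RateFit:
    """Inverse-MFPT unfolding rate per clamp force and its log-linear fit.

    Per force condition: alpha = 1 / mean(first-passage time) over
    uncensored traces; conditions with fewer than ``min_traces`` uncensored
    traces are dropped with a warning.  The fit weights each point by the
    inverse variance of ln(alpha) (SE = sd(FPT)/(mean*sqrt(n))).
    """
    tr = table.traces
    rows = []
    for force, grp in tr.groupby("force_condition"):
        ok = grp[~grp["censored"].astype(bool)]
        fpt = ok["first_passage_time"].to_numpy(dtype=float)
        fpt = fpt[np.isfinite(fpt)]
        if fpt.size < min_traces:
            warnings.warn(
                f"force {force}: only {fpt.size} uncensored traces; dropped",
                stacklevel=2,
            )
            continue
        mean = float(fpt.mean())
        se_ln = float(fpt.std(ddof=1) / (mean * np.sqrt(fpt.size))) if fpt.size > 1 else 0.0
        rows.append(
            {
                "force": float(force),
                "alpha": 1.0 / mean,
                "se_ln": se_ln,
                "n": fpt.size,
                "censored_fraction": 1.0 - fpt.size / len(grp),
            }
        )
    if len(rows) < 2:
        raise ValueError("need >= 2 force conditions with enough uncensored traces")
    df = pd.DataFrame(rows).sort_values("force").reset_index(drop=True)
    F = df["force"].to_numpy()
    ln_a = np.log(df["alpha"].to_numpy())
    se = df["se_ln"].to_numpy().copy()
    w = 1.0 / np.maximum(se, 1e-12) ** 2
    if np.all(se == 0):
        w = np.ones_like(se)

    # weighted least squares, ln(alpha) = intercept + slope * F
    W = np.diag(w)
    X = np.column_stack([np.ones_like(F), F])
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ W @ ln_a)
    cov = np.linalg.inv(xtwx)
    intercept, slope = float(beta[0]), float(beta[1])
    intercept_se, slope_se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    alpha0 = float(np.exp(intercept))
    ci = (
        float(np.exp(intercept - 1.96 * intercept_se)),
        float(np.exp(intercept + 1.96 * intercept_se)),
    )
    return RateFit(
        forces=F,
        alpha=df["alpha"].to_numpy(),
        alpha_se=df["alpha"].to_numpy() * df["se_ln"].to_numpy(),
        n_uncensored=df["n"].to_numpy(),
        censored_fraction=df["censored_fraction"].to_numpy(),
        slope=slope,
        intercept=intercept,
        slope_se=slope_se,
        intercept_se=intercept_se,
        alpha0=alpha0,
        alpha0_ci95=ci,
        dx_eff=slope * kT,
        kT=kT,
    )


# ---------------------------------------------------------------------------
# State labelling and network reconstruction
# ---------------------------------------------------------------------------


@dataclass
class StateSequence:
    """One trace rendered as a walk N -> (intermediates...) -> U."""

    trace_id: str
    force_condition: float
    states: list  # e.g. ["N", "C1", "C3", "U"]
    n_outliers: int = 0


def label_states(
    table: EventTable,
    solution: ClusterSolution,
    mode: str = "step",
    outlier_nsd: float = 3.0,
) -> list[StateSequence]:
    """Map detected steps to cluster labels and build per-trace sequences.

    ``mode="step"`` labels each intermediate by the length of the step that
    created it (default); ``mode="cumulative"`` labels by the cumulative
    extension instead.  A step farther than ``outlier_nsd`` cluster SDs from
    every centroid is labelled "outlier" (excluded from network counts
    downstream but kept in the sequence).  The final step of each trace is
    the transition into U.
    """
    if mode not in ("step", "cumulative"):
        raise ValueError(f"unknown labelling mode {mode!r}")
    tbl = solution.cluster_table()
    mus = tbl["mean_nm"].to_numpy()
    sds = np.maximum(tbl["sd_nm"].to_numpy(), 0.05)

    sequences = []
    traces = table.traces.set_index("trace_id")
    for tid, grp in table.events.groupby("trace_id", sort=False):
        grp = grp.sort_values("step_index")
        values = (
            grp["step_length"] if mode == "step" else grp["cumulative_length"]
        ).to_numpy(dtype=float)
        labels = []
        n_outliers = 0
        for v in values:
            c = int(np.argmin(np.abs(v - mus)))
            if abs(v - mus[c]) > outlier_nsd * sds[c]:
                labels.append("outlier")
                n_outliers += 1
            else:
                labels.append(f"C{c + 1}")
        # the last step completes unfolding: its arrival state is U
        states = ["N"] + labels[:-1] + ["U"]
        sequences.append(
            StateSequence(
                trace_id=tid,
                force_condition=float(traces.loc[tid, "force_condition"]),
                states=states,
                n_outliers=n_outliers,
            )
        )
    return sequences


@dataclass
class KineticNetwork:
    """Empirical state graph: transition counts per force + state lengths."""

    counts: pd.DataFrame  # columns force, origin, destiny, count
    occurrences: pd.DataFrame  # columns force, state, count
    lengths: dict  # state -> characteristic length (nm); N=0
    n_traces: dict = field(default_factory=dict)  # force -> labelled traces

    def transitions_at(self, force: float) -> pd.DataFrame:
        return self.counts[np.isclose(self.counts["force"], force)]

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)


def build_network(
    sequences: list[StateSequence],
    solution: ClusterSolution | None = None,
) -> KineticNetwork:
    """Count observed transitions per force condition.

    Transitions touching an "outlier" label are skipped.  State lengths come
    from the cluster table when a solution is provided (L(N) = 0).
    """
    counts: dict = {}
    occ: dict = {}
    n_traces: dict = {}
    for seq in sequences:
        f = seq.force_condition
        n_traces[f] = n_traces.get(f, 0) + 1
        for state in seq.states:
            if state != "outlier":
                occ[(f, state)] = occ.get((f, state), 0) + 1
        for a, b in zip(seq.states[:-1], seq.states[1:]):
            if "outlier" in (a, b):
                continue
            counts[(f, a, b)] = counts.get((f, a, b), 0) + 1
    counts_df = pd.DataFrame(
        [
            {"force": f, "origin": a, "destiny": b, "count": c}
            for (f, a, b), c in sorted(counts.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2]))
        ],
        columns=["force", "origin", "destiny", "count"],
    )
    occ_df = pd.DataFrame(
        [{"force": f, "state": s, "count": c} for (f, s), c in sorted(occ.items())],
        columns=["force", "state", "count"],
    )
    lengths = {"N": 0.0}
    if solution is not None:
        for _, row in solution.cluster_table().iterrows():
            lengths[row["cluster"]] = float(row["mean_nm"])
    return KineticNetwork(
        counts=counts_df, occurrences=occ_df, lengths=lengths, n_traces=n_traces
    )


def check_connectivity_rule(network: KineticNetwork, L_total: float) -> dict:
    """Audit the rule L(C_origin) + L(C_destiny) <= L_total over intermediates.

    Returns a report with the allowed intermediate pairs, the observed
    transitions that violate the rule, and the allowed-but-unobserved pairs.
    N and U are exempt (the native state connects to everything; every
    intermediate may complete unfolding).
    """
    inter = sorted(
        [s for s in network.lengths if s not in ("N", "U")],
        key=lambda s: network.lengths[s],
    )
    allowed = [
        (a, b)
        for a in inter
        for b in inter
        if a != b and network.lengths[a] + network.lengths[b] <= L_total
    ]
    observed = set(
        (row["origin"], row["destiny"])
        for _, row in network.counts.iterrows()
        if row["origin"] in inter and row["destiny"] in inter
    )
    violations = sorted(pair for pair in observed if pair not in set(allowed))
    unobserved = sorted(pair for pair in allowed if pair not in observed)
    return {
        "allowed_pairs": allowed,
        "observed_violations": violations,
        "allowed_unobserved": unobserved,
    }


def heterogeneity_profile(table: EventTable, max_bin: int = 4) -> pd.DataFrame:
    """Distribution and mean of intermediates per trace, per force.

    Columns: force, n (traces), mean_intermediates and occupancy columns
    ``m0 .. m{max_bin-1}`` plus ``m{max_bin}+`` (counts capped for
    reporting).
    """
    rows = []
    for force, grp in table.traces.groupby("force_condition"):
        m = grp["n_intermediates"].to_numpy(dtype=int)
        row = {
            "force": float(force),
            "n": int(len(grp)),
            "mean_intermediates": float(m.mean()) if m.size else 0.0,
        }
        for j in range(max_bin):
            row[f"m{j}"] = int(np.sum(m == j))
        row[f"m{max_bin}+"] = int(np.sum(m >= max_bin))
        rows.append(row)
    return pd.DataFrame(rows).sort_values("force").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Sequential-pathway test
# ---------------------------------------------------------------------------


def tail_detection_probability(t_res: float, mean_dwell: float) -> float:
    """P(exponential dwell >= t_res) = exp(-t_res/mean_dwell).

    The probability that an intermediate with exponential lifetime
    ``mean_dwell`` survives long enough to be detected; below 0.05 once the
    resolution exceeds three mean lifetimes.
    """
    if t_res < 0 or mean_dwell <= 0:
        raise ValueError("t_res must be >= 0 and mean_dwell > 0")
    return float(np.exp(-t_res / mean_dwell))


def _poisson_binomial_pmf(p: np.ndarray) -> np.ndarray:
    """PMF of sum of independent Bernoulli(p_i), by dynamic programming."""
    pmf = np.array([1.0])
    for pi in p:
        pmf = np.convolve(pmf, [1.0 - pi, pi])
    return pmf


def _fit_poisson_binomial(hist: np.ndarray, n_stages: int) -> np.ndarray:
    """MLE detection probabilities p (len n_stages) for a multiplicity hist.

    ``hist[m]`` counts traces with m detected intermediates (last bin
    open-ended).  The likelihood is multinomial with Poisson-binomial cell
    probabilities; multiplicities beyond n_stages are pooled into the top
    cell.
    """
    hist = np.asarray(hist, dtype=float)

    def nll(logit_p: np.ndarray) -> float:
        p = expit(logit_p)
        pmf = _poisson_binomial_pmf(p)
        cells = np.zeros(hist.size)
        for m, q in enumerate(pmf):
            cells[min(m, hist.size - 1)] += q
        cells = np.maximum(cells, 1e-300)
        return -float(np.dot(hist, np.log(cells)))

    best = None
    for start in ([-2.0] * n_stages, [0.0] * n_stages, [2.0] * n_stages,
                  list(np.linspace(-3, 3, n_stages))):
        res = optimize.minimize(nll, np.asarray(start, dtype=float), method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    p = expit(best.x)
    return np.sort(p)[::-1]


@dataclass
class SequentialTestReport:
    """Outcome of the sequential-versus-multiple-pathway test."""

    n_traces: int
    multiplicity_hist: np.ndarray  # counts for m = 0..n_stages (last open)
    analytic_bounds: dict  # m -> benchmark bound p**m
    fitted_p: np.ndarray  # per-stage detection probabilities under H0
    chi2_observed: float
    mc_pvalue: float
    n_mc: int
    t_res: float
    max_dwell: float
    max_dwell_tail_prob: float  # P(any dwell >= max_dwell | fitted H0)
    verdict: str  # "sequential rejected" | "not rejected" | "insufficient data"


def _chi2(hist: np.ndarray, expected: np.ndarray) -> float:
    return float(np.sum((hist - expected) ** 2 / np.maximum(expected, 0.5)))


def sequential_pathway_test(
    table: EventTable,
    t_res: float,
    n_mc: int = 2000,
    seed=None,
    n_stages: int = 5,
    benchmark_p: float = 0.05,
    reject_at: float = 0.01,
) -> SequentialTestReport:
    """Test whether a single sequential pathway can explain the event table.

    The observed per-trace intermediate multiplicities (n_steps - 1, capped
    at ``n_stages``) are compared with the best-fitting strict sequential
    chain in which stage i is detected independently with probability p_i
    (Poisson-binomial model, maximum likelihood).  The goodness-of-fit
    statistic is the chi-squared distance over multiplicity bins
    {0, 1, ..., n_stages-1, >=n_stages}; its null distribution is obtained
    by parametric bootstrap WITHOUT refitting, which makes the test
    conservative.  Verdict "sequential rejected" when the Monte Carlo
    p-value falls below ``reject_at``.
    """
    if t_res <= 0:
        raise ValueError("t_res must be positive")
    rng = np.random.default_rng(seed)
    m = table.traces["n_intermediates"].to_numpy(dtype=int)
    n = int(m.size)
    hist = np.array(
        [np.sum(m == j) for j in range(n_stages)] + [np.sum(m >= n_stages)],
        dtype=float,
    )

    # dwells of intermediates = dwell before every non-first step
    ev = table.events
    dwell_values = (
        ev.loc[ev["step_index"] >= 1, "dwell_before"].to_numpy(dtype=float)
        if len(ev)
        else np.array([])
    )
    max_dwell = float(dwell_values.max()) if dwell_values.size else 0.0

    bounds = {k: benchmark_p**k for k in range(1, n_stages + 1)}

    if n < 20:
        return SequentialTestReport(
            n_traces=n,
            multiplicity_hist=hist,
            analytic_bounds=bounds,
            fitted_p=np.full(n_stages, np.nan),
            chi2_observed=float("nan"),
            mc_pvalue=float("nan"),
            n_mc=0,
            t_res=t_res,
            max_dwell=max_dwell,
            max_dwell_tail_prob=float("nan"),
            verdict="insufficient data",
        )

    p_hat = _fit_poisson_binomial(hist, n_stages)
    pmf = _poisson_binomial_pmf(p_hat)
    cells = np.zeros(hist.size)
    for j, q in enumerate(pmf):
        cells[min(j, hist.size - 1)] += q
    expected = n * cells
    chi2_obs = _chi2(hist, expected)

    # parametric bootstrap of the multiplicity histogram
    draws = rng.random((n_mc, n, n_stages)) < p_hat[None, None, :]
    mult = draws.sum(axis=2)
    sim_hist = np.stack(
        [np.sum(mult == j, axis=1) for j in range(n_stages)]
        + [np.sum(mult >= n_stages, axis=1)],
        axis=1,
    ).astype(float)
    sim_chi2 = np.sum((sim_hist - expected[None, :]) ** 2 / np.maximum(expected[None, :], 0.5), axis=1)
    pvalue = float((1 + np.sum(sim_chi2 >= chi2_obs)) / (n_mc + 1))

    # how surprising is the longest observed dwell under the fitted chain?
    # fitted mean lifetime per stage: tau_i = -t_res / ln(p_i)
    with np.errstate(divide="ignore"):
        taus = -t_res / np.log(np.clip(p_hat, 1e-12, 1 - 1e-12))
    tau_max = float(np.max(taus))
    p_single = np.exp(-max_dwell / tau_max) if max_dwell > 0 else 1.0
    n_dwells = max(int(dwell_values.size), 1)
    tail_prob = float(1.0 - (1.0 - p_single) ** n_dwells)

    verdict = "sequential rejected" if pvalue < reject_at else "not rejected"
    return SequentialTestReport(
        n_traces=n,
        multiplicity_hist=hist,
        analytic_bounds=bounds,
        fitted_p=p_hat,
        chi2_observed=chi2_obs,
        mc_pvalue=pvalue,
        n_mc=n_mc,
        t_res=t_res,
        max_dwell=max_dwell,
        max_dwell_tail_prob=tail_prob,
        verdict=verdict,
    )
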