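"""Test a single sequential pathway against the observed heterogeneity.

Under one sequential pathway whose intermediates are mostly too brief to
resolve, seeing m intermediates requires m independent exponential dwells in
their distribution tails -- probability below 0.05^m.  The Monte Carlo
version fits the best strict sequential chain to the observed
intermediates-per-trace histogram and measures its goodness of fit.  The
default generator mixes fast single-sweep and slow trapped pathways, which
no sequential chain can imitate.
"""

import numpy as np
import pandas as pd

import mechpath as mp

network = mp.default_network()
rng = np.random.default_rng(23)
rows = []
for i in range(200):
    path = mp.gillespie_clamp(network, 40.0, rng, t_max=10.0)
    m = mp.observed_multiplicity(path, t_res=0.05)
    rows.append(dict(trace_id=f"t{i}", protocol="clamp", force_condition=40.0,
                     n_steps=m + 1, n_intermediates=m, total_length=19.0,
                     first_passage_time=float(path.times[-1]) if path.completed else np.nan,
                     censored=not path.completed))
table = mp.EventTable(
    events=pd.DataFrame(columns=["trace_id", "step_index", "step_length",
                                 "cumulative_length", "dwell_before",
                                 "force_at_step", "t_step"]),
    traces=pd.DataFrame(rows),
)

report = mp.sequential_pathway_test(table, t_res=0.05, n_mc=1000, seed=1)
print("intermediates per trace (0,1,2,3,>=4):",
      report.multiplicity_hist.astype(int).tolist())
print("analytic bounds P(m intermediates) under a sequential pathway:")
for m, bound in report.analytic_bounds.items():
    print(f"  m={m}: < {bound:.2e}")
print(f"best sequential fit detection probs: "
      f"{np.round(report.fitted_p, 3).tolist()}")
print(f"chi2 = {report.chi2_observed:.1f}, Monte Carlo p = {report.mc_pvalue:.4g}")
print(f"verdict: {report.verdict}")
print("\nThe simultaneous excess of zero-intermediate sweeps and of traces "
      "with 3-4 long-lived intermediates is incompatible with a single "
      "sequential pathway.")
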