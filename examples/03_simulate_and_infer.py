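"""Simulate one read dataset and infer abundances with EM.

Draws 100 000 reads from a random five-protein abundance profile, builds
oracle classifier posteriors with a 10% error rate, sparsifies them to the
top 20 strings per read, runs 30 EM epochs, and compares the estimate to
the ground truth and to the uniform-guess baseline.
"""

import numpy as np

import fluorem as fm

d = fm.build_dictionary(fm.synthetic_proteins(), fm.DEFAULT_SCHEME)
m, e, n_reads = 0.1, 0.1, 100_000
rng = np.random.default_rng(7)

p_true = fm.sample_abundances(d.n_proteins, rng)
reads = fm.simulate_reads(p_true, d, m, n_reads, rng, pool_per_string=1000)
post = fm.oracle_posterior(reads, e, d.n_strings, n_b=20,
                           null_index=d.null_index)

cond = fm.string_conditional(d, m)
efo = fm.expected_observable_strings(d, m)
state, p_hat = fm.run_em(post, cond, efo, fm.EMConfig(max_epochs=30),
                         p_true=p_true)

print("protein   truth   estimate")
for pid, t, h in zip(d.protein_ids, p_true, p_hat):
    print(f"{pid:9s} {t:.4f}  {h:.4f}")
print(f"EM MAE:              {fm.mae(p_hat, p_true):.2e}")
print(f"uniform-guess MAE:   {fm.uniform_baseline_mae(p_true):.2e}")
print(f"surrogate log-lik rose monotonically: "
      f"{bool(np.all(np.diff(state.surrogate_loglik_trace) >= -1e-8))}")
# the EM estimate tracks the truth to a few parts in a thousand; the
# uniform guess is an order of magnitude worse.
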