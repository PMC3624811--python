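"""Robustness of prior-aware inference to heavily corrupted priors.

Takes half of the true edges as true prior interactions (TPIs), adds ten
random false prior interactions (FPIs) per TPI (~91% of the prior is wrong),
and compares three rankings on the same data: BBSR with the corrupted prior
at the low-weight preset, BBSR without priors, and a naive baseline that
simply puts all prior edges first.
"""

import grnprior as gp

dataset, gold, _ = gp.standard_dataset(seed=0)
prior, tpis, fpis = gp.corrupt_priors(gold, tpi_fraction=0.5, fpi_ratio=10,
                                      seed=0)
frac = len(fpis) / (len(tpis) + len(fpis))
print(f"prior: {len(tpis)} true + {len(fpis)} false interactions "
      f"({100 * frac:.1f}% erroneous)")

with_prior = gp.run_inference(dataset, prior, "bbsr",
                              gprior=gp.GPriorSpec(g_prior=1.26), n_boot=20,
                              seed=0)
no_prior = gp.run_inference(dataset, None, "bbsr", n_boot=20, seed=0)
naive = gp.naive_prior_ranking(prior, gp.evaluation_universe(gold), seed=0)

a_with = gp.aupr(with_prior.ranked_pairs(), gold,
                 scores=with_prior.scores(), seed=0).aupr
a_none = gp.aupr(no_prior.ranked_pairs(), gold,
                 scores=no_prior.scores(), seed=0).aupr
a_naive = gp.aupr(naive, gold, seed=0).aupr

print(f"\nAUPR with corrupted prior (g = 1.26): {a_with:.3f}")
print(f"AUPR without priors:                  {a_none:.3f}")
print(f"AUPR naive priors-first ranking:      {a_naive:.3f}")
print("\nThe inference filters the bad prior through the data: it stays "
      "close to the no-prior run and far above the naive ranking, which "
      "trusts the corrupted prior blindly.")
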