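"""Compare the two model-selection engines on the same dataset.

MEN (Modified Elastic Net) down-weights the l1 penalty of prior edges;
BBSR (Bayesian Best Subset Regression) raises their g-prior weight.  Both
consume the same time-lagged design/response variables and the same
bootstrap/rank-combination machinery.  A reduced MEN grid and 5 bootstraps
keep this demo quick.
"""

import grnprior as gp

dataset, gold, _ = gp.standard_dataset(seed=0)
pki = gp.subsample_priors(gold, 0.5, seed=0)

men_cfg = gp.MenConfig(xi_grid=(0.0, 0.5, 1.0), n_lambdas=15, cv_folds=5,
                       theta_prior=0.5)
for method, kwargs in [
    ("bbsr", {"gprior": gp.GPriorSpec(g_prior=1.26)}),
    ("men", {"men_config": men_cfg}),
]:
    ranking = gp.run_inference(dataset, pki, method, n_boot=5, seed=0,
                               **kwargs)
    a = gp.aupr(ranking.ranked_pairs(), gold, scores=ranking.scores(),
                seed=0).aupr
    print(f"{method.upper():4s} with 50% of true edges as priors: "
          f"AUPR = {a:.3f}")
print("\nBBSR typically infers the more accurate network, consistent with "
      "its exhaustive per-gene subset search.")
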