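"""Synthetic regulatory networks and expression data with known ground truth.

The generator emulates the statistical structure the inference assumes: a
sparse signed TF -> gene network driving first-order linear kinetics

    dx_i/dt = -alpha_i * x_i + sum_j beta_ji * x_j + b_i

with basal transcription b_i chosen so that the unperturbed fixed point sits
at positive expression levels.  Time series start from randomly perturbed
states and relax back (integrated with classical fixed-step RK4 at step
delta_t/10, sampled every delta_t); steady states solve the linear fixed-point
system under random basal perturbations.  I.i.d. Gaussian noise is added to
every observation.  The returned gold standard is exactly the nonzero
adjacency.

Defaults define the standard study conditions used throughout the test and
acceptance machinery: a 20-gene / 10-TF network with 2 targets per TF, 5
series of 6 points at delta_t = 1, 20 steady states, noise sd 0.1, and
degradation rate ln(2)/10 (half-life 10 time units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import ConditionMeta, ExpressionDataset, GoldStandard

__all__ = ["SyntheticNetwork", "random_network", "simulate_dataset",
           "standard_dataset"]

STABILITY_RADIUS_FRACTION = 0.8  # spectral radius of B relative to min(alpha)


@dataclass
class SyntheticNetwork:
    """Known ground-truth network: signed TF x gene coefficient matrix."""

    adjacency: np.ndarray     # (n_tfs, n_genes) true beta, 0 = no edge
    alpha: np.ndarray         # (n_genes,) degradation rates
    tf_ids: list[str]
    gene_ids: list[str]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_tfs(self) -> int:
        return len(self.tf_ids)

    def system_matrix(self) -> np.ndarray:
        """Gene x gene Jacobian B - diag(alpha) of the linear dynamics."""
        n = self.n_genes
        M = np.zeros((n, n))
        tf_rows = [self.gene_ids.index(t) for t in self.tf_ids]
        for j, row in enumerate(tf_rows):
            M[:, row] += self.adjacency[j]
        return M - np.diag(self.alpha)

    def gold_standard(self) -> GoldStandard:
        return GoldStandard(entries=(self.adjacency != 0).astype(np.int8),
                            tf_ids=list(self.tf_ids), gene_ids=list(self.gene_ids))


def random_network(n_genes: int = 20, n_tfs: int = 10, edges_per_tf: int = 2,
                   beta_scale: float | None = None, half_life: float = 10.0,
                   seed: int | None = None) -> SyntheticNetwork:
    """Sparse random network with stable linear dynamics.

    Each TF regulates ``edges_per_tf`` targets drawn uniformly without
    replacement (never itself); coefficient magnitudes are uniform on
    [0.5, 2] * beta_scale with random sign.  ``beta_scale`` defaults to the
    degradation rate alpha = ln(2)/half_life, making per-edge regulatory gains
    beta/alpha uniform on [0.5, 2]: regulation comparable in strength to
    degradation, so a clamped regulator shifts its targets by an amount of the
    same order as its own shift.  If the spectral radius of the coupling
    matrix B exceeds ``STABILITY_RADIUS_FRACTION`` * min(alpha) (feedback
    loops strong enough to threaten stability of B - diag(alpha)), the
    coupling is rescaled down to that radius.
    """
    if n_tfs > n_genes:
        raise ValueError("n_tfs cannot exceed n_genes")
    if not 1 <= edges_per_tf <= n_genes - 1:
        raise ValueError(f"cannot place {edges_per_tf} edges per TF among "
                         f"{n_genes - 1} possible targets")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:03d}" for i in range(n_genes)]
    tf_ids = gene_ids[:n_tfs]
    alpha = np.full(n_genes, np.log(2.0) / half_life)
    if beta_scale is None:
        beta_scale = float(alpha.min())

    adjacency = np.zeros((n_tfs, n_genes))
    for j in range(n_tfs):
        allowed = [i for i in range(n_genes) if gene_ids[i] != tf_ids[j]]
        targets = rng.choice(allowed, size=edges_per_tf, replace=False)
        mags = rng.uniform(0.5, 2.0, size=edges_per_tf) * beta_scale
        signs = rng.choice([-1.0, 1.0], size=edges_per_tf)
        adjacency[j, targets] = mags * signs

    net = SyntheticNetwork(adjacency=adjacency, alpha=alpha,
                          tf_ids=tf_ids, gene_ids=gene_ids)
    B = net.system_matrix() + np.diag(alpha)
    radius = float(np.abs(np.linalg.eigvals(B)).max())
    target = STABILITY_RADIUS_FRACTION * float(alpha.min())
    if radius > target:
        net.adjacency *= target / radius
    if np.linalg.eigvals(net.system_matrix()).real.max() >= 0:  # pragma: no cover
        raise RuntimeError("could not stabilise the random network")
    return net


def _rk4(f, x0: np.ndarray, t_end: float, h: float) -> np.ndarray:
    x = x0.copy()
    steps = max(int(round(t_end / h)), 1)
    for _ in range(steps):
        k1 = f(x)
        k2 = f(x + 0.5 * h * k1)
        k3 = f(x + 0.5 * h * k2)
        k4 = f(x + h * k3)
        x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return x


def simulate_dataset(network: SyntheticNetwork, n_series: int = 5,
                     series_length: int = 6, delta_t: float = 1.0,
                     n_steady: int = 20, noise_sd: float = 0.1,
                     perturbation_sd: float = 1.0, clamp_prob: float = 0.3,
                     seed: int | None = None, return_info: bool = False):
    """Simulate time courses and steady states from a ground-truth network.

    Time series relax from randomly perturbed initial states under the fixed
    baseline basal rates.  Each steady-state condition emulates a multi-factor
    perturbation experiment: a random subset of TFs (each with probability
    ``clamp_prob``, at least one) is clamped to shifted expression levels and
    the remaining genes equilibrate exactly under the baseline basal rates, so
    every non-clamped gene's fixed-point relation holds to machine precision
    before observation noise is added.  Clamp draws that would push a gene
    near zero are redrawn.  With ``return_info=True`` a third element carries
    the clamped TFs per steady-state condition and the baseline state.
    """
    if delta_t <= 0 or (n_series > 0 and series_length < 2):
        raise ValueError("need delta_t > 0 and series of at least 2 points")
    rng = np.random.default_rng(seed)
    n = network.n_genes
    J = network.system_matrix()            # dx/dt = J x + b
    A = -J                                 # fixed point solves A x = b

    # baseline basal rates chosen so the unperturbed fixed point is positive
    x_base = rng.uniform(1.0, 3.0, size=n)
    b = A @ x_base

    columns, cond_ids, meta = [], [], []
    basal = []

    def rhs(x):
        return J @ x + b

    for s in range(n_series):
        x = np.clip(x_base + rng.normal(0.0, perturbation_sd, size=n), 0.0, None)
        for k in range(series_length):
            cid = f"ts{s}_t{k}"
            if k > 0:
                x = np.clip(_rk4(rhs, x, delta_t, delta_t / 10.0), 0.0, None)
            columns.append(x.copy())
            cond_ids.append(cid)
            basal.append(b.copy())
            meta.append(ConditionMeta(
                condition=cid, is_time_series=True, is_first_in_series=(k == 0),
                prev_condition=f"ts{s}_t{k - 1}" if k > 0 else None,
                delta_t=delta_t if k > 0 else None,
            ))

    tf_rows = np.asarray([network.gene_ids.index(t) for t in network.tf_ids])
    clamped: list[list[str]] = []
    for s in range(n_steady):
        x = None
        for _ in range(40):  # redraw draws that drive a gene near zero
            pick = rng.random(len(tf_rows)) < clamp_prob
            if not pick.any():
                pick[rng.integers(len(tf_rows))] = True
            sel = tf_rows[pick]
            c = x_base[sel] + rng.normal(0.0, perturbation_sd, size=len(sel))
            if c.min() < 0.05:
                continue
            rest = np.setdiff1d(np.arange(n), sel)
            rhs_vec = b[rest] - A[np.ix_(rest, sel)] @ c
            x_rest = np.linalg.solve(A[np.ix_(rest, rest)], rhs_vec)
            if x_rest.min() > 0.05:
                x = np.empty(n)
                x[rest] = x_rest
                x[sel] = c
                break
        if x is None:  # pragma: no cover - fall back to the unperturbed state
            x = x_base.copy()
            sel = []
        cid = f"ss{s}"
        columns.append(x)
        cond_ids.append(cid)
        basal.append(b.copy())
        clamped.append([network.gene_ids[j] for j in sel])
        meta.append(ConditionMeta(condition=cid, is_time_series=False))

    values = np.column_stack(columns)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)

    dataset = ExpressionDataset(values=values, gene_ids=list(network.gene_ids),
                                condition_ids=cond_ids, meta=meta,
                                tf_ids=list(network.tf_ids))
    gold = network.gold_standard()
    if return_info:
        info = {"basal": np.column_stack(basal), "x_base": x_base,
                "system_matrix": J, "clamped_tf": clamped}
        return dataset, gold, info
    return dataset, gold


def standard_dataset(seed: int | None = None, noise_sd: float = 0.1,
                     n_series: int = 5, series_length: int = 6,
                     n_steady: int = 20, **net_kwargs
                     ) -> tuple[ExpressionDataset, GoldStandard, SyntheticNetwork]:
    """The standard 20-gene / 10-TF study conditions used across experiments."""
    ss = np.random.SeedSequence(seed)
    net_seed, data_seed = ss.spawn(2)
    net = random_network(seed=net_seed.generate_state(1)[0] % (2**31), **net_kwargs)
    dataset, gold = simulate_dataset(
        net, n_series=n_series, series_length=series_length, n_steady=n_steady,
        noise_sd=noise_sd, seed=data_seed.generate_state(1)[0] % (2**31))
    return dataset, gold, net
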