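"""Time-lagged design/response construction from the core ODE model.

The regulatory model is first-order linear kinetics,

    dx_i/dt = -alpha_i * x_i + sum_{j in P_i} beta_ij * x_j,

with alpha_i the mRNA degradation rate (alpha = ln 2 / half-life).  For a pair
of consecutive time points (t_k, t_{k+1}) the finite-difference form gives the
response

    y_i = (x_i(t_{k+1}) - x_i(t_k)) / dt + alpha_i * x_i(t_k)

paired with the *time-lagged* design row x_j(t_k); at steady state dx/dt = 0 so
y_i = alpha_i * x_i paired with the same-condition design row.  Time-series and
steady-state rows are concatenated, then the response vector and every design
column are centred and scaled to zero mean and unit variance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .datasets import ExpressionDataset

__all__ = [
    "degradation_rate",
    "time_series_response",
    "steady_state_response",
    "build_design_response",
    "DesignResponseSet",
    "DesignResponse",
    "DegenerateDataError",
]

log = logging.getLogger(__name__)

_ZERO_VAR_TOL = 1e-12
DEFAULT_HALF_LIFE = 10.0


class DegenerateDataError(ValueError):
    """Raised when too few usable conditions exist to build a regression."""


def degradation_rate(half_life: float) -> float:
    """First-order degradation rate alpha = ln(2) / half_life."""
    if not half_life > 0:
        raise ValueError(f"half-life must be positive, got {half_life}")
    return math.log(2.0) / half_life


def time_series_response(x_prev: float, x_next: float, delta_t: float, alpha: float) -> float:
    """Finite-difference response for one consecutive time-point pair."""
    if not delta_t > 0:
        raise ValueError(f"delta_t must be positive, got {delta_t}")
    return (x_next - x_prev) / delta_t + alpha * x_prev


def steady_state_response(x: float, alpha: float) -> float:
    """Steady-state response alpha * x (the degradation term balances production)."""
    return alpha * x


def _scale(v: np.ndarray) -> tuple[np.ndarray, bool]:
    """Centre/scale to mean 0, sd 1 (ddof=1). Returns (scaled, was_constant)."""
    centred = v - v.mean()
    sd = v.std(ddof=1) if len(v) > 1 else 0.0
    if sd < _ZERO_VAR_TOL:
        return np.zeros_like(centred), True
    return centred / sd, False


@dataclass
class DesignResponse:
    """Per-gene regression problem: scaled response and lagged design matrix."""

    gene_id: str
    response: np.ndarray          # (R,) scaled
    design: np.ndarray            # (R, p) scaled
    predictor_ids: list[str]
    alpha: float
    raw_response: np.ndarray
    condition_index: list[str]    # response row -> source condition id

    @property
    def n_obs(self) -> int:
        return len(self.response)


class DesignResponseSet:
    """Design/response variables for every gene of a dataset.

    The design rows (lagged TF values) are shared across genes; only the
    response differs, so the transform is computed once.  ``for_gene`` carves
    out one gene's regression problem, excluding the gene's own column (no
    self-regulation is inferred).
    """

    def __init__(self, dataset: ExpressionDataset, half_life: float = DEFAULT_HALF_LIFE,
                 alpha: np.ndarray | float | None = None):
        self.dataset = dataset
        if alpha is None:
            alpha = degradation_rate(half_life)
        self.alpha = np.broadcast_to(np.asarray(alpha, dtype=float),
                                     (dataset.n_genes,)).copy()

        cond_pos = {c: k for k, c in enumerate(dataset.condition_ids)}
        design_cond: list[int] = []   # condition index providing the design row
        resp_cond: list[int] = []     # condition index providing the response value
        prev_cond: list[int] = []     # lagged condition (== design row source)
        delta_t: list[float] = []
        is_ts: list[bool] = []
        for m in dataset.meta:
            k = cond_pos[m.condition]
            if m.is_time_series:
                if m.is_first_in_series:
                    continue  # contributes a design row to its successor only
                p = cond_pos[m.prev_condition]
                design_cond.append(p)
                resp_cond.append(k)
                prev_cond.append(p)
                delta_t.append(float(m.delta_t))
                is_ts.append(True)
            else:
                design_cond.append(k)
                resp_cond.append(k)
                prev_cond.append(k)
                delta_t.append(np.nan)
                is_ts.append(False)

        if len(resp_cond) < 2:
            raise DegenerateDataError(
                f"only {len(resp_cond)} usable conditions; need at least 2"
            )

        self.condition_index = [dataset.condition_ids[k] for k in resp_cond]
        self._is_ts = np.asarray(is_ts)

        X = dataset.values  # genes x conditions
        tf_rows = np.asarray([dataset.gene_index(t) for t in dataset.tf_ids])
        self.raw_design = X[np.ix_(tf_rows, np.asarray(design_cond))].T  # R x n_tfs

        dt = np.asarray(delta_t)
        x_now = X[:, resp_cond]    # genes x R
        x_prev = X[:, prev_cond]
        ts = self._is_ts
        raw = np.empty_like(x_now)
        a = self.alpha[:, None]
        if ts.any():
            raw[:, ts] = (x_now[:, ts] - x_prev[:, ts]) / dt[ts] + a * x_prev[:, ts]
        if (~ts).any():
            raw[:, ~ts] = a * x_now[:, ~ts]
        self.raw_response = raw  # genes x R

        self._rescale()

    # -- scaling --------------------------------------------------------
    def _rescale(self) -> None:
        R, n_tfs = self.raw_design.shape
        self.design = np.empty_like(self.raw_design)
        self.dropped_predictors: list[str] = []
        self._constant_cols = np.zeros(n_tfs, dtype=bool)
        for j in range(n_tfs):
            self.design[:, j], const = _scale(self.raw_design[:, j])
            if const:
                self._constant_cols[j] = True
                self.dropped_predictors.append(self.dataset.tf_ids[j])
        if self.dropped_predictors:
            log.warning("dropped zero-variance predictor columns: %s",
                        self.dropped_predictors)
        self.response = np.empty_like(self.raw_response)
        self._constant_response = np.zeros(self.dataset.n_genes, dtype=bool)
        for i in range(self.dataset.n_genes):
            self.response[i], const = _scale(self.raw_response[i])
            self._constant_response[i] = const

    # -- views ----------------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.raw_design.shape[0]

    def predictor_mask(self, gene_id: str) -> np.ndarray:
        """Usable design columns for a gene: non-constant, not the gene itself."""
        mask = ~self._constant_cols
        if gene_id in self.dataset.tf_ids:
            mask = mask.copy()
            mask[self.dataset.tf_ids.index(gene_id)] = False
        return mask

    def for_gene(self, gene_id: str, predictor_ids: list[str] | None = None) -> DesignResponse:
        i = self.dataset.gene_index(gene_id)
        mask = self.predictor_mask(gene_id)
        if predictor_ids is None:
            cols = np.nonzero(mask)[0]
        else:
            tf_pos = {t: j for j, t in enumerate(self.dataset.tf_ids)}
            cols = np.asarray([tf_pos[t] for t in predictor_ids if mask[tf_pos[t]]],
                              dtype=int)
        return DesignResponse(
            gene_id=gene_id,
            response=self.response[i],
            design=self.design[:, cols],
            predictor_ids=[self.dataset.tf_ids[j] for j in cols],
            alpha=float(self.alpha[i]),
            raw_response=self.raw_response[i],
            condition_index=list(self.condition_index),
        )

    def resample(self, rows: np.ndarray) -> "DesignResponseSet":
        """Bootstrap view: resample design/response row pairs, then re-scale.

        Resampling the constructed rows (rather than raw conditions) keeps the
        lag pairing between response and design intact.
        """
        new = object.__new__(DesignResponseSet)
        new.dataset = self.dataset
        new.alpha = self.alpha
        new.raw_design = self.raw_design[rows]
        new.raw_response = self.raw_response[:, rows]
        new.condition_index = [self.condition_index[r] for r in rows]
        new._is_ts = self._is_ts[rows]
        new._rescale()
        return new


def build_design_response(dataset: ExpressionDataset, half_life: float = DEFAULT_HALF_LIFE,
                          alpha: np.ndarray | float | None = None) -> DesignResponseSet:
    """Build the shared time-lagged design and per-gene responses for a dataset."""
    return DesignResponseSet(dataset, half_life=half_life, alpha=alpha)
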