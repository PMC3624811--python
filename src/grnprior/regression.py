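"""Shared result container for the per-gene model-selection engines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RegressionResult"]


@dataclass
class RegressionResult:
    """Selected predictors and coefficients for one gene.

    ``betas`` aligns with ``selected``; predictors not selected have an
    implicit coefficient of zero.  ``model_score`` is the engine's selection
    score: cross-validated prediction error for the elastic net, BIC for the
    Bayesian subset regression.
    """

    gene_id: str
    selected: list[str]
    betas: np.ndarray
    residual_variance: float
    model_score: float
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.shape != (len(self.selected),):
            raise ValueError("betas must align with selected predictors")
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("non-finite coefficients")

    def coefficient(self, predictor_id: str) -> float:
        try:
            return float(self.betas[self.selected.index(predictor_id)])
        except ValueError:
            return 0.0
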