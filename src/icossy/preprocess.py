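"""Per-sample expression normalization.

The default transform is fuzzy rank normalization: within each sample the
top theta1 % of genes are mapped to 1, the bottom theta2 % to 0, and the
middle genes linearly in descending-expression rank.  The transform depends
only on within-sample ranks, so it is invariant to any strictly monotone
rescaling of a sample and clips outliers by construction.  The legacy
alternative is quantile normalization across samples followed by a per-gene
z-transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger("icossy")

__all__ = ["NormalizationParams", "fuzzy_rank_normalize", "quantile_z_normalize"]


@dataclass
class NormalizationParams:
    """theta1/theta2 are percentages of genes pinned to 1 and 0 respectively."""

    theta1: float = 5.0
    theta2: float = 15.0
    method: str = "fuzzy"

    def __post_init__(self) -> None:
        if not (self.theta1 > 0 and self.theta2 > 0 and self.theta1 + self.theta2 < 100):
            raise ValueError(
                f"need 0 < theta1, 0 < theta2, theta1 + theta2 < 100; "
                f"got theta1={self.theta1}, theta2={self.theta2}"
            )
        if self.method not in {"fuzzy", "quantile_z"}:
            raise ValueError(f"unknown normalization method {self.method!r}")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _fuzzy_column(values: np.ndarray, theta1: float, theta2: float) -> np.ndarray:
    g = values.size
    n1 = _round_half_up(theta1 / 100.0 * g)
    n2 = _round_half_up(theta2 / 100.0 * g)
    # Output for descending-expression rank r (1-based): 1 on the top plateau,
    # 0 on the bottom plateau, linear in between (continuous at both plateaus).
    ranks = np.arange(1, g + 1, dtype=float)
    out_by_rank = np.empty(g)
    out_by_rank[: n1] = 1.0
    out_by_rank[g - n2:] = 0.0
    mid = slice(n1, g - n2)
    denom = (g - n2 + 1) - n1
    if denom > 0:
        out_by_rank[mid] = ((g - n2 + 1) - ranks[mid]) / denom
    order = np.argsort(-values, kind="stable")
    out = np.empty(g)
    out[order] = out_by_rank
    # Ties: every tied value receives the mean of the outputs its positions
    # would get under a stable sort, making the transform permutation-invariant.
    if np.unique(values).size != g:
        s = pd.Series(out)
        out = s.groupby(values).transform("mean").to_numpy()
    return out


def fuzzy_rank_normalize(
    m: ExpressionMatrix, p: NormalizationParams | None = None
) -> ExpressionMatrix:
    """Map each sample's expressions to [0, 1] by within-sample rank.

    With G genes per sample, n1 = round(theta1/100 * G) genes take the value
    1 and n2 = round(theta2/100 * G) take 0 (round half up); a middle gene at
    descending rank r takes ((G - n2 + 1) - r) / ((G - n2 + 1) - n1), the
    linear ramp that meets 1 at rank n1 and 0 at rank G - n2 + 1, so the
    plateau counts are exact and the middle stays strictly inside (0, 1).
    """
    p = p or NormalizationParams()
    g = m.data.shape[0]
    n1 = _round_half_up(p.theta1 / 100.0 * g)
    n2 = _round_half_up(p.theta2 / 100.0 * g)
    if n1 == 0 or n2 == 0:
        logger.warning(
            "fuzzy normalization with %d genes yields n1=%d, n2=%d: a plateau is empty", g, n1, n2
        )
    values = m.values
    out = np.column_stack(
        [_fuzzy_column(values[:, j], p.theta1, p.theta2) for j in range(values.shape[1])]
    )
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
        m.row_descriptions.copy(),
    )


def quantile_z_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples, then z-transform each gene across samples.

    The quantile step replaces each sample's sorted values by the across-sample
    mean of sorted values (stable order within a sample resolves ties); the
    z-step centers and scales each gene (population sd; zero-variance genes
    become all-zero rows).
    """
    if m.data.shape[1] < 2:
        raise ValueError("quantile normalization requires >= 2 samples")
    values = m.values
    order = np.argsort(values, axis=0, kind="stable")
    mean_sorted = np.mean(np.take_along_axis(values, order, axis=0), axis=1)
    qn = np.empty_like(values)
    for j in range(values.shape[1]):
        qn[order[:, j], j] = mean_sorted
    mu = qn.mean(axis=1, keepdims=True)
    sd = qn.std(axis=1, keepdims=True, ddof=0)
    z = np.zeros_like(qn)
    nonzero = sd[:, 0] > 0
    z[nonzero] = (qn[nonzero] - mu[nonzero]) / sd[nonzero]
    return ExpressionMatrix(
        pd.DataFrame(z, index=m.data.index, columns=m.data.columns),
        m.row_descriptions.copy(),
    )
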