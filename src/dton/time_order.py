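"""Pairwise time-order scoring through the integrated-ODE regression.

The dynamic order relation G1 -> G2 ("G2 responds later") is modelled
by the ODE df2/dt = k1 f1(t) + k2 f2(t), or equivalently in integrated
form f2(t) = k1 F1(t) + k2 F2(t) where F_i is the running integral of
gene i's fitted spline from t_min. Each ordered direction of a pair is
scored by regressing the later gene's observed LCRs on the shared
predictor block X = (1, F1, F2); the difference of the two Gaussian
log-likelihoods (delta) is the evidence for one order over the other —
positive delta favours a -> b.

Integrating rather than differentiating uses the whole trajectory, so
an order can be resolved even when the two curves differ only briefly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import ExpressionTable
from .spline import KnotPair, SplineFit, gaussian_mle_loglik

__all__ = [
    "CumulativeCurve",
    "PairScore",
    "integrate_spline",
    "evaluate_cumulative",
    "pair_regression_loglik",
    "score_pair",
    "score_all_pairs",
    "write_pair_scores",
    "read_pair_scores",
]


@dataclass(frozen=True)
class CumulativeCurve:
    """Piecewise antiderivative F of a fitted spline, with F(t_min) = 0.

    ``coeffs`` holds one degree-4 polynomial per piece (constant through
    quartic term, global time variable); ``c1`` and ``c2`` are the
    accumulated integrals up to K1 and K2 that make F continuous.
    """

    gene_id: str
    knots: KnotPair
    coeffs: np.ndarray  # (3, 5)
    c1: float
    c2: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "coeffs", np.asarray(self.coeffs, dtype=float))
        if self.coeffs.shape != (3, 5):
            raise ValueError("coeffs must be a (3, 5) array")


def _antiderivative(beta: np.ndarray) -> np.ndarray:
    """Quartic antiderivative coefficients (zero constant) of a cubic."""
    return np.concatenate([[0.0], beta / np.arange(1, 5)])


def _poly_eval(coeffs: np.ndarray, t: np.ndarray) -> np.ndarray:
    powers = np.stack([np.ones_like(t), t, t**2, t**3, t**4], axis=-1)
    return np.einsum("...k,...k->...", powers, coeffs)


def integrate_spline(fit: SplineFit) -> CumulativeCurve:
    """Closed-form running integral of the fitted spline from t_min.

    C1 = integral of piece 1 over [t_min, K1]; C2 = C1 plus the integral
    of piece 2 over [K1, K2]; each piece's constant is shifted so F is
    continuous and F(t_min) = 0.
    """
    k = fit.knots
    raw = [_antiderivative(b) for b in (fit.beta1, fit.beta2, fit.beta3)]
    c1 = float(_poly_eval(raw[0], np.float64(k.k1)) - _poly_eval(raw[0], np.float64(k.t_min)))
    c2 = c1 + float(_poly_eval(raw[1], np.float64(k.k2)) - _poly_eval(raw[1], np.float64(k.k1)))
    coeffs = np.vstack(raw)
    coeffs[0, 0] = -_poly_eval(raw[0], np.float64(k.t_min))
    coeffs[1, 0] = c1 - _poly_eval(raw[1], np.float64(k.k1))
    coeffs[2, 0] = c2 - _poly_eval(raw[2], np.float64(k.k2))
    return CumulativeCurve(fit.gene_id, k, coeffs, c1, c2)


def evaluate_cumulative(curve: CumulativeCurve, t: float | np.ndarray) -> float | np.ndarray:
    """Evaluate F at time(s) t in [t_min, t_max]."""
    t = np.asarray(t, dtype=float)
    pieces = curve.knots.piece_index(t)
    out = _poly_eval(curve.coeffs[pieces], t)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PairScore:
    """Log-likelihoods of the two opposite orderings of a gene pair.

    ``loglik_a_to_b`` scores the model "b responds after a" (y_b
    regressed on X); ``loglik_b_to_a`` the reverse; ``delta`` their
    difference. ``direction`` is "a->b", "b->a" or "tie".
    """

    gene_a: str
    gene_b: str
    loglik_a_to_b: float
    loglik_b_to_a: float

    @property
    def delta(self) -> float:
        d = self.loglik_a_to_b - self.loglik_b_to_a
        if math.isnan(d):  # inf - inf: both directions fit exactly
            return 0.0
        return d

    @property
    def direction(self) -> str:
        if self.delta > 0:
            return "a->b"
        if self.delta < 0:
            return "b->a"
        return "tie"

    @property
    def ordered(self) -> tuple[str, str] | None:
        """(earlier, later) under the supported direction, or None on a tie."""
        if self.delta > 0:
            return (self.gene_a, self.gene_b)
        if self.delta < 0:
            return (self.gene_b, self.gene_a)
        return None


def pair_regression_loglik(
    y: Sequence[float], fa: Sequence[float], fb: Sequence[float]
) -> float:
    """Gaussian log-likelihood of y ~ intercept + F_a + F_b at the MLE.

    The variance is profiled out as RSS/n, matching the spline module's
    convention so that likelihood differences are comparable.
    """
    y = np.asarray(y, dtype=float)
    x = np.column_stack([np.ones_like(y), np.asarray(fa, float), np.asarray(fb, float)])
    if y.shape[0] != x.shape[0]:
        raise ValueError("y, fa, fb must have equal length")
    if np.linalg.matrix_rank(x) < 3:
        raise np.linalg.LinAlgError(
            "collinear predictors: the two cumulative curves (plus intercept) "
            "do not span 3 dimensions"
        )
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return gaussian_mle_loglik(float(resid @ resid), y.size)


def score_pair(
    ya: Sequence[float],
    yb: Sequence[float],
    fa: Sequence[float],
    fb: Sequence[float],
    gene_a: str = "a",
    gene_b: str = "b",
) -> PairScore:
    """Score both orderings of a pair on the shared predictor block (1, F_a, F_b)."""
    return PairScore(
        gene_a,
        gene_b,
        loglik_a_to_b=pair_regression_loglik(yb, fa, fb),
        loglik_b_to_a=pair_regression_loglik(ya, fa, fb),
    )


def score_all_pairs(
    table: ExpressionTable, fits: Sequence[SplineFit]
) -> list[PairScore]:
    """One :class:`PairScore` per unordered gene pair, in lexicographic index order.

    Cumulative curves are evaluated once per gene at the table's sampling
    times and reused across all pairs.
    """
    if table.stage != "standardized_lcr":
        raise ValueError("pair scoring expects a standardized_lcr table")
    by_gene = {f.gene_id: f for f in fits}
    missing = [g for g in table.gene_ids if g not in by_gene]
    if missing:
        raise KeyError(f"no spline fit for genes: {missing[:5]}")
    times = table.times
    cum = np.vstack(
        [
            np.atleast_1d(evaluate_cumulative(integrate_spline(by_gene[g]), times))
            for g in table.gene_ids
        ]
    )
    scores = []
    for i, j in itertools.combinations(range(table.n_genes), 2):
        scores.append(
            score_pair(
                table.values[i],
                table.values[j],
                cum[i],
                cum[j],
                table.gene_ids[i],
                table.gene_ids[j],
            )
        )
    return scores


def write_pair_scores(scores: Sequence[PairScore], path: str | Path) -> None:
    """Serialize pair scores to TSV (gene_a, gene_b, ll_ab, ll_ba, delta, direction)."""
    df = pd.DataFrame(
        {
            "gene_a": [s.gene_a for s in scores],
            "gene_b": [s.gene_b for s in scores],
            "ll_ab": [s.loglik_a_to_b for s in scores],
            "ll_ba": [s.loglik_b_to_a for s in scores],
            "delta": [s.delta for s in scores],
            "direction": [s.direction for s in scores],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_pair_scores(path: str | Path) -> list[PairScore]:
    df = pd.read_csv(path, sep="\t")
    return [
        PairScore(str(r.gene_a), str(r.gene_b), float(r.ll_ab), float(r.ll_ba))
        for r in df.itertuples()
    ]
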