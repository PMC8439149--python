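"""Empirical-Bayes variance shrinkage for moderated t-statistics.

Gene-wise sample variances s2_g (each on df residual degrees of freedom)
are modelled as draws from a scaled-inverse-chi-square prior with scale
s0^2 and d0 degrees of freedom, so that marginally s2_g / s0^2 follows an
F(df, d0) distribution. The prior is estimated by matching the first two
moments of the observed variance distribution to the F moments:

    E[s2]   = s0^2 * d0 / (d0 - 2)
    CV^2    = Var[s2] / E[s2]^2 = 2 (df + d0 - 2) / (df (d0 - 4))

The posterior (shrunken) variance is the precision-weighted blend

    s2_tilde_g = (d0 * s0^2 + df * s2_g) / (d0 + df)

and moderated t statistics gain d0 extra degrees of freedom. When the
observed variances are less dispersed than sampling noise alone predicts
(CV^2 at or below the pure-chi-square value), the prior degrees of
freedom are effectively infinite and every gene receives the common
variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class VariancePrior:
    s0_sq: float
    d0: float  # may be inf

    @property
    def is_infinite(self) -> bool:
        return np.isinf(self.d0)


_D0_CAP = 1e6  # treated as an effectively infinite prior


def moment_match_prior(s2: np.ndarray, df: float) -> VariancePrior:
    """Estimate (s0^2, d0) from gene-wise variances on ``df`` degrees of
    freedom by moment matching. Requires at least two positive-variance
    genes to estimate dispersion; degenerate inputs fall back to an
    infinite-d0 prior at the mean variance."""
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if s2.size == 0 or df <= 0:
        return VariancePrior(s0_sq=0.0, d0=np.inf)
    m = float(np.mean(s2))
    if m <= 0 or s2.size < 2:
        return VariancePrior(s0_sq=max(m, 0.0), d0=np.inf)
    v = float(np.var(s2, ddof=1))
    cv2 = v / m**2
    # pure chi-square dispersion (d0 -> inf) gives CV^2 = 2/df
    if cv2 <= 2.0 / df + 1e-12:
        return VariancePrior(s0_sq=m, d0=np.inf)
    # solve cv2 = 2 (df + d0 - 2) / (df (d0 - 4)) for d0
    denom = cv2 * df - 2.0
    d0 = (2.0 * df - 4.0 + 4.0 * cv2 * df) / denom
    if not np.isfinite(d0) or d0 > _D0_CAP:
        return VariancePrior(s0_sq=m, d0=np.inf)
    d0 = max(d0, 4.0 + 1e-6)  # moment solution only valid for d0 > 4
    s0_sq = m * (d0 - 2.0) / d0
    return VariancePrior(s0_sq=s0_sq, d0=d0)


def squeeze_variances(
    s2: np.ndarray, df: float, prior: VariancePrior | None = None
) -> tuple[np.ndarray, float, VariancePrior]:
    """Shrink gene-wise variances toward the empirical prior.

    Returns (posterior variances, total degrees of freedom, prior).
    """
    s2 = np.asarray(s2, dtype=float)
    if prior is None:
        prior = moment_match_prior(s2, df)
    if prior.is_infinite:
        post = np.full_like(s2, prior.s0_sq)
        df_total = np.inf if prior.s0_sq > 0 else df
        # with a degenerate zero prior there is nothing to shrink toward
        if prior.s0_sq == 0:
            post = s2.copy()
            df_total = df
    else:
        post = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
        df_total = df + prior.d0
    return post, df_total, prior


def moderated_t_pvalues(
    effect: np.ndarray,
    stderr_unit: np.ndarray | float,
    s2: np.ndarray,
    df: float,
    prior: VariancePrior | None = None,
) -> tuple[np.ndarray, np.ndarray, float, VariancePrior]:
    """Moderated t test for per-gene effects.

    ``stderr_unit`` is the standard-error multiplier for a unit standard
    deviation (e.g. 1/sqrt(n) for a paired mean, sqrt(1/n1 + 1/n2) for a
    two-group difference). Returns (t, two-sided p, df_total, prior).
    Zero posterior variance yields t=0, p=1 for zero effects and
    t=+/-inf, p=0 otherwise.
    """
    effect = np.asarray(effect, dtype=float)
    post, df_total, prior = squeeze_variances(s2, df, prior)
    se = np.sqrt(post) * stderr_unit
    t = np.zeros_like(effect)
    nz = se > 0
    t[nz] = effect[nz] / se[nz]
    exploding = (~nz) & (effect != 0)
    t[exploding] = np.sign(effect[exploding]) * np.inf
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.where(exploding, 0.0, p)
    p = np.where(nz | exploding, p, 1.0)
    return t, p, df_total, prior


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
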