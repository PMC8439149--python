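"""Two-class association of genomic features with metastatic potential.

Cell lines are split into high- and low-potential classes (lines between
the two thresholds are excluded), and every feature of a genomic matrix
— somatic mutation calls, binarized copy number, expression, dependency
scores — is tested for enrichment in the high class. Binary features use
Fisher's exact test on the 2x2 detection table; continuous features use
a two-sample moderated t with the same empirical-Bayes variance
shrinkage as the expression tests. Effects are signed so that positive
means higher in the high-potential class; q-values are
Benjamini-Hochberg across features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._moderated import bh_fdr, moderated_t_pvalues

BINARY_TYPES = ("mutation", "copy_number_binary")
CONTINUOUS_TYPES = ("expression", "dependency", "continuous")


@dataclass
class FeatureMatrix:
    """Features x cell lines matrix. Binary types hold {0, 1, NaN}."""

    values: np.ndarray
    feature_ids: list[str]
    line_ids: list[str]
    feature_type: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.line_ids)):
            raise ValueError("feature matrix shape does not match id lists")
        if self.feature_type in BINARY_TYPES:
            finite = self.values[np.isfinite(self.values)]
            if not np.all(np.isin(finite, (0.0, 1.0))):
                raise ValueError(
                    f"binary feature type {self.feature_type!r} must contain only 0/1/missing"
                )

    @property
    def is_binary(self) -> bool:
        return self.feature_type in BINARY_TYPES

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.line_ids)


def binarize_copy_number(
    cn: pd.DataFrame | FeatureMatrix, loss_cutoff: float = -1.0, gain_cutoff: float = 1.0
) -> FeatureMatrix:
    """Binarize relative copy-number values into loss/gain tracks.

    Loss is value <= -1, gain is value >= +1 (cutoffs inclusive and
    configurable). Each input gene yields two features, ``<gene>_loss``
    and ``<gene>_gain``; missing values stay missing.
    """
    if isinstance(cn, FeatureMatrix):
        df = cn.to_frame()
    else:
        df = cn
    vals = df.values.astype(float)
    loss = np.where(np.isnan(vals), np.nan, (vals <= loss_cutoff).astype(float))
    gain = np.where(np.isnan(vals), np.nan, (vals >= gain_cutoff).astype(float))
    feature_ids = [f"{g}_loss" for g in df.index] + [f"{g}_gain" for g in df.index]
    return FeatureMatrix(
        values=np.vstack([loss, gain]),
        feature_ids=feature_ids,
        line_ids=[str(c) for c in df.columns],
        feature_type="copy_number_binary",
    )


def classify_by_potential(
    overall: pd.Series, high_cutoff: float, low_cutoff: float
) -> dict[str, str]:
    """Gate lines into potential classes by their overall log10 potential:
    above ``high_cutoff`` -> 'high', below ``low_cutoff`` -> 'low',
    in between -> 'excluded'."""
    if low_cutoff > high_cutoff:
        raise ValueError("low_cutoff must not exceed high_cutoff")
    labels = {}
    for line, v in overall.items():
        if not np.isfinite(v):
            labels[line] = "excluded"
        elif v > high_cutoff:
            labels[line] = "high"
        elif v < low_cutoff:
            labels[line] = "low"
        else:
            labels[line] = "excluded"
    return labels


def _class_columns(
    features: FeatureMatrix, labels: Mapping[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    hi = np.array([labels.get(l) == "high" for l in features.line_ids])
    lo = np.array([labels.get(l) == "low" for l in features.line_ids])
    if hi.sum() < 2 or lo.sum() < 2:
        raise ValueError(
            f"need >= 2 lines per class; got {int(hi.sum())} high, {int(lo.sum())} low"
        )
    return hi, lo


def two_class_compare(
    features: FeatureMatrix,
    labels: Mapping[str, str],
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per-feature high-vs-low comparison.

    Binary features: effect = detection-rate difference (high minus low),
    p from Fisher's exact test (``alternative`` as in scipy, default
    two-sided). Continuous features: effect = class-mean difference,
    moderated two-sample t with pooled, empirical-Bayes-shrunken
    variances; constant continuous features are excluded. Missing values
    are dropped pairwise per feature. Returns a DataFrame with columns
    feature, effect, stat, p, q, n_high, n_low.
    """
    hi, lo = _class_columns(features, labels)
    X = features.values
    if features.is_binary:
        return _compare_binary(features, X, hi, lo, alternative)
    return _compare_continuous(features, X, hi, lo)


def _compare_binary(features, X, hi, lo, alternative) -> pd.DataFrame:
    rows = []
    for i, feat in enumerate(features.feature_ids):
        xh = X[i, hi]
        xl = X[i, lo]
        xh = xh[np.isfinite(xh)]
        xl = xl[np.isfinite(xl)]
        if xh.size < 2 or xl.size < 2:
            continue
        a, b = int(xh.sum()), int(xh.size - xh.sum())
        c, d = int(xl.sum()), int(xl.size - xl.sum())
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        effect = a / xh.size - c / xl.size
        rows.append(
            {"feature": feat, "effect": effect, "stat": np.nan, "p": p,
             "n_high": xh.size, "n_low": xl.size}
        )
    df = pd.DataFrame(rows, columns=["feature", "effect", "stat", "p", "n_high", "n_low"])
    df["q"] = bh_fdr(df["p"].values) if len(df) else []
    return df[["feature", "effect", "stat", "p", "q", "n_high", "n_low"]]


def _compare_continuous(features, X, hi, lo) -> pd.DataFrame:
    keep, effects, s2s, dfs, units, nh_list, nl_list = [], [], [], [], [], [], []
    for i, feat in enumerate(features.feature_ids):
        xh = X[i, hi]
        xl = X[i, lo]
        xh = xh[np.isfinite(xh)]
        xl = xl[np.isfinite(xl)]
        if xh.size < 2 or xl.size < 2:
            continue
        pooled = np.concatenate([xh, xl])
        if np.ptp(pooled) == 0:  # constant feature: untestable
            continue
        n1, n2 = xh.size, xl.size
        sp2 = ((n1 - 1) * xh.var(ddof=1) + (n2 - 1) * xl.var(ddof=1)) / (n1 + n2 - 2)
        keep.append(feat)
        effects.append(xh.mean() - xl.mean())
        s2s.append(sp2)
        dfs.append(n1 + n2 - 2)
        units.append(np.sqrt(1.0 / n1 + 1.0 / n2))
        nh_list.append(n1)
        nl_list.append(n2)
    if not keep:
        return pd.DataFrame(
            columns=["feature", "effect", "stat", "p", "q", "n_high", "n_low"]
        )
    # residual df can vary with missingness; shrink on the modal df
    df_mode = float(np.bincount(dfs).argmax())
    t, p, _, _ = moderated_t_pvalues(
        effect=np.array(effects),
        stderr_unit=np.array(units),
        s2=np.array(s2s),
        df=df_mode,
    )
    out = pd.DataFrame(
        {"feature": keep, "effect": effects, "stat": t, "p": p,
         "n_high": nh_list, "n_low": nl_list}
    )
    out["q"] = bh_fdr(out["p"].values)
    return out[["feature", "effect", "stat", "p", "q", "n_high", "n_low"]]


def rank_top_correlates(result: pd.DataFrame, k: int | None = None) -> pd.DataFrame:
    """Order features by signed effect (descending), ties broken by
    smaller q then feature name; deterministic. ``k`` truncates."""
    ranked = result.sort_values(
        by=["effect", "q", "feature"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return ranked.head(k) if k is not None else ranked
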