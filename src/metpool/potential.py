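"""Metastatic-potential estimation from pooled barcode counts.

Two estimators are provided:

* **Absolute potential** M_ij: the mean over mice of the inferred number
  of cancer cells of line j in organ i — the organ's total sorted cancer
  cell count c_i times the line's barcode fraction p_j in that mouse.
  Units are cells.
* **Relative potential** rM_ij: the mean over mice of the line's
  depth-normalized organ read count divided by its mean depth-normalized
  pre-injection read count. Dimensionless; rM = 1 means the line is as
  abundant in the organ as it was in the injected pool.

Penetrance is the fraction of mice in which a line is detected in an
organ under a configurable detection rule (default: at least 5 raw
reads). Confidence intervals come from a percentile bootstrap that
resamples *mice* — the biological replicate — with replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .barcode_quant import CompositionEstimate, depth_normalize
from .core_io import (
    PRE_INJECTION,
    BarcodeCountTable,
    CellCountTable,
    SampleMeta,
)


@dataclass
class PotentialTable:
    """Per (cell line, organ) potential estimates with uncertainty.

    ``kind`` is ``"absolute"`` (M_ij, cells) or ``"relative"`` (rM_ij,
    dimensionless). Undefined entries (e.g. a line absent from the
    pre-injection pool) are NaN, never infinite.
    """

    lines: list[str]
    organs: list[str]
    potential: np.ndarray  # (n_lines, n_organs)
    ci_low: np.ndarray
    ci_high: np.ndarray
    penetrance: np.ndarray  # in [0, 1]
    n_mice: np.ndarray  # (n_organs,)
    kind: str  # absolute | relative

    def __post_init__(self) -> None:
        if self.kind not in ("absolute", "relative"):
            raise ValueError(f"unknown potential kind {self.kind!r}")
        shape = (len(self.lines), len(self.organs))
        for name in ("potential", "ci_low", "ci_high", "penetrance"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            setattr(self, name, arr)
        with np.errstate(invalid="ignore"):
            if np.any(self.ci_low > self.potential + 1e-9) or np.any(
                self.ci_high < self.potential - 1e-9
            ):
                raise ValueError("confidence bounds must bracket the estimate")
            pen = self.penetrance[np.isfinite(self.penetrance)]
            if np.any((pen < 0) | (pen > 1)):
                raise ValueError("penetrance must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.potential, index=self.lines, columns=self.organs)


def _line_labels(library) -> tuple[list[str], np.ndarray]:
    """Map barcodes to cell-line labels (barcode id when unnamed); returns
    unique labels in library order and the barcode->label index."""
    labels = [bc.cell_line or bc.id for bc in library]
    uniq: list[str] = []
    index = {}
    for lab in labels:
        if lab not in index:
            index[lab] = len(uniq)
            uniq.append(lab)
    return uniq, np.array([index[lab] for lab in labels])


def _collapse_lines(matrix: np.ndarray, line_idx: np.ndarray, n_lines: int) -> np.ndarray:
    """Sum barcode rows sharing a cell line."""
    out = np.zeros((n_lines, matrix.shape[1]), dtype=matrix.dtype)
    np.add.at(out, line_idx, matrix)
    return out


def _organ_groups(samples: Sequence[SampleMeta]) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        if s.organ != PRE_INJECTION:
            groups.setdefault(s.organ, []).append(i)
    return groups


def expanded_tail_level(level: float, n: int) -> float:
    """Small-sample adjusted tail level for percentile intervals.

    Plain percentile intervals are systematically narrow with few
    resampling units (they behave like z-intervals built on a /n rather
    than /(n-1) variance). The expanded-percentile correction reads the
    bootstrap distribution at the wider tail level
    Phi(t_{alpha/2, n-1} * sqrt(n/(n-1))) so that nominal coverage is
    restored for mean-like statistics at small n.
    """
    from scipy import stats as _stats

    alpha = (1.0 - level) / 2.0
    if n < 2:
        return alpha
    t = _stats.t.ppf(alpha, df=n - 1) * np.sqrt(n / (n - 1))
    return float(_stats.norm.cdf(t))


def bootstrap_ci(
    per_mouse_values: np.ndarray,
    B: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    statistic: Callable[[np.ndarray], np.ndarray] | None = None,
    expand: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap over mice.

    ``per_mouse_values`` has mice on the **last** axis; the same mouse
    resample is applied across all leading axes (lines, organs), keeping
    within-mouse correlation intact. The statistic (default: mean over
    mice) is recomputed on each resample and tail quantiles of the B
    replicates are returned as (ci_low, ci_high). By default the tail
    levels carry the expanded-percentile small-sample adjustment
    (``expand=False`` gives the plain percentile interval).
    Deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    values = np.asarray(per_mouse_values, dtype=float)
    n = values.shape[-1]
    if n < 1:
        raise ValueError("need at least one mouse")
    if statistic is None:
        statistic = lambda v: np.nanmean(v, axis=-1)
    rng = np.random.default_rng(seed)
    reps = np.empty((B,) + values.shape[:-1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        for b in range(B):
            idx = rng.integers(0, n, size=n)
            reps[b] = statistic(values[..., idx])
        alpha = expanded_tail_level(level, n) if expand else (1.0 - level) / 2.0
        lo = np.nanquantile(reps, alpha, axis=0)
        hi = np.nanquantile(reps, 1.0 - alpha, axis=0)
    return lo, hi


def penetrance(
    organ_counts: BarcodeCountTable,
    min_reads: int | None = 5,
    min_fraction: float | None = None,
) -> pd.DataFrame:
    """Fraction of mice in which each line is detected in each organ.

    Detection is ``raw reads >= min_reads`` (default 5) or, if
    ``min_fraction`` is given instead, ``barcode fraction >=
    min_fraction`` within the mouse's assigned reads.
    """
    if min_fraction is not None:
        min_reads = None
    lines, line_idx = _line_labels(organ_counts.library)
    raw = _collapse_lines(organ_counts.counts, line_idx, len(lines))
    groups = _organ_groups(organ_counts.samples)
    out = np.zeros((len(lines), len(groups)))
    organs = sorted(groups)
    for j, organ in enumerate(organs):
        cols = groups[organ]
        sub = raw[:, cols].astype(float)
        if min_reads is not None:
            detected = sub >= min_reads
        else:
            totals = sub.sum(axis=0)
            frac = sub / np.where(totals > 0, totals, 1.0)
            detected = frac >= min_fraction
        out[:, j] = detected.mean(axis=1)
    return pd.DataFrame(out, index=lines, columns=organs)


def absolute_potential(
    compositions: CompositionEstimate,
    cell_counts: CellCountTable,
    B: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> PotentialTable:
    """Absolute metastatic potential M_ij = mean over mice of c_i * p_j.

    ``compositions`` must carry one sample per (mouse, organ); each needs
    a matching total cell count. Detection for penetrance is p_j > 0.
    """
    lines, line_idx = _line_labels_from_ids(compositions)
    groups = _organ_groups(compositions.samples)
    organs = sorted(groups)
    n_lines = len(lines)
    pot = np.full((n_lines, len(organs)), np.nan)
    lo = np.full_like(pot, np.nan)
    hi = np.full_like(pot, np.nan)
    pen = np.zeros_like(pot)
    n_mice = np.zeros(len(organs), dtype=int)
    for j, organ in enumerate(organs):
        cols = groups[organ]
        per_mouse = np.empty((n_lines, len(cols)))
        for k, col in enumerate(cols):
            s = compositions.samples[col]
            c = cell_counts.get(s.mouse_id, s.organ)
            if c is None:
                raise ValueError(
                    f"no total cell count for mouse {s.mouse_id!r}, organ {s.organ!r}"
                )
            frac = compositions.fractions[:, col]
            collapsed = np.zeros(n_lines)
            np.add.at(collapsed, line_idx, np.nan_to_num(frac))
            per_mouse[:, k] = c * collapsed
        n_mice[j] = len(cols)
        pot[:, j] = per_mouse.mean(axis=1)
        blo, bhi = bootstrap_ci(per_mouse, B=B, level=level, seed=seed)
        # percentile intervals at small B may miss the point estimate
        lo[:, j] = np.fmin(blo, pot[:, j])
        hi[:, j] = np.fmax(bhi, pot[:, j])
        pen[:, j] = (per_mouse > 0).mean(axis=1)
    return PotentialTable(
        lines=lines, organs=organs, potential=pot, ci_low=lo, ci_high=hi,
        penetrance=pen, n_mice=n_mice, kind="absolute",
    )


def _line_labels_from_ids(compositions: CompositionEstimate):
    # compositions carry barcode ids only; treat each barcode as a line
    lines = list(compositions.barcode_ids)
    return lines, np.arange(len(lines))


def relative_potential(
    organ_counts: BarcodeCountTable,
    preinjection_counts: BarcodeCountTable,
    B: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    detection_min_reads: int = 5,
) -> PotentialTable:
    """Relative metastatic potential rM_ij.

    Counts are depth-normalized (counts-per-million) internally;
    rM_ij = mean over mice of normalized organ counts of line j, divided
    by the mean over pre-injection replicates of its normalized counts.
    Lines with zero pre-injection counts in every replicate get NaN (with
    a warning), never infinity. Bootstrap CIs resample mice, holding the
    pre-injection denominator fixed.
    """
    if organ_counts.library != preinjection_counts.library:
        raise ValueError("organ and pre-injection tables use different libraries")
    lines, line_idx = _line_labels(organ_counts.library)
    n_lines = len(lines)

    org_norm = _collapse_lines(depth_normalize(organ_counts), line_idx, n_lines)
    pre_norm = _collapse_lines(
        depth_normalize(preinjection_counts), line_idx, n_lines
    )
    if pre_norm.shape[1] < 1:
        raise ValueError("need at least one pre-injection replicate")
    pre_mean = pre_norm.mean(axis=1)
    absent = pre_mean == 0
    if absent.any():
        missing = [lines[i] for i in np.flatnonzero(absent)]
        warnings.warn(
            f"{len(missing)} line(s) absent from the pre-injection pool; "
            f"relative potential undefined for: {missing[:10]}"
        )
    denom = np.where(absent, np.nan, pre_mean)

    groups = _organ_groups(organ_counts.samples)
    organs = sorted(groups)
    pot = np.full((n_lines, len(organs)), np.nan)
    lo = np.full_like(pot, np.nan)
    hi = np.full_like(pot, np.nan)
    n_mice = np.zeros(len(organs), dtype=int)
    for j, organ in enumerate(organs):
        cols = groups[organ]
        per_mouse = org_norm[:, cols] / denom[:, None]
        n_mice[j] = len(cols)
        pot[:, j] = per_mouse.mean(axis=1)
        blo, bhi = bootstrap_ci(per_mouse, B=B, level=level, seed=seed)
        lo[:, j] = np.fmin(blo, pot[:, j])
        hi[:, j] = np.fmax(bhi, pot[:, j])
    pen = penetrance(organ_counts, min_reads=detection_min_reads)
    pen = pen.reindex(index=lines, columns=organs).values
    return PotentialTable(
        lines=lines, organs=organs, potential=pot, ci_low=lo, ci_high=hi,
        penetrance=pen, n_mice=n_mice, kind="relative",
    )


def overall_potential(
    table: PotentialTable,
    floor: float = 1e-4,
    aggregate: Callable[[np.ndarray], np.ndarray] | None = None,
) -> pd.Series:
    """Single overall-potential scalar per line: the mean over organs of
    floored log10 relative potential. The floor (default 1e-4) bounds the
    penalty for organs where a line was never detected; NaN (undefined)
    organs are skipped."""
    if table.kind != "relative":
        raise ValueError("overall potential is defined for relative tables")
    if len(table.organs) == 0:
        raise ValueError("empty organ set")
    logp = np.log10(np.maximum(table.potential, floor))
    if aggregate is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            agg = np.nanmean(logp, axis=1)
    else:
        agg = aggregate(logp)
    return pd.Series(agg, index=table.lines, name="overall_log10_potential")


def export_petal(table: PotentialTable, path: str | Path | None = None) -> pd.DataFrame:
    """Long-format petal-plot quantities: one row per (line, organ) with
    potential (petal length), CI bounds, and penetrance (petal width)."""
    rows = []
    for i, line in enumerate(table.lines):
        for j, organ in enumerate(table.organs):
            rows.append(
                {
                    "line": line,
                    "organ": organ,
                    "potential": table.potential[i, j],
                    "ci_low": table.ci_low[i, j],
                    "ci_high": table.ci_high[i, j],
                    "penetrance": table.penetrance[i, j],
                }
            )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
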