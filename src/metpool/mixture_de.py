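"""Composition-corrected differential expression via in-silico mixtures.

A bulk expression profile measured from a metastasis formed by a *pool*
of cell lines is confounded by the pool's composition: organs colonized
by different lines differ in expression for compositional reasons alone.
The correction is to pair every in vivo sample with an *in-silico
mixture* — the composition-weighted average of the constituent lines'
baseline (in vitro) profiles, mixed on the linear scale:

    g_hat_i = sum_j g_ij p_j

where p_j is line j's barcode fraction in that sample. The in vivo
profile and its matched mixture are then compared gene-by-gene with a
paired moderated t-test per organ: paired differences d = log2(in vivo)
- log2(in silico), gene-wise variances shrunk toward a moment-matched
empirical-Bayes prior, p-values from a t distribution with the gained
degrees of freedom, Benjamini-Hochberg adjustment across genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._moderated import bh_fdr as _bh_fdr
from ._moderated import moderated_t_pvalues
from .barcode_quant import CompositionEstimate
from .core_io import ExpressionMatrix

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class MixtureProfile:
    """In-silico mixture expression for one in vivo sample (linear scale)."""

    values: np.ndarray  # per gene
    gene_ids: list[str]
    sample_id: str
    composition: dict[str, float]  # line -> fraction actually used


@dataclass
class DEResult:
    """Per-organ differential-expression table.

    ``table`` columns: gene, lfc (log2 in vivo minus in silico), t
    (moderated), p, q (Benjamini-Hochberg). ``excluded_genes`` lists
    genes dropped as all-constant.
    """

    organ: str
    table: pd.DataFrame
    n_pairs: int
    prior_df: float
    excluded_genes: list[str]


def _composition_mapping(
    composition: Mapping[str, float] | CompositionEstimate,
    sample: int | str = 0,
) -> tuple[dict[str, float], str]:
    if isinstance(composition, CompositionEstimate):
        if isinstance(sample, str):
            idx = [s.sample_id for s in composition.samples].index(sample)
        else:
            idx = sample
        mapping = dict(zip(composition.barcode_ids, composition.fractions[:, idx]))
        return mapping, composition.samples[idx].sample_id
    return dict(composition), "mixture"


def insilico_mixture(
    invitro: ExpressionMatrix,
    composition: Mapping[str, float] | CompositionEstimate,
    sample: int | str = 0,
    tol: float = 1e-6,
) -> MixtureProfile:
    """Composition-weighted average of baseline profiles, linear scale.

    ``invitro`` columns are cell lines (matched by sample_id); only lines
    with fraction > 0 participate and each must be present. Fractions
    must sum to 1 within ``tol``.
    """
    if invitro.scale == "log2":
        raise ValueError("mixing must happen on the linear scale, not log2")
    frac, sample_id = _composition_mapping(composition, sample)
    active = {k: v for k, v in frac.items() if v > 0}
    total = sum(active.values())
    if not np.isfinite(total) or abs(total - 1.0) > tol:
        raise ValueError(f"composition sums to {total!r}, not 1 within {tol}")
    cols = {s.sample_id: i for i, s in enumerate(invitro.samples)}
    missing = sorted(set(active) - set(cols))
    if missing:
        raise ValueError(f"lines in composition missing from in vitro matrix: {missing}")
    mix = np.zeros(len(invitro.gene_ids))
    for line, p in active.items():
        mix += p * invitro.values[:, cols[line]]
    return MixtureProfile(
        values=mix, gene_ids=list(invitro.gene_ids),
        sample_id=sample_id, composition=active,
    )


def mixture_matrix(
    invitro: ExpressionMatrix, compositions: CompositionEstimate
) -> ExpressionMatrix:
    """Build the full in-silico counterpart matrix, one mixture per
    composition sample."""
    profiles = [
        insilico_mixture(invitro, compositions, sample=i)
        for i in range(len(compositions.samples))
    ]
    return ExpressionMatrix(
        values=np.column_stack([p.values for p in profiles]),
        gene_ids=list(invitro.gene_ids),
        samples=list(compositions.samples),
        scale=invitro.scale,
    )


def log2_cpm(matrix: ExpressionMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> ExpressionMatrix:
    """Library-size normalize to counts-per-million and log2-transform
    with a pseudocount. A no-op on matrices already in log2."""
    if matrix.scale == "log2":
        return matrix
    vals = matrix.values
    if matrix.scale == "counts":
        totals = vals.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError("cannot CPM-normalize zero-total samples")
        vals = vals * (1e6 / totals)
    return ExpressionMatrix(
        values=np.log2(vals + pseudocount),
        gene_ids=list(matrix.gene_ids),
        samples=list(matrix.samples),
        scale="log2",
    )


def paired_moderated_test(
    invivo: ExpressionMatrix,
    insilico: ExpressionMatrix,
    organ_labels: Sequence[str] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> dict[str, DEResult]:
    """Paired moderated t-test of in vivo vs matched in-silico mixture,
    run separately for each organ.

    Columns of the two matrices are paired positionally (sample i of
    ``invivo`` against mixture i of ``insilico``). Matrices on a linear
    scale are log2(CPM + pseudocount)-transformed first. Each organ needs
    at least two pairs. Genes whose paired differences are identical in
    every pair of an organ are reported with the common difference as the
    LFC; genes constant *and equal* across both matrices everywhere are
    testable but carry no signal (t=0, p=1).
    """
    if invivo.values.shape != insilico.values.shape:
        raise ValueError("in vivo and in silico matrices must have equal shape")
    if list(invivo.gene_ids) != list(insilico.gene_ids):
        raise ValueError("gene ids differ between in vivo and in silico matrices")
    if organ_labels is None:
        organ_labels = [s.organ for s in invivo.samples]
    organ_labels = list(organ_labels)
    if len(organ_labels) != len(invivo.samples):
        raise ValueError("organ_labels length must match sample count")

    a = log2_cpm(invivo, pseudocount).values
    b = log2_cpm(insilico, pseudocount).values
    d = a - b  # genes x samples, paired differences

    results: dict[str, DEResult] = {}
    for organ in sorted(set(organ_labels)):
        cols = [i for i, o in enumerate(organ_labels) if o == organ]
        n = len(cols)
        if n < 2:
            raise ValueError(
                f"organ {organ!r} has {n} pair(s); the paired test needs >= 2"
            )
        do = d[:, cols]
        dbar = do.mean(axis=1)
        s2 = do.var(axis=1, ddof=1)
        t, p, df_total, prior = moderated_t_pvalues(
            effect=dbar, stderr_unit=1.0 / np.sqrt(n), s2=s2, df=n - 1
        )
        q = _bh_fdr(p)
        table = pd.DataFrame(
            {"gene": invivo.gene_ids, "lfc": dbar, "t": t, "p": p, "q": q}
        )
        results[organ] = DEResult(
            organ=organ,
            table=table,
            n_pairs=n,
            prior_df=prior.d0,
            excluded_genes=[],
        )
    return results


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, clipped to [0,1])."""
    return _bh_fdr(np.asarray(pvalues, dtype=float))


def signature_score(
    expr: ExpressionMatrix, gene_set: Sequence[str]
) -> pd.Series:
    """Mean gene-wise z-score of a gene set, per sample.

    Each set gene is standardized across samples (sample mean 0, sd 1,
    ddof=1); a sample's score is the mean standardized value over the set
    genes found in the matrix. Invariant to gene-wise affine rescaling.
    """
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    present = [g for g in gene_set if g in gene_index]
    if not present:
        raise ValueError(
            f"no gene-set members found in matrix; missing: {sorted(gene_set)[:10]}"
        )
    rows = np.array([gene_index[g] for g in present])
    sub = expr.values[rows]
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)  # constant genes contribute 0
    z = (sub - mu) / sd
    return pd.Series(z.mean(axis=0), index=expr.sample_ids, name="signature_score")
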