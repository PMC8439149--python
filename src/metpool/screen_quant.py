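"""Mini-pool in vivo CRISPR screen scoring.

Guide counts from tissue and reference (pre-injection) samples are
depth-normalized with the upper-quartile method, log2-transformed, and
each guide's log2 fold-change (tissue minus reference) is computed. A
gene's depletion or enrichment is then tested by contrasting its guides'
LFCs against the distribution of control-guide LFCs with a moderated
two-sample t — anchoring on controls absorbs global outgrowth
differences between animals, which in intracranial mini-pools span
orders of magnitude. q-values are Benjamini-Hochberg across genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from scipy import stats

from ._moderated import bh_fdr

CONTROL_GENE = "control"
LOG_PSEUDOCOUNT = 0.5


@dataclass
class GuideLibrary:
    """CRISPR guide registry: guide id, target gene (or the control
    class), ~20-nt spacer sequence."""

    guides: pd.DataFrame  # columns: guide_id, gene, sequence, is_control

    def __post_init__(self) -> None:
        required = {"guide_id", "gene"}
        if not required.issubset(self.guides.columns):
            raise ValueError(f"guide table needs columns {sorted(required)}")
        if self.guides["guide_id"].duplicated().any():
            dup = self.guides.loc[self.guides["guide_id"].duplicated(), "guide_id"]
            raise ValueError(f"duplicate guide ids: {dup.tolist()}")
        if "is_control" not in self.guides.columns:
            self.guides = self.guides.assign(
                is_control=self.guides["gene"].str.lower().eq(CONTROL_GENE)
            )
        if "sequence" not in self.guides.columns:
            self.guides = self.guides.assign(sequence="")

    @property
    def guide_ids(self) -> list[str]:
        return self.guides["guide_id"].tolist()

    @property
    def genes(self) -> list[str]:
        mask = ~self.guides["is_control"]
        return sorted(self.guides.loc[mask, "gene"].unique())

    @property
    def n_controls(self) -> int:
        return int(self.guides["is_control"].sum())


def read_guide_library(path: str | Path) -> GuideLibrary:
    """Read a guide library CSV (columns guide_id, gene, sequence;
    guides with gene == 'control' are the control class)."""
    return GuideLibrary(pd.read_csv(path, dtype=str).fillna(""))


@dataclass
class ScreenResult:
    """Gene- and guide-level screen statistics.

    ``gene_table`` columns: gene, lfc (mean of its guides' LFCs), t, p,
    q, n_guides. ``guide_table`` columns: guide_id, gene, is_control,
    lfc. ``excluded_genes`` lists genes with no guides in the counts.
    """

    gene_table: pd.DataFrame
    guide_table: pd.DataFrame
    excluded_genes: list[str]


def upper_quartile_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Upper-quartile depth normalization.

    Each sample is scaled so its 75th percentile of *nonzero* counts
    equals the geometric mean of all samples' 75th percentiles.
    Idempotent; a single sample is returned unchanged (its UQ is its own
    geometric mean). All-zero samples are an error.
    """
    vals = counts.values.astype(float)
    uqs = np.empty(vals.shape[1])
    for j in range(vals.shape[1]):
        nonzero = vals[vals[:, j] > 0, j]
        if nonzero.size == 0:
            raise ValueError(f"sample {counts.columns[j]!r} has no nonzero guide counts")
        uqs[j] = np.percentile(nonzero, 75)
    target = np.exp(np.mean(np.log(uqs)))
    return pd.DataFrame(
        vals * (target / uqs), index=counts.index, columns=counts.columns
    )


def guide_depletion(
    normalized: pd.DataFrame,
    design: Sequence[str],
    library: GuideLibrary,
    pseudocount: float = LOG_PSEUDOCOUNT,
) -> ScreenResult:
    """Quantify per-gene depletion/enrichment relative to control guides.

    ``design`` labels each sample column as ``"reference"`` or
    ``"tissue"`` (>= 2 tissue replicates required). Per guide,
    LFC = mean log2(normalized + pseudocount) over tissue minus over
    reference. Gene-level inference is a one-way linear model on the
    guide LFCs (groups: each gene, plus the control class): a single
    residual variance is estimated from all within-group scatter, and
    each gene is tested by the contrast mean(gene guides) minus
    mean(control guides) with a t on the model's residual degrees of
    freedom. This is the complete-pooling limit of empirical-Bayes
    variance moderation, appropriate here because a two-guide gene
    carries only one residual degree of freedom of its own. BH across
    genes.
    """
    design = list(design)
    if len(design) != normalized.shape[1]:
        raise ValueError("design length must match sample count")
    bad = set(design) - {"reference", "tissue"}
    if bad:
        raise ValueError(f"design labels must be reference/tissue, got {sorted(bad)}")
    tis = np.array([d == "tissue" for d in design])
    ref = ~tis
    if tis.sum() < 2:
        raise ValueError("need >= 2 tissue replicates")
    if ref.sum() < 1:
        raise ValueError("need >= 1 reference sample")

    guides = library.guides.set_index("guide_id")
    known = [g for g in normalized.index if g in guides.index]
    unknown = set(normalized.index) - set(known)
    if unknown:
        raise ValueError(f"counts contain guides not in library: {sorted(unknown)[:10]}")
    log = np.log2(normalized.loc[known].values + pseudocount)
    lfc = log[:, tis].mean(axis=1) - log[:, ref].mean(axis=1)
    guide_table = pd.DataFrame(
        {
            "guide_id": known,
            "gene": guides.loc[known, "gene"].values,
            "is_control": guides.loc[known, "is_control"].values.astype(bool),
            "lfc": lfc,
        }
    )

    ctrl = guide_table.loc[guide_table["is_control"], "lfc"].values
    if ctrl.size < 2:
        raise ValueError("need >= 2 control guides for the control-anchored contrast")
    n_c = ctrl.size
    ctrl_mean = ctrl.mean()

    # one-way layout: pooled residual variance over all groups
    rss = float(((ctrl - ctrl_mean) ** 2).sum())
    df_resid = n_c - 1
    per_gene: dict[str, np.ndarray] = {}
    excluded = []
    for gene in library.genes:
        g_lfc = guide_table.loc[
            (guide_table["gene"] == gene) & ~guide_table["is_control"], "lfc"
        ].values
        if g_lfc.size == 0:
            excluded.append(gene)
            continue
        per_gene[gene] = g_lfc
        rss += float(((g_lfc - g_lfc.mean()) ** 2).sum())
        df_resid += g_lfc.size - 1

    if per_gene:
        if df_resid < 1:
            raise ValueError("no residual degrees of freedom: need replicate guides")
        s2 = rss / df_resid
        genes = list(per_gene)
        gene_lfc = np.array([per_gene[g].mean() for g in genes])
        n_guides = np.array([per_gene[g].size for g in genes])
        effects = gene_lfc - ctrl_mean
        se = np.sqrt(s2 * (1.0 / n_guides + 1.0 / n_c))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, effects / np.where(se > 0, se, 1.0), 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df=df_resid)
        q = bh_fdr(p)
        gene_table = pd.DataFrame(
            {"gene": genes, "lfc": gene_lfc, "effect_vs_control": effects,
             "t": t, "p": p, "q": q, "n_guides": n_guides}
        )
    else:
        gene_table = pd.DataFrame(
            columns=["gene", "lfc", "effect_vs_control", "t", "p", "q", "n_guides"]
        )
    return ScreenResult(
        gene_table=gene_table, guide_table=guide_table, excluded_genes=excluded
    )
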