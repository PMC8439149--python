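"""Forward simulation of pooled in vivo barcoding experiments.

The generative model mirrors the intracardiac pooled-injection assay:

1. A library of distinct random 26-nt barcodes, one per cell line.
2. The pre-injection pool is nominally equimolar; replicate sequencing
   of it sees equal proportions up to multiplicative lognormal jitter.
3. In each mouse and organ, each line seeds independently with its
   penetrance probability. A seeded line grows to
   ``cells_per_line x 10^potential x LogNormal(0, growth_cv)`` cells,
   where the organ-specific log10 potential spans several orders of
   magnitude (default Uniform(-4, 1)); an unseeded line contributes 0.
4. The organ's barcode composition is the cell-number simplex; amplicon
   sequencing draws reads from a Dirichlet-multinomial whose
   concentration ``overdispersion x p`` controls extra-multinomial
   noise (the multinomial limit as overdispersion -> infinity).
5. The total cells per (mouse, organ) — what sorting would report — is
   the sum of the per-line cell numbers.

Everything is deterministic given the seed. ``emit_fastq`` additionally
materializes reads (each embedding its barcode in random flanking
sequence, with an optional per-base error rate), so the read-matching
stage can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core_io import (
    CANONICAL_ORGANS,
    PRE_INJECTION,
    Barcode,
    BarcodeCountTable,
    BarcodeLibrary,
    CellCountTable,
    ExpressionMatrix,
    SampleMeta,
)

_NT = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-design parameters of a simulated pooled experiment.

    Defaults follow the 25-lines-per-pool intracardiac design: 5 target
    organs, cohorts of 5 mice, 500 injected cells per line, organ
    potentials spanning Uniform(-4, 1) in log10, incomplete penetrance
    (0.8), lognormal outgrowth with CV 0.5, one million reads per
    sample, and moderately overdispersed counts (Dirichlet concentration
    100).
    """

    n_lines: int = 25
    organs: tuple[str, ...] = CANONICAL_ORGANS
    n_mice: int = 5
    cells_per_line: int = 500
    true_log10_potential: np.ndarray | None = None  # (n_lines, n_organs)
    potential_range: tuple[float, float] = (-4.0, 1.0)
    penetrance_prob: np.ndarray | float = 0.8
    growth_cv: float = 0.5
    read_depth: int = 1_000_000
    overdispersion: float = 100.0
    n_pre_replicates: int = 3
    pre_jitter_sd: float = 0.2
    barcode_length: int = 26
    read_length: int = 75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1 or self.n_mice < 1 or self.read_depth < 1:
            raise ValueError("n_lines, n_mice and read_depth must be positive")
        if self.overdispersion < 0 or self.growth_cv < 0:
            raise ValueError("overdispersion and growth_cv must be >= 0")
        pen = np.asarray(self.penetrance_prob, dtype=float)
        if np.any((pen < 0) | (pen > 1)):
            raise ValueError("penetrance probabilities must lie in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment, for recovery testing."""

    true_log10_potential: np.ndarray  # (n_lines, n_organs)
    penetrance_prob: np.ndarray  # (n_lines, n_organs)
    cells: np.ndarray  # (n_lines, n_organs, n_mice) realized cell numbers
    compositions: np.ndarray  # (n_lines, n_organs, n_mice), NaN where organ empty
    pre_fractions: np.ndarray  # (n_lines,) true injected proportions
    line_ids: list[str]
    organs: list[str]


def random_library(
    n: int, length: int = 26, rng: np.random.Generator | None = None
) -> BarcodeLibrary:
    """Generate ``n`` distinct random barcodes of the given length."""
    rng = rng or np.random.default_rng()
    seqs: set[str] = set()
    while len(seqs) < n:
        seqs.add("".join(rng.choice(_NT, size=length)))
    ordered = sorted(seqs)
    rng.shuffle(ordered)
    return BarcodeLibrary.from_barcodes(
        Barcode(id=f"BC{i:04d}", sequence=s, cell_line=f"line{i:04d}")
        for i, s in enumerate(ordered)
    )


def _dirichlet_multinomial(
    rng: np.random.Generator, depth: int, p: np.ndarray, concentration: float
) -> np.ndarray:
    """One Dirichlet-multinomial draw over the support of ``p``."""
    counts = np.zeros(p.size, dtype=np.int64)
    pos = p > 0
    if not pos.any():
        return counts
    if np.isinf(concentration):
        probs = p[pos] / p[pos].sum()
    else:
        probs = rng.dirichlet(concentration * p[pos] / p[pos].sum())
        total = probs.sum()
        if total <= 0:  # extreme sparsity can zero the draw numerically
            probs = p[pos] / p[pos].sum()
        else:
            probs = probs / total
    counts[pos] = rng.multinomial(depth, probs)
    return counts


def simulate_experiment(
    config: SimConfig,
    library: BarcodeLibrary | None = None,
) -> tuple[BarcodeCountTable, CellCountTable, SimTruth]:
    """Simulate a full pooled experiment.

    Returns the count table over all samples (pre-injection replicates
    first, then one sample per (organ, mouse)), the per-(mouse, organ)
    total-cell table, and the ground truth. A configuration whose
    penetrance is everywhere zero is valid and yields all-zero organ
    counts (with a warning).
    """
    rng = np.random.default_rng(config.seed)
    n, organs, m = config.n_lines, list(config.organs), config.n_mice
    if library is None:
        library = random_library(n, config.barcode_length, rng)
    elif len(library) != n:
        raise ValueError("library size does not match n_lines")

    if config.true_log10_potential is None:
        lo, hi = config.potential_range
        pot = rng.uniform(lo, hi, size=(n, len(organs)))
    else:
        pot = np.asarray(config.true_log10_potential, dtype=float)
        if pot.shape != (n, len(organs)):
            raise ValueError("true_log10_potential shape mismatch")
    pen = np.broadcast_to(
        np.asarray(config.penetrance_prob, dtype=float), (n, len(organs))
    ).copy()
    if np.all(pen == 0):
        import warnings

        warnings.warn("penetrance is zero everywhere; organ counts will be all zero")

    # pre-injection pool: equimolar with lognormal jitter, renormalized
    pre_frac = np.exp(rng.normal(0.0, config.pre_jitter_sd, size=n))
    pre_frac /= pre_frac.sum()

    samples: list[SampleMeta] = []
    columns: list[np.ndarray] = []
    for r in range(config.n_pre_replicates):
        samples.append(
            SampleMeta(
                sample_id=f"pre_{r}", organ=PRE_INJECTION, replicate_index=r
            )
        )
        columns.append(
            _dirichlet_multinomial(
                rng, config.read_depth, pre_frac, config.overdispersion
            )
        )

    cells = np.zeros((n, len(organs), m))
    comps = np.full((n, len(organs), m), np.nan)
    total_cells: dict[tuple[str, str], float] = {}
    for oi, organ in enumerate(organs):
        for k in range(m):
            mouse = f"mouse_{organ}_{k}"
            seeded = rng.random(n) < pen[:, oi]
            growth = np.exp(rng.normal(0.0, config.growth_cv, size=n))
            c = np.where(
                seeded,
                config.cells_per_line * 10.0 ** pot[:, oi] * growth,
                0.0,
            )
            cells[:, oi, k] = c
            total = c.sum()
            total_cells[(mouse, organ)] = total
            p = c / total if total > 0 else np.zeros(n)
            if total > 0:
                comps[:, oi, k] = p
            samples.append(
                SampleMeta(
                    sample_id=f"{organ}_{k}",
                    mouse_id=mouse,
                    organ=organ,
                    replicate_index=k,
                )
            )
            columns.append(
                _dirichlet_multinomial(
                    rng, config.read_depth, p, config.overdispersion
                )
            )

    table = BarcodeCountTable(
        counts=np.column_stack(columns), library=library, samples=samples
    )
    truth = SimTruth(
        true_log10_potential=pot,
        penetrance_prob=pen,
        cells=cells,
        compositions=comps,
        pre_fractions=pre_frac,
        line_ids=[bc.cell_line or bc.id for bc in library],
        organs=organs,
    )
    return table, CellCountTable(total_cells=total_cells), truth


def emit_fastq(
    table: BarcodeCountTable,
    out_dir: str | Path,
    read_length: int = 75,
    error_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, Path]:
    """Materialize one FASTQ per sample, one read per counted fragment.

    Each read embeds its barcode at a random offset within random
    flanking sequence; with ``error_rate`` > 0, every base is substituted
    independently with that probability. With error rate 0, counting the
    emitted reads reproduces the input counts exactly.
    """
    L = table.library.barcode_length
    if read_length < L:
        raise ValueError(
            f"read_length {read_length} shorter than barcode length {L}"
        )
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seqs = table.library.sequences
    qual = "I" * read_length
    paths: dict[str, Path] = {}
    for j, sample in enumerate(table.samples):
        path = out_dir / f"{sample.sample_id}.fastq"
        with open(path, "w") as fh:
            read_no = 0
            for i, bc_seq in enumerate(seqs):
                for _ in range(int(table.counts[i, j])):
                    offset = int(rng.integers(0, read_length - L + 1))
                    flank = rng.choice(_NT, size=read_length - L)
                    read = np.empty(read_length, dtype="<U1")
                    read[:offset] = flank[:offset]
                    read[offset:offset + L] = list(bc_seq)
                    read[offset + L:] = flank[offset:]
                    if error_rate > 0:
                        hit = rng.random(read_length) < error_rate
                        if hit.any():
                            read[hit] = _NT[rng.integers(0, 4, size=int(hit.sum()))]
                    fh.write(
                        f"@{sample.sample_id}:{read_no}\n{''.join(read)}\n+\n{qual}\n"
                    )
                    read_no += 1
        paths[sample.sample_id] = path
    return paths


def simulate_expression(
    truth: SimTruth,
    n_genes: int = 2000,
    n_de: int = 0,
    de_lfc: float = 0.0,
    de_organ: str | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix, dict]:
    """Generate matched in vitro baselines and in vivo pool profiles.

    Baselines per line are lognormal on the linear scale. Each in vivo
    sample is the composition-weighted mixture of the baselines of the
    lines in it, times multiplicative lognormal noise; ``n_de`` genes
    additionally shift by ``de_lfc`` log2 units in ``de_organ`` (default:
    the first organ). The returned truth dict lists the DE gene ids and
    the exact compositions used.
    """
    if n_de > n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    n_lines = len(truth.line_ids)
    gene_ids = [f"gene{g:05d}" for g in range(n_genes)]

    base_mean = rng.lognormal(mean=4.0, sigma=1.0, size=n_genes)
    baselines = base_mean[:, None] * rng.lognormal(
        mean=0.0, sigma=0.5, size=(n_genes, n_lines)
    )
    invitro = ExpressionMatrix(
        values=baselines,
        gene_ids=gene_ids,
        samples=[SampleMeta(sample_id=l, organ="invitro") for l in truth.line_ids],
        scale="cpm",
    )

    de_organ = de_organ or truth.organs[0]
    de_genes = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], int)
    cols, metas, comps_used = [], [], {}
    for oi, organ in enumerate(truth.organs):
        for k in range(truth.compositions.shape[2]):
            p = truth.compositions[:, oi, k]
            if not np.isfinite(p).any() or np.nansum(p) == 0:
                continue
            p = np.nan_to_num(p)
            mix = baselines @ p
            if organ == de_organ and n_de:
                mix = mix.copy()
                mix[de_genes] *= 2.0 ** de_lfc
            if noise_sd > 0:
                mix = mix * rng.lognormal(0.0, noise_sd, size=n_genes)
            sid = f"{organ}_{k}_invivo"
            cols.append(mix)
            metas.append(SampleMeta(sample_id=sid, organ=organ, replicate_index=k))
            comps_used[sid] = dict(zip(truth.line_ids, p))
    invivo = ExpressionMatrix(
        values=np.column_stack(cols), gene_ids=gene_ids, samples=metas, scale="cpm"
    )
    de_truth = {
        "de_genes": [gene_ids[g] for g in de_genes],
        "de_organ": de_organ,
        "de_lfc": de_lfc,
        "compositions": comps_used,
    }
    return invitro, invivo, de_truth
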