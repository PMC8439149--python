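"""End-to-end pipeline orchestration.

A run is driven by a single YAML-serializable configuration and a single
seed. Per-stage random generators are forked from the run seed by stable
stage labels, so adding or reordering stages never silently changes the
randomness another stage sees. Every run echoes its effective
configuration and a JSON manifest (with a config hash) into the output
directory, and logs per-stage shapes and tallies to ``run.log``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import core_io
from .barcode_quant import MatchParams, count_barcodes, estimate_composition
from .core_io import PRE_INJECTION, read_barcode_library, write_count_table
from .mixture_de import mixture_matrix, paired_moderated_test
from .potential import export_petal, overall_potential, relative_potential
from .synthetic_data import SimConfig, emit_fastq, simulate_experiment, simulate_expression


def stage_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-stage generator: the run seed is combined with a
    CRC32 of the stage label so stage order is irrelevant."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(label.encode())])
    )


def stage_seed(seed: int, label: str) -> int:
    """A plain integer seed forked by stage label (for APIs taking ints)."""
    return int((seed * 1_000_003 + zlib.crc32(label.encode())) % (2**31 - 1))


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run; fully YAML-serializable."""

    out_dir: str = "metpool_run"
    seed: int = 0
    # either simulate in-process ...
    simulate: dict | None = None  # SimConfig fields
    emit_fastq: bool = False
    # ... or start from existing files
    library_path: str | None = None
    counts_path: str | None = None
    meta_path: str | None = None
    # stage parameters
    match: dict = field(default_factory=dict)  # MatchParams fields
    bootstrap_B: int = 1000
    ci_level: float = 0.95
    detection_min_reads: int = 5
    expression: dict | None = None  # simulate_expression kwargs
    error_rate: float = 0.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the stages in dependency order; identical config + seed
    gives identical outputs. Returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger = logging.getLogger("metpool.pipeline")
    logger.setLevel(logging.INFO)
    logger.handlers = [
        logging.FileHandler(out / "run.log", mode="w"),
        logging.StreamHandler(),
    ]
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in logger.handlers:
        h.setFormatter(fmt)

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    try:
        # --- stage: obtain counts ----------------------------------------
        truth = None
        cells = None
        if config.simulate is not None:
            sim_cfg = SimConfig(
                **{**config.simulate, "seed": stage_seed(config.seed, "simulate")}
            )
            table, cells, truth = simulate_experiment(sim_cfg)
            logger.info(
                "simulate: %d lines x %d samples", len(table.library), len(table.samples)
            )
            if config.emit_fastq:
                fq_dir = out / "fastq"
                emit_fastq(
                    table, fq_dir, read_length=sim_cfg.read_length,
                    error_rate=config.error_rate,
                    seed=stage_seed(config.seed, "emit_fastq"),
                )
                params = MatchParams(**config.match)
                cols = []
                for sample in table.samples:
                    col = count_barcodes(
                        fq_dir / f"{sample.sample_id}.fastq",
                        table.library, params, sample,
                    )
                    cols.append(col)
                recounted = cols[0]
                for col in cols[1:]:
                    recounted = recounted.concat(col)
                logger.info(
                    "count: re-quantified %d samples from FASTQ; "
                    "unassigned=%d ambiguous=%d",
                    len(cols), int(recounted.unassigned.sum()),
                    int(recounted.ambiguous.sum()),
                )
                table = recounted
        else:
            if not (config.library_path and config.counts_path):
                raise ValueError(
                    "config must provide either a simulate block or "
                    "library_path + counts_path"
                )
            library = read_barcode_library(config.library_path)
            samples = (
                core_io.read_sample_meta(config.meta_path)
                if config.meta_path else None
            )
            table = core_io.read_count_table(config.counts_path, library, samples)
            logger.info(
                "load: %d lines x %d samples", len(table.library), len(table.samples)
            )

        write_count_table(table, out / "counts.tsv")

        # --- stage: potential --------------------------------------------
        is_pre = [s.organ == PRE_INJECTION for s in table.samples]
        if not any(is_pre):
            raise ValueError("no pre-injection samples; cannot compute rM")
        pre = table.select_samples(is_pre)
        organs = table.select_samples([not x for x in is_pre])
        pot = relative_potential(
            organs, pre, B=config.bootstrap_B, level=config.ci_level,
            seed=stage_seed(config.seed, "bootstrap"),
            detection_min_reads=config.detection_min_reads,
        )
        petal = export_petal(pot, out / "petal.csv")
        overall = overall_potential(pot)
        overall.to_csv(out / "potential.csv", header=True, index_label="line")
        logger.info(
            "potential: %d lines x %d organs; petal rows=%d",
            len(pot.lines), len(pot.organs), len(petal),
        )

        # --- stage: expression / DE (simulation-driven only) -------------
        if config.expression is not None and truth is not None:
            invitro, invivo, de_truth = simulate_expression(
                truth, seed=stage_seed(config.seed, "expression"),
                **config.expression,
            )
            comp = estimate_composition(organs)
            # mixtures from the *measured* compositions, as in a real run
            keep = [i for i, ok in enumerate(comp.defined) if ok]
            comp_defined = estimate_composition(
                organs.select_samples([i in keep for i in range(len(organs.samples))])
            )
            # pair in vivo columns with their sample's composition
            by_sid = {s.sample_id: i for i, s in enumerate(comp_defined.samples)}
            order = [
                by_sid[s.sample_id.replace("_invivo", "")]
                for s in invivo.samples
                if s.sample_id.replace("_invivo", "") in by_sid
            ]
            comp_defined.fractions = comp_defined.fractions[:, order]
            comp_defined.samples = [comp_defined.samples[i] for i in order]
            comp_defined.assigned_total = comp_defined.assigned_total[order]
            # rename composition barcode rows to cell-line labels
            comp_defined.barcode_ids = [
                bc.cell_line or bc.id for bc in organs.library
            ]
            insilico = mixture_matrix(invitro, comp_defined)
            results = paired_moderated_test(invivo, insilico)
            for organ, res in results.items():
                res.table.to_csv(out / f"de_{organ}.tsv", sep="\t", index=False)
            logger.info("de: tested %d organs", len(results))

        manifest = {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        for h in logger.handlers:
            h.close()
        logger.handlers = []
    return out
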