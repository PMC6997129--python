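"""End-to-end orchestration: config, staged execution, manifest.

Stages mirror the analysis: prep (normalize + logFC + DE calls), classify
(mutation counts -> gene classes -> disease signature), score (connectivity
of every drug against the signature), bench (ranking, precision curve,
partitions), overlap (gene-set overlap graph, optional).  Each stage reads
the previous stage's files so it can also run standalone; ``run_pipeline``
composes them, writes every intermediate to the output directory, and records
a manifest (thresholds, seed, counts, sha256 of every output).  Two runs from
the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import benchmark as bm
from . import connectivity as cn
from . import expression as xp
from . import gene_classes as gc
from . import pathway_overlap as po

logger = logging.getLogger("kernelsig")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s:%(stage)s] %(message)s"))
    logger.addHandler(_h)
logger.setLevel(logging.INFO)


def _log(stage: str, msg: str) -> None:
    logger.info(msg, extra={"stage": stage})


class PipelineStageError(RuntimeError):
    """Failure inside a named stage, carrying the offending file/record."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    """Flat configuration for a full run; round-trips through YAML unchanged."""

    expression: str = ""
    sample_sheet: str = ""
    mutations: str = ""  # binary matrix TSV
    maf: str = ""  # alternative to `mutations`
    instances: str = ""
    benchmark: str = ""
    gene_sets_a: str = ""
    gene_sets_b: str = ""
    outdir: str = "results"
    lfc_threshold: float = xp.DEFAULT_LFC_THRESHOLD
    p_threshold: float = xp.DEFAULT_P_THRESHOLD
    mutation_fraction: float = gc.DEFAULT_MUTATION_FRACTION
    pseudocount: float = xp.DEFAULT_PSEUDOCOUNT
    top_n: int = cn.DEFAULT_TOP_N
    cutoffs: list[int] = field(default_factory=lambda: [10, 20, 30])
    min_shared: int = 1
    cmap_zeroing: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lfc_threshold", "p_threshold", "mutation_fraction", "top_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.cutoffs = [int(x) for x in self.cutoffs]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        bad = sorted(set(data) - known)
        if bad:
            raise ValueError(f"unknown config keys: {bad}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# --------------------------------------------------------------------------
# Stages.  Each takes explicit inputs and an output directory and returns
# what the next stage needs, so the CLI can run any one of them alone.
# --------------------------------------------------------------------------

def stage_prep(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    """Expression -> z-score report, logFC, p-values, DE table."""
    try:
        sheet = xp.read_sample_sheet(config.sample_sheet) if config.sample_sheet else None
        matrix = xp.read_expression_tsv(config.expression, sample_sheet=sheet)
        normalized = xp.zscore_normalize(matrix)
        logfc = xp.compute_logfc(matrix, pseudocount=config.pseudocount)
        pvals = xp.differential_test(matrix)
        de = xp.call_de_genes(logfc, pvals, config.lfc_threshold, config.p_threshold)
    except (OSError, ValueError) as exc:
        raise PipelineStageError("prep", str(exc)) from exc
    xp.write_de_table(de, outdir / "de_table.tsv")
    gc.write_grp(normalized.dropped_genes, outdir / "dropped_genes.txt")
    _log(
        "prep",
        f"{de['is_de'].sum()} DE genes of {len(de)}; "
        f"{len(normalized.dropped_genes)} zero-variance genes dropped",
    )
    return de


def stage_classify(
    config: PipelineConfig, de: pd.DataFrame, outdir: Path
) -> gc.DiseaseSignature:
    """Mutations -> counts, threshold, gene classes, disease signature."""
    try:
        if config.mutations:
            raw = pd.read_csv(config.mutations, sep="\t", index_col=0)
            if raw.empty:
                raise gc.MutationTableError(
                    f"mutation matrix {config.mutations} contains no records"
                )
            table = gc.MutationTable.from_matrix(raw)
        elif config.maf:
            table = gc.MutationTable.from_maf(config.maf)
        else:
            raise gc.MutationTableError("no mutation input configured")
        counts = gc.mutation_frequency_counts(table, gene_universe=de.index)
        threshold = gc.frequency_threshold(table.n_samples, config.mutation_fraction)
        classification = gc.classify_genes(counts, threshold, de.index[de["is_de"]])
        signature = gc.build_disease_signature(classification, de["logFC"])
    except (OSError, ValueError) as exc:
        raise PipelineStageError("classify", str(exc)) from exc
    gc.write_classification(classification, outdir / "classification.tsv")
    gc.write_grp(signature.up, outdir / "signature_up.grp")
    gc.write_grp(signature.down, outdir / "signature_down.grp")
    n_kernel = int((classification["gene_class"] == gc.KERNEL).sum())
    _log(
        "classify",
        f"threshold {threshold} of {table.n_samples} samples; {n_kernel} kernel "
        f"genes -> signature |up|={len(signature.up)} |down|={len(signature.down)}",
    )
    return signature


def stage_score(
    config: PipelineConfig, signature: gc.DiseaseSignature, outdir: Path
) -> tuple[pd.DataFrame, list[str]]:
    """Instance library -> per-drug therapeutic scores."""
    try:
        library = cn.read_instances_long(config.instances)
        scores, unmatched = cn.score_all_drugs(
            signature, library, cmap_zeroing=config.cmap_zeroing
        )
    except (OSError, ValueError) as exc:
        raise PipelineStageError("score", str(exc)) from exc
    cn.write_scores(scores, outdir / "scores.tsv")
    cn.write_scores(cn.instance_score_table(scores), outdir / "instance_scores.tsv")
    gc.write_grp(unmatched, outdir / "unmatched_drugs.txt")
    _log("score", f"{len(scores)} drugs scored; {len(unmatched)} unmatched")
    return scores, unmatched


def stage_bench(
    config: PipelineConfig, scores: pd.DataFrame, outdir: Path
) -> dict[str, pd.DataFrame]:
    """Scores + benchmark -> ranking, precision curve, top-x partitions."""
    try:
        bench = bm.BenchmarkTable.read_tsv(config.benchmark)
        ranked, exclusions = bm.rank_drugs(scores, bench)
        cutoffs = [x for x in config.cutoffs if x <= len(ranked)]
        curve = bm.precision_curve(ranked, cutoffs)
        x = max(cutoffs) if cutoffs else len(ranked)
        parts = bm.partition_topx(ranked, x)
    except (OSError, ValueError) as exc:
        raise PipelineStageError("bench", str(exc)) from exc
    ranked.to_csv(outdir / "ranking.tsv", sep="\t", index=False, float_format="%.10g")
    gc.write_grp(exclusions, outdir / "excluded_drugs.txt")
    bm.write_precision(curve, outdir / "precision.tsv")
    bm.write_partitions(parts, outdir / "partitions.tsv")
    _log(
        "bench",
        f"{len(ranked)} ranked ({len(exclusions)} excluded); "
        + "; ".join(f"P@{r.x}={r.precision:.3f}" for r in curve.itertuples()),
    )
    return {"ranked": ranked, "curve": curve, **parts}


def stage_overlap(config: PipelineConfig, outdir: Path) -> list[po.OverlapEdge]:
    try:
        a = po.read_gmt(config.gene_sets_a)
        b = po.read_gmt(config.gene_sets_b)
        edges = po.overlap_graph(a, b, min_shared=config.min_shared)
    except (OSError, ValueError) as exc:
        raise PipelineStageError("overlap", str(exc)) from exc
    po.write_edges(edges, outdir / "overlap_edges.tsv")
    _log("overlap", f"{len(edges)} overlap edges")
    return edges


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage and write the result bundle plus manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    de = stage_prep(config, outdir)
    signature = stage_classify(config, de, outdir)
    scores, unmatched = stage_score(config, signature, outdir)
    bench_out = stage_bench(config, scores, outdir)
    if config.gene_sets_a and config.gene_sets_b:
        stage_overlap(config, outdir)
    config.to_yaml(outdir / "config.yaml")

    outputs = sorted(
        str(p.relative_to(outdir)) for p in outdir.iterdir() if p.name != "manifest.json"
    )
    manifest = {
        "package": "kernelsig",
        "version": __version__,
        "config": asdict(config),
        "counts": {
            "genes": int(len(de)),
            "de_genes": int(de["is_de"].sum()),
            "signature_up": len(signature.up),
            "signature_down": len(signature.down),
            "drugs_scored": int(len(scores)),
            "drugs_unmatched": len(unmatched),
            "drugs_ranked": int(len(bench_out["ranked"])),
        },
        "checksums": {name: _sha256(outdir / name) for name in outputs},
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _log("run", f"bundle written to {outdir}")
    return manifest
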