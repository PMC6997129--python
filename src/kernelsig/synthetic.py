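"""Synthetic inputs with the statistical structure the pipeline assumes.

Every downstream stage can be exercised against planted ground truth:

* expression — log-normal intensities (Gaussian on the log2 scale) over one
  shared gene universe, with a subset of genes carrying an additive log2
  shift of +/- ``effect_size`` in the tumor group only.  Intensities are
  2^(log-scale draw), hence strictly positive, so log-ratio fold changes are
  always defined.
* mutations — a binary gene x sample matrix over a separate tumor cohort;
  planted frequent genes mutate per sample with a high rate, the rest with a
  low background rate.
* drug instances — full permutations of the universe.  A ``reversal`` drug
  places the disease signature's up genes uniformly at random inside the
  bottom ceil(s*n) positions and the down genes inside the top window
  (``mimic`` mirrors this; ``null`` is a uniform random permutation).  The
  hard window makes the attainable enrichment scores analytically checkable.
* benchmark — a CTD-style table marking a known subset of drugs, with
  evidence tags for the known ones.

All generators are pure functions of (config, seed): the same inputs give
bit-identical outputs.  Defaults match the study conditions used throughout
the test-bed: 1000 genes, 20 tumor vs 10 normal expression samples, a
100-sample mutation cohort, effect size 2 on the log2 scale with noise sd
0.5, 20 planted frequent genes at per-sample rate 0.5 over background 0.005.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import expression as xp
from . import gene_classes as gc
from .connectivity import DrugInstanceProfile
from .gene_classes import DiseaseSignature

# named RNG substreams so stages are isolated but all flow from one seed
_STREAM_EXPR = 0
_STREAM_MUT = 1
_STREAM_DRUGS = 2
_STREAM_BENCH = 3
_STREAM_SETS = 4

Mode = Literal["reversal", "mimic", "null"]


@dataclass(frozen=True)
class SimulationConfig:
    """Shapes, effect sizes and rates of the synthetic study.

    ``effect_size`` is the additive tumor-group shift on the log2 scale
    (delta >= 0); ``noise_sd`` the per-observation Gaussian sd on that scale;
    ``baseline_log_mean``/``baseline_log_sd`` parametrize the per-gene
    log-normal baseline.  Mutation rates are per-sample Bernoulli
    probabilities.  ``n_mut_samples`` sizes the mutated tumor cohort, which
    is distinct from the expression samples.
    """

    n_genes: int = 1000
    n_tumor: int = 20
    n_normal: int = 10
    n_up: int = 25
    n_down: int = 25
    effect_size: float = 2.0
    noise_sd: float = 0.5
    baseline_log_mean: float = 8.0
    baseline_log_sd: float = 1.0
    mut_background_rate: float = 0.005
    mut_planted_rate: float = 0.5
    n_planted_frequent: int = 20
    n_mut_samples: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_tumor, self.n_normal, self.n_mut_samples) <= 0:
            raise ValueError("dimensions must be positive")
        if self.n_up < 0 or self.n_down < 0 or self.n_up + self.n_down > self.n_genes:
            raise ValueError("need 0 <= n_up + n_down <= n_genes")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ValueError("effect_size and noise_sd must be non-negative")
        for r in (self.mut_background_rate, self.mut_planted_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"mutation rates must be in [0, 1], got {r}")
        if not 0 <= self.n_planted_frequent <= self.n_genes:
            raise ValueError("n_planted_frequent must be within the universe")

    def gene_universe(self) -> tuple[str, ...]:
        width = len(str(self.n_genes))
        return tuple(f"G{i:0{width}d}" for i in range(1, self.n_genes + 1))


@dataclass(frozen=True)
class DrugSpec:
    name: str
    n_instances: int
    mode: Mode
    strength: float = 0.05

    def __post_init__(self) -> None:
        if self.n_instances < 1:
            raise ValueError("n_instances must be >= 1")
        if self.mode not in ("reversal", "mimic", "null"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.strength <= 1.0:
            raise ValueError("strength must lie in (0, 1]")


@dataclass(frozen=True)
class DrugLibraryConfig:
    drug_specs: tuple[DrugSpec, ...]
    seed: int = 0


def default_drug_library_config(
    seed: int = 0,
    n_reversal: int = 5,
    n_mimic: int = 5,
    n_null: int = 90,
    n_instances: int = 2,
    strength: float = 0.05,
) -> DrugLibraryConfig:
    """The standard test-bed library: a few planted drugs among many nulls."""
    specs = (
        [DrugSpec(f"rev{i:02d}", n_instances, "reversal", strength) for i in range(1, n_reversal + 1)]
        + [DrugSpec(f"mim{i:02d}", n_instances, "mimic", strength) for i in range(1, n_mimic + 1)]
        + [DrugSpec(f"null{i:03d}", n_instances, "null", strength) for i in range(1, n_null + 1)]
    )
    return DrugLibraryConfig(drug_specs=tuple(specs), seed=seed)


def gen_expression(
    config: SimulationConfig,
) -> tuple[xp.ExpressionMatrix, tuple[str, ...], tuple[str, ...]]:
    """Two-group log-normal expression with planted log2 shifts.

    Returns the matrix plus the planted up- and down-gene tuples.  Tumor
    samples carry TCGA-style barcodes with type code 01, normals 11, so
    barcode-based grouping recovers the truth.
    """
    rng = np.random.default_rng([config.seed, _STREAM_EXPR])
    genes = config.gene_universe()
    perm = rng.permutation(config.n_genes)
    planted_up = tuple(sorted(genes[i] for i in perm[: config.n_up]))
    planted_down = tuple(
        sorted(genes[i] for i in perm[config.n_up : config.n_up + config.n_down])
    )
    shift = np.zeros(config.n_genes)
    shift[perm[: config.n_up]] = config.effect_size
    shift[perm[config.n_up : config.n_up + config.n_down]] = -config.effect_size

    mu = rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
    n_s = config.n_tumor + config.n_normal
    log2_vals = mu[:, None] + rng.normal(0.0, config.noise_sd, (config.n_genes, n_s))
    log2_vals[:, : config.n_tumor] += shift[:, None]
    values = 2.0 ** log2_vals

    tumor_ids = [f"TCGA-SY-{i:04d}-01A" for i in range(1, config.n_tumor + 1)]
    normal_ids = [f"TCGA-SY-{i:04d}-11A" for i in range(config.n_tumor + 1, n_s + 1)]
    samples = tumor_ids + normal_ids
    groups = pd.Series(
        [xp.TUMOR] * config.n_tumor + [xp.NORMAL] * config.n_normal, index=samples
    )
    matrix = xp.ExpressionMatrix(
        values=pd.DataFrame(values, index=list(genes), columns=samples), groups=groups
    )
    return matrix, planted_up, planted_down


def gen_mutations(config: SimulationConfig) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Binary mutation matrix over the tumor cohort, with planted frequent genes.

    Each entry is Bernoulli(mut_planted_rate) for planted genes and
    Bernoulli(mut_background_rate) otherwise, independently per sample.
    """
    rng = np.random.default_rng([config.seed, _STREAM_MUT])
    genes = config.gene_universe()
    planted_idx = rng.choice(config.n_genes, size=config.n_planted_frequent, replace=False)
    planted = tuple(sorted(genes[i] for i in planted_idx))
    rates = np.full(config.n_genes, config.mut_background_rate)
    rates[planted_idx] = config.mut_planted_rate
    draws = rng.random((config.n_genes, config.n_mut_samples)) < rates[:, None]
    cohort = [f"TCGA-SY-{i:04d}-01A" for i in range(5001, 5001 + config.n_mut_samples)]
    matrix = pd.DataFrame(draws.astype(int), index=list(genes), columns=cohort)
    return matrix, planted


def _place_in_windows(
    universe: Sequence[str],
    top_set: Sequence[str],
    bottom_set: Sequence[str],
    window: int,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    """Permutation with top_set inside the first `window` slots and bottom_set
    inside the last `window` slots, everything else uniform."""
    n = len(universe)
    slots: list[str | None] = [None] * n
    top_slots = rng.choice(window, size=len(top_set), replace=False)
    for g, s in zip(top_set, top_slots):
        slots[s] = g
    avail_bottom = [n - window + j for j in range(window) if slots[n - window + j] is None]
    pick = rng.choice(len(avail_bottom), size=len(bottom_set), replace=False)
    for g, s in zip(bottom_set, pick):
        slots[avail_bottom[s]] = g
    placed = set(top_set) | set(bottom_set)
    rest = [g for g in universe if g not in placed]
    rest = list(rng.permutation(rest))
    it = iter(rest)
    return tuple(g if g is not None else next(it) for g in slots)


def gen_drug_instances(
    universe: Sequence[str],
    config: DrugLibraryConfig,
    signature: DiseaseSignature,
) -> list[DrugInstanceProfile]:
    """Instance library with planted signature-reversing/-mimicking drugs.

    A reversal drug buries the signature's up genes in the bottom
    ceil(strength*n) positions and floats its down genes into the top window,
    so its enrichment runs opposite to the disease; a mimic does the mirror
    image; a null drug is an unconstrained uniform permutation.
    """
    universe = tuple(universe)
    n = len(universe)
    missing = sorted(set(signature.genes) - set(universe))
    if missing:
        raise ValueError(f"signature genes outside the universe: {missing[:5]}")
    rng = np.random.default_rng([config.seed, _STREAM_DRUGS])
    profiles = []
    for spec in config.drug_specs:
        window = math.ceil(spec.strength * n)
        m = max(len(signature.up), len(signature.down))
        if spec.mode != "null" and window < m:
            raise ValueError(
                f"drug {spec.name!r}: extreme window ceil({spec.strength}*{n})={window} "
                f"cannot hold a {m}-gene signature side"
            )
        for j in range(1, spec.n_instances + 1):
            if spec.mode == "null":
                ranked = tuple(rng.permutation(universe))
            elif spec.mode == "reversal":
                ranked = _place_in_windows(universe, signature.down, signature.up, window, rng)
            else:  # mimic
                ranked = _place_in_windows(universe, signature.up, signature.down, window, rng)
            profiles.append(
                DrugInstanceProfile(
                    instance_id=f"{spec.name}_i{j}", drug_name=spec.name, ranked_genes=ranked
                )
            )
    return profiles


def gen_benchmark(
    drug_names: Sequence[str],
    known_fraction: float,
    seed: int = 0,
    forced_known: Sequence[str] = (),
) -> pd.DataFrame:
    """CTD-style benchmark marking exactly round(known_fraction * n) drugs known.

    Drugs in ``forced_known`` (e.g. the planted ones) are always known and
    count toward the quota; the remaining known slots are drawn uniformly.
    Known drugs get a random evidence tag from {T, M, Inferred}; unknown
    drugs get "none".
    """
    names = [str(d) for d in drug_names]
    if not names:
        raise ValueError("drug list is empty")
    if not 0.0 <= known_fraction <= 1.0:
        raise ValueError("known_fraction must be in [0, 1]")
    rng = np.random.default_rng([seed, _STREAM_BENCH])
    forced = {str(d) for d in forced_known} & set(names)
    n_known = round(known_fraction * len(names))
    pool = [d for d in names if d not in forced]
    extra = max(0, n_known - len(forced))
    chosen = set(rng.choice(pool, size=min(extra, len(pool)), replace=False)) | forced
    rows = []
    for name in names:
        known = name in chosen
        evidence = str(rng.choice(["T", "M", "Inferred"])) if known else "none"
        rows.append({"drug_name": name, "known": int(known), "evidence": evidence})
    return pd.DataFrame(rows, columns=["drug_name", "known", "evidence"])


def gen_gene_sets(
    universe: Sequence[str],
    n_sets: int,
    set_size: int,
    seed: int = 0,
    prefix: str = "SET",
) -> dict[str, frozenset]:
    """Random gene-set collection over the universe (overlap-demo plumbing)."""
    rng = np.random.default_rng([seed, _STREAM_SETS])
    universe = list(universe)
    out = {}
    for i in range(1, n_sets + 1):
        members = rng.choice(universe, size=min(set_size, len(universe)), replace=False)
        out[f"{prefix}{i:02d}"] = frozenset(str(g) for g in members)
    return out


@dataclass
class SyntheticDataset:
    """One coherent bundle of pipeline inputs plus the planted ground truth."""

    config: SimulationConfig
    drug_config: DrugLibraryConfig
    expression: xp.ExpressionMatrix
    mutations: pd.DataFrame
    instances: list[DrugInstanceProfile]
    benchmark: pd.DataFrame
    signature: DiseaseSignature
    planted_up: tuple[str, ...]
    planted_down: tuple[str, ...]
    planted_frequent: tuple[str, ...]
    planted_drugs: dict[str, str] = field(default_factory=dict)  # name -> mode
    gene_sets_a: dict[str, frozenset] = field(default_factory=dict)
    gene_sets_b: dict[str, frozenset] = field(default_factory=dict)


def generate_dataset(
    config: SimulationConfig,
    drug_config: DrugLibraryConfig | None = None,
    known_fraction: float = 0.1,
    lfc_threshold: float = xp.DEFAULT_LFC_THRESHOLD,
    p_threshold: float = xp.DEFAULT_P_THRESHOLD,
    mutation_fraction: float = gc.DEFAULT_MUTATION_FRACTION,
    pseudocount: float = xp.DEFAULT_PSEUDOCOUNT,
) -> SyntheticDataset:
    """Generate every pipeline input from one seed.

    The drug library must be planted against the signature the analysis will
    actually derive, so this runs the real prep/classify stages on its own
    expression and mutation output to obtain that signature before placing
    reversal and mimic drugs.  Planted (non-null) drugs are forced known in
    the benchmark, which marks round(known_fraction * n_drugs) drugs known in
    total (the default quota covers exactly the ten planted drugs of the
    default library).
    """
    if drug_config is None:
        drug_config = default_drug_library_config(seed=config.seed)
    matrix, planted_up, planted_down = gen_expression(config)
    mutations, planted_frequent = gen_mutations(config)

    logfc = xp.compute_logfc(matrix, pseudocount=pseudocount)
    pvals = xp.differential_test(matrix)
    de = xp.call_de_genes(logfc, pvals, lfc_threshold, p_threshold)
    table = gc.MutationTable.from_matrix(mutations)
    counts = gc.mutation_frequency_counts(table, gene_universe=matrix.gene_ids)
    threshold = gc.frequency_threshold(table.n_samples, mutation_fraction)
    classification = gc.classify_genes(counts, threshold, de.index[de["is_de"]])
    signature = gc.build_disease_signature(classification, logfc)

    instances = gen_drug_instances(matrix.gene_ids, drug_config, signature)
    planted_drugs = {s.name: s.mode for s in drug_config.drug_specs if s.mode != "null"}
    benchmark = gen_benchmark(
        [s.name for s in drug_config.drug_specs],
        known_fraction,
        seed=drug_config.seed,
        forced_known=list(planted_drugs),
    )
    gene_sets_a = gen_gene_sets(matrix.gene_ids, 3, 40, seed=config.seed, prefix="DRUGPATH")
    gene_sets_b = gen_gene_sets(matrix.gene_ids, 4, 60, seed=config.seed + 1, prefix="TISSUE")
    return SyntheticDataset(
        config=config,
        drug_config=drug_config,
        expression=matrix,
        mutations=mutations,
        instances=instances,
        benchmark=benchmark,
        signature=signature,
        planted_up=planted_up,
        planted_down=planted_down,
        planted_frequent=planted_frequent,
        planted_drugs=planted_drugs,
        gene_sets_a=gene_sets_a,
        gene_sets_b=gene_sets_b,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write the standard pipeline input files plus a ground-truth sidecar.

    Returns the mapping of logical names to paths.  Formats: expression TSV
    (gene rows, barcode columns), sample sheet, binary mutation matrix TSV and
    an equivalent minimal MAF, long-form instance library TSV, benchmark TSV,
    two GMT collections, and ``truth.txt`` with comma-joined planted sets.
    """
    from . import connectivity as cn
    from . import pathway_overlap as po

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def p(name: str, key: str | None = None) -> Path:
        paths[key or name.split(".")[0]] = str(outdir / name)
        return outdir / name

    ds = dataset
    vals = ds.expression.values.copy()
    vals.insert(0, "gene", vals.index)
    vals.to_csv(p("expression.tsv"), sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(
        {"sample_id": ds.expression.sample_ids, "group": ds.expression.groups.values}
    ).to_csv(p("sample_sheet.tsv"), sep="\t", index=False)
    mut = ds.mutations.copy()
    mut.insert(0, "gene", mut.index)
    mut.to_csv(p("mutations.tsv"), sep="\t", index=False)
    table = gc.MutationTable.from_matrix(ds.mutations)
    maf = table.records.rename(columns={"gene": "Hugo_Symbol", "sample": "Tumor_Sample_Barcode"})
    with open(p("mutations.maf", key="maf"), "w", encoding="utf-8") as fh:
        fh.write("#synthetic minimal MAF\n")
        maf.sort_values(["Hugo_Symbol", "Tumor_Sample_Barcode"]).to_csv(
            fh, sep="\t", index=False
        )
    cn.write_instances_long(ds.instances, p("instances.tsv"))
    ds.benchmark.to_csv(p("benchmark.tsv"), sep="\t", index=False)
    po.write_gmt(ds.gene_sets_a, p("drug_pathways.gmt"))
    po.write_gmt(ds.gene_sets_b, p("tissue_pathways.gmt"))
    with open(p("truth.txt"), "w", encoding="utf-8") as fh:
        fh.write(f"planted_up={','.join(ds.planted_up)}\n")
        fh.write(f"planted_down={','.join(ds.planted_down)}\n")
        fh.write(f"planted_frequent={','.join(ds.planted_frequent)}\n")
        for mode in ("reversal", "mimic"):
            drugs = sorted(d for d, m in ds.planted_drugs.items() if m == mode)
            fh.write(f"planted_{mode}_drugs={','.join(drugs)}\n")
        fh.write(f"seed={ds.config.seed}\n")
    return paths


def read_truth(path) -> dict[str, tuple[str, ...]]:
    out: dict[str, tuple[str, ...]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if "=" not in line:
                continue
            key, _, val = line.strip().partition("=")
            out[key] = tuple(v for v in val.split(",") if v)
    return out
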