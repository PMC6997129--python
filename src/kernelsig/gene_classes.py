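"""Gene taxonomy from mutation frequency, and the ordered disease signature.

Genes are partitioned by two observables: how often they are somatically
mutated across the tumor cohort, and whether they are differentially
expressed.  Genes mutated in at least a fixed fraction of samples (default
3%) are *kernel* genes — the disease feature set — regardless of their
expression behavior.  Of the rest, differentially expressed genes are
*secondary* and the remainder *marginal*.

The disease signature orders the kernel genes by log2 fold change: positive
logFC genes form the up-regulated list G_up, negative logFC genes the
down-regulated list G_down, each sorted by decreasing logFC (ties broken by
gene symbol so outputs are deterministic).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

KERNEL = "kernel"
SECONDARY = "secondary"
MARGINAL = "marginal"

DEFAULT_MUTATION_FRACTION = 0.03


class MutationTableError(ValueError):
    """Malformed mutation input (bad records, unknown samples, empty cohort)."""


class SignatureError(ValueError):
    """The disease signature cannot be built (e.g. empty kernel set)."""


@dataclass
class MutationTable:
    """Somatic mutation events as (gene, sample) pairs over a declared cohort.

    Duplicate (gene, sample) pairs collapse to a single event: mutation
    frequency counts *distinct samples*, not variants.  Records referring to a
    sample outside the cohort are rejected by name.
    """

    records: pd.DataFrame  # columns: gene, sample (deduplicated)
    cohort: tuple[str, ...]

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str]] | pd.DataFrame, cohort: Sequence[str]
    ) -> "MutationTable":
        if isinstance(records, pd.DataFrame):
            df = records[["gene", "sample"]].astype(str)
        else:
            df = pd.DataFrame(list(records), columns=["gene", "sample"], dtype=str)
        cohort = tuple(dict.fromkeys(str(s) for s in cohort))
        if not cohort:
            raise MutationTableError("mutation cohort is empty")
        unknown = sorted(set(df["sample"]) - set(cohort))
        if unknown:
            raise MutationTableError(
                f"mutation records reference samples outside the cohort: {unknown[:5]}"
            )
        df = df.drop_duplicates().reset_index(drop=True)
        return cls(records=df, cohort=cohort)

    @classmethod
    def from_matrix(cls, matrix: pd.DataFrame) -> "MutationTable":
        """Build from a binary gene x sample matrix (nonzero = mutated)."""
        arr = matrix.to_numpy()
        genes, samples = matrix.index.astype(str), matrix.columns.astype(str)
        gi, si = (arr != 0).nonzero()
        df = pd.DataFrame({"gene": genes[gi], "sample": samples[si]})
        return cls.from_records(df, cohort=list(samples))

    @classmethod
    def from_maf(cls, path, cohort: Sequence[str] | None = None) -> "MutationTable":
        """Read a minimal MAF: Hugo_Symbol + Tumor_Sample_Barcode columns.

        Other columns are ignored; '#' comment lines are tolerated.  When no
        cohort is declared, the samples present in the file define it.
        """
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        needed = {"Hugo_Symbol", "Tumor_Sample_Barcode"}
        if not needed <= set(df.columns):
            raise MutationTableError(
                f"MAF {path} lacks required columns {sorted(needed - set(df.columns))}"
            )
        if df.empty:
            raise MutationTableError(f"MAF {path} contains no mutation records")
        records = df.rename(
            columns={"Hugo_Symbol": "gene", "Tumor_Sample_Barcode": "sample"}
        )[["gene", "sample"]]
        if cohort is None:
            cohort = sorted(records["sample"].unique())
        return cls.from_records(records, cohort)

    @property
    def n_samples(self) -> int:
        return len(self.cohort)


def mutation_frequency_counts(
    table: MutationTable, gene_universe: Sequence[str] | None = None
) -> pd.Series:
    """Count, per gene, the distinct cohort samples carrying >=1 mutation.

    Genes in ``gene_universe`` absent from the records get count 0 (absence
    from the mutation data is not an error).  Without a universe, only genes
    seen in the records appear.
    """
    counts = table.records.groupby("gene")["sample"].nunique()
    if gene_universe is not None:
        counts = counts.reindex([str(g) for g in gene_universe], fill_value=0)
    counts = counts.astype(int)
    counts.name = "mutation_count"
    return counts.sort_index()


def frequency_threshold(n_samples: int, fraction: float = DEFAULT_MUTATION_FRACTION) -> int:
    """Integer mutation-count threshold: floor(fraction * n_samples), min 1.

    With 373 tumor samples and the default 3% this gives 11.  The floor makes
    the threshold the largest count consistent with the stated fraction; the
    clamp keeps tiny cohorts from admitting every gene.
    """
    if n_samples <= 0:
        raise ValueError(f"n_samples must be positive, got {n_samples}")
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    return max(1, math.floor(fraction * n_samples))


def classify_genes(
    counts: pd.Series, threshold: int, de_genes: Iterable[str]
) -> pd.DataFrame:
    """Partition genes into kernel / secondary / marginal.

    kernel: mutation count >= threshold (DE status irrelevant — frequently
    mutated genes whose expression does not change are still kernel genes);
    secondary: below threshold but differentially expressed;
    marginal: neither.
    """
    de = set(str(g) for g in de_genes)
    df = pd.DataFrame({"mutation_count": counts.astype(int)})
    is_kernel = df["mutation_count"] >= threshold
    is_de = df.index.isin(de)
    df["gene_class"] = MARGINAL
    df.loc[~is_kernel & is_de, "gene_class"] = SECONDARY
    df.loc[is_kernel, "gene_class"] = KERNEL
    return df


@dataclass
class DiseaseSignature:
    """Ordered up/down gene lists anchoring the connectivity query.

    ``up`` holds genes with positive score (logFC for disease signatures, or
    a rank-derived score for drug queries) sorted by decreasing score; ``down``
    holds negative-score genes, also by decreasing score.  The two lists are
    disjoint.  Genes whose score is exactly zero anchor neither tail and are
    recorded in ``excluded_zero``.
    """

    up: tuple[str, ...]
    down: tuple[str, ...]
    scores: pd.Series | None = None
    excluded_zero: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise SignatureError("up and down lists must be disjoint")

    @property
    def genes(self) -> tuple[str, ...]:
        return self.up + self.down


def build_disease_signature(
    classification: pd.DataFrame, logfc: pd.Series
) -> DiseaseSignature:
    """Order kernel genes by logFC into the up/down disease signature.

    Kernel genes with logFC > 0 go up, logFC < 0 go down, each list sorted by
    decreasing logFC with lexicographic tie-break on the symbol.  Genes with
    logFC exactly 0 are excluded from both lists (a zero-effect gene should
    anchor neither tail) and reported via ``excluded_zero`` plus a warning.
    """
    kernel = classification.index[classification["gene_class"] == KERNEL]
    if len(kernel) == 0:
        raise SignatureError("kernel gene set is empty; no signature can be built")
    missing = sorted(set(kernel) - set(logfc.index))
    if missing:
        raise SignatureError(f"kernel genes without a logFC value: {missing[:5]}")
    lfc = logfc.loc[kernel]

    def ordered(mask: pd.Series) -> tuple[str, ...]:
        sub = lfc[mask]
        order = sorted(sub.index, key=lambda g: (-sub[g], g))
        return tuple(order)

    up = ordered(lfc > 0)
    down = ordered(lfc < 0)
    zero = tuple(sorted(lfc.index[lfc == 0]))
    if zero:
        warnings.warn(
            f"{len(zero)} kernel gene(s) with logFC exactly 0 excluded from the signature",
            stacklevel=2,
        )
    if not up or not down:
        warnings.warn(
            "degenerate disease signature: one side is empty "
            f"(|up|={len(up)}, |down|={len(down)})",
            stacklevel=2,
        )
    return DiseaseSignature(up=up, down=down, scores=lfc, excluded_zero=zero)


# --- .grp-style plain gene lists (one symbol per line, rank order) ----------

def write_grp(genes: Sequence[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_grp(path) -> tuple[str, ...]:
    with open(path, encoding="utf-8") as fh:
        return tuple(line.strip() for line in fh if line.strip())


def write_classification(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_classification(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene": str}).set_index("gene")
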