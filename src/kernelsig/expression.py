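"""Expression preprocessing: normalization, logFC, differential-expression calls.

The pipeline starts from a non-negative gene x sample intensity matrix with
tumor/normal group labels (either parsed from TCGA-style barcodes or supplied
in a sample sheet).  Genes are z-score standardized across all samples, the
per-gene log2 fold change is the log ratio of tumor to normal group means on
the raw scale (with a pseudocount so zeros are safe), and a two-sided Welch
t-test provides per-gene p-values.  A gene is called differentially expressed
when |logFC| >= 1 and p <= 0.02 (both thresholds configurable, comparisons
inclusive).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

TUMOR = "tumor"
NORMAL = "normal"
UNKNOWN = "unknown"

DEFAULT_LFC_THRESHOLD = 1.0
DEFAULT_P_THRESHOLD = 0.02
DEFAULT_PSEUDOCOUNT = 1.0


class BarcodeError(ValueError):
    """A sample barcode does not follow the TCGA layout."""


class ExpressionError(ValueError):
    """Invalid expression matrix or group structure."""


_BARCODE_PART4 = re.compile(r"^(\d{2})")


def classify_sample_barcode(barcode: str) -> str:
    """Type a TCGA-style sample barcode as tumor, normal, or unknown.

    The fourth dash-delimited field carries the sample-type code: 01-09 are
    tumor samples, 10-19 are matched normals, any other two-digit code (e.g.
    control analytes, 20-29) is reported as unknown.

    Raises
    ------
    BarcodeError
        If the barcode has fewer than four dash-delimited parts or the fourth
        part does not start with two digits.
    """
    parts = barcode.split("-")
    if len(parts) < 4:
        raise BarcodeError(
            f"barcode {barcode!r} has {len(parts)} dash-delimited parts; "
            "need at least 4"
        )
    m = _BARCODE_PART4.match(parts[3])
    if m is None:
        raise BarcodeError(
            f"barcode {barcode!r}: fourth part {parts[3]!r} does not start "
            "with a two-digit sample-type code"
        )
    code = int(m.group(1))
    if 1 <= code <= 9:
        return TUMOR
    if 10 <= code <= 19:
        return NORMAL
    return UNKNOWN


@dataclass
class ExpressionMatrix:
    """Gene x sample intensity matrix with tumor/normal labels.

    ``values`` is a genes-by-samples DataFrame of finite, non-negative
    intensities; ``groups`` maps every sample to ``"tumor"`` or ``"normal"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ExpressionError(f"duplicate gene IDs: {dup[:5]}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ExpressionError(f"duplicate sample IDs: {dup[:5]}")
        arr = v.to_numpy()
        if not np.isfinite(arr).all():
            raise ExpressionError("expression values must be finite")
        if (arr < 0).any():
            raise ExpressionError("expression values must be non-negative")
        self.groups = self.groups.reindex(v.columns)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise ExpressionError(f"samples without a group label: {missing[:5]}")
        bad = sorted(set(self.groups.unique()) - {TUMOR, NORMAL})
        if bad:
            raise ExpressionError(f"unrecognized group labels: {bad}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == TUMOR])

    @property
    def normal_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == NORMAL])


@dataclass
class NormalizedMatrix:
    """Per-gene z-scores; every retained row has mean 0 and sample sd 1."""

    values: pd.DataFrame
    groups: pd.Series
    dropped_genes: tuple[str, ...] = field(default_factory=tuple)


def groups_from_barcodes(sample_ids: Iterable[str]) -> pd.Series:
    """Derive tumor/normal labels from TCGA-style barcodes.

    Samples whose type code falls outside both ranges are excluded from the
    result (callers decide whether to drop or fail on them).
    """
    labels = {}
    for s in sample_ids:
        g = classify_sample_barcode(s)
        if g != UNKNOWN:
            labels[s] = g
    return pd.Series(labels, dtype=object)


def zscore_normalize(matrix: ExpressionMatrix) -> NormalizedMatrix:
    """Standardize every gene across all samples: z = (g - mean) / sd.

    Uses the sample standard deviation (n-1 denominator).  Genes with zero
    variance carry no signal and cannot be standardized; they are dropped and
    listed in ``dropped_genes``.
    """
    if matrix.values.shape[1] < 2:
        raise ExpressionError("z-score normalization needs at least 2 samples")
    arr = matrix.values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    keep = (sd > 0).ravel()
    dropped = tuple(matrix.values.index[~keep])
    z = (arr[keep] - mean[keep]) / sd[keep]
    values = pd.DataFrame(z, index=matrix.values.index[keep], columns=matrix.values.columns)
    return NormalizedMatrix(values=values, groups=matrix.groups.copy(), dropped_genes=dropped)


def compute_logfc(
    matrix: ExpressionMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.Series:
    """Per-gene log2 fold change of tumor over normal group means.

    logFC_i = log2((mean_T(g_i) + c) / (mean_N(g_i) + c)), computed on the raw
    non-negative intensities.  The pseudocount c keeps the ratio defined when a
    group mean is zero; with c = 0 a gene whose both group means are zero is an
    error.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    t_cols, n_cols = matrix.tumor_samples, matrix.normal_samples
    if not t_cols or not n_cols:
        raise ExpressionError("both tumor and normal groups must be non-empty")
    mean_t = matrix.values[t_cols].mean(axis=1) + pseudocount
    mean_n = matrix.values[n_cols].mean(axis=1) + pseudocount
    if ((mean_t == 0) | (mean_n == 0)).any():
        bad = matrix.values.index[(mean_t == 0) | (mean_n == 0)].tolist()
        raise ExpressionError(
            f"zero group mean with pseudocount 0 for genes {bad[:5]}; "
            "use a positive pseudocount"
        )
    out = np.log2(mean_t / mean_n)
    out.name = "logFC"
    return out


def welch_ttest(tumor: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Two-sided Welch t-test per gene row, on the given scale.

    Operating on the raw intensities makes the p-values exactly invariant to
    any per-gene affine rescaling (so whether upstream data were z-scored or
    not is immaterial).  Degenerate rows where both groups have zero variance
    get p = 1 when the group means agree and p = 0 otherwise.
    """
    res = stats.ttest_ind(tumor, normal, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        equal = np.isclose(tumor[bad].mean(axis=1), normal[bad].mean(axis=1))
        p[bad] = np.where(equal, 1.0, 0.0)
    return p


def log_welch_ttest(pseudocount: float = DEFAULT_PSEUDOCOUNT) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Welch t-test on log2(g + c); alternative plug-in for heavy-tailed data."""

    def _test(tumor: np.ndarray, normal: np.ndarray) -> np.ndarray:
        return welch_ttest(np.log2(tumor + pseudocount), np.log2(normal + pseudocount))

    return _test


def differential_test(
    matrix: ExpressionMatrix,
    stat_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> pd.Series:
    """Per-gene two-sided p-values for a tumor-vs-normal location difference.

    ``stat_fn`` maps (tumor block, normal block) row-wise to p-values; the
    default is :func:`welch_ttest`.  Each group must have at least 2 samples.
    """
    t_cols, n_cols = matrix.tumor_samples, matrix.normal_samples
    if len(t_cols) < 2 or len(n_cols) < 2:
        raise ExpressionError(
            f"differential test needs >=2 samples per group "
            f"(got {len(t_cols)} tumor, {len(n_cols)} normal)"
        )
    fn = stat_fn if stat_fn is not None else welch_ttest
    p = fn(
        matrix.values[t_cols].to_numpy(dtype=float),
        matrix.values[n_cols].to_numpy(dtype=float),
    )
    p = np.clip(np.asarray(p, dtype=float), 0.0, 1.0)
    return pd.Series(p, index=matrix.values.index, name="p_value")


def call_de_genes(
    logfc: pd.Series,
    p_values: pd.Series,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Flag differentially expressed genes: |logFC| >= lfc AND p <= p_thr.

    Both comparisons are inclusive.  Returns a DataFrame indexed by gene with
    columns ``logFC``, ``p_value``, ``is_de`` and ``direction`` (``up`` for
    positive logFC, ``down`` for negative, ``none`` for non-DE genes).
    """
    if lfc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    df = pd.DataFrame({"logFC": logfc, "p_value": p_values.reindex(logfc.index)})
    if df["p_value"].isna().any():
        missing = df.index[df["p_value"].isna()].tolist()
        raise ExpressionError(f"genes without a p-value: {missing[:5]}")
    df["is_de"] = (df["logFC"].abs() >= lfc_threshold) & (df["p_value"] <= p_threshold)
    direction = np.where(df["logFC"] > 0, "up", "down")
    df["direction"] = np.where(df["is_de"], direction, "none")
    return df


# ---------------------------------------------------------------------------
# File I/O: expression TSV (first column gene ID, header of sample IDs),
# optional sample sheet (sample_id, group), DE results TSV.
# ---------------------------------------------------------------------------

def read_expression_tsv(
    path,
    sample_sheet: Mapping[str, str] | pd.Series | None = None,
    drop_unknown: bool = True,
) -> ExpressionMatrix:
    """Load an expression TSV; group samples by sheet or, failing that, barcode.

    When a sample sheet (sample -> group) is given it overrides barcode
    parsing.  Otherwise group labels come from the TCGA barcode rule; samples
    with out-of-range type codes are dropped when ``drop_unknown`` is set and
    are an error otherwise.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    if sample_sheet is not None:
        groups = pd.Series(dict(sample_sheet), dtype=object)
        groups = groups.reindex(values.columns)
    else:
        groups = groups_from_barcodes(values.columns)
        if not drop_unknown and len(groups) < values.shape[1]:
            missing = sorted(set(values.columns) - set(groups.index))
            raise ExpressionError(f"samples of unknown type: {missing[:5]}")
        values = values[groups.index]
    return ExpressionMatrix(values=values, groups=groups)


def read_sample_sheet(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ExpressionError(
            f"sample sheet {path} must have columns sample_id and group"
        )
    return pd.Series(df["group"].values, index=df["sample_id"].values, dtype=object)


def write_de_table(de: pd.DataFrame, path) -> None:
    out = de.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    df = df.set_index("gene")
    df["is_de"] = df["is_de"].astype(bool)
    return df
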