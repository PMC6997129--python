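"""Ranking drugs by |TS| and evaluating against a curated benchmark.

The benchmark is a CTD-style table of drug-disease associations: each drug is
known or unknown for the disease, optionally with an evidence tag (``T`` for
curated therapeutic, ``M`` for marker/mechanism, ``Inferred`` for gene-based
inference).  Drugs absent from the benchmark's name universe are excluded
before ranking — a drug with no entry in the reference cannot be evaluated —
and reported.  Remaining drugs are sorted by decreasing |TS| (strong
connections of either sign first) and precision@top-x is the fraction of the
top x that are known.  The top drugs are further partitioned by TS sign into
therapeutic (TS < 0, signature-reversing) vs aggravating (TS > 0) and by
benchmark status into known vs novel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

EVIDENCE_LEVELS = ("T", "M", "Inferred", "none")


class BenchmarkError(ValueError):
    """Malformed benchmark table or invalid evaluation request."""


def normalize_drug_name(name: str) -> str:
    """Case-insensitive, whitespace-trimmed matching key for drug names."""
    return str(name).strip().casefold()


@dataclass
class BenchmarkTable:
    """Drug -> (known flag, evidence tag), keyed by normalized name."""

    table: pd.DataFrame  # index: normalized name; columns: drug_name, known, evidence

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BenchmarkTable":
        if "drug_name" not in df.columns or "known" not in df.columns:
            raise BenchmarkError("benchmark needs columns drug_name and known")
        out = df.copy()
        out["drug_name"] = out["drug_name"].astype(str)
        out["known"] = out["known"].astype(int).astype(bool)
        if "evidence" not in out.columns:
            out["evidence"] = "none"
        out["evidence"] = out["evidence"].fillna("none").astype(str)
        bad = sorted(set(out["evidence"]) - set(EVIDENCE_LEVELS))
        if bad:
            raise BenchmarkError(f"unknown evidence tags: {bad}")
        key = out["drug_name"].map(normalize_drug_name)
        if key.duplicated().any():
            dup = out.loc[key.duplicated(), "drug_name"].tolist()
            raise BenchmarkError(
                f"duplicate drug names after case-insensitive match: {dup[:5]}"
            )
        out.index = key
        return cls(table=out)

    @classmethod
    def read_tsv(cls, path) -> "BenchmarkTable":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype={"drug_name": str}))

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out["known"] = out["known"].astype(int)
        out.to_csv(path, sep="\t", index=False)

    def __contains__(self, drug_name: str) -> bool:
        return normalize_drug_name(drug_name) in self.table.index

    def is_known(self, drug_name: str) -> bool:
        return bool(self.table.loc[normalize_drug_name(drug_name), "known"])

    def evidence(self, drug_name: str) -> str:
        return str(self.table.loc[normalize_drug_name(drug_name), "evidence"])


@dataclass(frozen=True)
class PrecisionPoint:
    x: int
    hits: int
    precision: float


def rank_drugs(
    scores: pd.DataFrame, benchmark: BenchmarkTable
) -> tuple[pd.DataFrame, list[str]]:
    """Rank benchmark-matched drugs by decreasing |TS|.

    Drugs whose (normalized) name is absent from the benchmark universe are
    excluded before ranking and returned as the exclusions report.  Ties in
    |TS| break lexicographically on the drug name.  Result columns: rank
    (1-based), drug_name, ts, abs_ts, known, evidence.
    """
    if scores.empty:
        raise BenchmarkError("score table is empty")
    df = scores.copy()
    in_universe = df["drug_name"].map(lambda d: d in benchmark)
    exclusions = sorted(df.loc[~in_universe, "drug_name"].tolist())
    df = df.loc[in_universe].copy()
    if df.empty:
        raise BenchmarkError("no scored drug matches the benchmark name universe")
    df["abs_ts"] = df["ts"].abs()
    df["_key"] = df["drug_name"].map(normalize_drug_name)
    df = df.sort_values(["abs_ts", "_key"], ascending=[False, True], kind="mergesort")
    df = df.drop(columns="_key").reset_index(drop=True)
    df.insert(0, "rank", df.index + 1)
    df["known"] = df["drug_name"].map(benchmark.is_known)
    df["evidence"] = df["drug_name"].map(benchmark.evidence)
    return df, exclusions


def precision_at(ranked: pd.DataFrame, x: int) -> PrecisionPoint:
    """Fraction of the top-x ranked drugs found in the benchmark (known)."""
    if not 1 <= x <= len(ranked):
        raise BenchmarkError(f"cutoff x={x} outside [1, {len(ranked)}]")
    hits = int(ranked["known"].iloc[:x].sum())
    return PrecisionPoint(x=x, hits=hits, precision=hits / x)


def precision_curve(ranked: pd.DataFrame, cutoffs: Sequence[int]) -> pd.DataFrame:
    """Precision at each cutoff, as a (x, hits, precision) table."""
    points = [precision_at(ranked, int(x)) for x in cutoffs]
    return pd.DataFrame(
        [(p.x, p.hits, p.precision) for p in points],
        columns=["x", "hits", "precision"],
    )


def partition_topx(ranked: pd.DataFrame, x: int) -> dict[str, pd.DataFrame]:
    """Split the top-x drugs by TS sign and benchmark status.

    therapeutic: ts < 0 (reverses the disease signature); aggravating: ts > 0
    (mimics it); known/novel by the benchmark flag.  Drugs with ts exactly 0
    fit neither sign and land in a separate ``zero_ts`` bucket.  Rank order
    and evidence tags are preserved in every bucket.
    """
    if not 1 <= x <= len(ranked):
        raise BenchmarkError(f"cutoff x={x} outside [1, {len(ranked)}]")
    top = ranked.iloc[:x]
    buckets = {
        "known_therapeutic": top[(top["ts"] < 0) & top["known"]],
        "novel_therapeutic": top[(top["ts"] < 0) & ~top["known"]],
        "known_aggravating": top[(top["ts"] > 0) & top["known"]],
        "novel_aggravating": top[(top["ts"] > 0) & ~top["known"]],
        "zero_ts": top[top["ts"] == 0],
    }
    return {k: v.reset_index(drop=True) for k, v in buckets.items()}


def write_precision(curve: pd.DataFrame, path) -> None:
    curve.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_partitions(parts: dict[str, pd.DataFrame], path) -> None:
    """Single TSV mirroring the published top-x tables: rank, drug, evidence, list."""
    frames = []
    for label, df in parts.items():
        if df.empty:
            continue
        out = df[["rank", "drug_name", "ts", "evidence"]].copy()
        out["list"] = label
        frames.append(out)
    if frames:
        combined = pd.concat(frames).sort_values("rank")
    else:
        combined = pd.DataFrame(columns=["rank", "drug_name", "ts", "evidence", "list"])
    combined.to_csv(path, sep="\t", index=False, float_format="%.10g")
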