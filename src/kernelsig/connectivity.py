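"""Connectivity scoring of disease signatures against drug rank profiles.

Each drug *instance* is one treatment experiment summarized as a full
permutation of the gene universe, position 1 = most up-regulated under
treatment.  For a query gene set with sorted 1-based positions V(1..m) inside
an n-gene profile, the Kolmogorov-Smirnov-style enrichment statistics are

    a = max_{p=1..m} [ p/m - V(p)/n ]
    b = max_{p=1..m} [ V(p)/n - (p-1)/m ]

and the enrichment score is ES = a if a > b, -b if b > a, 0 on an exact tie.
ES is positive when the query concentrates at the top of the ranking and
negative at the bottom, always within [-1, 1].

A drug's therapeutic score averages ES_up - ES_down over its k instances:

    TS = (1/k) * sum_j (ES_up,j - ES_down,j)

Positive TS means the drug's expression response mimics the disease (the
disease's up genes are up under treatment) and may aggravate it; negative TS
means the drug reverses the disease signature and is a treatment candidate.

Drug-drug connectivity reuses the same machinery: one drug's instances are
reduced to a signature-shaped query (top/bottom mean-rank genes) and scored
against the other drug's instances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_classes import DiseaseSignature

DEFAULT_TOP_N = 250


class ProfileError(ValueError):
    """Invalid drug instance profile (not a permutation, too small)."""


class SignatureMismatchError(ValueError):
    """No query gene matches the profile's gene universe."""


@dataclass
class DrugInstanceProfile:
    """One instance: a drug name plus a full ranking of the gene universe."""

    instance_id: str
    drug_name: str
    ranked_genes: tuple[str, ...]
    _pos: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.ranked_genes)
        if n < 2:
            raise ProfileError(
                f"instance {self.instance_id!r}: profile needs >=2 genes, got {n}"
            )
        self._pos = {g: i + 1 for i, g in enumerate(self.ranked_genes)}
        if len(self._pos) != n:
            raise ProfileError(
                f"instance {self.instance_id!r}: ranked gene list is not a "
                "permutation (duplicate symbols)"
            )

    @property
    def n(self) -> int:
        return len(self.ranked_genes)

    def position(self, gene: str) -> int | None:
        """1-based rank of ``gene``, or None if absent from the universe."""
        return self._pos.get(gene)


@dataclass(frozen=True)
class KSResult:
    a: float
    b: float
    es: float
    m: int
    positions: tuple[int, ...]


@dataclass(frozen=True)
class InstanceScore:
    instance_id: str
    es_up: float
    es_down: float
    n_dropped_up: int = 0
    n_dropped_down: int = 0


@dataclass(frozen=True)
class DrugScore:
    drug_name: str
    ts: float
    k: int
    instance_scores: tuple[InstanceScore, ...]


def query_positions(
    query_genes: Iterable[str], profile: DrugInstanceProfile
) -> tuple[tuple[int, ...], int]:
    """Sorted 1-based positions of the query genes inside the profile.

    Query genes absent from the profile's universe are dropped (their count is
    returned); if nothing matches at all the signature and profile share no
    platform and scoring is meaningless, so that is an error.
    """
    genes = list(dict.fromkeys(query_genes))
    hits = [profile.position(g) for g in genes]
    positions = tuple(sorted(p for p in hits if p is not None))
    n_dropped = len(genes) - len(positions)
    if not positions:
        raise SignatureMismatchError(
            f"none of {len(genes)} query genes occur in instance "
            f"{profile.instance_id!r} (universe size {profile.n})"
        )
    return positions, n_dropped


def compute_es(positions: Sequence[int], n: int) -> KSResult:
    """KS enrichment score of a sorted 1-based position set in an n-gene list."""
    v = np.asarray(positions, dtype=float)
    m = v.size
    if m == 0:
        raise ValueError("positions must be non-empty")
    if m > n:
        raise ValueError(f"m={m} exceeds universe size n={n}")
    if (np.diff(v) <= 0).any():
        raise ValueError("positions must be strictly increasing")
    if v[0] < 1 or v[-1] > n:
        raise ValueError(f"positions must lie in [1, {n}]")
    p = np.arange(1, m + 1, dtype=float)
    a = float(np.max(p / m - v / n))
    b = float(np.max(v / n - (p - 1) / m))
    if a > b:
        es = a
    elif b > a:
        es = -b
    else:
        es = 0.0
    # hard bounds implied by the formulas; violation means a logic error
    assert -1.0 < a < 1.0 and 0.0 <= b <= 1.0 and abs(es) <= 1.0
    return KSResult(a=a, b=b, es=es, m=int(m), positions=tuple(int(x) for x in v))


def score_instance(
    signature: DiseaseSignature, profile: DrugInstanceProfile
) -> InstanceScore:
    """ES_up and ES_down of a disease signature against one instance.

    Signature genes missing from the instance's universe are dropped per side
    with a warning; a side that matches nothing is an error naming the side.
    """
    if not signature.up or not signature.down:
        side = "up" if not signature.up else "down"
        raise SignatureMismatchError(f"signature has an empty {side} list")
    scores, dropped = {}, {}
    for side, genes in (("up", signature.up), ("down", signature.down)):
        try:
            positions, n_dropped = query_positions(genes, profile)
        except SignatureMismatchError:
            raise SignatureMismatchError(
                f"no {side}-signature gene matches instance "
                f"{profile.instance_id!r} of drug {profile.drug_name!r}"
            ) from None
        if n_dropped:
            warnings.warn(
                f"instance {profile.instance_id!r}: dropped {n_dropped} "
                f"{side}-signature gene(s) absent from the profile universe",
                stacklevel=2,
            )
        scores[side] = compute_es(positions, profile.n).es
        dropped[side] = n_dropped
    return InstanceScore(
        instance_id=profile.instance_id,
        es_up=scores["up"],
        es_down=scores["down"],
        n_dropped_up=dropped["up"],
        n_dropped_down=dropped["down"],
    )


def _instance_contribution(s: InstanceScore, cmap_zeroing: bool) -> float:
    if cmap_zeroing and s.es_up * s.es_down > 0:
        # original CMap convention: discordant evidence (both sides enriched
        # the same way) contributes no connectivity
        return 0.0
    return s.es_up - s.es_down


def therapeutic_score(
    signature: DiseaseSignature,
    instances: Sequence[DrugInstanceProfile],
    cmap_zeroing: bool = False,
) -> DrugScore:
    """Average (ES_up - ES_down) over all instances of one drug.

    TS lies in [-2, 2]: negative values flag signature-reversing treatment
    candidates, positive values signature-mimicking potential aggravators.
    ``cmap_zeroing`` optionally zeroes instances whose ES_up and ES_down share
    a sign (the original CMap rule; off by default, the plain mean is used).
    """
    if not instances:
        raise ValueError("therapeutic_score needs at least one instance")
    names = {p.drug_name for p in instances}
    if len(names) > 1:
        raise ValueError(f"instances belong to multiple drugs: {sorted(names)}")
    per = tuple(score_instance(signature, p) for p in instances)
    ts = float(np.mean([_instance_contribution(s, cmap_zeroing) for s in per]))
    assert -2.0 <= ts <= 2.0
    return DrugScore(drug_name=instances[0].drug_name, ts=ts, k=len(per), instance_scores=per)


def score_all_drugs(
    signature: DiseaseSignature,
    library: Sequence[DrugInstanceProfile],
    cmap_zeroing: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Therapeutic score for every distinct drug in an instance library.

    Returns one row per drug (drug_name, ts, k) plus the list of drugs none of
    whose instances matched the signature (reported, never silently dropped).
    The per-instance ES values ride along in the ``scores`` attribute-free
    companion produced by :func:`instance_score_table`.
    """
    if not library:
        raise ValueError("instance library is empty")
    by_drug: dict[str, list[DrugInstanceProfile]] = {}
    for prof in library:
        by_drug.setdefault(prof.drug_name, []).append(prof)
    rows, unmatched, details = [], [], []
    for name in sorted(by_drug):
        try:
            ds = therapeutic_score(signature, by_drug[name], cmap_zeroing=cmap_zeroing)
        except SignatureMismatchError:
            unmatched.append(name)
            continue
        rows.append({"drug_name": ds.drug_name, "ts": ds.ts, "k": ds.k})
        details.append(ds)
    table = pd.DataFrame(rows, columns=["drug_name", "ts", "k"])
    table.attrs["drug_scores"] = details
    return table, unmatched


def instance_score_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Flatten the per-instance ES values carried by a score_all_drugs table."""
    rows = []
    for ds in scores.attrs.get("drug_scores", []):
        for s in ds.instance_scores:
            rows.append(
                {
                    "drug_name": ds.drug_name,
                    "instance_id": s.instance_id,
                    "es_up": s.es_up,
                    "es_down": s.es_down,
                }
            )
    return pd.DataFrame(rows, columns=["drug_name", "instance_id", "es_up", "es_down"])


def drug_query_signature(
    instances: Sequence[DrugInstanceProfile], top_n: int = DEFAULT_TOP_N
) -> DiseaseSignature:
    """Reduce a drug's instances to a signature-shaped query.

    Each gene's position is averaged across the drug's instances; the top_n
    genes with the smallest mean position form the up list (most up-regulated
    first) and the top_n with the largest form the down list.  Ties are broken
    lexicographically by symbol (with a warning, since a tie means the data do
    not order those genes).
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if not instances:
        raise ValueError("need at least one instance")
    universe = instances[0].ranked_genes
    n = len(universe)
    if 2 * top_n > n:
        raise ValueError(f"2*top_n = {2 * top_n} exceeds universe size {n}")
    mean_pos = pd.Series(0.0, index=list(universe))
    for prof in instances:
        if set(prof.ranked_genes) != set(universe):
            raise ProfileError("instances of one drug must share a gene universe")
        mean_pos += pd.Series({g: prof.position(g) for g in universe})
    mean_pos /= len(instances)
    if mean_pos.duplicated().any():
        warnings.warn(
            "mean-position ties in drug query signature; broken by symbol",
            stacklevel=2,
        )
    order = sorted(mean_pos.index, key=lambda g: (mean_pos[g], g))
    up = tuple(order[:top_n])
    down = tuple(order[-top_n:])
    # score = how far above the profile midpoint each gene sits, so that the
    # up list carries positive scores like a logFC-based signature
    scores = (n + 1) / 2 - mean_pos
    return DiseaseSignature(up=up, down=down, scores=scores[list(up + down)])


def drug_drug_connectivity(
    query_instances: Sequence[DrugInstanceProfile],
    reference_instances: Sequence[DrugInstanceProfile],
    top_n: int = DEFAULT_TOP_N,
    cmap_zeroing: bool = False,
) -> dict:
    """Connectivity of a reference drug to a query drug's rank signature.

    The query drug's instances are collapsed with :func:`drug_query_signature`
    and scored against the reference drug's instances.  ``score`` is on the
    raw [-2, 2] TS scale; ``normalized`` divides by 2 onto [-1, 1] for
    display (the normalization is recorded in the result).
    """
    sig = drug_query_signature(query_instances, top_n=top_n)
    ds = therapeutic_score(sig, list(reference_instances), cmap_zeroing=cmap_zeroing)
    return {
        "query_drug": query_instances[0].drug_name,
        "reference_drug": ds.drug_name,
        "score": ds.ts,
        "normalized": ds.ts / 2.0,
        "normalization": "ts/2",
        "top_n": top_n,
        "k": ds.k,
    }


# ---------------------------------------------------------------------------
# Instance library I/O.  Long form: one row per (instance, rank, gene) with
# columns instance_id, drug_name, rank, gene.  Rank-matrix form: genes x
# instances of integer ranks, column headers "instance_id|drug_name".
# Positions are 1-based in both formats.
# ---------------------------------------------------------------------------

def read_instances_long(path) -> list[DrugInstanceProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"instance_id": str, "drug_name": str, "gene": str})
    needed = {"instance_id", "drug_name", "rank", "gene"}
    if not needed <= set(df.columns):
        raise ProfileError(f"{path}: long-form library needs columns {sorted(needed)}")
    profiles = []
    for (iid, drug), grp in df.groupby(["instance_id", "drug_name"], sort=True):
        grp = grp.sort_values("rank")
        if (grp["rank"].to_numpy() != np.arange(1, len(grp) + 1)).any():
            raise ProfileError(
                f"instance {iid!r}: ranks must be exactly 1..n with no ties or gaps"
            )
        profiles.append(
            DrugInstanceProfile(
                instance_id=str(iid), drug_name=str(drug), ranked_genes=tuple(grp["gene"])
            )
        )
    return profiles


def write_instances_long(profiles: Sequence[DrugInstanceProfile], path) -> None:
    rows = []
    for prof in profiles:
        for rank, gene in enumerate(prof.ranked_genes, start=1):
            rows.append((prof.instance_id, prof.drug_name, rank, gene))
    pd.DataFrame(rows, columns=["instance_id", "drug_name", "rank", "gene"]).to_csv(
        path, sep="\t", index=False
    )


def read_instances_rank_matrix(path) -> list[DrugInstanceProfile]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    profiles = []
    for col in df.columns:
        if "|" not in col:
            raise ProfileError(
                f"{path}: rank-matrix column header {col!r} must be 'instance_id|drug_name'"
            )
        iid, drug = col.split("|", 1)
        ranks = df[col].astype(int)
        order = ranks.sort_values(kind="mergesort")
        if (order.to_numpy() != np.arange(1, len(order) + 1)).any():
            raise ProfileError(f"instance {iid!r}: ranks must be a permutation of 1..n")
        profiles.append(
            DrugInstanceProfile(instance_id=iid, drug_name=drug, ranked_genes=tuple(order.index))
        )
    return sorted(profiles, key=lambda p: (p.instance_id, p.drug_name))


def write_instances_rank_matrix(profiles: Sequence[DrugInstanceProfile], path) -> None:
    cols = {}
    for prof in profiles:
        cols[f"{prof.instance_id}|{prof.drug_name}"] = pd.Series(
            {g: i + 1 for i, g in enumerate(prof.ranked_genes)}
        )
    pd.DataFrame(cols).sort_index().to_csv(path, sep="\t", index_label="gene")


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"drug_name": str})
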