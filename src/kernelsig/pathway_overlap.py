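"""Bipartite overlap structure between two gene-set collections.

Used to relate a drug's target pathways to a disease's tissue-specific
pathways: an edge joins one set from each collection whenever they share at
least ``min_shared`` genes, weighted by the shared count.  Only the overlap
structure is computed here; an optional hypergeometric enrichment test is
available for users who supply a gene-universe size, but pathway enrichment
calling is otherwise out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats


class GeneSetError(ValueError):
    pass


@dataclass(frozen=True)
class OverlapEdge:
    set_a: str
    set_b: str
    shared: int
    shared_genes: tuple[str, ...]
    p_value: float | None = None


def _validate_collection(coll: Mapping[str, frozenset], label: str) -> dict[str, frozenset]:
    if not coll:
        raise GeneSetError(f"collection {label!r} is empty")
    out = {}
    for name, members in coll.items():
        members = frozenset(str(g) for g in members)
        if not members:
            raise GeneSetError(f"collection {label!r}: set {name!r} is empty")
        out[str(name)] = members
    return out


def overlap_graph(
    collection_a: Mapping[str, frozenset],
    collection_b: Mapping[str, frozenset],
    min_shared: int = 1,
    universe_size: int | None = None,
) -> list[OverlapEdge]:
    """All cross-collection set pairs sharing >= min_shared genes.

    Symmetric in its two arguments: swapping them yields the same edges with
    sides exchanged.  When ``universe_size`` is given, each edge also carries
    a hypergeometric tail p-value P(overlap >= shared) — a generic overlap
    test, not a replacement for any particular enrichment tool.
    """
    if min_shared < 1:
        raise GeneSetError("min_shared must be >= 1")
    a = _validate_collection(collection_a, "A")
    b = _validate_collection(collection_b, "B")
    edges = []
    for name_a in sorted(a):
        for name_b in sorted(b):
            common = a[name_a] & b[name_b]
            if len(common) < min_shared:
                continue
            p = None
            if universe_size is not None:
                if universe_size < len(a[name_a] | b[name_b]):
                    raise GeneSetError("universe_size smaller than the sets' union")
                p = float(
                    stats.hypergeom.sf(
                        len(common) - 1, universe_size, len(a[name_a]), len(b[name_b])
                    )
                )
            edges.append(
                OverlapEdge(
                    set_a=name_a,
                    set_b=name_b,
                    shared=len(common),
                    shared_genes=tuple(sorted(common)),
                    p_value=p,
                )
            )
    return edges


def edges_to_frame(edges: Sequence[OverlapEdge]) -> pd.DataFrame:
    rows = [
        {
            "set_a": e.set_a,
            "set_b": e.set_b,
            "shared": e.shared,
            "shared_genes": ",".join(e.shared_genes),
            **({"p_value": e.p_value} if e.p_value is not None else {}),
        }
        for e in edges
    ]
    cols = ["set_a", "set_b", "shared", "shared_genes"]
    if edges and edges[0].p_value is not None:
        cols.append("p_value")
    return pd.DataFrame(rows, columns=cols)


def write_edges(edges: Sequence[OverlapEdge], path) -> None:
    edges_to_frame(edges).to_csv(path, sep="\t", index=False, float_format="%.6g")


# --- GMT: set name, description, tab-separated members ----------------------

def read_gmt(path) -> dict[str, frozenset]:
    """Read a GMT file into an ordered name -> member-set mapping."""
    sets: dict[str, frozenset] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GeneSetError(
                    f"{path}:{lineno}: GMT line needs name, description, >=1 member"
                )
            name = parts[0]
            if name in sets:
                raise GeneSetError(f"{path}: duplicate set name {name!r}")
            members = frozenset(g for g in parts[2:] if g)
            if not members:
                raise GeneSetError(f"{path}: set {name!r} has no members")
            sets[name] = members
    if not sets:
        raise GeneSetError(f"{path}: no gene sets found")
    return sets


def write_gmt(
    collection: Mapping[str, frozenset], path, descriptions: Mapping[str, str] | None = None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection:
            desc = (descriptions or {}).get(name, "na")
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")
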