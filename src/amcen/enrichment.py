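"""Hypergeometric over-representation analysis against GMT gene sets.

Plain one-sided hypergeometric test (no EASE-style overlap adjustment):
for a query of n genes drawn from a background of N, a set overlapping the
background in m genes, and an observed overlap x, the enrichment p-value
is P(X >= x) from the same hypergeometric core as ceRNA pair calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .hypergeom import hypergeom_cerna_p


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with category labels (e.g. BP/CC/MF/pathway)."""

    sets: dict[str, frozenset[str]]
    categories: dict[str, str]

    def __post_init__(self) -> None:
        empties = [name for name, s in self.sets.items() if not s]
        if empties:
            raise ValueError(f"empty gene sets: {empties[:5]}")


def read_gmt(path: str | Path, category: str = "pathway") -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated member genes).

    The description field doubles as the category label when non-empty.
    """
    sets: dict[str, frozenset[str]] = {}
    cats: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        name, desc, genes = fields[0], fields[1], fields[2:]
        if name in sets:
            raise ValueError(f"duplicate gene-set name: {name}")
        sets[name] = frozenset(g.strip().upper() for g in genes if g.strip())
        cats[name] = desc if desc else category
    return GeneSetCollection(sets=sets, categories=cats)


def ora(query: set[str], background: set[str], collection: GeneSetCollection,
        p_threshold: float = 0.05) -> pd.DataFrame:
    """Over-representation table: one row per gene set with overlap count,
    percentage of the query, and P(X >= overlap); rows with p < p_threshold,
    sorted ascending by p."""
    query = {g.strip().upper() for g in query}
    background = {g.strip().upper() for g in background}
    stray = query - background
    if stray:
        raise ValueError(f"query genes absent from background: {sorted(stray)[:10]}")
    if len(background) < 2:
        raise ValueError("background must contain at least 2 genes")
    N, n = len(background), len(query)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & background
        m = len(members)
        if m == 0:
            continue
        x = len(query & members)
        p = hypergeom_cerna_p(N, n, m, x, tail="ge")
        rows.append({"category": collection.categories[name], "term": name,
                     "count": x, "percent": 100.0 * x / n if n else 0.0, "p": p})
    df = pd.DataFrame(rows, columns=["category", "term", "count", "percent", "p"])
    df = df[df["p"] < p_threshold].sort_values(["p", "term"], kind="stable")
    return df.reset_index(drop=True)


def write_enrichment_tsv(table: pd.DataFrame, path: str | Path) -> None:
    out = table.rename(columns={"category": "Category", "term": "Term",
                                "count": "Gene count", "percent": "%",
                                "p": "P-value"})
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
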