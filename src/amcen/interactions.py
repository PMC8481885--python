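"""Typed molecular-interaction edge lists (mRNA-miRNA, miRNA-lncRNA, PPI)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

EDGE_TYPES = ("mrna-mirna", "mirna-lncrna", "ppi")


def normalize_mirna(mirna_id: str) -> str:
    """Canonical miRNA ID: lowercase, species prefix 'hsa-' stripped, arm
    suffixes (-5p/-3p) kept distinct."""
    m = mirna_id.strip().lower()
    if m.startswith("hsa-"):
        m = m[4:]
    return m


@dataclass(frozen=True)
class InteractionTable:
    """A set of undirected (source, target) interaction edges with a type."""

    edges: frozenset[tuple[str, str]]
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in EDGE_TYPES:
            raise ValueError(f"kind must be one of {EDGE_TYPES}, got {self.kind!r}")
        selfloops = [e for e in self.edges if e[0] == e[1]]
        if selfloops:
            raise ValueError(f"self-edges not allowed: {selfloops[:5]}")

    def sources(self) -> set[str]:
        return {s for s, _ in self.edges}

    def targets(self) -> set[str]:
        return {t for _, t in self.edges}

    def partners_of_source(self, source: str) -> set[str]:
        return {t for s, t in self.edges if s == source}

    def __len__(self) -> int:
        return len(self.edges)


def make_table(edges, kind: str) -> InteractionTable:
    """Build a table from any (source, target) iterable, deduplicating and
    normalizing miRNA endpoints according to the table kind."""
    norm = []
    for s, t in edges:
        s, t = str(s).strip(), str(t).strip()
        if kind == "mrna-mirna":
            norm.append((s.upper(), normalize_mirna(t)))
        elif kind == "mirna-lncrna":
            norm.append((normalize_mirna(s), t.upper()))
        else:
            norm.append((s.upper(), t.upper()))
    return InteractionTable(edges=frozenset(norm), kind=kind)


def read_interactions_tsv(path: str | Path, kind: str) -> InteractionTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a 2-column TSV with a header")
    return make_table(zip(df.iloc[:, 0], df.iloc[:, 1]), kind)


def write_interactions_tsv(table: InteractionTable, path: str | Path,
                           columns: tuple[str, str] | None = None) -> None:
    if columns is None:
        columns = {"mrna-mirna": ("mrna", "mirna"),
                   "mirna-lncrna": ("mirna", "lncrna"),
                   "ppi": ("gene_a", "gene_b")}[table.kind]
    df = pd.DataFrame(sorted(table.edges), columns=list(columns))
    df.to_csv(path, sep="\t", index=False)
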