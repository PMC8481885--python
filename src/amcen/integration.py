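"""Intersect methylation and expression calls into the two aberrant classes.

A gene that is hypermethylated and downregulated falls in the
``hyper_low`` class; hypomethylated and upregulated genes form the mirror
``hypo_high`` class. These two classes seed the two separate ceRNA runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .differential import DifferentialRecord


def _norm(gene_id: str) -> str:
    return gene_id.strip().upper()


@dataclass(frozen=True)
class AberrantGeneSets:
    hyper_low: frozenset[str]
    hypo_high: frozenset[str]

    def __post_init__(self) -> None:
        both = self.hyper_low & self.hypo_high
        if both:
            raise ValueError(f"genes in both aberrant classes: {sorted(both)[:5]}")


def intersect_aberrant(expression_calls: list[DifferentialRecord],
                       methylation_calls: list[DifferentialRecord]) -> AberrantGeneSets:
    """hyper_low = hypermethylated AND downregulated; hypo_high = the mirror.

    Gene IDs are matched exactly after uppercasing and whitespace stripping.
    Genes screened on one platform only are non-members.
    """
    up = {_norm(r.feature_id) for r in expression_calls if r.direction == "up"}
    down = {_norm(r.feature_id) for r in expression_calls if r.direction == "down"}
    hyper = {_norm(r.feature_id) for r in methylation_calls if r.direction == "hyper"}
    hypo = {_norm(r.feature_id) for r in methylation_calls if r.direction == "hypo"}
    return AberrantGeneSets(hyper_low=frozenset(hyper & down),
                            hypo_high=frozenset(hypo & up))


def write_aberrant_sets(sets: AberrantGeneSets, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, genes in (("hyper_low", sets.hyper_low), ("hypo_high", sets.hypo_high)):
        (outdir / f"{name}_genes.txt").write_text("\n".join(sorted(genes)) + "\n")
    summary = {"hyper_low": len(sets.hyper_low), "hypo_high": len(sets.hypo_high)}
    (outdir / "aberrant_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
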