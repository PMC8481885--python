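"""Small built-in example inputs.

``pten_cerna_rows`` is a curated example of PTEN-associated ceRNA triples
reported in myasthenia-gravis monocytes: 15 (gene, miRNA, lncRNA) rows over
three partner lncRNAs. It exercises the biomarker-ranking stage end to end
without any external files.
"""

from __future__ import annotations

from .cerna import CeRNAPair, CeRNATriple

_PTEN_ROWS: tuple[tuple[str, str, str], ...] = (
    ("PTEN", "hsa-miR-106b", "FAM13A-AS1"),
    ("PTEN", "hsa-miR-23a", "FAM13A-AS1"),
    ("PTEN", "hsa-miR-25", "FAM13A-AS1"),
    ("PTEN", "hsa-miR-93", "FAM13A-AS1"),
    ("PTEN", "hsa-miR-106b", "LINC00173"),
    ("PTEN", "hsa-miR-181a", "LINC00173"),
    ("PTEN", "hsa-miR-181b", "LINC00173"),
    ("PTEN", "hsa-miR-181c", "LINC00173"),
    ("PTEN", "hsa-miR-23a", "LINC00173"),
    ("PTEN", "hsa-miR-93", "LINC00173"),
    ("PTEN", "hsa-miR-181a", "OIP5-AS1"),
    ("PTEN", "hsa-miR-181b", "OIP5-AS1"),
    ("PTEN", "hsa-miR-181c", "OIP5-AS1"),
    ("PTEN", "hsa-miR-25", "OIP5-AS1"),
    ("PTEN", "hsa-miR-93", "OIP5-AS1"),
)


def pten_cerna_rows() -> tuple[tuple[str, str, str], ...]:
    return _PTEN_ROWS


def pten_cerna_triples() -> list[CeRNATriple]:
    """The example rows as validated triples (one pair per lncRNA)."""
    by_lnc: dict[str, list[str]] = {}
    for _, mi, lnc in _PTEN_ROWS:
        by_lnc.setdefault(lnc, []).append(mi)
    universe = {mi for _, mi, _ in _PTEN_ROWS}
    triples = []
    for lnc, mis in by_lnc.items():
        pair = CeRNAPair(mrna="PTEN", lncrna=lnc, N=len(universe), n=len(universe),
                         m=len(mis), x=len(mis), shared_mirnas=frozenset(mis),
                         p_hyper=0.0)
        triples.extend(CeRNATriple("PTEN", mi, lnc, pair) for mi in sorted(mis))
    return triples
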