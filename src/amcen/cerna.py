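"""ceRNA triple inference.

A lncRNA acts as a competing endogenous RNA (ceRNA, a miRNA sponge) for an
mRNA when the two share miRNA binding partners and are positively
co-expressed. For each candidate (mRNA, lncRNA) pair the pipeline computes:

1. the cumulative hypergeometric probability of the observed shared-miRNA
   count x, given the universe of N miRNAs interacting with the aberrant
   gene class, the mRNA's n partners and the lncRNA's m in-universe
   partners (pairs with p < 0.05 survive; raw p-values, by design — only
   the co-expression p-values receive FDR adjustment);
2. the Pearson correlation of the pair across samples, with a t-transform
   p-value, BH-adjusted across all pairs in the run (PCC > 0.5 and
   FDR < 0.05 survive).

Each surviving pair then expands into one (mRNA, miRNA, lncRNA) triple per
shared miRNA, optionally restricted to a curated disease-risk miRNA list.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .hypergeom import hypergeom_cerna_p
from .interactions import InteractionTable, normalize_mirna
from .matrix import LabeledMatrix

log = logging.getLogger(__name__)


@dataclass
class CeRNAPair:
    """An (mRNA, lncRNA) candidate with its shared-miRNA test and
    co-expression statistics. ``pcc``/``fdr`` are NaN until the
    co-expression filter runs."""

    mrna: str
    lncrna: str
    N: int
    n: int
    m: int
    x: int
    shared_mirnas: frozenset[str]
    p_hyper: float
    pcc: float = math.nan
    p_corr: float = math.nan
    fdr: float = math.nan

    def __post_init__(self) -> None:
        if not 0 <= self.x <= min(self.n, self.m) <= self.N:
            raise ValueError(
                f"pair ({self.mrna}, {self.lncrna}): need 0 <= x <= min(n, m) <= N, "
                f"got x={self.x}, n={self.n}, m={self.m}, N={self.N}")
        if len(self.shared_mirnas) != self.x:
            raise ValueError(f"shared_mirnas has {len(self.shared_mirnas)} members, x={self.x}")


@dataclass(frozen=True)
class CeRNATriple:
    mrna: str
    mirna: str
    lncrna: str
    parent_pair: CeRNAPair = field(compare=False)
    curated: bool = False

    def __post_init__(self) -> None:
        if self.mirna not in self.parent_pair.shared_mirnas:
            raise ValueError(f"{self.mirna} not shared by ({self.mrna}, {self.lncrna})")


def match_dmg_mirna(genes: set[str], mrna_mirna: InteractionTable) -> InteractionTable:
    """Sub-table of mRNA-miRNA edges whose mRNA is in the aberrant gene set.

    The distinct miRNAs of the result define the universe N for the run.
    """
    if mrna_mirna.kind != "mrna-mirna":
        raise ValueError(f"expected an mrna-mirna table, got {mrna_mirna.kind!r}")
    genes_n = {g.strip().upper() for g in genes}
    kept = frozenset((s, t) for s, t in mrna_mirna.edges if s in genes_n)
    if not kept:
        log.warning("no mRNA-miRNA edges match the %d aberrant genes; "
                    "downstream stages will be empty", len(genes))
    return InteractionTable(edges=kept, kind="mrna-mirna")


def bh_fdr(pvalues: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enumerate_pairs(dmg_mirna: InteractionTable, mirna_lncrna: InteractionTable,
                    tail: str = "ge") -> list[CeRNAPair]:
    """All (mRNA, lncRNA) pairs sharing at least one universe miRNA, with
    their hypergeometric statistics."""
    if mirna_lncrna.kind != "mirna-lncrna":
        raise ValueError(f"expected a mirna-lncrna table, got {mirna_lncrna.kind!r}")
    universe = dmg_mirna.targets()
    N = len(universe)
    if N == 0:
        return []
    mrna_partners: dict[str, set[str]] = {}
    for g, mi in dmg_mirna.edges:
        mrna_partners.setdefault(g, set()).add(mi)
    lnc_partners: dict[str, set[str]] = {}
    for mi, lnc in mirna_lncrna.edges:
        if mi in universe:  # m counted within the run's universe
            lnc_partners.setdefault(lnc, set()).add(mi)
    pairs = []
    for g, gp in sorted(mrna_partners.items()):
        for lnc, lp in sorted(lnc_partners.items()):
            shared = gp & lp
            if not shared:
                continue
            p = hypergeom_cerna_p(N, len(gp), len(lp), len(shared), tail=tail)
            pairs.append(CeRNAPair(mrna=g, lncrna=lnc, N=N, n=len(gp), m=len(lp),
                                   x=len(shared), shared_mirnas=frozenset(shared),
                                   p_hyper=p))
    return pairs


def coexpression_filter(pairs: list[CeRNAPair], mrna_expr: LabeledMatrix,
                        lnc_expr: LabeledMatrix, pcc_threshold: float = 0.5,
                        fdr_threshold: float = 0.05) -> list[CeRNAPair]:
    """Attach Pearson correlations and BH-adjusted p-values; keep pairs with
    pcc > pcc_threshold and fdr < fdr_threshold (strict).

    The correlation p-value is the exact-under-normality t-transform
    t = r sqrt((s - 2) / (1 - r^2)) on s shared samples. Pairs whose
    molecules are missing from the matrices or have zero variance are
    dropped with a warning.
    """
    if mrna_expr.sample_ids != lnc_expr.sample_ids:
        raise ValueError("mRNA and lncRNA matrices must share the same ordered samples")
    s = len(mrna_expr.sample_ids)
    scored: list[CeRNAPair] = []
    for pair in pairs:
        if pair.mrna not in mrna_expr.values.index:
            log.warning("pair (%s, %s) dropped: mRNA absent from expression matrix",
                        pair.mrna, pair.lncrna)
            continue
        if pair.lncrna not in lnc_expr.values.index:
            log.warning("pair (%s, %s) dropped: lncRNA absent from expression matrix",
                        pair.mrna, pair.lncrna)
            continue
        xv = mrna_expr.values.loc[pair.mrna].to_numpy(dtype=float)
        yv = lnc_expr.values.loc[pair.lncrna].to_numpy(dtype=float)
        if np.std(xv) == 0 or np.std(yv) == 0:
            log.warning("pair (%s, %s) dropped: zero-variance profile", pair.mrna, pair.lncrna)
            continue
        r = float(np.corrcoef(xv, yv)[0, 1])
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((s - 2) / (1.0 - r * r))
            p = 2.0 * float(stats.t.sf(abs(t), s - 2))
        pair.pcc = r
        pair.p_corr = p
        scored.append(pair)
    if not scored:
        return []
    fdrs = bh_fdr([p.p_corr for p in scored])
    kept = []
    for pair, q in zip(scored, fdrs):
        pair.fdr = float(q)
        if pair.pcc > pcc_threshold and pair.fdr < fdr_threshold:
            kept.append(pair)
    return kept


def expand_triples(pairs: list[CeRNAPair]) -> list[CeRNATriple]:
    """One triple per shared miRNA of each surviving pair."""
    return [CeRNATriple(mrna=p.mrna, mirna=mi, lncrna=p.lncrna, parent_pair=p)
            for p in pairs for mi in sorted(p.shared_mirnas)]


def assemble_triples(dmg_mirna: InteractionTable, mirna_lncrna: InteractionTable,
                     mrna_expr: LabeledMatrix, lnc_expr: LabeledMatrix,
                     p_threshold: float = 0.05, tail: str = "ge",
                     pcc_threshold: float = 0.5,
                     fdr_threshold: float = 0.05) -> list[CeRNATriple]:
    """Full pair-to-triple inference for one aberrant gene class."""
    pairs = enumerate_pairs(dmg_mirna, mirna_lncrna, tail=tail)
    pairs = [p for p in pairs if p.p_hyper < p_threshold]
    pairs = coexpression_filter(pairs, mrna_expr, lnc_expr,
                                pcc_threshold=pcc_threshold, fdr_threshold=fdr_threshold)
    return expand_triples(pairs)


def restrict_to_curated(triples: list[CeRNATriple], curated: list[str]) -> list[CeRNATriple]:
    """Keep triples whose miRNA is in the curated risk list (matched after
    miRNA ID normalization) and set the curated flag."""
    if not curated:
        raise ValueError("curated miRNA list must be non-empty")
    curated_n = {normalize_mirna(c) for c in curated}
    return [CeRNATriple(t.mrna, t.mirna, t.lncrna, t.parent_pair, curated=True)
            for t in triples if normalize_mirna(t.mirna) in curated_n]


# ---------------------------------------------------------------------------
# persistence

def pairs_to_frame(pairs: list[CeRNAPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.mrna, p.lncrna, p.N, p.n, p.m, p.x, ";".join(sorted(p.shared_mirnas)),
          p.p_hyper, p.pcc, p.p_corr, p.fdr) for p in pairs],
        columns=["mrna", "lncrna", "N", "n", "m", "x", "shared_mirnas",
                 "p_hyper", "pcc", "p_corr", "fdr"],
    )


def write_pairs_tsv(pairs: list[CeRNAPair], path: str | Path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False, float_format="%.6g")


def triples_to_frame(triples: list[CeRNATriple]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.mrna, t.mirna, t.lncrna, t.curated) for t in triples],
        columns=["mrna", "mirna", "lncrna", "curated"],
    )


def write_triples(triples: list[CeRNATriple], tsv_path: str | Path,
                  json_path: str | Path | None = None) -> None:
    df = triples_to_frame(triples)
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(df.to_dict(orient="records"), indent=2) + "\n")
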