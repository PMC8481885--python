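"""Synthetic two-group expression/methylation study with planted structure.

Generates everything the pipeline consumes — case/control expression and
methylation matrices, an lncRNA expression matrix, mRNA-miRNA and
miRNA-lncRNA interaction tables, and a curated risk-miRNA list — together
with the ground truth that was planted, so recovery can be scored exactly:

* differentially expressed genes: a mean shift of ``de_effect`` (log2-like
  units) added to case samples, up and down in equal numbers;
* differentially methylated genes: a beta-value shift of ``dm_effect``
  applied to case samples and clamped to [0, 1];
* aberrant-class genes: blocks constructed to be simultaneously
  hypermethylated+down (hyper_low) and hypomethylated+up (hypo_high);
* ceRNA triples: planted (mRNA, lncRNA) pairs that share a block of
  miRNAs in the interaction tables and whose expression profiles are
  sampled with Pearson correlation ``planted_rho`` (bivariate Gaussian
  mixing), on top of uniform background edges at ``edge_density``.

``planted_triples`` counts (mRNA, miRNA, lncRNA) tuples; they are grouped
into pairs of ``shared_per_pair`` shared miRNAs each, because a pair
sharing a single miRNA carries no shared-miRNA signal a hypergeometric
test could distinguish from background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import CASE, CONTROL, LabeledMatrix, write_matrix_tsv
from .interactions import InteractionTable, make_table, normalize_mirna, write_interactions_tsv

METH_NOISE_SD = 0.05  # beta-value measurement noise around per-gene baselines


@dataclass(frozen=True)
class SimConfig:
    n_case: int = 25
    n_control: int = 25
    n_genes: int = 400
    n_mirnas: int = 120
    n_lncrnas: int = 200
    frac_de: float = 0.1
    de_effect: float = 2.0
    frac_dm: float = 0.1
    dm_effect: float = 0.2
    noise_sd: float = 1.0
    planted_triples: int = 20
    planted_rho: float = 0.8
    edge_density: float = 0.02
    shared_per_pair: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_case", "n_control", "n_genes", "n_mirnas", "n_lncrnas"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_case < 3 or self.n_control < 3:
            raise ValueError("need at least 3 samples per group (t-statistic degenerate)")
        for name in ("frac_de", "frac_dm", "dm_effect", "edge_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if abs(self.planted_rho) > 1.0:
            raise ValueError(f"|planted_rho| must be <= 1, got {self.planted_rho}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.planted_triples < 0 or self.shared_per_pair <= 0:
            raise ValueError("planted_triples >= 0 and shared_per_pair > 0 required")
        if self.planted_triples % self.shared_per_pair != 0:
            raise ValueError("planted_triples must be a multiple of shared_per_pair")
        n_pairs = self.planted_triples // self.shared_per_pair
        if n_pairs > self.n_lncrnas or n_pairs > self.n_genes:
            raise ValueError("planted pairs exceed available mRNA/lncRNA identifiers")
        if self.planted_triples > self.n_mirnas:
            raise ValueError("planted triples exceed available miRNA identifiers")


@dataclass(frozen=True)
class GroundTruth:
    true_up: frozenset[str]
    true_down: frozenset[str]
    true_hyper: frozenset[str]
    true_hypo: frozenset[str]
    true_hyperlow: frozenset[str]
    true_hypohigh: frozenset[str]
    true_triples: tuple[tuple[str, str, str], ...]  # (mRNA, miRNA normalized, lncRNA)

    def __post_init__(self) -> None:
        assert self.true_hyperlow <= self.true_hyper & self.true_down
        assert self.true_hypohigh <= self.true_hypo & self.true_up


@dataclass(frozen=True)
class SyntheticDataset:
    expression: LabeledMatrix
    methylation: LabeledMatrix
    lnc_expression: LabeledMatrix
    mrna_mirna: InteractionTable
    mirna_lncrna: InteractionTable
    curated_mirnas: tuple[str, ...]
    truth: GroundTruth
    config: SimConfig = field(repr=False)


def _sample_frame(rng, ids, samples, baselines, sd) -> pd.DataFrame:
    vals = baselines[:, None] + rng.normal(0.0, sd, size=(len(ids), len(samples)))
    return pd.DataFrame(vals, index=ids, columns=samples)


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate one reproducible synthetic study (same config+seed gives
    element-identical matrices and tables)."""
    c = config
    rng = np.random.default_rng(c.seed)

    genes = [f"GENE{i:04d}" for i in range(c.n_genes)]
    mirnas_raw = [f"hsa-miR-{i:03d}" for i in range(c.n_mirnas)]
    lncs = [f"LNC{i:04d}" for i in range(c.n_lncrnas)]
    samples = [f"MG{i:02d}" for i in range(c.n_case)] + \
              [f"CTRL{i:02d}" for i in range(c.n_control)]
    groups = pd.Series([CASE] * c.n_case + [CONTROL] * c.n_control,
                       index=samples, name="group")
    case_mask = np.array([g == CASE for g in groups])

    # ----- allocate differential blocks over a shuffled gene list
    pool = list(genes)
    rng.shuffle(pool)
    n_de_half = int(round(c.frac_de * c.n_genes / 2))
    n_dm_half = int(round(c.frac_dm * c.n_genes / 2))
    n_both = min(n_de_half, n_dm_half) // 2  # planted intersection per class

    def take(k: int) -> list[str]:
        out, pool[:] = pool[:k], pool[k:]
        return out

    hyperlow_block = take(n_both)                      # hyper AND down
    hypohigh_block = take(n_both)                      # hypo AND up
    down_only = take(n_de_half - n_both)
    up_only = take(n_de_half - n_both)
    hyper_only = take(n_dm_half - n_both)
    hypo_only = take(n_dm_half - n_both)

    true_down = frozenset(hyperlow_block + down_only)
    true_up = frozenset(hypohigh_block + up_only)
    true_hyper = frozenset(hyperlow_block + hyper_only)
    true_hypo = frozenset(hypohigh_block + hypo_only)

    # ----- planted ceRNA pairs: mRNAs hosted in the aberrant blocks when
    # they exist, otherwise in unused (non-differential) genes
    n_pairs = c.planted_triples // c.shared_per_pair
    hosts: list[str] = []
    a, b = list(hyperlow_block), list(hypohigh_block)
    while len(hosts) < n_pairs and (a or b):
        if a:
            hosts.append(a.pop(0))
        if len(hosts) < n_pairs and b:
            hosts.append(b.pop(0))
    while len(hosts) < n_pairs:
        if not pool:
            raise ValueError("planted pairs exceed available mRNA identifiers")
        hosts.append(pool.pop(0))

    pair_lncs = lncs[:n_pairs]
    pair_mirnas = [mirnas_raw[i * c.shared_per_pair:(i + 1) * c.shared_per_pair]
                   for i in range(n_pairs)]
    true_triples = tuple((g, normalize_mirna(mi), l)
                         for g, mis, l in zip(hosts, pair_mirnas, pair_lncs)
                         for mi in mis)

    # ----- expression matrix (log2-like scale)
    expr_base = rng.uniform(6.0, 10.0, size=c.n_genes)
    expr = _sample_frame(rng, genes, samples, expr_base, c.noise_sd)
    for g in true_up:
        expr.loc[g, case_mask] += c.de_effect
    for g in true_down:
        expr.loc[g, case_mask] -= c.de_effect

    # ----- methylation beta values, clamped Gaussian around baselines
    meth_base = rng.uniform(0.3, 0.7, size=c.n_genes)
    meth = _sample_frame(rng, genes, samples, meth_base, METH_NOISE_SD)
    for g in true_hyper:
        meth.loc[g, case_mask] += c.dm_effect
    for g in true_hypo:
        meth.loc[g, case_mask] -= c.dm_effect
    meth = meth.clip(0.0, 1.0)

    # ----- lncRNA expression; planted pairs correlate with their mRNA via
    # bivariate Gaussian mixing on the standardized mRNA profile
    lnc_base = rng.uniform(6.0, 10.0, size=c.n_lncrnas)
    lnc_expr = _sample_frame(rng, lncs, samples, lnc_base, c.noise_sd)
    for g, l in zip(hosts, pair_lncs):
        x = expr.loc[g].to_numpy()
        z = (x - x.mean()) / x.std() if x.std() > 0 else np.zeros_like(x)
        eps = rng.normal(0.0, 1.0, size=len(samples))
        mixed = c.planted_rho * z + np.sqrt(1.0 - c.planted_rho**2) * eps
        lnc_expr.loc[l] = lnc_base[lncs.index(l)] + c.noise_sd * mixed

    # ----- interaction tables: planted edges plus uniform background
    mm_edges = {(g, mi) for g, mis in zip(hosts, pair_mirnas) for mi in mis}
    bg = rng.random((c.n_genes, c.n_mirnas)) < c.edge_density
    mm_edges |= {(genes[i], mirnas_raw[j]) for i, j in zip(*np.nonzero(bg))}
    ml_edges = {(mi, l) for mis, l in zip(pair_mirnas, pair_lncs) for mi in mis}
    bg = rng.random((c.n_mirnas, c.n_lncrnas)) < c.edge_density
    ml_edges |= {(mirnas_raw[i], lncs[j]) for i, j in zip(*np.nonzero(bg))}

    # ----- curated risk miRNAs: every planted miRNA plus decoys
    planted_mi = sorted({mi for mis in pair_mirnas for mi in mis})
    decoy_pool = [m for m in mirnas_raw if m not in set(planted_mi)]
    n_decoys = min(30, len(decoy_pool))
    decoys = sorted(rng.choice(decoy_pool, size=n_decoys, replace=False)) if n_decoys else []
    curated = tuple(planted_mi + list(decoys))

    truth = GroundTruth(
        true_up=true_up, true_down=true_down,
        true_hyper=true_hyper, true_hypo=true_hypo,
        true_hyperlow=frozenset(hyperlow_block),
        true_hypohigh=frozenset(hypohigh_block),
        true_triples=true_triples,
    )
    return SyntheticDataset(
        expression=LabeledMatrix(expr, groups.copy()),
        methylation=LabeledMatrix(meth, groups.copy()),
        lnc_expression=LabeledMatrix(lnc_expr, groups.copy()),
        mrna_mirna=make_table(sorted(mm_edges), "mrna-mirna"),
        mirna_lncrna=make_table(sorted(ml_edges), "mirna-lncrna"),
        curated_mirnas=curated,
        truth=truth,
        config=c,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write all files the pipeline reads; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "methylation": outdir / "methylation.tsv",
        "lnc_expression": outdir / "lnc_expression.tsv",
        "groups": outdir / "groups.tsv",
        "mrna_mirna": outdir / "mrna_mirna.tsv",
        "mirna_lncrna": outdir / "mirna_lncrna.tsv",
        "curated_mirnas": outdir / "curated_mirnas.txt",
        "truth": outdir / "ground_truth.json",
    }
    write_matrix_tsv(ds.expression, paths["expression"], paths["groups"])
    write_matrix_tsv(ds.methylation, paths["methylation"])
    write_matrix_tsv(ds.lnc_expression, paths["lnc_expression"])
    write_interactions_tsv(ds.mrna_mirna, paths["mrna_mirna"])
    write_interactions_tsv(ds.mirna_lncrna, paths["mirna_lncrna"])
    paths["curated_mirnas"].write_text("\n".join(ds.curated_mirnas) + "\n")
    t = ds.truth
    paths["truth"].write_text(json.dumps({
        "true_up": sorted(t.true_up), "true_down": sorted(t.true_down),
        "true_hyper": sorted(t.true_hyper), "true_hypo": sorted(t.true_hypo),
        "true_hyperlow": sorted(t.true_hyperlow),
        "true_hypohigh": sorted(t.true_hypohigh),
        "true_triples": [list(x) for x in t.true_triples],
    }, indent=2) + "\n")
    return paths
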