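"""Two-group differential screening of expression and methylation matrices.

Features are called differential when ``p < p_threshold`` and ``|t| >
t_threshold`` (strict inequalities), the screening rule used throughout this
pipeline for both DEGs (differentially expressed genes) and DMGs
(differentially methylated genes). Three t-statistic flavors are offered:

``student``
    Ordinary pooled-variance two-sample t; the self-contained default.
``welch``
    Unequal-variance t with Welch–Satterthwaite degrees of freedom.
``moderated``
    Empirical-Bayes moderated t in the microarray tradition: each feature's
    pooled variance s_g^2 is shrunk toward a common prior,
    s~_g^2 = (d0 s0^2 + d s_g^2) / (d0 + d), with the prior degrees of
    freedom d0 and scale s0^2 estimated by method of moments on
    log variances; p-values use d + d0 degrees of freedom. This is the
    flavor to use when chasing GEO2R/limma-style calls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq

from .matrix import LabeledMatrix

log = logging.getLogger(__name__)

METHODS = ("student", "welch", "moderated")

# direction vocabularies per screening mode
_DIRECTIONS = {"expression": ("up", "down"), "methylation": ("hyper", "hypo")}
NONE = "none"


@dataclass(frozen=True)
class DifferentialRecord:
    """Per-feature screen result: signed t (positive = higher in cases),
    two-sided p, and a direction call (set by :func:`classify_differential`)."""

    feature_id: str
    t: float
    p: float
    direction: str = NONE


def _moments_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from per-feature sample variances.

    If z_g = log s_g^2 then Var(z) = psi'(d/2) + psi'(d0/2) and
    E[z] = log s0^2 + psi(d/2) - log(d/2) - (psi(d0/2) - log(d0/2));
    psi' is inverted numerically. An excess variance of ~0 means the
    variances are essentially equal and d0 -> infinity (full shrinkage).
    """
    z = np.log(s2[s2 > 0])
    if z.size < 2:
        return math.inf, float(np.exp(z.mean())) if z.size else 1.0
    evar = float(np.var(z, ddof=1)) - float(special.polygamma(1, d / 2))
    if evar <= 1e-8:
        d0 = math.inf
        s0_log = float(np.mean(z)) - float(special.psi(d / 2)) + math.log(d / 2)
        return d0, float(np.exp(s0_log))
    # solve trigamma(d0/2) = evar
    f = lambda d0: float(special.polygamma(1, d0 / 2)) - evar
    lo, hi = 1e-6, 1e6
    d0 = brentq(f, lo, hi) if f(lo) > 0 > f(hi) else (lo if f(lo) <= 0 else hi)
    s0_log = (float(np.mean(z)) - float(special.psi(d / 2)) + math.log(d / 2)
              + float(special.psi(d0 / 2)) - math.log(d0 / 2))
    return float(d0), float(np.exp(s0_log))


def two_group_t(matrix: LabeledMatrix, method: str = "student") -> list[DifferentialRecord]:
    """Per-feature case-vs-control t statistics and two-sided p-values.

    Missing cells are dropped per feature; features with fewer than 3
    available samples in either group are skipped with a warning. A feature
    with zero variance in both groups and equal means yields t = 0, p = 1.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")

    case = matrix.case_columns().to_numpy(dtype=float)
    ctrl = matrix.control_columns().to_numpy(dtype=float)
    features = matrix.feature_ids

    records: list[DifferentialRecord] = []
    rows: list[tuple[str, float, float, float, float]] = []  # id, diff, s2_pooled, d, se_factor
    for i, fid in enumerate(features):
        a = case[i][~np.isnan(case[i])]
        b = ctrl[i][~np.isnan(ctrl[i])]
        n1, n2 = a.size, b.size
        if n1 < 3 or n2 < 3:
            log.warning("feature %s skipped: <3 available samples per group", fid)
            continue
        diff = float(a.mean() - b.mean())
        v1 = float(a.var(ddof=1))
        v2 = float(b.var(ddof=1))
        if method == "welch":
            if v1 == 0.0 and v2 == 0.0:
                t, p = (0.0, 1.0) if diff == 0 else (math.copysign(math.inf, diff), 0.0)
                if diff == 0:
                    log.warning("feature %s: zero variance and equal means; t undefined, p=1", fid)
            else:
                se2 = v1 / n1 + v2 / n2
                df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
                t = diff / math.sqrt(se2)
                p = 2.0 * float(stats.t.sf(abs(t), df))
            records.append(DifferentialRecord(fid, t, p))
            continue
        d = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
        rows.append((fid, diff, s2, float(d), math.sqrt(1 / n1 + 1 / n2)))

    if method == "welch":
        return records

    if not rows:
        return records

    if method == "moderated":
        dfs = np.array([r[3] for r in rows])
        s2s = np.array([r[2] for r in rows])
        d0, s02 = _moments_prior(s2s, float(dfs.mean()))
    for fid, diff, s2, d, sef in rows:
        if method == "moderated":
            if math.isinf(d0):
                s2_t, df = s02, math.inf
            else:
                s2_t = (d0 * s02 + d * s2) / (d0 + d)
                df = d + d0
        else:
            s2_t, df = s2, d
        if s2_t == 0.0:
            if diff == 0.0:
                log.warning("feature %s: zero variance and equal means; t undefined, p=1", fid)
                t, p = 0.0, 1.0
            else:
                t, p = math.copysign(math.inf, diff), 0.0
        else:
            t = diff / (math.sqrt(s2_t) * sef)
            p = 2.0 * float(stats.t.sf(abs(t), df)) if math.isfinite(df) \
                else 2.0 * float(stats.norm.sf(abs(t)))
        records.append(DifferentialRecord(fid, t, p))
    return records


def classify_differential(records: list[DifferentialRecord],
                          p_threshold: float = 0.05,
                          t_threshold: float = 2.0,
                          mode: str = "expression") -> list[DifferentialRecord]:
    """Attach direction calls: up/hyper where t > t_threshold and
    p < p_threshold, down/hypo for the mirror; strict comparisons."""
    if p_threshold <= 0 or t_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if mode not in _DIRECTIONS:
        raise ValueError(f"mode must be one of {tuple(_DIRECTIONS)}, got {mode!r}")
    pos, neg = _DIRECTIONS[mode]
    out = []
    for r in records:
        if r.p < p_threshold and r.t > t_threshold:
            direction = pos
        elif r.p < p_threshold and r.t < -t_threshold:
            direction = neg
        else:
            direction = NONE
        out.append(DifferentialRecord(r.feature_id, r.t, r.p, direction))
    return out


def records_to_frame(records: list[DifferentialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.feature_id, r.t, r.p, r.direction) for r in records],
        columns=["feature_id", "t", "p", "direction"],
    ).set_index("feature_id")


def write_records_tsv(records: list[DifferentialRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", float_format="%.6g")


def read_records_tsv(path) -> list[DifferentialRecord]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [DifferentialRecord(str(i), float(r["t"]), float(r["p"]), str(r["direction"]))
            for i, r in df.iterrows()]
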