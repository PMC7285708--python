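"""Viral functional profiles: COG coverage, indicator COGs, AMG reporting.

Indicator COGs are orthologous groups whose normalized coverage differs
between the surface and deep sample groups under an unpaired two-sample
Wilcoxon rank-sum test with Benjamini-Hochberg correction. Sample counts here
are tiny (11 in the reference design), so the test is exact: the two-sided
p-value is computed by complete enumeration of group assignments using
mid-ranks for ties whenever C(n, n1) <= 100,000 assignments, and falls back to
the tie-corrected normal approximation beyond that.

The AMG of interest is COG0175 (PAPS/sulfonucleotide reductase, assimilatory
sulfate reduction); viral scaffolds carrying it are reported with per-sample
coverage of both scaffold and gene and whether the AMG is flanked by
virus-specific genes on both sides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .identify import classify_gene

log = logging.getLogger("tailvirkit.functions")

ENUM_LIMIT = 100_000
UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def ranksum_exact(x, y) -> float:
    """Two-sided two-sample rank-sum p-value.

    Exact by complete enumeration (mid-ranks for ties): p is the fraction of
    the C(n, n1) equally likely group assignments whose rank-sum deviates from
    the tie-invariant mean n1(n+1)/2 at least as much as observed. Falls back
    to the tie-corrected normal approximation when enumeration is infeasible.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    n = n1 + n2
    ranks = sps.rankdata(np.concatenate([x, y]))
    mu = n1 * (n + 1) / 2.0
    w_obs = ranks[:n1].sum()
    dev = abs(w_obs - mu)
    if comb(n, n1) <= ENUM_LIMIT:
        count = total = 0
        for idx in combinations(range(n), n1):
            w = ranks[list(idx)].sum()
            total += 1
            if abs(w - mu) >= dev - 1e-9:
                count += 1
        return count / total
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# COG-level coverage
# ---------------------------------------------------------------------------

def cog_coverage(genes, gene_cov_norm: pd.DataFrame) -> pd.DataFrame:
    """Sum gene-level normalized coverage per COG (COGs x libraries).

    Genes without a COG assignment are pooled into an "unassigned" row so the
    column sums conserve the total viral gene coverage.
    """
    if not genes:
        return pd.DataFrame(columns=gene_cov_norm.columns)
    ids = [g.gene_id for g in genes]
    missing = [i for i in ids if i not in gene_cov_norm.index]
    if missing:
        raise ValueError(f"genes without coverage rows: {missing[:5]}")
    labels = pd.Series({g.gene_id: (g.cog_id or UNASSIGNED) for g in genes})
    return gene_cov_norm.loc[ids].groupby(labels).sum().sort_index()


# ---------------------------------------------------------------------------
# indicator COGs
# ---------------------------------------------------------------------------

@dataclass
class IndicatorResult:
    cog_id: str
    mean_cov_surface: float
    mean_cov_deep: float
    p_value: float
    q_value: float
    direction: str                      # "surface" | "deep"
    significant: bool
    carrier_viral_ids: frozenset = frozenset()


def indicator_cogs(cog_matrix: pd.DataFrame, groups: pd.Series,
                   alpha: float = 0.05,
                   carriers: dict[str, frozenset] | None = None
                   ) -> list[IndicatorResult]:
    """Rank-sum + BH screen of every testable COG between surface and deep.

    ``groups`` maps sample_id -> "surface" | "deep". COGs with all-zero
    coverage across samples are untestable and skipped (they do not enter the
    BH family). Direction is the group with the larger mean normalized
    coverage.
    """
    bad = set(groups.unique()) - {"surface", "deep"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    surface = [s for s in cog_matrix.columns if groups.get(s) == "surface"]
    deep = [s for s in cog_matrix.columns if groups.get(s) == "deep"]
    if not surface or not deep:
        raise ValueError("both groups must be non-empty")
    carriers = carriers or {}

    testable, pvals = [], []
    for cog, row in cog_matrix.iterrows():
        if cog == UNASSIGNED:
            continue
        if (row == 0).all():
            log.info("COG %s all-zero across samples: skipped", cog)
            continue
        testable.append(cog)
        pvals.append(ranksum_exact(row[surface].values, row[deep].values))
    if not testable:
        return []
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")

    results = []
    for cog, p, q in zip(testable, pvals, qvals):
        ms = float(cog_matrix.loc[cog, surface].mean())
        md = float(cog_matrix.loc[cog, deep].mean())
        results.append(IndicatorResult(
            cog_id=cog, mean_cov_surface=ms, mean_cov_deep=md,
            p_value=float(p), q_value=float(max(q, p)),
            direction="surface" if ms >= md else "deep",
            significant=bool(q < alpha),
            carrier_viral_ids=carriers.get(cog, frozenset())))
    results.sort(key=lambda r: (r.q_value, r.p_value, r.cog_id))
    return results


def indicator_table(results: list[IndicatorResult]) -> pd.DataFrame:
    rows = [{"cog_id": r.cog_id, "mean_cov_surface": r.mean_cov_surface,
             "mean_cov_deep": r.mean_cov_deep, "p_value": r.p_value,
             "q_value": r.q_value, "direction": r.direction,
             "significant": r.significant,
             "carrier_viral_ids": ",".join(sorted(r.carrier_viral_ids))}
            for r in results]
    return pd.DataFrame(rows, columns=["cog_id", "mean_cov_surface", "mean_cov_deep",
                                       "p_value", "q_value", "direction",
                                       "significant", "carrier_viral_ids"])


# ---------------------------------------------------------------------------
# AMG report
# ---------------------------------------------------------------------------

@dataclass
class AmgReport:
    viral_id: str
    amg_gene_ids: list[str]
    flanked_by_hallmark: bool
    scaffold_coverage: pd.Series        # per-sample normalized coverage
    gene_coverage: pd.Series            # summed over the scaffold's AMG genes
    group_p: float


def amg_report(catalogue, scaffold_cov_norm: pd.DataFrame,
               gene_cov_norm: pd.DataFrame, groups: pd.Series,
               cfg: PipelineConfig | None = None) -> list[AmgReport]:
    """One report per curated viral scaffold carrying >= 1 COG0175 gene.

    ``flanked_by_hallmark`` is true when a virus-specific gene occurs both
    strictly before and strictly after an AMG gene on the scaffold.
    """
    cfg = cfg or PipelineConfig()
    surface = [s for s in scaffold_cov_norm.columns if groups.get(s) == "surface"]
    deep = [s for s in scaffold_cov_norm.columns if groups.get(s) == "deep"]
    out = []
    for v in catalogue:
        amg = [g for g in v.genes if g.cog_id == cfg.amg_cog]
        if not amg:
            continue
        hall_pos = [(g.start, g.end) for g in v.genes
                    if classify_gene(g, cfg).virus_specific]
        flanked = any(
            any(h_end <= a.start for _, h_end in hall_pos)
            and any(h_start >= a.end for h_start, _ in hall_pos)
            for a in amg)
        scov = scaffold_cov_norm.loc[v.viral_id]
        gcov = gene_cov_norm.loc[[g.gene_id for g in amg]].sum(axis=0)
        p = ranksum_exact(scov[surface].values, scov[deep].values) \
            if surface and deep else float("nan")
        out.append(AmgReport(v.viral_id, [g.gene_id for g in amg], flanked,
                             scov, gcov, p))
    out.sort(key=lambda r: r.viral_id)
    return out


def amg_table(reports: list[AmgReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {"viral_id": r.viral_id,
               "amg_gene_ids": ",".join(r.amg_gene_ids),
               "flanked_by_hallmark": r.flanked_by_hallmark,
               "group_p": r.group_p}
        row.update({f"scaffold_cov_{s}": v for s, v in r.scaffold_coverage.items()})
        row.update({f"gene_cov_{s}": v for s, v in r.gene_coverage.items()})
        rows.append(row)
    return pd.DataFrame(rows)
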