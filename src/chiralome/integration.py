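"""Metabolome-transcriptome integration.

Stages: CV-band gene filtering, fold-change gene filtering, Pearson
gene-metabolite edges (positive correlations only), overlap of edge genes
with pathway gene sets, and joint pathway enrichment combining a gene-side
and a compound-side hypergeometric test with a degree-centrality topology
impact score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from chiralome.config import AnalysisConfig
from chiralome.io_formats import ExpressionMatrix, PathwayDefinition

logger = logging.getLogger(__name__)


@dataclass
class CorrelationEdge:
    gene: str
    metabolite: str
    r: float
    n: int


@dataclass
class JointPathwayResult:
    pathway_id: str
    name: str
    total: int
    hits_cmpd: int
    hits_gene: int
    p_gene: float        # NaN when the pathway has no gene members
    p_cmpd: float        # NaN when the pathway has no compound members
    p_combined: float
    impact: float
    impact_flagged: bool  # True when computed without topology
    reported: bool


def coefficient_of_variation(expr: ExpressionMatrix) -> pd.Series:
    """Per-gene CV (sample standard deviation, n-1 denominator, over mean).

    Genes with mean 0 get NaN.
    """
    if expr.tpm.shape[1] < 2:
        raise ValueError("CV needs >= 2 samples")
    mean = expr.tpm.mean(axis=1)
    sd = expr.tpm.std(axis=1, ddof=1)
    cv = sd / mean.mask(mean == 0)
    return cv


def cv_filter(expr: ExpressionMatrix, config: AnalysisConfig | None = None) -> list[str]:
    """Genes whose CV falls strictly inside (cv_lo, cv_hi)."""
    config = config or AnalysisConfig()
    cv = coefficient_of_variation(expr)
    keep = cv[(cv > config.cv_lo) & (cv < config.cv_hi)]
    return list(keep.index)


def de_gene_filter(
    fold_changes: Mapping[str, float] | pd.Series,
    config: AnalysisConfig | None = None,
) -> list[str]:
    """Genes whose linear fold change exceeds the threshold (strict).

    In absolute mode (default) FC < 1/threshold also passes.
    """
    config = config or AnalysisConfig()
    fc = pd.Series(fold_changes, dtype=float)
    if not np.isfinite(fc.to_numpy()).all():
        bad = fc.index[~np.isfinite(fc.to_numpy())][0]
        raise ValueError(f"non-finite fold change for gene {bad!r}")
    thr = config.gene_fc_threshold
    mask = fc > thr
    if config.gene_fc_absolute:
        mask |= fc < 1.0 / thr
    return list(fc.index[mask])


def correlate(
    expr: ExpressionMatrix,
    metabolite_abundances: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> list[CorrelationEdge]:
    """Pearson edges between genes (rows of ``expr``) and metabolites.

    ``metabolite_abundances`` is metabolites x samples with the same sample
    columns (order enforced here).  Only edges with r >= r_min are emitted;
    zero-variance genes or metabolites yield no edge and are logged.
    """
    config = config or AnalysisConfig()
    samples = list(metabolite_abundances.columns)
    missing = [s for s in samples if s not in expr.tpm.columns]
    if missing:
        raise ValueError(f"expression matrix lacks samples {missing}")
    n = len(samples)
    if n < 3:
        raise ValueError(f"correlation needs >= 3 samples, got {n}")
    g = expr.tpm[samples].to_numpy(dtype=float)
    m = metabolite_abundances[samples].to_numpy(dtype=float)

    g_c = g - g.mean(axis=1, keepdims=True)
    m_c = m - m.mean(axis=1, keepdims=True)
    g_ss = np.sqrt((g_c**2).sum(axis=1))
    m_ss = np.sqrt((m_c**2).sum(axis=1))
    zero_g = g_ss == 0
    zero_m = m_ss == 0
    if zero_g.any():
        logger.info("correlate: %d zero-variance genes skipped", int(zero_g.sum()))
    if zero_m.any():
        logger.info(
            "correlate: zero-variance metabolites skipped: %s",
            list(metabolite_abundances.index[zero_m]),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (g_c @ m_c.T) / np.outer(g_ss, m_ss)

    edges: list[CorrelationEdge] = []
    genes = expr.tpm.index
    mets = metabolite_abundances.index
    keep = ~zero_g[:, None] & ~zero_m[None, :] & (r >= config.r_min)
    for i, j in zip(*np.nonzero(keep)):
        edges.append(
            CorrelationEdge(gene=str(genes[i]), metabolite=str(mets[j]),
                            r=float(r[i, j]), n=n)
        )
    return edges


def edges_frame(edges: Iterable[CorrelationEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene": e.gene, "metabolite": e.metabolite, "r": e.r, "n": e.n} for e in edges],
        columns=["gene", "metabolite", "r", "n"],
    )


def overlap_with_pathway_genes(
    edges: Iterable[CorrelationEdge],
    pathways: Iterable[PathwayDefinition],
) -> pd.DataFrame:
    """Intersect each metabolite's correlated genes with pathway gene sets.

    Returns one row per (metabolite, overlapping gene) with the
    semicolon-joined list of pathways containing that gene.
    """
    pathways = list(pathways)
    gene_to_pathways: dict[str, list[str]] = {}
    for pw in pathways:
        for gene in pw.gene_members:
            gene_to_pathways.setdefault(gene, []).append(pw.pathway_id)
    per_met: dict[str, set[str]] = {}
    for edge in edges:
        per_met.setdefault(edge.metabolite, set()).add(edge.gene)
    rows = []
    for met in sorted(per_met):
        for gene in sorted(per_met[met] & set(gene_to_pathways)):
            rows.append(
                {
                    "metabolite": met,
                    "gene": gene,
                    "pathways": ";".join(sorted(gene_to_pathways[gene])),
                }
            )
    return pd.DataFrame(rows, columns=["metabolite", "gene", "pathways"])


def hypergeometric_enrichment(
    query: Iterable[str], members: Iterable[str], universe: Iterable[str]
) -> float:
    """Upper-tail hypergeometric P(X >= k) of the query/member overlap.

    k successes among |query| draws without replacement from a universe
    containing |members| successes.
    """
    query, members, universe = set(query), set(members), set(universe)
    outside = members - universe
    if outside:
        raise ValueError(f"pathway members outside universe: {sorted(outside)[:5]}")
    outside_q = query - universe
    if outside_q:
        raise ValueError(f"query items outside universe: {sorted(outside_q)[:5]}")
    k = len(query & members)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, len(universe), len(members), len(query)))


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's unweighted combination: chi-square(2k) upper tail of
    -2 * sum(ln p)."""
    ps = [float(p) for p in p_values]
    if not ps:
        raise ValueError("no p-values to combine")
    for p in ps:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-value out of (0, 1]: {p}")
    x = -2.0 * sum(math.log(p) for p in ps)
    return float(stats.chi2.sf(x, df=2 * len(ps)))


def topology_impact(pathway: PathwayDefinition, hit_nodes: Iterable[str]) -> float:
    """Degree-centrality impact: hit-node degree mass over total degree mass.

    Without topology, falls back to the complete-graph equivalent
    |hits| / |members| (flagged by the caller).
    """
    hits = set(hit_nodes)
    members = pathway.members
    outside = hits - members
    if outside:
        raise ValueError(f"hit nodes outside pathway: {sorted(outside)[:5]}")
    if not members:
        raise ValueError(f"pathway {pathway.pathway_id!r} has no members")
    if pathway.topology is None:
        return len(hits) / len(members)
    degree: dict[str, int] = {m: 0 for m in members}
    for a, b in pathway.topology:
        degree[a] += 1
        degree[b] += 1
    total = sum(degree.values())
    if total == 0:
        # topology present but edgeless: fall back to membership fraction
        return len(hits) / len(members)
    return sum(degree[h] for h in hits) / total


def joint_pathway_analysis(
    gene_query: Iterable[str],
    cmpd_query: Iterable[str],
    pathways: Iterable[PathwayDefinition],
    gene_universe: Iterable[str],
    cmpd_universe: Iterable[str],
    config: AnalysisConfig | None = None,
) -> list[JointPathwayResult]:
    """Joint enrichment over gene and compound queries.

    Per pathway: hypergeometric tests for the gene and compound member
    subsets (each run only when the pathway has members of that kind in the
    universe), Fisher-combined; topology impact over the union of hit nodes.
    ``reported`` marks pathways passing the headline filter: at least one
    compound hit AND one gene hit, combined p below ``p_combined_max`` and
    impact above ``impact_min``.
    """
    config = config or AnalysisConfig()
    gene_query = set(gene_query)
    cmpd_query = set(cmpd_query)
    gene_universe = set(gene_universe)
    cmpd_universe = set(cmpd_universe)
    results: list[JointPathwayResult] = []
    for pw in pathways:
        gene_members = pw.gene_members & gene_universe
        cmpd_members = pw.compound_members & cmpd_universe
        gene_hits = gene_query & gene_members
        cmpd_hits = cmpd_query & cmpd_members
        ps: list[float] = []
        p_gene = float("nan")
        p_cmpd = float("nan")
        if gene_members:
            p_gene = hypergeometric_enrichment(gene_query, gene_members, gene_universe)
            ps.append(p_gene)
        if cmpd_members:
            p_cmpd = hypergeometric_enrichment(cmpd_query, cmpd_members, cmpd_universe)
            ps.append(p_cmpd)
        p_combined = fisher_combine(ps) if ps else 1.0
        impact = topology_impact(pw, gene_hits | cmpd_hits)
        reported = (
            len(cmpd_hits) >= 1
            and len(gene_hits) >= 1
            and p_combined < config.p_combined_max
            and impact > config.impact_min
        )
        results.append(
            JointPathwayResult(
                pathway_id=pw.pathway_id,
                name=pw.name,
                total=len(pw.members),
                hits_cmpd=len(cmpd_hits),
                hits_gene=len(gene_hits),
                p_gene=p_gene,
                p_cmpd=p_cmpd,
                p_combined=p_combined,
                impact=impact,
                impact_flagged=pw.topology is None,
                reported=reported,
            )
        )
    return results


def pathways_frame(
    results: Iterable[JointPathwayResult], reported_only: bool = False
) -> pd.DataFrame:
    rows = [
        {
            "pathway_id": r.pathway_id,
            "name": r.name,
            "total": r.total,
            "hits_cmpd": r.hits_cmpd,
            "hits_gene": r.hits_gene,
            "p_value": r.p_combined,
            "impact": r.impact,
            "impact_flagged": r.impact_flagged,
            "reported": r.reported,
        }
        for r in results
        if r.reported or not reported_only
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "pathway_id", "name", "total", "hits_cmpd", "hits_gene",
            "p_value", "impact", "impact_flagged", "reported",
        ],
    )
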