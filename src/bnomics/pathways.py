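"""Metabolite-only and joint metabolite+gene pathway enrichment.

Over-representation analysis (ORA) uses the upper-tail hypergeometric
probability of the observed query/pathway overlap against a background
universe; Wilcoxon enrichment analysis (WEA) rank-compares pathway members'
case/control fold differences against non-members; per-pathway gene and
metabolite p-values are combined with Fisher's method (4 degrees of
freedom) and BH-adjusted across the evaluated pathways. Topology-based
"pathway impact" is the matched metabolites' share of the pathway graph's
total relative betweenness centrality. The MetPA-style concentration test
is a permutation surrogate: the statistic is the sum of squared
standardized case/control mean differences over the pathway's members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 1e-300  # floor before logs; printed inputs reach the 1e-20 scale

ENRICHMENT_COLUMNS = [
    "pathway", "name", "n_overlap_genes", "n_overlap_metabolites",
    "p_gene", "p_metabolite", "p_joint", "q_joint", "impact",
    "genes", "metabolites",
]


@dataclass
class PathwaySet:
    """GMT-style pathway memberships over a gene+metabolite universe."""

    pathways: dict[str, dict] = field(default_factory=dict)
    gene_universe: set[str] = field(default_factory=set)
    metabolite_universe: set[str] = field(default_factory=set)

    def add(self, pathway_id: str, name: str, genes: set[str],
            metabolites: set[str]) -> None:
        if not genes and not metabolites:
            raise ValueError(f"pathway {pathway_id!r} has no members")
        entry = self.pathways.setdefault(
            pathway_id, {"name": name, "genes": set(), "metabolites": set()})
        entry["genes"] |= genes
        entry["metabolites"] |= metabolites
        self.gene_universe |= genes
        self.metabolite_universe |= metabolites

    @classmethod
    def from_gmt(cls, gene_gmt: str | Path | None = None,
                 metabolite_gmt: str | Path | None = None) -> "PathwaySet":
        """Merge gene-member and metabolite-member GMT files by pathway id.

        Standard tab-separated GMT: id, description, then members.
        """
        ps = cls()
        for path, kind in ((gene_gmt, "genes"), (metabolite_gmt, "metabolites")):
            if path is None:
                continue
            for line in Path(path).read_text().splitlines():
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed GMT line: {line[:60]!r}")
                pid, desc, members = parts[0], parts[1], set(parts[2:]) - {""}
                entry = ps.pathways.setdefault(
                    pid, {"name": desc, "genes": set(), "metabolites": set()})
                entry[kind] |= members
                if kind == "genes":
                    ps.gene_universe |= members
                else:
                    ps.metabolite_universe |= members
        return ps


def read_pathway_graphs(path: str | Path) -> dict[str, nx.Graph]:
    """SIF-like TSV (pathway, source, relation, target) -> directed graphs."""
    tab = pd.read_csv(path, sep="\t")
    need = {"pathway", "source", "target"}
    if not need <= set(tab.columns):
        raise ValueError(f"pathway graph file needs columns {sorted(need)}")
    graphs: dict[str, nx.DiGraph] = {}
    for pid, sub in tab.groupby("pathway"):
        g = nx.DiGraph()
        for _, row in sub.iterrows():
            g.add_edge(row["source"], row["target"])
        graphs[pid] = g
    return graphs


# ------------------------------------------------------------------ tests


def ora_hypergeometric(query: set[str], members: set[str],
                       universe: set[str]) -> float:
    """Upper-tail hypergeometric p of >= observed query/pathway overlap."""
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    if not query <= universe:
        raise ValueError("query ids outside the universe")
    members = members & universe
    k = len(query & members)
    if k == 0:
        return 1.0
    # P(X >= k), X ~ Hypergeom(N=|universe|, K=|members|, n=|query|)
    return float(min(1.0, stats.hypergeom.sf(
        k - 1, len(universe), len(members), len(query))))


def fishers_method(p_values) -> float:
    """Fisher's combined p: upper chi-square tail of -2*sum(ln p), 2k df."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0):
        raise ValueError("p = 0 passed to fishers_method; floor first")
    if np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, 2 * p.size))


def wilcoxon_enrichment(member_stats, non_member_stats) -> float:
    """Two-sided rank-sum p comparing member vs non-member statistics
    (exact for small samples without ties, tie-corrected normal
    approximation otherwise)."""
    a = np.asarray(list(member_stats), dtype=float)
    b = np.asarray(list(non_member_stats), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both sides need at least one value")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(min(1.0, res.pvalue))


def pathway_impact(graph: nx.Graph, matched: set[str]) -> float:
    """Matched metabolites' share of the total relative betweenness
    centrality of the pathway graph; 0 when the graph has no centrality."""
    missing = matched - set(graph.nodes)
    if missing:
        raise ValueError(f"metabolites not in pathway graph: {sorted(missing)[:5]}")
    centrality = nx.betweenness_centrality(graph, normalized=True)
    total = sum(centrality.values())
    if total == 0:
        return 0.0
    return float(sum(centrality[m] for m in matched) / total)


def pathway_concentration_test(
    abundances: pd.DataFrame,
    phenotype: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p for pathway-level association with a binary phenotype.

    Statistic: sum over member metabolites of the squared standardized
    case/control mean difference; phenotype labels permuted ``n_perm``
    times; p = (1 + #{perm >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = phenotype.loc[abundances.columns].to_numpy(dtype=int)
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 subjects per phenotype class")
    X = abundances.to_numpy(dtype=float)

    def statistic(labels: np.ndarray) -> float:
        g1 = X[:, labels == 1]
        g0 = X[:, labels == 0]
        d = np.nanmean(g1, axis=1) - np.nanmean(g0, axis=1)
        pooled = np.nanstd(X, axis=1, ddof=1)
        pooled[pooled == 0] = 1.0
        return float(np.nansum((d / pooled) ** 2))

    observed = statistic(y)
    rng = np.random.default_rng(seed)
    hits = 0
    labels = y.copy()
    for _ in range(n_perm):
        rng.shuffle(labels)
        if statistic(labels) >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


# ------------------------------------------------------------- pipeline


def run_integrative_ora(
    query_genes: set[str],
    query_metabolites: set[str],
    pathway_set: PathwaySet,
    graphs: dict[str, nx.Graph] | None = None,
) -> pd.DataFrame:
    """Joint ORA over pathways with at least one overlapping gene AND one
    overlapping metabolite: hypergeometric p per side, Fisher joint p
    (4 df), BH across evaluated pathways, impact where a graph exists."""
    graphs = graphs or {}
    qg = query_genes & pathway_set.gene_universe
    qm = query_metabolites & pathway_set.metabolite_universe
    rows = []
    for pid, entry in sorted(pathway_set.pathways.items()):
        og = qg & entry["genes"]
        om = qm & entry["metabolites"]
        if not og or not om:
            continue
        p_gene = ora_hypergeometric(qg, entry["genes"],
                                    pathway_set.gene_universe)
        p_met = ora_hypergeometric(qm, entry["metabolites"],
                                   pathway_set.metabolite_universe)
        p_joint = fishers_method([max(p_gene, P_FLOOR), max(p_met, P_FLOOR)])
        impact = np.nan
        if pid in graphs:
            matched = om & set(graphs[pid].nodes)
            impact = pathway_impact(graphs[pid], matched)
        rows.append({
            "pathway": pid, "name": entry["name"],
            "n_overlap_genes": len(og), "n_overlap_metabolites": len(om),
            "p_gene": p_gene, "p_metabolite": p_met, "p_joint": p_joint,
            "q_joint": np.nan, "impact": impact,
            "genes": sorted(og), "metabolites": sorted(om),
        })
    if not rows:
        import warnings

        warnings.warn("no pathway has both a gene and a metabolite overlap")
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    out = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    from .association import bh_fdr

    out["q_joint"] = bh_fdr(np.maximum(out["p_joint"].to_numpy(), P_FLOOR))
    return out.sort_values(
        ["q_joint", "p_joint", "pathway"], kind="stable"
    ).reset_index(drop=True)


def run_wea(
    fold_differences: pd.Series,
    pathway_set: PathwaySet,
    kind: str = "metabolites",
) -> pd.DataFrame:
    """Wilcoxon enrichment of per-feature case/control fold differences
    for every pathway with members among the scored features."""
    scored = set(fold_differences.index)
    rows = []
    for pid, entry in sorted(pathway_set.pathways.items()):
        members = entry[kind] & scored
        others = scored - members
        if not members or not others:
            continue
        p = wilcoxon_enrichment(fold_differences[sorted(members)],
                                fold_differences[sorted(others)])
        rows.append({"pathway": pid, "name": entry["name"],
                     "n_members_scored": len(members), "p_wea": p})
    out = pd.DataFrame(rows)
    if len(out):
        from .association import bh_fdr

        out["q_wea"] = bh_fdr(out["p_wea"].to_numpy())
    return out
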