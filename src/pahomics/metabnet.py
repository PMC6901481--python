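"""Metabolomics differential analysis, pathway enrichment and the
metabolite-enzyme network mapping.

Metabolite differential abundance uses a Welch two-sample t-test on log2
abundances (half-minimum replacement for zeros / missing values). Pathway
enrichment is a hypergeometric over-representation test with the fold
enrichment defined as the significant-member proportion inside the pathway
relative to the overall significant proportion; a pathway is flagged
dysregulated when p < 0.05 and fold enrichment > 1. Significant enzymes and
metabolites are then mapped onto a bipartite metabolite-enzyme reaction
network and connected dysregulated subnetworks are extracted and ranked.
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr
from .omics_io import GeneSetCollection, IntensityMatrix
from .proximity import NodeSet

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300  # exact-separation guard: p pushed to (0, 1] boundary


class MetabNetError(ValueError):
    pass


def metabolite_diff(m: IntensityMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Welch t-test per metabolite on log2 abundances.

    Zeros and missing values are replaced by half the metabolite's smallest
    positive abundance before the log. Metabolites with zero variance in
    both groups get p = 1 when the means agree, otherwise a floor p with
    ``exact_separation`` flagged.
    """
    case = m.samples_in_group("case")
    control = m.samples_in_group("control")
    if len(case) < 2 or len(control) < 2:
        raise MetabNetError("need >=2 samples per group")
    x = m.values.to_numpy(dtype=float)
    pos_min = np.nanmin(np.where(x > 0, x, np.nan), axis=1)
    if np.isnan(pos_min).any():
        bad = m.values.index[np.isnan(pos_min)][0]
        raise MetabNetError(f"metabolite {bad!r} has no positive abundance")
    fill = (pos_min / 2.0)[:, None]
    x = np.where(np.isnan(x) | (x <= 0), fill, x)
    logx = np.log2(x)
    ci = [m.sample_ids.index(s) for s in case]
    ki = [m.sample_ids.index(s) for s in control]
    xc, xk = logx[:, ci], logx[:, ki]
    log2fc = xc.mean(axis=1) - xk.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(xc, xk, axis=1, equal_var=False)
    degenerate = (xc.var(axis=1) == 0) & (xk.var(axis=1) == 0)
    exact_sep = degenerate & (log2fc != 0)
    p = np.where(degenerate & (log2fc == 0), 1.0, p)
    p = np.where(exact_sep, _P_FLOOR, p)
    t_deg = np.where(exact_sep, np.where(log2fc > 0, np.inf, -np.inf), 0.0)
    t = np.where(degenerate, t_deg, t)
    out = pd.DataFrame({
        "feature_id": m.feature_ids,
        "log2fc": log2fc,
        "fold_change": np.exp2(log2fc),
        "t": t,
        "p": p,
        "exact_separation": exact_sep,
    })
    out["q"] = bh_fdr(out["p"].to_numpy())
    sig = out["p"] < alpha
    out["direction"] = np.where(~sig, "ns",
                                np.where(out["log2fc"] > 0, "up", "down"))
    return out


def pathway_enrichment(diff: pd.DataFrame, pathways: GeneSetCollection,
                       alpha_member: float = 0.05, rule: str = "raw_p"
                       ) -> pd.DataFrame:
    """Hypergeometric over-representation of significant metabolites.

    N counts all measured metabolites (unnamed included); pathway sizes m
    count measured members only, so pathways are intersected with the data
    first. ``dysregulated`` is the printed rule: p < 0.05 and fold
    enrichment > 1.
    """
    if rule not in ("raw_p", "fdr"):
        raise MetabNetError(f"unknown rule {rule!r}")
    measured = set(diff["feature_id"])
    crit = diff["p"] if rule == "raw_p" else diff["q"]
    sig = set(diff.loc[crit < alpha_member, "feature_id"])
    n_total, n_sig = len(measured), len(sig)
    rows = []
    for name, members in pathways.items():
        inside = set(members) & measured
        m_size = len(inside)
        if m_size == 0:
            logger.warning("pathway %s has no measured members; skipped", name)
            continue
        k = len(inside & sig)
        if n_sig == 0:
            fold, p = 0.0, 1.0
        else:
            fold = (k / m_size) / (n_sig / n_total)
            p = float(stats.hypergeom.sf(k - 1, n_total, n_sig, m_size))
        rows.append((name, k, m_size, n_sig, n_total, fold, p))
    out = pd.DataFrame(rows, columns=["pathway", "k", "m", "K", "N",
                                      "fold_enrichment", "p"])
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out["dysregulated"] = (out["p"] < 0.05) & (out["fold_enrichment"] > 1)
        out = out.sort_values(["p", "pathway"], kind="mergesort",
                              ignore_index=True)
    else:
        out["q"] = np.array([], dtype=float)
        out["dysregulated"] = np.array([], dtype=bool)
    return out


class MetEnzNetwork:
    """Bipartite enzyme <-> metabolite graph with reaction annotations."""

    def __init__(self, graph: nx.Graph):
        for u, v in graph.edges:
            if graph.nodes[u]["kind"] == graph.nodes[v]["kind"]:
                raise MetabNetError(
                    f"edge ({u}, {v}) joins two {graph.nodes[u]['kind']} "
                    "nodes; network must be bipartite")
        self.graph = graph

    @property
    def enzymes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True)
                if d["kind"] == "enzyme"}

    @property
    def metabolites(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True)
                if d["kind"] == "metabolite"}

    def is_bipartite(self) -> bool:
        return all(self.graph.nodes[u]["kind"] != self.graph.nodes[v]["kind"]
                   for u, v in self.graph.edges)


def build_met_enz_network(edge_table: pd.DataFrame) -> MetEnzNetwork:
    """Assemble the bipartite network from an (enzyme_gene, metabolite_id,
    reaction_id) table; duplicate edges merge their reaction ids."""
    required = ["enzyme_gene", "metabolite_id", "reaction_id"]
    for col in required:
        if col not in edge_table.columns:
            raise MetabNetError(f"edge table lacks column {col!r}")
    both = set(edge_table["enzyme_gene"]) & set(edge_table["metabolite_id"])
    if both:
        raise MetabNetError(
            f"ids used as both enzyme and metabolite: {sorted(both)[:3]}")
    g = nx.Graph()
    for enz, met, rid in edge_table[required].itertuples(index=False):
        enz, met = str(enz), str(met)
        g.add_node(enz, kind="enzyme")
        g.add_node(met, kind="metabolite")
        if g.has_edge(enz, met):
            g.edges[enz, met]["reactions"] = (
                g.edges[enz, met]["reactions"] | {rid})
        else:
            g.add_edge(enz, met, reactions=frozenset({rid}))
    return MetEnzNetwork(g)


def map_dysregulated(net: MetEnzNetwork, sig_enzymes: NodeSet,
                     sig_metabolites: NodeSet, max_hops: int = 2
                     ) -> tuple[MetEnzNetwork, pd.DataFrame]:
    """Extract the dysregulated subnetwork around significant nodes.

    The subnetwork is induced on all significant nodes plus any node lying
    on a path of at most ``max_hops`` edges between two distinct significant
    nodes (the default 2 admits one intermediate). Components are ranked by
    significant-member count, then total size, then smallest node id.
    """
    if max_hops < 0:
        raise MetabNetError("max_hops must be >= 0")
    g = net.graph
    sig = ((set(sig_enzymes.members) | set(sig_metabolites.members))
           & set(g.nodes))
    if not sig:
        logger.warning("no significant node maps into the network")
        empty = MetEnzNetwork(nx.Graph())
        return empty, pd.DataFrame(columns=["component", "n_significant",
                                            "size", "members"])
    keep = set(sig)
    if max_hops >= 2 and len(sig) >= 2:
        dists = {s: nx.single_source_shortest_path_length(g, s,
                                                          cutoff=max_hops)
                 for s in sorted(sig)}
        for node in g.nodes:
            if node in keep:
                continue
            best = sorted(d[node] for d in dists.values() if node in d)[:2]
            if len(best) == 2 and best[0] + best[1] <= max_hops:
                keep.add(node)
    sub = MetEnzNetwork(g.subgraph(keep).copy())
    comps = [sorted(c) for c in nx.connected_components(sub.graph)]
    comps.sort(key=lambda c: (-len(set(c) & sig), -len(c), c[0]))
    rows = [(i + 1, len(set(c) & sig), len(c), ";".join(c))
            for i, c in enumerate(comps)]
    table = pd.DataFrame(rows, columns=["component", "n_significant", "size",
                                        "members"])
    return sub, table
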