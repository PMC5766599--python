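"""lncRNA-protein-coding co-expression network.

Vertices are features differentially expressed in *both* cohorts
(discovery FDR < 0.2, confirmation FDR < 0.05), split into lncRNA and
protein-coding classes. Edges connect an lncRNA to a protein-coding gene
when their Pearson correlation — over confirmation-cohort tumor samples,
on log2(CPM + 0.5) — falls in the strongest 0.5% positive or strongest
0.5% negative tail of all candidate lncRNA-PCG pairs. The graph is
bipartite by construction; high-degree lncRNAs are the network's hubs.

The 0.5% percentile is taken globally over all candidate pairs (the
closest literal reading of a single edge-selection rule); a per-lncRNA
variant is available via ``per_lncrna=True``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import log_cpm
from .errors import ValidationError
from .io import CountMatrix, FeatureAnnotation, SampleSheet

logger = logging.getLogger(__name__)


def select_vertices(
    discovery: pd.DataFrame,
    confirmation: pd.DataFrame,
    annotation: FeatureAnnotation,
    fdr_disc: float = 0.2,
    fdr_conf: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Candidate vertex sets (lncRNA ids, protein-coding ids).

    A feature qualifies when its FDR is strictly below both thresholds.
    Features the annotation does not classify are excluded with a warning.
    """
    d = discovery.set_index("feature_id")["fdr"]
    c = confirmation.set_index("feature_id")["fdr"]
    both = d.index.intersection(c.index)
    passing = both[(d[both] < fdr_disc) & (c[both] < fdr_conf)]
    flags = annotation.is_lncrna()
    known = passing.intersection(flags.index)
    dropped = passing.difference(flags.index)
    if len(dropped):
        logger.warning("%d vertex candidate(s) lack annotation; excluded", len(dropped))
    lnc = sorted(f for f in known if flags[f])
    pcg = sorted(f for f in known if not flags[f])
    return lnc, pcg


def select_edges(corr: pd.DataFrame, edge_fraction: float = 0.005) -> pd.DataFrame:
    """Percentile-threshold edges from an lncRNA x PCG correlation matrix.

    With P defined pairs, the ceil(edge_fraction * P) largest correlations
    become positive edges and the ceil(edge_fraction * P) smallest become
    negative edges. Ties at either cutoff are resolved by (lncRNA id,
    PCG id) lexicographic order, so the output is deterministic. NaN
    entries (undefined correlations) never enter the candidate pool.

    Returns a DataFrame with columns lnc_id, pcg_id, r, sign.
    """
    if not 0.0 < edge_fraction <= 0.5:
        raise ValidationError("edge_fraction must lie in (0, 0.5]")
    long = corr.stack(future_stack=True).rename("r").reset_index()
    long.columns = ["lnc_id", "pcg_id", "r"]
    long = long.dropna(subset=["r"])
    n_pairs = len(long)
    if n_pairs == 0:
        return pd.DataFrame(columns=["lnc_id", "pcg_id", "r", "sign"])
    k = math.ceil(edge_fraction * n_pairs)
    pos = long.sort_values(
        ["r", "lnc_id", "pcg_id"], ascending=[False, True, True], kind="mergesort"
    ).head(k)
    neg = long.sort_values(
        ["r", "lnc_id", "pcg_id"], ascending=[True, True, True], kind="mergesort"
    ).head(k)
    pos = pos.assign(sign="positive")
    neg = neg.assign(sign="negative")
    edges = pd.concat([pos, neg], ignore_index=True)
    # when 2k > P a middle pair can land in both tails; keep its positive call
    edges = edges.drop_duplicates(subset=["lnc_id", "pcg_id"], keep="first")
    return edges.reset_index(drop=True)


@dataclass
class CoexpressionNetwork:
    """A bipartite lncRNA-PCG graph plus the parameters that built it."""

    graph: nx.Graph
    params: dict = field(default_factory=dict)

    @property
    def lncrna_vertices(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("cls") == "lncRNA"
        )

    @property
    def pcg_vertices(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("cls") == "protein_coding"
        )

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {"lnc_id": u if self.graph.nodes[u]["cls"] == "lncRNA" else v,
             "pcg_id": v if self.graph.nodes[u]["cls"] == "lncRNA" else u,
             "r": d["r"], "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["lnc_id", "pcg_id", "r", "sign"]).sort_values(
            ["lnc_id", "pcg_id"]
        ).reset_index(drop=True)


def correlation_matrix(
    expr: CountMatrix,
    sheet: SampleSheet,
    lnc_ids: list[str],
    pcg_ids: list[str],
    sample_subset: str = "tumor",
) -> pd.DataFrame:
    """Pearson correlations (lncRNA rows x PCG columns) on log2(CPM+0.5)
    over the chosen sample subset; zero-variance features give NaN."""
    samples = (
        expr.sample_ids
        if sample_subset == "all"
        else [s for s in expr.sample_ids if s in set(sheet.samples_where(sample_subset))]
    )
    if len(samples) < 3:
        raise ValidationError("need >= 3 samples in the subset to correlate")
    mat = log_cpm(expr.subset_samples(samples))
    sub = mat.loc[lnc_ids + pcg_ids].to_numpy()
    centred = sub - sub.mean(axis=1, keepdims=True)
    norms = np.sqrt((centred**2).sum(axis=1))
    nl = len(lnc_ids)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centred[:nl] @ centred[nl:].T) / np.outer(norms[:nl], norms[nl:])
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=lnc_ids, columns=pcg_ids)


def build_network(
    expr: CountMatrix,
    sheet: SampleSheet,
    vertices: tuple[list[str], list[str]],
    edge_fraction: float = 0.005,
    sample_subset: str = "tumor",
    drop_isolated: bool = True,
    per_lncrna: bool = False,
) -> CoexpressionNetwork:
    """Assemble the co-expression network; see module docstring.

    ``vertices`` comes from :func:`select_vertices`. Isolated candidate
    vertices are dropped by default so the graph matches what would be
    drawn. ``per_lncrna`` applies the edge percentile within each
    lncRNA's own candidate pairs instead of globally.
    """
    lnc_ids, pcg_ids = (sorted(vertices[0]), sorted(vertices[1]))
    g = nx.Graph()
    if lnc_ids and pcg_ids:
        corr = correlation_matrix(expr, sheet, lnc_ids, pcg_ids, sample_subset)
        if per_lncrna:
            edges = pd.concat(
                [select_edges(corr.loc[[l]], edge_fraction) for l in lnc_ids],
                ignore_index=True,
            )
        else:
            edges = select_edges(corr, edge_fraction)
    else:
        edges = pd.DataFrame(columns=["lnc_id", "pcg_id", "r", "sign"])

    for n in lnc_ids:
        g.add_node(n, cls="lncRNA")
    for n in pcg_ids:
        g.add_node(n, cls="protein_coding")
    for row in edges.itertuples(index=False):
        g.add_edge(row.lnc_id, row.pcg_id, r=float(row.r), sign=row.sign)
    if drop_isolated:
        g.remove_nodes_from(list(nx.isolates(g)))

    for u, v in g.edges():
        if g.nodes[u]["cls"] == g.nodes[v]["cls"]:  # pragma: no cover
            raise ValidationError("network is not bipartite")
    params = {
        "edge_fraction": edge_fraction,
        "sample_subset": sample_subset,
        "drop_isolated": drop_isolated,
        "per_lncrna": per_lncrna,
        "n_lnc_candidates": len(lnc_ids),
        "n_pcg_candidates": len(pcg_ids),
    }
    return CoexpressionNetwork(graph=g, params=params)


def hub_report(net: CoexpressionNetwork, top_k: int | None = None) -> pd.DataFrame:
    """lncRNA vertices ranked by degree (ties by id), with per-hub counts
    of positive and negative edges."""
    g = net.graph
    rows = []
    for n in net.lncrna_vertices:
        signs = [d["sign"] for _, _, d in g.edges(n, data=True)]
        rows.append(
            {
                "feature_id": n,
                "degree": g.degree(n),
                "n_positive": signs.count("positive"),
                "n_negative": signs.count("negative"),
            }
        )
    out = pd.DataFrame(rows, columns=["feature_id", "degree", "n_positive", "n_negative"])
    out = out.sort_values(
        ["degree", "feature_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out.head(top_k) if top_k else out


def neighbor_jaccard(net: CoexpressionNetwork, a: str, b: str) -> float:
    """Jaccard overlap of two vertices' neighbor sets (1.0 when both empty
    sets coincide trivially is avoided: two isolated vertices give 0)."""
    na = set(net.graph.neighbors(a)) if a in net.graph else set()
    nb = set(net.graph.neighbors(b)) if b in net.graph else set()
    union = na | nb
    if not union:
        return 0.0
    return len(na & nb) / len(union)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_edge_list(net: CoexpressionNetwork, path) -> None:
    net.edges.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_sif(net: CoexpressionNetwork, path) -> None:
    """Simple interaction format: `lnc coexpr_pos|coexpr_neg pcg` lines."""
    lines = [
        f"{row.lnc_id}\tcoexpr_{'pos' if row.sign == 'positive' else 'neg'}\t{row.pcg_id}"
        for row in net.edges.itertuples(index=False)
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def write_graphml(net: CoexpressionNetwork, path) -> None:
    g = net.graph.copy()
    for n in g.nodes:
        g.nodes[n]["degree"] = g.degree(n)
    nx.write_graphml(g, path)


def write_hub_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)
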