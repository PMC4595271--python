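"""Signed, thresholded co-expression networks with anchor genes.

Two network constructions are provided:

* ``correlation_edges`` scores every cross pair between two profile sets
  (e.g. structural genes vs. transcription factors) and keeps edges with
  |Pearson r| at or above a threshold (default 0.8, inclusive -- the
  source convention oscillates between "> 0.8" and ">= |0.8|"; the
  boundary is configurable via ``inclusive``).  Edges are undirected and
  canonicalized by id ordering, and carry r and its sign.

* ``build_anchored_network`` builds the focused three-layer network
  around anchor genes (e.g. the MEP-pathway reductase HDR and the
  monoterpenol glucosyltransferase GT14): a TF is admitted only when it
  passes the threshold against EVERY anchor; a ripening-associated gene
  is admitted when it passes against at least one admitted TF.  Anchors
  never connect directly to ripening genes in this construction.  TFs
  whose qualifying correlations are all positive (or all negative)
  toward the anchors are labelled accordingly; TFs positive to one
  anchor and negative to another are kept and labelled ``mixed``.

Networks export to Cytoscape-loadable SIF ("pos"/"neg" interaction
types) and GraphML (r as edge weight) plus node/edge attribute tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CoexpressionEdge:
    source: str
    target: str
    r: float

    def __post_init__(self) -> None:
        if self.source > self.target:
            raise ValueError("edge endpoints must be in canonical (sorted) order")

    @property
    def sign(self) -> str:
        return "pos" if self.r >= 0 else "neg"


def _corr_matrix(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Pearson r for all row pairs of two aligned profile matrices."""
    av = a.to_numpy(dtype=float)
    bv = b.to_numpy(dtype=float)
    az = av - av.mean(axis=1, keepdims=True)
    bz = bv - bv.mean(axis=1, keepdims=True)
    an = np.linalg.norm(az, axis=1)
    bn = np.linalg.norm(bz, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (az @ bz.T) / np.outer(an, bn)
    return pd.DataFrame(r, index=a.index, columns=b.index)


def correlation_edges(
    profiles_a: pd.DataFrame,
    profiles_b: pd.DataFrame,
    *,
    threshold: float = 0.8,
    inclusive: bool = True,
) -> list[CoexpressionEdge]:
    """Thresholded signed correlation edges between two profile sets.

    Profiles are rows over identical condition cells (>= 3).  Self pairs
    are skipped; zero-variance profiles are skipped with a warning; the
    edge set is canonical and deduplicated, so swapping the two sets
    yields the same edges.
    """
    if not profiles_a.columns.equals(profiles_b.columns):
        raise ValueError("profile sets are not on identical condition cells")
    if profiles_a.shape[1] < 3:
        raise ValueError("need at least 3 condition cells")
    for name, prof in (("A", profiles_a), ("B", profiles_b)):
        flat = prof.to_numpy(dtype=float).std(axis=1)
        if (flat == 0).any():
            bad = list(prof.index[flat == 0])
            warnings.warn(
                f"zero-variance profiles skipped in set {name}: {bad}",
                UserWarning,
                stacklevel=2,
            )
    r = _corr_matrix(profiles_a, profiles_b)
    edges: dict[tuple[str, str], float] = {}
    for ida in r.index:
        for idb in r.columns:
            if ida == idb:
                continue
            val = r.loc[ida, idb]
            if not np.isfinite(val):
                continue
            ok = abs(val) >= threshold if inclusive else abs(val) > threshold
            if ok:
                key = (str(min(ida, idb)), str(max(ida, idb)))
                edges.setdefault(key, float(val))
    return [
        CoexpressionEdge(s, t, v) for (s, t), v in sorted(edges.items())
    ]


@dataclass
class AnchoredNetwork:
    anchors: list[str]
    tfs: list[str]
    ripening: list[str]
    #: admitted TF -> sign toward the anchors: "positive"/"negative"/"mixed"
    tf_signs: dict[str, str]
    anchor_tf_edges: list[CoexpressionEdge] = field(default_factory=list)
    tf_ripening_edges: list[CoexpressionEdge] = field(default_factory=list)

    @property
    def edges(self) -> list[CoexpressionEdge]:
        return self.anchor_tf_edges + self.tf_ripening_edges

    def node_categories(self) -> dict[str, str]:
        cats = {a: "anchor" for a in self.anchors}
        cats.update({t: "TF" for t in self.tfs})
        cats.update({g: "ripening" for g in self.ripening})
        return cats

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for node, cat in self.node_categories().items():
            g.add_node(node, category=cat)
        for node, sign in self.tf_signs.items():
            g.nodes[node]["tf_sign"] = sign
        for e in self.edges:
            g.add_edge(e.source, e.target, r=e.r, sign=e.sign)
        return g


def build_anchored_network(
    anchor_profiles: pd.DataFrame,
    tf_profiles: pd.DataFrame,
    ripening_profiles: pd.DataFrame,
    *,
    threshold: float = 0.8,
    inclusive: bool = True,
) -> AnchoredNetwork:
    """Three-layer anchor - TF - ripening-gene network.

    Raising the threshold above every observed |r| yields an empty
    network, never an error.
    """
    if len(anchor_profiles) == 0:
        raise ValueError("need at least one anchor profile")

    def passes(v: float) -> bool:
        return np.isfinite(v) and (
            abs(v) >= threshold if inclusive else abs(v) > threshold
        )

    r_at = _corr_matrix(tf_profiles, anchor_profiles)  # TFs x anchors
    admitted_tfs: list[str] = []
    tf_signs: dict[str, str] = {}
    anchor_tf_edges: list[CoexpressionEdge] = []
    for tf in r_at.index:
        vals = r_at.loc[tf]
        if all(passes(v) for v in vals):
            admitted_tfs.append(str(tf))
            signs = {"pos" if v >= 0 else "neg" for v in vals}
            tf_signs[str(tf)] = (
                "mixed" if len(signs) > 1
                else ("positive" if signs == {"pos"} else "negative")
            )
            for anchor in r_at.columns:
                s, t = sorted((str(tf), str(anchor)))
                anchor_tf_edges.append(
                    CoexpressionEdge(s, t, float(r_at.loc[tf, anchor]))
                )

    ripening_nodes: list[str] = []
    tf_ripening_edges: list[CoexpressionEdge] = []
    if admitted_tfs and len(ripening_profiles) > 0:
        r_rt = _corr_matrix(ripening_profiles, tf_profiles.loc[admitted_tfs])
        for gene in r_rt.index:
            hits = [tf for tf in r_rt.columns if passes(r_rt.loc[gene, tf])]
            if hits:
                ripening_nodes.append(str(gene))
                for tf in hits:
                    s, t = sorted((str(gene), str(tf)))
                    tf_ripening_edges.append(
                        CoexpressionEdge(s, t, float(r_rt.loc[gene, tf]))
                    )

    return AnchoredNetwork(
        anchors=[str(a) for a in anchor_profiles.index],
        tfs=admitted_tfs,
        ripening=ripening_nodes,
        tf_signs=tf_signs,
        anchor_tf_edges=sorted(
            anchor_tf_edges, key=lambda e: (e.source, e.target)
        ),
        tf_ripening_edges=sorted(
            tf_ripening_edges, key=lambda e: (e.source, e.target)
        ),
    )


def export_network(
    network: AnchoredNetwork | Sequence[CoexpressionEdge],
    out_dir,
    *,
    basename: str = "network",
    node_attributes: Mapping[str, Mapping[str, object]] | None = None,
) -> dict[str, Path]:
    """Write SIF, GraphML and node/edge attribute tables for Cytoscape.

    An empty network produces valid empty files plus a warning.  Returns
    the written paths keyed by format.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(network, AnchoredNetwork):
        graph = network.to_graph()
        edges = network.edges
    else:
        edges = list(network)
        graph = nx.Graph()
        for e in edges:
            graph.add_edge(e.source, e.target, r=e.r, sign=e.sign)
    if node_attributes:
        for node, attrs in node_attributes.items():
            if node in graph:
                graph.nodes[node].update(attrs)
    if graph.number_of_edges() == 0:
        warnings.warn("exporting an empty network", UserWarning, stacklevel=2)

    paths = {
        "sif": out_dir / f"{basename}.sif",
        "graphml": out_dir / f"{basename}.graphml",
        "nodes": out_dir / f"{basename}_node_attributes.tsv",
        "edges": out_dir / f"{basename}_edge_attributes.tsv",
    }
    with open(paths["sif"], "w") as fh:
        for e in edges:
            fh.write(f"{e.source}\t{e.sign}\t{e.target}\n")
    nx.write_graphml(graph, paths["graphml"])
    pd.DataFrame(
        [{"node": n, **attrs} for n, attrs in sorted(graph.nodes(data=True))]
    ).to_csv(paths["nodes"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"source": e.source, "target": e.target, "r": e.r, "sign": e.sign}
            for e in edges
        ],
        columns=["source", "target", "r", "sign"],
    ).to_csv(paths["edges"], sep="\t", index=False)
    return paths
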