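"""Assembly and export of the genotype-transcript-phenotype network.

Association records from the four mapping layers become a directed typed
graph: SNP and transcript nodes point at the transcripts or the single
phenotype node they are associated with.  An epistatic pair is rendered
as a "Y": an explicit junction node with two incoming edges from the
interacting loci and one outgoing edge to the target (standard graph
formats have no hyperedges).  Edges carry the layer, the effect estimate,
a sign class, a sex pattern (the four colour classes of the study's
network figure: same-sign positive/negative, female-positive with
male-negative, and the reverse), a significance tier, and a drawing width
proportional to |effect|.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import networkx as nx

from .io_formats import LAYERS
from .mapping_layers import AssociationRecord

logger = logging.getLogger(__name__)

NODE_TYPES = ("snp", "transcript", "phenotype", "epistasis_junction")
SEX_PATTERNS = (
    "both_same_sign_positive",
    "both_same_sign_negative",
    "female_pos_male_neg",
    "male_pos_female_neg",
)

#: Edge widths are |effect| rescaled into this range.
WIDTH_RANGE = (0.5, 5.0)

_SOURCE_TYPE = {"QTS": "snp", "QTT": "transcript",
                "tQTS": "snp", "tQTT": "transcript"}


@dataclass
class GeneticNetwork:
    """A typed, directed association network for one trait."""

    graph: nx.DiGraph
    trait: str

    def nodes_of_type(self, node_type: str) -> list:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["type"] == node_type
        )

    def validate(self) -> None:
        pheno = self.nodes_of_type("phenotype")
        if pheno != [self.trait]:
            raise ValueError(f"expected exactly one phenotype node, found {pheno}")
        for n in self.nodes_of_type("epistasis_junction"):
            if self.graph.in_degree(n) != 2 or self.graph.out_degree(n) != 1:
                raise ValueError(
                    f"junction {n} must have in-degree 2 and out-degree 1"
                )
        for u, v in self.graph.edges():
            for n in (u, v):
                if n not in self.graph:
                    raise ValueError(f"edge endpoint {n} missing")


def sex_pattern(effect_female: float, effect_male: float) -> str:
    """Classify an edge by the signs of its per-sex effects.

    A zero per-sex effect inherits the other sex's sign (a pure main
    effect is same-sign by definition).
    """
    f, m = effect_female, effect_male
    if f == 0.0:
        f = m
    if m == 0.0:
        m = f
    if f >= 0 and m >= 0:
        return "both_same_sign_positive"
    if f <= 0 and m <= 0:
        return "both_same_sign_negative"
    if f > 0 > m:
        return "female_pos_male_neg"
    return "male_pos_female_neg"


def build_network(records, trait: str) -> GeneticNetwork:
    """Assemble the network from association records.

    One node per distinct SNP/transcript/trait, one junction node per
    epistatic record, no duplicate (source, target, layer) edges;
    conflicting duplicates (same key, different attributes) raise.  Node
    insertion order is deterministic (type, then id), so exports are
    byte-stable regardless of record order.
    """
    records = sorted(
        records, key=lambda r: (LAYERS.index(r.layer), r.source, r.target)
    )
    seen: dict = {}
    for rec in records:
        key = (rec.source, rec.target, rec.layer)
        if key in seen:
            if seen[key].as_row() != rec.as_row():
                raise ValueError(
                    f"conflicting duplicate records for {key}: "
                    f"{seen[key].as_row()} vs {rec.as_row()}"
                )
            continue
        seen[key] = rec
    records = list(seen.values())

    nodes: dict = {trait: "phenotype"}
    for rec in records:
        for src in rec.source:
            nodes[src] = _SOURCE_TYPE[rec.layer]
        if rec.layer in ("tQTS", "tQTT"):
            nodes.setdefault(rec.target, "transcript")

    abs_effects = [abs(r.effect) for r in records]
    max_abs = max(abs_effects) if abs_effects else 1.0
    lo, hi = WIDTH_RANGE

    def width(effect: float) -> float:
        if max_abs == 0:
            return lo
        return lo + (hi - lo) * abs(effect) / max_abs

    g = nx.DiGraph()
    order = {t: i for i, t in enumerate(NODE_TYPES)}
    for node, ntype in sorted(nodes.items(), key=lambda kv: (order[kv[1]], kv[0])):
        g.add_node(node, type=ntype, label=str(node))

    def edge_attrs(rec: AssociationRecord) -> dict:
        return {
            "layer": rec.layer,
            "effect": float(rec.effect),
            "sign_class": "positive" if rec.effect >= 0 else "negative",
            "sex_pattern": sex_pattern(rec.effect_female, rec.effect_male),
            "tier": rec.tier,
            "width": float(width(rec.effect)),
        }

    for rec in records:
        attrs = edge_attrs(rec)
        if rec.is_epistatic:
            junction = f"epi:{rec.source[0]}|{rec.source[1]}->{rec.target}"
            g.add_node(junction, type="epistasis_junction", label=junction)
            g.add_edge(rec.source[0], junction, **attrs)
            g.add_edge(rec.source[1], junction, **attrs)
            g.add_edge(junction, rec.target, **attrs)
        else:
            if g.has_edge(rec.source[0], rec.target):
                raise ValueError(
                    f"duplicate edge {rec.source[0]} -> {rec.target} "
                    f"({rec.layer})"
                )
            g.add_edge(rec.source[0], rec.target, **attrs)

    net = GeneticNetwork(g, trait)
    net.validate()
    return net


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_network(net: GeneticNetwork, path, format: str = "graphml") -> None:
    """Write the network to GraphML (all attributes), SIF (topology with
    the layer as interaction type), or JSON node-link (lossless)."""
    if format == "graphml":
        nx.write_graphml(net.graph, path, named_key_ids=True)
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v, d in sorted(net.graph.edges(data=True)):
                fh.write(f"{u}\t{d['layer']}\t{v}\n")
    elif format == "json":
        data = nx.node_link_data(net.graph, edges="edges")
        data["trait"] = net.trait
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)
    else:
        raise ValueError(f"unsupported format {format!r}")


def import_network(path, format: str = "graphml", trait: str | None = None) -> GeneticNetwork:
    """Read a network written by :func:`export_network` (graphml or json)."""
    if format == "graphml":
        g = nx.DiGraph(nx.read_graphml(path))
    elif format == "json":
        with open(path) as fh:
            data = json.load(fh)
        trait = trait or data.get("trait")
        g = nx.node_link_graph(data, directed=True, edges="edges")
    else:
        raise ValueError(f"unsupported import format {format!r}")
    if trait is None:
        pheno = [n for n, d in g.nodes(data=True) if d.get("type") == "phenotype"]
        trait = pheno[0] if pheno else ""
    return GeneticNetwork(g, trait)


def network_summary(net: GeneticNetwork) -> dict:
    """Counts of nodes by type, edges by layer, junctions, direct/indirect.

    Direct edges target the phenotype node; indirect edges target a
    transcript.
    """
    g = net.graph
    by_type = {t: len(net.nodes_of_type(t)) for t in NODE_TYPES}
    by_layer = {layer: 0 for layer in LAYERS}
    direct = indirect = 0
    for _, v, d in g.edges(data=True):
        if g.nodes[v]["type"] == "epistasis_junction":
            continue   # count the junction's outgoing edge instead
        by_layer[d["layer"]] += 1
        if g.nodes[v]["type"] == "phenotype":
            direct += 1
        elif g.nodes[v]["type"] == "transcript":
            indirect += 1
    return {
        "nodes_by_type": by_type,
        "edges_by_layer": by_layer,
        "n_junctions": by_type["epistasis_junction"],
        "direct_edges": direct,
        "indirect_edges": indirect,
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
    }
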