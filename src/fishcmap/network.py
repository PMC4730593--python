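"""Chemical mode-of-action networks from significant connections.

Significant, non-self connections are aggregated into an undirected network
whose nodes are treatment conditions at a chosen granularity (chemical,
chemical+tissue, or chemical+dose+tissue) and whose edges carry the maximum
connectivity score observed between the two conditions in either query
direction.  Sub-networks of strongly connected conditions are obtained by
keeping nodes with at least one edge above a score threshold; a node's
neighbor count measures its connectivity within the network.

The informative-connection evaluation asks, for each query signature,
whether any of its top-k significant hits involves a chemical of the same
(or declared-similar) MOA class — with self hits counting as the same
chemical — and summarizes the success rate as "informative/total (x %)".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx

from .iodata import MOATable, ValidationError
from .connectivity import ConnectionResult

GRANULARITIES = {
    "chemical": ("chemical",),
    "chemical+tissue": ("chemical", "tissue"),
    "chemical+dose+tissue": ("chemical", "dose", "tissue"),
}


@dataclass
class ChemicalNetwork:
    """Weighted undirected graph over condition labels."""

    graph: nx.Graph
    granularity: str = "chemical"

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class InformativeSummary:
    """Informative-connection counts for a batch of query signatures."""

    n_informative: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_informative / self.n_total if self.n_total else 0.0

    def formatted(self) -> str:
        pct = int(100.0 * self.fraction + 0.5) if self.n_total else 0
        return f"{self.n_informative}/{self.n_total} ({pct} %)"


def _label(fields: Mapping[str, str], granularity: str) -> str:
    keys = GRANULARITIES[granularity]
    parts = [str(fields.get(k, "") or "") for k in keys]
    return "_".join(p for p in parts if p)


def _endpoint_labels(result: ConnectionResult, granularity: str) -> tuple[str, str]:
    meta = result.signature_meta
    sig_fields = (
        {
            "chemical": getattr(meta, "chemical", ""),
            "dose": getattr(meta, "dose", ""),
            "tissue": getattr(meta, "tissue", ""),
        }
        if meta is not None
        else {}
    )
    return _label(sig_fields, granularity), _label(result.set_condition, granularity)


def build_network(
    results: Sequence[ConnectionResult], granularity: str = "chemical"
) -> ChemicalNetwork:
    """Keep, per unordered condition pair, the single highest-scored connection.

    Only significant connections enter; connections whose signature and ROGL
    set share an experiment of origin are excluded regardless of score, and
    pairs collapsing to the same node label are skipped.  The construction is
    order-independent in the input results.
    """
    if granularity not in GRANULARITIES:
        raise ValidationError(
            f"unknown granularity {granularity!r}; allowed: {sorted(GRANULARITIES)}"
        )
    graph = nx.Graph()
    for r in sorted(results, key=lambda r: (r.signature, r.set_id)):
        if not r.significant or r.self:
            continue
        a, b = _endpoint_labels(r, granularity)
        if not a or not b or a == b:
            continue
        a, b = sorted((a, b))
        prev = graph.get_edge_data(a, b)
        if prev is None or r.score > prev["weight"]:
            graph.add_edge(
                a, b, weight=float(r.score), p_value=float(r.p_value),
                signature=r.signature, set_id=r.set_id,
            )
    return ChemicalNetwork(graph=graph, granularity=granularity)


def filter_subnetwork(net: ChemicalNetwork, min_score: float = 10.0) -> ChemicalNetwork:
    """Keep nodes having >= 1 incident edge with weight >= min_score.

    All surviving edges among kept nodes are retained, including those below
    the threshold.
    """
    keep = {
        n
        for n in net.graph.nodes
        if any(d["weight"] >= min_score for _, _, d in net.graph.edges(n, data=True))
    }
    sub = net.graph.subgraph(keep).copy()
    return ChemicalNetwork(graph=sub, granularity=net.granularity)


def node_degrees(net: ChemicalNetwork) -> dict[str, int]:
    """Neighbor count per node, in deterministic (sorted) node order."""
    return {n: int(d) for n, d in sorted(net.graph.degree())}


def evaluate_informative(
    results_by_signature: Mapping[str, Sequence[ConnectionResult]],
    moa: MOATable,
    k: int = 5,
) -> tuple[InformativeSummary, dict[str, bool]]:
    """Fraction of query signatures with an informative top-k hit.

    A query is informative when at least one of its top-k ranked significant
    hits is a self hit (same experiment, hence the same chemical) or involves
    a chemical sharing an MOA class with the signature's chemical.  Chemicals
    absent from the MOA table never match, so such hits are uninformative.
    """
    if k < 1:
        raise ValidationError(f"require k >= 1; got {k}")
    verdicts: dict[str, bool] = {}
    for name in sorted(results_by_signature):
        results = sorted(results_by_signature[name], key=lambda r: r.rank)
        hits = [r for r in results if r.significant][:k]
        informative = False
        for r in hits:
            if r.self:
                informative = True
                break
            sig_chem = getattr(r.signature_meta, "chemical", "") if r.signature_meta else ""
            hit_chem = r.set_condition.get("chemical", "")
            if sig_chem and hit_chem and (
                sig_chem == hit_chem or moa.share_class(sig_chem, hit_chem)
            ):
                informative = True
                break
        verdicts[name] = informative
    summary = InformativeSummary(
        n_informative=sum(verdicts.values()), n_total=len(verdicts)
    )
    return summary, verdicts
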