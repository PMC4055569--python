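"""Directed signed interaction networks and their comparison to references.

The filtered predications are assembled into a directed graph whose nodes are
official gene symbols and whose edges carry a sign (+1 stimulatory, -1
inhibitory, 0 unsigned/conflicting), the predicates asserting them, the
supporting PMIDs, and — after effect quantification — a trained weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import networkx as nx
import pandas as pd

from .predications import UniquePredication, ValidationError

_SIGN_WORDS = {1: "stimulates", -1: "inhibits", 0: "interacts"}
_WORD_SIGNS = {w: s for s, w in _SIGN_WORDS.items()}


def sign_from_predicates(predicates: Iterable[str]) -> int:
    """Sign of an interaction given the predicates asserting it.

    +1 iff STIMULATES present without INHIBITS, -1 iff INHIBITS without
    STIMULATES, 0 otherwise (pure INTERACTS_WITH or conflicting evidence).
    """
    ps = set(predicates)
    stim, inhib = "STIMULATES" in ps, "INHIBITS" in ps
    if stim and not inhib:
        return 1
    if inhib and not stim:
        return -1
    return 0


@dataclass
class Interaction:
    """A directed gene-gene interaction, possibly backed by many predications."""

    source: str
    target: str
    sign: int
    predicates: frozenset[str] = frozenset()
    pmids: frozenset[str] = frozenset()
    weight: float | None = None

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValidationError("interaction endpoints must be non-empty")
        if self.predicates and self.sign != sign_from_predicates(self.predicates):
            raise ValidationError("sign inconsistent with predicate set")


@dataclass
class InteractionNetwork:
    """A directed signed gene interaction graph (self-loops permitted)."""

    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], Interaction] = field(default_factory=dict)

    def add(self, inter: Interaction) -> None:
        key = (inter.source, inter.target)
        if key in self.edges:
            raise ValidationError(f"duplicate edge {key}")
        self.edges[key] = inter
        self.nodes.update(key)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for (s, t), e in self.edges.items():
            g.add_edge(s, t, sign=e.sign, predicates=set(e.predicates),
                       pmids=set(e.pmids), weight=e.weight)
        return g

    def write_tsv(self, path: Union[str, Path]) -> None:
        """Lossless TSV edge list (sorted by source, target)."""
        rows = []
        for (s, t) in sorted(self.edges):
            e = self.edges[(s, t)]
            rows.append({
                "source": s, "target": t, "sign": e.sign,
                "predicates": ",".join(sorted(e.predicates)),
                "n_pmids": len(e.pmids),
                "pmids": ",".join(sorted(e.pmids)),
                "weight": "" if e.weight is None else repr(e.weight),
            })
        cols = ["source", "target", "sign", "predicates",
                "n_pmids", "pmids", "weight"]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, source: Union[str, Path]) -> "InteractionNetwork":
        df = pd.read_csv(source, sep="\t", comment="#", dtype=str,
                         keep_default_na=False)
        net = cls()
        for row in df.itertuples(index=False):
            predicates = frozenset(
                p for p in str(getattr(row, "predicates", "")).split(",") if p)
            pmids = frozenset(
                p for p in str(getattr(row, "pmids", "")).split(",") if p)
            wtxt = str(getattr(row, "weight", ""))
            net.add(Interaction(
                source=row.source, target=row.target, sign=int(row.sign),
                predicates=predicates, pmids=pmids,
                weight=float(wtxt) if wtxt else None))
        return net

    def write_sif(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for (s, t) in sorted(self.edges):
                fh.write(f"{s}\t{_SIGN_WORDS[self.edges[(s, t)].sign]}\t{t}\n")


def build_network(upreds: Sequence[UniquePredication]) -> InteractionNetwork:
    """Assemble unique predications into a directed signed network.

    Predications sharing an ordered (subject, object) pair merge into a single
    edge with pooled predicates and PMIDs; the sign follows
    :func:`sign_from_predicates`. Output is independent of input order.
    """
    acc: dict[tuple[str, str], dict[str, set]] = {}
    for u in upreds:
        key = (u.subject_symbol, u.object_symbol)
        rec = acc.setdefault(key, {"predicates": set(), "pmids": set()})
        rec["predicates"].add(u.predicate)
        rec["pmids"].update(u.pmids)
    net = InteractionNetwork()
    for (s, t) in sorted(acc):
        rec = acc[(s, t)]
        net.add(Interaction(
            source=s, target=t,
            sign=sign_from_predicates(rec["predicates"]),
            predicates=frozenset(rec["predicates"]),
            pmids=frozenset(rec["pmids"])))
    return net


def restrict_to_genes(net: InteractionNetwork,
                      gene_list: Iterable[str]) -> InteractionNetwork:
    """Subnetwork over the given genes (edges need both endpoints kept)."""
    keep = set(gene_list)
    out = InteractionNetwork(nodes=net.nodes & keep)
    for (s, t), e in net.edges.items():
        if s in keep and t in keep:
            out.edges[(s, t)] = e
    return out


@dataclass
class NetworkComparison:
    """Node/edge overlap counts between an inferred network and a reference."""

    pred_nodes: int
    pred_edges: int
    ref_nodes: int
    ref_edges: int
    common_nodes: int
    common_edges: int
    new_nodes: int
    new_edges: int

    def __post_init__(self) -> None:
        if self.common_nodes + self.new_nodes != self.pred_nodes:
            raise ValidationError("node counts not additive")
        if self.common_edges + self.new_edges != self.pred_edges:
            raise ValidationError("edge counts not additive")


def compare_networks(pred: InteractionNetwork, ref: InteractionNetwork,
                     directed: bool = True) -> NetworkComparison:
    """Count nodes/edges of ``pred`` found in (common) or absent from (new) ``ref``.

    With ``directed=False`` a predicted edge counts as common if the reference
    contains it in either orientation.
    """
    common_nodes = len(pred.nodes & ref.nodes)
    ref_keys = set(ref.edges)
    if not directed:
        ref_keys |= {(t, s) for (s, t) in ref.edges}
    common_edges = sum(1 for k in pred.edges if k in ref_keys)
    return NetworkComparison(
        pred_nodes=pred.n_nodes, pred_edges=pred.n_edges,
        ref_nodes=ref.n_nodes, ref_edges=ref.n_edges,
        common_nodes=common_nodes, common_edges=common_edges,
        new_nodes=pred.n_nodes - common_nodes,
        new_edges=pred.n_edges - common_edges)


@dataclass
class PrecisionResult:
    """Gene/edge precision of a weighted network against a reference."""

    threshold: float
    pred_genes: int
    pred_edges: int
    found_genes: int
    found_edges: int
    gene_precision: float | None
    edge_precision: float | None


def interaction_precision(pred_weighted: InteractionNetwork,
                          ref: InteractionNetwork,
                          weight_threshold: float = 0.0,
                          directed: bool = True) -> PrecisionResult:
    """Precision (found/predicted) of trained edges above a weight threshold.

    Threshold 0 keeps every trained edge regardless of weight; a positive
    threshold keeps edges with ``|weight| > threshold``. Gene counts always
    refer to the whole weighted network. Precision over an empty predicted
    set is undefined and reported as None.
    """
    if weight_threshold < 0:
        raise ValidationError("weight_threshold must be >= 0")
    if weight_threshold == 0:
        kept = list(pred_weighted.edges)
    else:
        kept = [k for k, e in pred_weighted.edges.items()
                if e.weight is not None and abs(e.weight) > weight_threshold]
    ref_keys = set(ref.edges)
    if not directed:
        ref_keys |= {(t, s) for (s, t) in ref.edges}
    found_edges = sum(1 for k in kept if k in ref_keys)
    genes = pred_weighted.nodes
    found_genes = len(genes & ref.nodes)
    return PrecisionResult(
        threshold=weight_threshold,
        pred_genes=len(genes), pred_edges=len(kept),
        found_genes=found_genes, found_edges=found_edges,
        gene_precision=found_genes / len(genes) if genes else None,
        edge_precision=found_edges / len(kept) if kept else None)


def validation_percentages(counts: dict[str, int],
                           total: int) -> dict[str, float]:
    """Percent of ``total`` for each labelled count, to one decimal place."""
    if total <= 0:
        raise ValidationError("total must be positive")
    for label, c in counts.items():
        if c > total:
            raise ValidationError(f"count {label}={c} exceeds total {total}")
    return {label: round(100.0 * c / total, 1) for label, c in counts.items()}


def read_reference_network(source: Union[str, Path]) -> InteractionNetwork:
    """Read a plain reference edge list: TSV ``source target [sign]``."""
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValidationError("reference network needs source/target columns")
    net = InteractionNetwork()
    for row in df.itertuples(index=False):
        if (row[0], row[1]) in net.edges:  # tolerate duplicate assertions
            continue
        sign = int(row[2]) if len(cols) >= 3 and str(row[2]).strip() else 0
        net.add(Interaction(source=row[0], target=row[1], sign=sign))
    return net
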