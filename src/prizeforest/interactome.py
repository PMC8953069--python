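"""Weighted gene interactomes derived from STRING-like interaction tables.

Edges carry a confidence score in (0, 1] and a cost = -log10(confidence), so
high-confidence interactions are cheap to traverse.  Protein identifiers are
mapped to gene symbols before filtering; edges below the confidence floor
(0.7 in the study, the STRING "high confidence" cutoff) are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import InputError, ParseError

__all__ = ["Interactome", "load_interactome", "build_prizes"]


@dataclass
class Interactome:
    """Undirected gene graph; every edge has `confidence` and `cost` attributes."""

    graph: nx.Graph
    unmapped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        g = self.graph
        if any(u == v for u, v in g.edges()):
            raise InputError("interactome must not contain self-loops")
        for u, v, d in g.edges(data=True):
            conf = d.get("confidence")
            if conf is None or not (0 < conf <= 1):
                raise InputError(f"edge ({u},{v}): confidence must be in (0,1]")
            d.setdefault("cost", -math.log10(conf))
            if abs(d["cost"] - (-math.log10(conf))) > 1e-12:
                raise InputError(f"edge ({u},{v}): cost != -log10(confidence)")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node) -> int:
        return self.graph.degree[node]

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"node_a": min(u, v), "node_b": max(u, v), "confidence": d["confidence"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return (
            pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"])
            .sort_values(["node_a", "node_b"])
            .reset_index(drop=True)
        )

    def to_tsv(self, path) -> None:
        self.edge_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, min_conf: float = 0.0) -> "Interactome":
        return load_interactome(path, min_conf=min_conf)


def _read_edge_table(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", comment="#")
    cols = list(df.columns)
    if len(cols) < 3:
        raise ParseError("edge table needs three columns: node_a, node_b, confidence")
    df = df.rename(
        columns={cols[0]: "node_a", cols[1]: "node_b", cols[2]: "confidence"}
    )
    return df


def load_interactome(
    edge_table,
    mapping_table=None,
    min_conf: float = 0.7,
    collision: str = "max",
) -> Interactome:
    """Load, map, filter and deduplicate a STRING-like interaction table.

    ``edge_table`` is a path or DataFrame with columns (protein_a, protein_b,
    confidence).  Confidences on the STRING 0-1000 integer scale are detected
    (max > 1) and rescaled to 0-1.  ``mapping_table`` (path or DataFrame with
    columns protein_id, gene_symbol) converts protein nodes to gene nodes;
    unmapped proteins are dropped and reported on the returned object.
    Duplicate gene pairs after mapping are collapsed keeping the max (or,
    with ``collision='mean'``, the mean) confidence; self-loops produced by
    the mapping are discarded.  Edges below ``min_conf`` are removed.
    """
    df = _read_edge_table(edge_table)
    conf = pd.to_numeric(df["confidence"], errors="coerce")
    if conf.isna().any():
        line = int(conf.index[conf.isna()][0]) + 2  # 1-based incl. header
        raise ParseError(f"line {line}: confidence is not numeric")
    if conf.max() > 1:
        conf = conf / 1000.0
    bad = (conf <= 0) | (conf > 1)
    if bad.any():
        line = int(conf.index[bad][0]) + 2
        raise ParseError(f"line {line}: confidence outside (0, 1]")
    df["confidence"] = conf

    unmapped: list[str] = []
    if mapping_table is not None:
        if not isinstance(mapping_table, pd.DataFrame):
            mapping_table = pd.read_csv(mapping_table, sep="\t", comment="#")
        mcols = list(mapping_table.columns)
        mapping = dict(
            zip(mapping_table[mcols[0]].astype(str), mapping_table[mcols[1]].astype(str))
        )
        known = df["node_a"].astype(str).isin(mapping) & df["node_b"].astype(str).isin(
            mapping
        )
        unmapped = sorted(
            set(df.loc[~df["node_a"].astype(str).isin(mapping), "node_a"].astype(str))
            | set(df.loc[~df["node_b"].astype(str).isin(mapping), "node_b"].astype(str))
        )
        df = df[known].copy()
        df["node_a"] = df["node_a"].astype(str).map(mapping)
        df["node_b"] = df["node_b"].astype(str).map(mapping)

    df = df[df["node_a"] != df["node_b"]].copy()
    key = df.apply(lambda r: tuple(sorted((str(r["node_a"]), str(r["node_b"])))), axis=1)
    df["_a"] = [k[0] for k in key]
    df["_b"] = [k[1] for k in key]
    agg = "max" if collision == "max" else "mean"
    collapsed = df.groupby(["_a", "_b"], as_index=False)["confidence"].agg(agg)
    collapsed = collapsed[collapsed["confidence"] >= min_conf]

    g = nx.Graph()
    for _, row in collapsed.iterrows():
        c = float(row["confidence"])
        g.add_edge(row["_a"], row["_b"], confidence=c, cost=-math.log10(c))
    return Interactome(g, unmapped=unmapped)


def build_prizes(deg_table: pd.DataFrame, mode: str = "abslogfc") -> pd.Series:
    """Node prizes from a DEG table: |logFC| for called genes, 0 otherwise.

    ``mode='constant'`` assigns prize 1 to every called gene instead.
    Genes with call 'ns' receive no prize (and are omitted).
    """
    called = deg_table[deg_table["call"] != "ns"]
    if mode == "abslogfc":
        prizes = called.set_index("gene_id")["logFC"].abs()
    elif mode == "constant":
        prizes = pd.Series(1.0, index=called["gene_id"])
    else:
        raise InputError(f"unknown prize mode: {mode}")
    prizes.name = "prize"
    return prizes.astype(float)
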