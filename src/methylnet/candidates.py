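"""Topology-based candidate gene ranking and panel assembly.

Hub genes are nominated per network by sorting nodes on degree (descending),
breaking ties by betweenness, then closeness, then node id — a deterministic
total order — and truncating to the top k (default 10).  The validation panel
is the union of selected network candidates and a user-supplied supplementary
list (genes implicated by earlier studies), with provenance tags preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CandidateList",
    "rank_candidates",
    "merge_candidates",
    "DEFAULT_SUPPLEMENTARY",
    "DEFAULT_PANEL",
    "gene_symbol",
]

#: Supplementary candidates from prior evidence, outside the network ranking.
DEFAULT_SUPPLEMENTARY: tuple[str, ...] = ("CDK5", "DRD4", "IL17RE")

#: Curated default validation panel: six network hubs plus the three
#: supplementary genes.
DEFAULT_PANEL: tuple[str, ...] = (
    "ANGEL1", "BECN1", "BOLL", "CD14", "LYAR", "MBP", "CDK5", "DRD4", "IL17RE",
)


@dataclass
class CandidateList:
    """Ranked hub candidates for one gene class ("LMG" or "HMG")."""

    network_class: str
    ranked: pd.DataFrame  # node_id, degree, betweenness, closeness, rank


def gene_symbol(node_id: str) -> str:
    """Gene part of a ``gene@chrom:start`` node id (the id itself if bare)."""
    return node_id.split("@", 1)[0]


def rank_candidates(metrics: pd.DataFrame, k: int = 10, network_class: str = "") -> CandidateList:
    """Top-k nodes by degree, ties broken by betweenness, closeness, node id.

    The sort key is a total order, so the result is deterministic and
    independent of the input row order.
    """
    if metrics.empty:
        raise ValueError("metrics table is empty")
    if k < 1:
        raise ValueError("k must be at least 1")
    cols = ["node_id", "degree", "betweenness", "closeness"]
    df = metrics[cols].copy()
    df = df.sort_values(
        by=["degree", "betweenness", "closeness", "node_id"],
        ascending=[False, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df = df.head(k)
    df["rank"] = range(1, len(df) + 1)
    return CandidateList(network_class=network_class, ranked=df)


def merge_candidates(
    lmg: CandidateList,
    hmg: CandidateList,
    supplementary: Iterable[str] = DEFAULT_SUPPLEMENTARY,
    selected: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble the validation gene panel with provenance tags.

    Network candidates contribute their gene symbols tagged ``network-LMG`` /
    ``network-HMG``; supplementary genes are tagged ``supplementary``.  A gene
    appearing in several sources keeps every tag (comma-joined).  If
    ``selected`` is given, network candidates are filtered to those symbols
    (the literature-screening step is user input, not computation).
    """
    tags: dict[str, list[str]] = {}

    def add(gene: str, tag: str) -> None:
        tags.setdefault(gene, [])
        if tag not in tags[gene]:
            tags[gene].append(tag)

    for clist, tag in ((lmg, "network-LMG"), (hmg, "network-HMG")):
        for node_id in clist.ranked["node_id"]:
            sym = gene_symbol(node_id)
            if selected is None or sym in selected:
                add(sym, tag)
    for gene in supplementary:
        add(gene, "supplementary")
    return pd.DataFrame(
        {"gene": list(tags), "provenance": [",".join(v) for v in tags.values()]}
    )
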