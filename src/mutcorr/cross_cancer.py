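"""Cross-cancer aggregation of per-cancer top-K gene lists.

Counts, for every gene, in how many cancer types it reaches the top-K
positive (and negative) correlation list, then partitions genes into
positive-only / negative-only / positive-negative / unclassified. "Showing
positive correlation in a cancer type" means membership in that type's
top-K positive list, not merely a positive rho.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .correlation import TopKLists

LABELS = ("positive_only", "negative_only", "positive_negative", "unclassified")


def recurrence(all_lists: Sequence[TopKLists]) -> pd.DataFrame:
    """Per-gene recurrence counts across cancer types.

    Returns a DataFrame indexed by gene with ``n_cancers_positive`` and
    ``n_cancers_negative``: the number of cancers whose top-K positive
    (negative) list contains the gene. Order of cancer types is irrelevant.
    """
    if not all_lists:
        raise ValueError("need at least one cancer type")
    counts: dict[str, list[int]] = {}
    for lists in all_lists:
        for g in set(lists.positive_genes):
            counts.setdefault(g, [0, 0])[0] += 1
        for g in set(lists.negative_genes):
            counts.setdefault(g, [0, 0])[1] += 1
    df = pd.DataFrame.from_dict(counts, orient="index",
                                columns=["n_cancers_positive", "n_cancers_negative"])
    df.index.name = "gene"
    return df.sort_index()


def recurrent_genes(table: pd.DataFrame,
                    direction: Literal["positive", "negative"],
                    min_cancers: int) -> list[str]:
    """Genes in the top-K list of at least ``min_cancers`` cancer types for
    one direction, sorted by count descending then symbol."""
    if min_cancers < 1:
        raise ValueError("min_cancers must be >= 1")
    col = f"n_cancers_{direction}"
    if col not in table.columns:
        raise ValueError(f"direction must be 'positive' or 'negative', got {direction!r}")
    hits = table[table[col] >= min_cancers]
    return sorted(hits.index, key=lambda g: (-int(hits.at[g, col]), g))


def classify_genes(gene_set: Iterable[str], table: pd.DataFrame) -> pd.DataFrame:
    """Tripartite cross-cancer classification of a gene set.

    positive_only: in >= 1 positive list, never negative; negative_only: the
    mirror; positive_negative: positive in at least one cancer type and
    negative in at least one; unclassified: in no list at all. The labels
    partition the gene set.
    """
    genes = list(dict.fromkeys(gene_set))
    if not genes:
        raise ValueError("gene_set is empty")
    rows = []
    for g in genes:
        n_pos = int(table.at[g, "n_cancers_positive"]) if g in table.index else 0
        n_neg = int(table.at[g, "n_cancers_negative"]) if g in table.index else 0
        if n_pos >= 1 and n_neg == 0:
            label = "positive_only"
        elif n_neg >= 1 and n_pos == 0:
            label = "negative_only"
        elif n_pos >= 1 and n_neg >= 1:
            label = "positive_negative"
        else:
            label = "unclassified"
        rows.append((g, label, n_pos, n_neg))
    out = pd.DataFrame(rows, columns=["gene", "label", "n_pos", "n_neg"])
    return out.set_index("gene")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")
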