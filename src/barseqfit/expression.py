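"""Threshold-based classification of differential-expression tables.

Consumes (gene, contrast, timepoint, log2FC, padj) tables produced by any
DE tool (the count model itself is out of scope here): genes with
padj < 1% (Benjamini-Hochberg) and |log2FC| >= 1 are called up- or
down-regulated per timepoint, pooled by union over timepoints, compared
between pairwise and community contexts, and screened for amplified
responses. Enrichment of gene sets in user-supplied categories uses the
exact hypergeometric upper tail with BH correction.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .interactions import CrossClassification


def de_sets(
    records: pd.DataFrame,
    alpha: float = 0.01,
    lfc_threshold: float = 1.0,
    strict_gt: bool = False,
) -> dict[str, dict[str, frozenset[str]]]:
    """Up/down-regulated gene sets per contrast, pooled over timepoints.

    Per timepoint a gene is *up* iff ``padj < alpha`` and ``log2FC >=
    lfc_threshold`` (strictly greater with ``strict_gt``), *down*
    symmetrically; the per-contrast set is the union over timepoints.
    Records with missing padj are skipped with a warning. Returns
    ``{contrast: {"up": set, "down": set}}``.
    """
    contrasts = list(dict.fromkeys(records["contrast"]))
    missing = records["padj"].isna()
    if missing.any():
        warnings.warn(f"skipping {int(missing.sum())} records with missing padj", stacklevel=2)
        records = records[~missing]
    sig = records["padj"] < alpha
    if strict_gt:
        up = sig & (records["log2FC"] > lfc_threshold)
        down = sig & (records["log2FC"] < -lfc_threshold)
    else:
        up = sig & (records["log2FC"] >= lfc_threshold)
        down = sig & (records["log2FC"] <= -lfc_threshold)
    out: dict[str, dict[str, frozenset[str]]] = {
        c: {"up": frozenset(), "down": frozenset()} for c in contrasts
    }
    for contrast, grp in records.groupby("contrast", sort=False):
        out[contrast] = {
            "up": frozenset(grp.loc[up.reindex(grp.index, fill_value=False), "locus_tag"]),
            "down": frozenset(grp.loc[down.reindex(grp.index, fill_value=False), "locus_tag"]),
        }
    return out


def compare_de_sets(
    pairwise_sets: Mapping[str, Iterable[str]] | Iterable[Iterable[str]],
    community_set: Iterable[str],
) -> CrossClassification:
    """Compare the pairwise union with the community set (one direction).

    ``conserved`` genes respond in both contexts, ``pairwise_specific``
    only with a single partner, ``community_specific`` only with the full
    community.
    """
    if isinstance(pairwise_sets, Mapping):
        pairwise_sets = list(pairwise_sets.values())
    sets = [frozenset(s) for s in pairwise_sets]
    if not sets:
        raise ValueError("need at least one pairwise set")
    union = frozenset().union(*sets)
    community = frozenset(community_set)
    return CrossClassification(
        conserved=union & community,
        pairwise_specific=union - community,
        community_specific=community - union,
    )


def amplified_genes(
    conserved: Iterable[str],
    community_vs_pairwise: pd.DataFrame,
    alpha: float = 0.01,
    lfc_threshold: float = 1.0,
) -> frozenset[str]:
    """Conserved responders that are significantly stronger in the community.

    ``community_vs_pairwise`` is a DE table of the community-versus-
    pairwise contrast; a conserved gene is amplified iff it meets
    ``padj < alpha`` and ``log2FC >= lfc_threshold`` there (at any listed
    timepoint). Conserved genes missing from the table are excluded with
    a warning.
    """
    conserved = frozenset(conserved)
    table = community_vs_pairwise[community_vs_pairwise["locus_tag"].isin(conserved)]
    absent = conserved - set(table["locus_tag"])
    if absent:
        warnings.warn(
            f"{len(absent)} conserved genes missing from the contrast table", stacklevel=2
        )
    hit = (table["padj"] < alpha) & (table["log2FC"] >= lfc_threshold)
    return frozenset(table.loc[hit, "locus_tag"])


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (ties broken by stable input order)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def hypergeometric_enrichment(
    query: Iterable[str],
    universe: Iterable[str],
    category_map: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of a gene set in functional categories.

    ``category_map`` maps each gene to its categories (e.g. pathways).
    For each category with K genes in the universe of M, an overlap of k
    with the n-gene query has upper-tail probability
    ``p = sum_{i>=k} C(K,i) C(M-K,n-i) / C(M,n)``; p-values are BH
    corrected across categories and a category is enriched iff
    ``padj < alpha``. Empty categories are skipped.
    """
    query = frozenset(query)
    universe = frozenset(universe)
    if not query:
        raise ValueError("empty query set")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    members: dict[str, set[str]] = {}
    for gene, cats in category_map.items():
        if gene not in universe:
            raise ValueError(f"category map gene {gene!r} not in universe")
        for cat in [cats] if isinstance(cats, str) else cats:
            members.setdefault(cat, set()).add(gene)
    M, n = len(universe), len(query)
    rows = []
    for cat in sorted(members):
        K = len(members[cat])
        if K == 0:
            continue
        k = len(members[cat] & query)
        # upper tail P(X >= k); sf(k-1) by the survival-function convention
        p = float(hypergeom.sf(k - 1, M, K, n))
        rows.append({"category": cat, "overlap": k, "set_size": n, "category_size": K,
                     "universe_size": M, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    if len(table):
        table["padj"] = benjamini_hochberg(table["p"])
        table["enriched"] = table["padj"] < alpha
    else:
        table["padj"] = []
        table["enriched"] = []
    return table
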