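"""Set-based classification of genetic requirements across growth contexts.

Starting from per-condition sets of genes with a significant negative
fitness (|t| >= threshold and fitness < 0, pooled over timepoints by
union), the comparisons are:

- growth alone A vs interactive contexts S1..Sk: *conserved* genes stay
  required, *induced* genes become required only with partners,
  *alleviated* genes are relieved by partners;
- per-partner breakdown of the induced/alleviated families;
- pairwise vs community cross-classification (conserved interactions vs
  pairwise-specific vs community-specific pieces);
- the core set required in every condition;
- a higher-order summary: the fraction of community interactions already
  explained by pairwise interactions vs those emerging only at full
  community complexity.

Every operation is a pure function of its input sets.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class SignificantSet:
    """Genes significantly required in one condition (timepoints pooled).

    ``provenance`` maps each gene to the timepoints at which it was
    significant (a gene enters the set if significant at >= 1 timepoint).
    """

    condition: str
    genes: frozenset[str]
    provenance: Mapping[str, frozenset[str]] = field(default_factory=dict)


@dataclass(frozen=True)
class CrossClassification:
    """Partition of an interaction family across pairwise vs community."""

    conserved: frozenset[str]
    pairwise_specific: frozenset[str]
    community_specific: frozenset[str]


@dataclass(frozen=True)
class HigherOrderSummary:
    """Counts and integer percentages of pairwise-derived vs higher-order
    interactions observed in the community."""

    pairwise_derived: int
    higher_order: int
    fraction_pairwise: int | None
    fraction_higher: int | None


def significant_negative(
    records: pd.DataFrame, t_threshold: float = 3.0
) -> dict[tuple[str, str], frozenset[str]]:
    """Per (condition, timepoint) sets of genes with |t| >= threshold and
    fitness < 0.

    The t-score cutoff (default 3, inclusive) removes unreliable fitness
    values; the sign filter keeps only growth defects.
    """
    hit = (records["t"].abs() >= t_threshold) & (records["fitness"] < 0)
    out: dict[tuple[str, str], frozenset[str]] = {}
    for (cond, tp), grp in records.groupby(["condition", "timepoint"], sort=False):
        out[(cond, tp)] = frozenset(grp.loc[hit.reindex(grp.index), "locus_tag"])
    return out


def pool_timepoints(
    per_timepoint: Mapping[str, Iterable[str]], condition: str
) -> SignificantSet:
    """Union the per-timepoint sets of one condition, keeping provenance."""
    if not per_timepoint:
        raise ValueError("need at least one timepoint")
    provenance: dict[str, set[str]] = {}
    for tp, genes in per_timepoint.items():
        for g in genes:
            provenance.setdefault(g, set()).add(tp)
    return SignificantSet(
        condition=condition,
        genes=frozenset(provenance),
        provenance={g: frozenset(tps) for g, tps in provenance.items()},
    )


def significant_sets(
    records: pd.DataFrame, t_threshold: float = 3.0
) -> dict[str, SignificantSet]:
    """Convenience: significant-negative sets per condition, pooled over
    timepoints."""
    per_ct = significant_negative(records, t_threshold)
    by_condition: dict[str, dict[str, frozenset[str]]] = {}
    for (cond, tp), genes in per_ct.items():
        by_condition.setdefault(cond, {})[tp] = genes
    return {cond: pool_timepoints(tps, cond) for cond, tps in by_condition.items()}


def _genes(s) -> frozenset[str]:
    return s.genes if isinstance(s, SignificantSet) else frozenset(s)


def classify_vs_alone(
    alone, contexts: Sequence, conserved_rule: str = "all"
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """Compare growth alone against one or more interactive contexts.

    Returns ``(conserved, induced, alleviated)``:

    - conserved: required alone and in all contexts (``conserved_rule=
      "all"``, default) or in at least one (``"any"``);
    - induced: required in at least one context but not alone;
    - alleviated: the complement of conserved within the alone set.

    With a single context both rules coincide and the result is the plain
    two-set comparison (A&C, C-A, A-C).
    """
    if conserved_rule not in ("all", "any"):
        raise ValueError("conserved_rule must be 'all' or 'any'")
    A = _genes(alone)
    sets = [_genes(s) for s in contexts]
    if not sets:
        raise ValueError("need at least one context set")
    union = frozenset().union(*sets)
    inter = frozenset(sets[0]).intersection(*sets[1:])
    conserved = A & (inter if conserved_rule == "all" else union)
    return conserved, union - A, A - conserved


def partner_breakdown(
    family: str, alone, partner_sets: Mapping[str, Iterable[str]]
) -> dict[str, frozenset[str]]:
    """Attribute induced/alleviated genes to partners.

    For ``family="alleviated"`` a gene (in the alone set) counts as
    alleviated by partner *i* iff absent from that partner's set; for
    ``family="induced"`` a gene (absent alone) counts as induced by
    partner *i* iff present in that partner's set. Keys of the result:
    ``"all"`` (every partner), ``"specific:<partner>"`` (only that
    partner) and ``"other"`` (any remaining combination).
    """
    if family not in ("induced", "alleviated"):
        raise ValueError("family must be 'induced' or 'alleviated'")
    A = _genes(alone)
    partners = {p: _genes(s) for p, s in partner_sets.items()}
    if family == "alleviated":
        members = {g for g in A if any(g not in s for s in partners.values())}
        hit = {g: {p for p, s in partners.items() if g not in s} for g in members}
    else:
        members = set().union(*partners.values()) - A
        hit = {g: {p for p, s in partners.items() if g in s} for g in members}
    for g, ps in hit.items():
        if not ps:
            raise ValueError(f"gene {g!r} is in the {family} family but matches no partner")
    out: dict[str, set[str]] = {"all": set(), "other": set()}
    for p in partners:
        out[f"specific:{p}"] = set()
    for g, ps in hit.items():
        if len(ps) == len(partners):
            out["all"].add(g)
        elif len(ps) == 1:
            out[f"specific:{next(iter(ps))}"].add(g)
        else:
            out["other"].add(g)
    return {k: frozenset(v) for k, v in out.items()}


def cross_classify(pairwise_family, community_family) -> CrossClassification:
    """Split an interaction family by pairwise vs community context.

    Both inputs must be the same family (induced or alleviated) computed
    against the same alone set; the pieces partition their union.
    """
    P = _genes(pairwise_family)
    C = _genes(community_family)
    return CrossClassification(
        conserved=P & C, pairwise_specific=P - C, community_specific=C - P
    )


def core_set(condition_sets: Sequence) -> frozenset[str]:
    """Genes required in every condition."""
    sets = [_genes(s) for s in condition_sets]
    if len(sets) < 2:
        raise ValueError("core set needs at least two condition sets")
    return frozenset(sets[0]).intersection(*sets[1:])


def higher_order_summary(
    induced: CrossClassification, alleviated: CrossClassification
) -> HigherOrderSummary:
    """Decompose observed interactions into pairwise-derived vs higher-order.

    Pairwise-derived interactions are those conserved from pairwise to
    community (in either family); higher-order ones are specific to one
    context. Percentages are rounded half-to-even to integers and the raw
    counts always accompany them; with no interactions at all the
    fractions are undefined (None).
    """
    pairwise_derived = len(induced.conserved) + len(alleviated.conserved)
    higher_order = (
        len(induced.pairwise_specific)
        + len(induced.community_specific)
        + len(alleviated.pairwise_specific)
        + len(alleviated.community_specific)
    )
    total = pairwise_derived + higher_order
    if total == 0:
        return HigherOrderSummary(0, 0, None, None)
    return HigherOrderSummary(
        pairwise_derived=pairwise_derived,
        higher_order=higher_order,
        fraction_pairwise=round(100 * pairwise_derived / total),
        fraction_higher=round(100 * higher_order / total),
    )


def membership_patterns(
    condition_sets: Mapping[str, SignificantSet] | Mapping[str, Iterable[str]],
    genes: Iterable[str],
) -> dict[str, frozenset[str]]:
    """For each gene, the set of conditions in which it is significant.

    Useful for comparing a recovered classification against a planted
    ground-truth effect pattern gene by gene.
    """
    sets = {c: _genes(s) for c, s in condition_sets.items()}
    return {g: frozenset(c for c, s in sets.items() if g in s) for g in genes}
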