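"""Signed multi-set (Venn) partitioning of differential gene lists.

Each input list is a *signed* set: gene -> polarity (+1 up, -1 down).
Partitioning assigns every gene to exactly one region keyed by (the subset
of input sets containing it, a polarity category):

* ``up``     — present with polarity +1 in every containing set,
* ``down``   — present with polarity -1 in every containing set,
* ``contra`` — contra-regulated: at least one pair of containing sets
  disagrees in sign (only possible for genes shared by >= 2 sets).

The cross-omics variant reconciles transcript and protein identifiers by
case-insensitive symbol match and annotates shared identifiers as
concordant or discordant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

__all__ = [
    "SignedGeneSet",
    "VennPartitionResult",
    "build_signed_set",
    "venn_partition",
    "cross_omics_overlap",
]

RegionKey = tuple[tuple[str, ...], str]  # (labels containing the gene, category)


@dataclass
class SignedGeneSet:
    label: str
    members: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g: s for g, s in self.members.items() if s not in (+1, -1)}
        if bad:
            raise ValueError(f"polarity must be +1 or -1, got {bad}")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def casefolded(self) -> "SignedGeneSet":
        """Lower-case identifiers (raises if two members collide)."""
        folded: dict[str, int] = {}
        for g, s in self.members.items():
            key = g.lower()
            if key in folded and folded[key] != s:
                raise ValueError(f"case-folding collision with opposite signs: {g}")
            folded[key] = s
        return SignedGeneSet(label=self.label, members=folded)


def build_signed_set(records: pd.DataFrame, label: str) -> SignedGeneSet:
    """Signed set of the genes called up (+1) or down (-1) in a DE table."""
    members = {}
    for gene, call in records["call"].items():
        if call == "up":
            members[str(gene)] = +1
        elif call == "down":
            members[str(gene)] = -1
    return SignedGeneSet(label=label, members=members)


@dataclass
class VennPartitionResult:
    """Disjoint regions covering the union of the input signed sets."""

    regions: dict[RegionKey, frozenset]
    labels: tuple[str, ...]

    @property
    def counts(self) -> dict[RegionKey, int]:
        return {k: len(v) for k, v in self.regions.items()}

    def region(self, labels: Sequence[str], category: str) -> frozenset:
        return self.regions.get((tuple(labels), category), frozenset())

    def shared(self, category: str) -> frozenset:
        """Members of the full-overlap region with the given category."""
        return self.region(self.labels, category)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "&".join(labels), "category": cat, "identifier": g}
            for (labels, cat), genes in sorted(self.regions.items())
            for g in sorted(genes)
        ]
        return pd.DataFrame(rows, columns=["region", "category", "identifier"])

    def counts_json(self) -> str:
        return json.dumps(
            {f"{'&'.join(labels)}:{cat}": n for (labels, cat), n in sorted(self.counts.items())},
            indent=2,
        )


def venn_partition(sets: Sequence[SignedGeneSet]) -> VennPartitionResult:
    """Partition 2–4 signed sets into up / down / contra regions.

    Every identifier lands in exactly one region; region keys preserve the
    input set order.
    """
    if not 2 <= len(sets) <= 4:
        raise ValueError("venn_partition takes between 2 and 4 sets")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate set labels: {labels}")

    regions: dict[RegionKey, set] = {}
    universe = set().union(*(s.members for s in sets))
    for gene in universe:
        containing = tuple(s.label for s in sets if gene in s)
        signs = {s.members[gene] for s in sets if gene in s}
        if signs == {+1}:
            cat = "up"
        elif signs == {-1}:
            cat = "down"
        else:
            cat = "contra"
        regions.setdefault((containing, cat), set()).add(gene)
    return VennPartitionResult(
        regions={k: frozenset(v) for k, v in regions.items()},
        labels=tuple(labels),
    )


def cross_omics_overlap(
    transcripts: SignedGeneSet, proteins: SignedGeneSet
) -> tuple[VennPartitionResult, pd.DataFrame]:
    """Overlap a transcript list with a protein list, matched case-insensitively.

    Returns the two-set partition (on case-folded symbols) and a
    concordance table for the shared identifiers: ``concordant`` when the
    polarities agree across omics layers, ``discordant`` when a factor
    moves one way at the transcript level and the other way at the protein
    level.
    """
    t = transcripts.casefolded()
    p = proteins.casefolded()
    part = venn_partition([t, p])
    shared = sorted(set(t.members) & set(p.members))
    table = pd.DataFrame(
        {
            "identifier": shared,
            "transcript_polarity": [t.members[g] for g in shared],
            "protein_polarity": [p.members[g] for g in shared],
        }
    )
    table["concordant"] = table["transcript_polarity"] == table["protein_polarity"]
    return part, table
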