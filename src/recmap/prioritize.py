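"""Rank-consensus gene prioritization and the human coding-variant filter.

Consensus prioritization intersects the top fraction (default 20%,
ceiling per list length) of several independently ranked candidate
lists; genes every algorithm places near the top are robust candidates.
The human variant filter keeps coding variants that are predicted
damaging (score >= 0.85, the conventional "probably damaging" band),
sit at residues conserved across the aligned mammals, and are absent
from every required population database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .types import FilterTrace


@dataclass
class RankedList:
    """Ordered gene identifiers with scores, best first."""

    source: str
    table: pd.DataFrame  # gene_id, score

    def __post_init__(self) -> None:
        if list(self.table.columns) != ["gene_id", "score"]:
            raise ValueError("ranked list needs columns gene_id, score")
        if self.table["gene_id"].duplicated().any():
            raise ValueError(f"duplicate gene ids in ranked list {self.source!r}")

    def top(self, fraction: float) -> list[str]:
        k = math.ceil(fraction * len(self.table))
        return self.table["gene_id"].head(k).tolist()


@dataclass
class ConsensusResult:
    consensus: set[str]
    top_sets: dict[str, list[str]]
    membership: pd.DataFrame  # union of top genes x lists (bool)
    pairwise_overlaps: dict[tuple[str, str], int]

    def venn_counts(self) -> dict[str, int]:
        """Exclusive region sizes keyed by '+'-joined list names."""
        names = list(self.top_sets)
        sets = {n: set(g) for n, g in self.top_sets.items()}
        out = {}
        for r in range(1, len(names) + 1):
            for combo in combinations(names, r):
                inside = set.intersection(*(sets[n] for n in combo))
                outside = set.union(*(sets[n] for n in names if n not in combo), set())
                out["+".join(combo)] = len(inside - outside)
        return out


def top_fraction_consensus(
    ranked_lists: list[RankedList], fraction: float = 0.20
) -> ConsensusResult:
    """Genes ranked in the top ``fraction`` of every list.

    The per-list cut is ``ceil(fraction * n)`` so no convention-dependent
    gene is excluded.  Also reports pairwise overlap counts (Venn data).
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if len(ranked_lists) < 2:
        raise ValueError("need at least two ranked lists")
    top_sets = {rl.source: rl.top(fraction) for rl in ranked_lists}
    consensus = set.intersection(*(set(v) for v in top_sets.values()))
    union = sorted(set.union(*(set(v) for v in top_sets.values())))
    membership = pd.DataFrame(
        {name: [g in set(genes) for g in union] for name, genes in top_sets.items()},
        index=union,
    )
    pairwise = {
        (a, b): len(set(top_sets[a]) & set(top_sets[b]))
        for a, b in combinations(top_sets, 2)
    }
    return ConsensusResult(consensus, top_sets, membership, pairwise)


def conservation_fraction(
    alignment_window: dict[str, str], focal_species: str, position: int
) -> float:
    """Fraction of non-focal species matching the focal residue.

    ``alignment_window`` maps species -> aligned (equal-length) protein
    sequence; ``position`` is 1-based in alignment coordinates.  Gaps in
    other species count as mismatches; a gap at the focal residue is an
    error.
    """
    if focal_species not in alignment_window:
        raise ValueError(f"focal species {focal_species!r} absent")
    lengths = {len(s) for s in alignment_window.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must be equal length")
    (length,) = lengths
    if not (1 <= position <= length):
        raise ValueError("position out of range")
    focal = alignment_window[focal_species][position - 1].upper()
    if focal == "-":
        raise ValueError("focal residue is a gap")
    others = [s for sp, s in alignment_window.items() if sp != focal_species]
    if not others:
        raise ValueError("need at least one non-focal species")
    matches = sum(1 for s in others if s[position - 1].upper() == focal)
    return matches / len(others)


def human_variant_filter(
    variants: pd.DataFrame,
    damaging_min: float = 0.85,
    conservation_min: float = 1.0,
    required_absent_dbs: tuple[str, ...] = ("thousand_genomes", "dbsnp", "evs"),
) -> tuple[pd.DataFrame, FilterTrace]:
    """Filter human coding variants to disease-implicating candidates.

    ``variants`` carries columns ``gene, protein_change, damaging_score,
    conservation`` plus a boolean presence flag ``in_<db>`` per required
    database.  Steps: damaging score, conservation, database presence.
    """
    for db in required_absent_dbs:
        if f"in_{db}" not in variants.columns:
            raise ValueError(f"required database flag column in_{db} absent")
    if "id" not in variants.columns:
        variants = variants.assign(id=variants["gene"] + ":" + variants["protein_change"])
    trace = FilterTrace()

    keep = variants["damaging_score"] >= damaging_min
    out = variants.loc[keep]
    trace.add("damaging_score", len(variants), int((~keep).sum()), out["id"].tolist())

    keep = out["conservation"] >= conservation_min
    out2 = out.loc[keep]
    trace.add("conservation", len(out), int((~keep).sum()), out2["id"].tolist())

    present = pd.Series(False, index=out2.index)
    for db in required_absent_dbs:
        present |= out2[f"in_{db}"].astype(bool)
    out3 = out2.loc[~present]
    trace.add("db_presence", len(out2), int(present.sum()), out3["id"].tolist())
    return out3, trace
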