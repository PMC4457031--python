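"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* genomic coordinates are 1-based and intervals are closed (inclusive on
  both ends); interval length in bp is ``end - start + 1``.
* genotypes are stored as B-allele dosage in ``{0, 1, 2}`` with ``-1`` as
  the missing sentinel, where allele B is the alphabetically later of the
  two alleles observed at a marker.
* phenotypes are the strings ``"affected"`` / ``"unaffected"`` /
  ``"unknown"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: missing-genotype sentinel in dosage matrices
MISSING: int = -1

AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"

PHENOTYPES = (AFFECTED, UNAFFECTED, UNKNOWN)


@dataclass
class Pedigree:
    """Three-generation intercross pedigree with binary phenotype.

    ``table`` has one row per individual with columns
    ``iid, sire, dam, sex, generation, phenotype``.  ``sire``/``dam`` are
    ``"0"`` for founders, ``generation`` is one of ``"F0", "F1", "F2"``,
    ``sex`` is ``1`` (male), ``2`` (female) or ``0`` (unknown).
    Parents must appear before their offspring.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["iid", "sire", "dam", "sex", "generation", "phenotype"]
        missing_cols = set(required) - set(self.table.columns)
        if missing_cols:
            raise ValueError(f"pedigree table missing columns: {sorted(missing_cols)}")
        iids = self.table["iid"].tolist()
        if len(set(iids)) != len(iids):
            raise ValueError("duplicate individual id in pedigree")
        bad_phen = set(self.table["phenotype"]) - set(PHENOTYPES)
        if bad_phen:
            raise ValueError(f"invalid phenotype labels: {sorted(bad_phen)}")
        seen: set[str] = set()
        for row in self.table.itertuples(index=False):
            for parent in (row.sire, row.dam):
                if parent != "0" and parent not in seen:
                    raise ValueError(
                        f"parent {parent!r} of {row.iid!r} does not precede it"
                    )
            seen.add(row.iid)
        f1_parents_ok = self.table[self.table["generation"] == "F2"]
        f1_ids = set(self.table.loc[self.table["generation"] == "F1", "iid"])
        for row in f1_parents_ok.itertuples(index=False):
            if row.sire not in f1_ids or row.dam not in f1_ids:
                raise ValueError(f"F2 individual {row.iid!r} lacks F1 parents")

    @property
    def iids(self) -> list[str]:
        return self.table["iid"].tolist()

    def ids_of(self, generation: str | None = None, phenotype: str | None = None) -> list[str]:
        sel = pd.Series(True, index=self.table.index)
        if generation is not None:
            sel &= self.table["generation"] == generation
        if phenotype is not None:
            sel &= self.table["phenotype"] == phenotype
        return self.table.loc[sel, "iid"].tolist()

    def affected_ids(self) -> list[str]:
        return self.ids_of(phenotype=AFFECTED)

    def parents_of(self, iid: str) -> tuple[str, str]:
        row = self.table.loc[self.table["iid"] == iid]
        if row.empty:
            raise KeyError(iid)
        return str(row["sire"].iloc[0]), str(row["dam"].iloc[0])

    def founders(self) -> list[str]:
        return self.ids_of(generation="F0")


@dataclass
class GenotypeMatrix:
    """Individuals x markers B-allele dosage matrix.

    ``markers`` has columns ``id, chrom, cm, bp, allele_a, allele_b``
    sorted by (chromosome, position); ``dosage`` is an ``int8`` array of
    shape ``(len(individuals), len(markers))`` over ``{0, 1, 2, MISSING}``.
    """

    markers: pd.DataFrame
    individuals: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        required = ["id", "chrom", "cm", "bp", "allele_a", "allele_b"]
        missing_cols = set(required) - set(self.markers.columns)
        if missing_cols:
            raise ValueError(f"marker table missing columns: {sorted(missing_cols)}")
        ids = self.markers["id"].tolist()
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker id")
        if self.dosage.shape != (len(self.individuals), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        for _, grp in self.markers.groupby("chrom", sort=False):
            bp = grp["bp"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise ValueError("marker positions not strictly increasing within chromosome")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def individual_index(self, iid: str) -> int:
        try:
            return self.individuals.index(iid)
        except ValueError:
            raise KeyError(f"individual {iid!r} not genotyped") from None

    def subset(self, individuals: list[str] | None = None, marker_mask: np.ndarray | None = None) -> "GenotypeMatrix":
        dosage = self.dosage
        inds = self.individuals
        markers = self.markers
        if individuals is not None:
            rows = [self.individual_index(i) for i in individuals]
            dosage = dosage[rows, :]
            inds = list(individuals)
        if marker_mask is not None:
            dosage = dosage[:, marker_mask]
            markers = markers.loc[marker_mask].reset_index(drop=True)
        return GenotypeMatrix(markers=markers, individuals=inds, dosage=dosage.copy())


@dataclass(frozen=True)
class Interval:
    """Genomic interval, 1-based inclusive on both ends."""

    chrom: str
    start_bp: int
    end_bp: int
    n_markers: int = 0
    provenance: str = "ibd_scan"
    start_marker: str | None = None
    end_marker: str | None = None

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"start_bp {self.start_bp} > end_bp {self.end_bp}")
        if self.start_bp < 1:
            raise ValueError("coordinates are 1-based; start_bp must be >= 1")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def contains(self, bp: int) -> bool:
        return self.start_bp <= bp <= self.end_bp


@dataclass
class FilterStep:
    """One step of a variant filter cascade."""

    name: str
    n_in: int
    n_removed: int
    surviving_ids: list[str] = field(default_factory=list)

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed


@dataclass
class FilterTrace:
    """Ordered record of a filter cascade; counts conserve at every step."""

    steps: list[FilterStep] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_removed: int, surviving_ids: list[str]) -> None:
        step = FilterStep(name=name, n_in=n_in, n_removed=n_removed, surviving_ids=list(surviving_ids))
        if step.n_out != len(step.surviving_ids):
            raise ValueError(f"trace step {name!r} does not conserve counts")
        if self.steps and self.steps[-1].n_out != n_in:
            raise ValueError(f"trace step {name!r} input does not match previous output")
        self.steps.append(step)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"step": s.name, "n_in": s.n_in, "n_removed": s.n_removed, "n_out": s.n_out}
                for s in self.steps
            ]
        )
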