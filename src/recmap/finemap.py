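"""Shared-homozygosity (IBD) scanning and recombinant-carrier refinement.

Under a fully penetrant recessive model, all affected F2s are homozygous
identical-by-descent across the segment surrounding the causal locus, so
maximal runs of markers at which every affected individual is homozygous
for the same allele delimit the candidate region.  Unaffected carriers
whose disease-line chromosome is recombinant inside that region then
trim it: wherever the carrier's disease-line chromosome demonstrably
carries normal-haplotype alleles (or has recombined away entirely), the
causal locus cannot lie, and those markers are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import ORIGIN_B, ORIGIN_UNKNOWN, FounderOriginMatrix
from .types import MISSING, GenotypeMatrix, Interval

#: per-marker shared-homozygosity status codes
_INCOMPATIBLE = -9
_WILDCARD = -2  # every affected missing: compatible with either allele


@dataclass
class DiseaseHaplotype:
    """Shared homozygous allele sequence of the affected F2s.

    ``dosages[j]`` is 0 or 2 (the shared homozygous dosage) or None where
    every affected call was missing.  ``alleles`` holds the corresponding
    allele symbols.  ``source_line`` names the founder line the haplotype
    descends from when origins were supplied.
    """

    marker_ids: list[str]
    dosages: list[int | None]
    alleles: list[str | None]
    source_line: str | None = None


def _marker_status(column: np.ndarray, strict: bool) -> int:
    """Status of one marker column restricted to affected individuals."""
    called = column != MISSING
    if strict and not called.all():
        return _INCOMPATIBLE
    if not called.any():
        return _WILDCARD
    vals = np.unique(column[called])
    if len(vals) == 1 and vals[0] in (0, 2):
        return int(vals[0])
    return _INCOMPATIBLE


def shared_homozygosity_scan(
    genotypes: GenotypeMatrix,
    affected_ids: list[str],
    min_markers: int = 2,
    matching: str = "missing_compatible",
    origins: FounderOriginMatrix | None = None,
    bridge_markers: int = 2,
) -> list[tuple[Interval, DiseaseHaplotype]]:
    """Find maximal runs of markers homozygous-identical in all affecteds.

    Missing genotypes are treated as compatible (``matching="strict"``
    breaks runs instead).  Up to ``bridge_markers`` consecutive
    incompatible markers are bridged when compatible markers flank them
    on the same chromosome — a single discordant call among many
    affected individuals is far more likely a genotyping error than two
    recombination events; bridged markers enter the reported interval
    with an unresolved haplotype allele and do not count toward its
    marker total.  Runs shorter than ``min_markers`` are dropped;
    results are sorted by marker count descending (ties: longer bp
    span, then lower coordinate).
    """
    if not affected_ids:
        raise ValueError("no affected individuals")
    if matching not in ("missing_compatible", "strict"):
        raise ValueError(f"matching={matching!r} unknown")
    rows = [genotypes.individual_index(i) for i in affected_ids]
    dos = genotypes.dosage[rows, :]
    markers = genotypes.markers
    status = np.array(
        [_marker_status(dos[:, j], matching == "strict") for j in range(genotypes.n_markers)]
    )

    results: list[tuple[Interval, DiseaseHaplotype]] = []
    chrom_arr = markers["chrom"].to_numpy()
    n = len(status)

    # strict maximal runs first, then bridge short incompatible gaps
    strict_runs: list[tuple[int, int]] = []
    j = 0
    while j < n:
        if status[j] == _INCOMPATIBLE:
            j += 1
            continue
        k = j
        while k + 1 < n and status[k + 1] != _INCOMPATIBLE and chrom_arr[k + 1] == chrom_arr[j]:
            k += 1
        strict_runs.append((j, k))
        j = k + 1
    merged: list[tuple[int, int]] = []
    for s, e in strict_runs:
        if (
            merged
            and chrom_arr[s] == chrom_arr[merged[-1][1]]
            and 0 < s - merged[-1][1] - 1 <= bridge_markers
        ):
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    for j, k in merged:
        run = slice(j, k + 1)
        n_compat = int((status[run] != _INCOMPATIBLE).sum())
        if n_compat >= min_markers:
            sub = markers.iloc[run]
            dosages = [
                None if s in (_WILDCARD, _INCOMPATIBLE) else int(s) for s in status[run]
            ]
            alleles = []
            for d, m in zip(dosages, sub.itertuples(index=False)):
                if d is None:
                    alleles.append(None)
                else:
                    alleles.append(m.allele_a if d == 0 else m.allele_b)
            source_line = None
            if origins is not None:
                cols = [origins.marker_ids.index(m) for m in sub["id"]]
                aff_rows = [origins.individuals.index(i) for i in affected_ids]
                o = origins.origins[np.ix_(aff_rows, cols)]
                known = o[o != ORIGIN_UNKNOWN]
                if known.size:
                    source_line = "lineB" if np.mean(known == ORIGIN_B) >= 0.5 else "lineA"
            interval = Interval(
                chrom=str(sub["chrom"].iloc[0]),
                start_bp=int(sub["bp"].iloc[0]),
                end_bp=int(sub["bp"].iloc[-1]),
                n_markers=n_compat,
                provenance="ibd_scan",
                start_marker=str(sub["id"].iloc[0]),
                end_marker=str(sub["id"].iloc[-1]),
            )
            results.append(
                (interval, DiseaseHaplotype(sub["id"].tolist(), dosages, alleles, source_line))
            )

    results.sort(
        key=lambda r: (-r[0].n_markers, -(r[0].length_bp), r[0].start_bp, r[0].chrom)
    )
    return results


def refine_by_carrier_recombinants(
    interval: Interval,
    genotypes: GenotypeMatrix,
    origins: FounderOriginMatrix,
    carrier_ids: list[str],
    disease_haplotype: DiseaseHaplotype,
    boundary: str = "inner",
    min_support: int = 2,
    support_window: int = 5,
    anchor_bp: int | None = None,
) -> Interval:
    """Trim the IBD interval using recombinant carrier haplotypes.

    ``carrier_ids`` must be unaffected individuals known to carry the
    mutation (obligate carriers, or individuals carrying one complete
    disease haplotype across the interval).  A marker is excluded when
    a carrier's state there is resolvable and incompatible with the
    causal locus lying at that marker:

    * the carrier has no line-B gamete (the disease chromosome
      recombined away), or its homozygous genotype shows the disease
      chromosome carrying the normal allele — the mutation cannot be
      there; or
    * the carrier is homozygous for the disease haplotype (two line-B
      gametes, genotype matching) — were the locus there, the carrier
      would be affected.

    Heterozygous or unresolvable markers are kept.  A recombinant
    segment spans several markers, so a carrier's exclusion only counts
    when that carrier excludes at least ``min_support`` markers within
    ``support_window`` positions of each other — an isolated exclusion
    is more likely a single miscalled genotype (set ``min_support=1``
    to disable).  The refined interval is the longest remaining run
    (ties: lowest coordinate), or the run containing/nearest
    ``anchor_bp`` when given; with ``boundary="inner"`` its limits sit
    on the first non-excluded markers, with ``"midpoint"`` halfway
    toward the adjacent excluded marker.
    """
    if boundary not in ("inner", "midpoint"):
        raise ValueError(f"boundary={boundary!r} unknown")
    markers = genotypes.markers
    in_iv = (
        (markers["chrom"].astype(str) == interval.chrom)
        & (markers["bp"] >= interval.start_bp)
        & (markers["bp"] <= interval.end_bp)
    ).to_numpy()
    idx = np.flatnonzero(in_iv)
    if idx.size == 0:
        raise ValueError("interval contains no markers")
    hap = {m: d for m, d in zip(disease_haplotype.marker_ids, disease_haplotype.dosages)}

    excluded = np.zeros(idx.size, dtype=bool)
    b_dos = origins.b_dosage()
    for iid in carrier_ids:
        gi = genotypes.individual_index(iid)
        oi = origins.individuals.index(iid)
        carrier_excl = np.zeros(idx.size, dtype=bool)
        for local_j, j in enumerate(idx):
            marker_id = markers["id"].iloc[j]
            n_b = b_dos[oi, origins.marker_ids.index(marker_id)]
            if np.isnan(n_b):
                continue
            if n_b == 0:
                carrier_excl[local_j] = True  # disease chromosome recombined away
                continue
            v = hap.get(marker_id)
            d = int(genotypes.dosage[gi, j])
            if v is None or d == MISSING or d == 1:
                continue
            if d != v:
                # homozygous normal: the disease-line chromosome carries
                # the normal allele here
                carrier_excl[local_j] = True
            elif n_b == 2:
                # homozygous for the disease haplotype yet unaffected
                carrier_excl[local_j] = True
        if min_support > 1:
            hits = np.flatnonzero(carrier_excl)
            supported = np.zeros(idx.size, dtype=bool)
            for h in hits:
                near = hits[np.abs(hits - h) <= support_window]
                if len(near) >= min_support:
                    supported[h] = True
            carrier_excl = supported
        excluded |= carrier_excl

    keep = ~excluded
    if not keep.any():
        raise ValueError("refinement removed every marker: phenotype/haplotype data inconsistent")

    # longest remaining run, ties -> lowest coordinate
    runs = []
    s = None
    for t, flag in enumerate(keep):
        if flag and s is None:
            s = t
        if (not flag or t == len(keep) - 1) and s is not None:
            e = t if flag else t - 1
            runs.append((s, e))
            s = None
    bps = markers["bp"].to_numpy()
    if anchor_bp is None:
        run_key = lambda r: (-(bps[idx[r[1]]] - bps[idx[r[0]]]), bps[idx[r[0]]])
    else:
        def run_key(r):
            lo, hi = bps[idx[r[0]]], bps[idx[r[1]]]
            dist = 0 if lo <= anchor_bp <= hi else min(abs(lo - anchor_bp), abs(hi - anchor_bp))
            return (dist, -(hi - lo), lo)
    rs, re = min(runs, key=run_key)

    start_bp = int(bps[idx[rs]])
    end_bp = int(bps[idx[re]])
    if boundary == "midpoint":
        if rs > 0 and excluded[rs - 1]:
            start_bp = int((bps[idx[rs - 1]] + bps[idx[rs]]) // 2)
        if re < len(idx) - 1 and excluded[re + 1]:
            end_bp = int((bps[idx[re]] + bps[idx[re + 1]] + 1) // 2)
    return Interval(
        chrom=interval.chrom,
        start_bp=start_bp,
        end_bp=end_bp,
        n_markers=re - rs + 1,
        provenance="refined",
        start_marker=str(markers["id"].iloc[idx[rs]]),
        end_marker=str(markers["id"].iloc[idx[re]]),
    )


def interval_length_mb(interval: Interval) -> float:
    """Interval length in megabases: (end - start + 1) / 1e6."""
    return interval.length_bp / 1e6
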