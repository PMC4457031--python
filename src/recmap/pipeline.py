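"""End-to-end chain: QC -> founder-origin scan -> IBD -> refinement."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import (
    AssociationResult,
    FounderOriginMatrix,
    infer_founder_origin,
    origin_association_scan,
)
from .config import PipelineConfig
from .finemap import (
    DiseaseHaplotype,
    refine_by_carrier_recombinants,
    shared_homozygosity_scan,
)
from .pedigree_qc import QcReport, qc_filter_markers
from .types import MISSING, UNAFFECTED, GenotypeMatrix, Interval, Pedigree


@dataclass
class MappingResult:
    qc_report: QcReport
    origins: FounderOriginMatrix
    association: AssociationResult
    ibd_interval: Interval
    disease_haplotype: DiseaseHaplotype
    carrier_ids: list[str]
    refined_interval: Interval


def find_carriers(
    pedigree: Pedigree,
    origins: FounderOriginMatrix,
    genotypes: GenotypeMatrix,
    interval: Interval,
    disease_haplotype: DiseaseHaplotype,
    include_certified: bool = False,
) -> list[str]:
    """Carriers usable for breakpoint refinement.

    Returns the obligate carriers (unaffected parents of an affected
    individual, heterozygous by necessity).  With
    ``include_certified=True`` it adds unaffected F2s whose genotypes
    are compatible with one complete copy of the disease haplotype
    across the whole interval; that certification is state-based and
    can be fooled when the interval is weakly informative, so the
    default pipeline relies on obligate carriers only.
    """
    markers = genotypes.markers
    in_iv = (
        (markers["chrom"].astype(str) == interval.chrom)
        & (markers["bp"] >= interval.start_bp)
        & (markers["bp"] <= interval.end_bp)
    ).to_numpy()
    marker_rows = markers.loc[in_iv]
    cols = [origins.marker_ids.index(m) for m in marker_rows["id"]]
    geno_cols = marker_rows.index.to_numpy()
    hap = {m: d for m, d in zip(disease_haplotype.marker_ids, disease_haplotype.dosages)}
    b_dos = origins.b_dosage()

    affected = set(pedigree.affected_ids())
    obligate: list[str] = []
    for row in pedigree.table.itertuples(index=False):
        if row.iid in affected:
            for p in (row.sire, row.dam):
                if p != "0" and p not in obligate:
                    obligate.append(p)
    obligate = [p for p in obligate if p in origins.individuals]

    carriers = list(obligate)
    if not include_certified:
        return carriers
    for iid in pedigree.ids_of(generation="F2", phenotype=UNAFFECTED):
        oi = origins.individuals.index(iid)
        gi = genotypes.individual_index(iid)
        ok = True
        het_somewhere = False
        for c, g in zip(cols, geno_cols):
            nb = b_dos[oi, c]
            if not np.isnan(nb) and nb == 0:
                ok = False
                break
            v = hap.get(str(markers["id"].iloc[g]))
            d = int(genotypes.dosage[gi, g])
            if v is None or d == MISSING:
                continue
            if d == 1:
                het_somewhere = True
            elif d != v:  # homozygous normal: no disease allele here
                ok = False
                break
        if ok and het_somewhere:
            carriers.append(iid)
    return carriers


def _descent_core(
    origins: FounderOriginMatrix, genotypes: GenotypeMatrix, affected_ids: list[str]
) -> tuple[int, int] | None:
    """Longest stretch (bp bounds) where all affecteds are line-B homozygous."""
    cols = [origins.marker_ids.index(m) for m in genotypes.markers["id"]]
    rows = [origins.individuals.index(i) for i in affected_ids]
    b = origins.b_dosage()[np.ix_(rows, cols)]
    core = (
        np.all((b == 2) | np.isnan(b), axis=0) & (~np.isnan(b)).any(axis=0)
    )
    if not core.any():
        return None
    bp = genotypes.markers["bp"].to_numpy()
    best = None
    s = None
    for j, flag in enumerate(core):
        if flag and s is None:
            s = j
        if s is not None and (not flag or j == len(core) - 1):
            e = j if flag else j - 1
            span = bp[e] - bp[s]
            if best is None or span > best[0]:
                best = (span, s, e)
            s = None
    _, s, e = best
    return int(bp[s]), int(bp[e])


def map_recessive_locus(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    config: PipelineConfig | None = None,
) -> MappingResult:
    """Run marker QC, the origin scan, IBD detection and refinement.

    The IBD scan runs on the chromosome carrying the minimum-p marker;
    the top shared-homozygosity run (most markers, then longest span,
    then lowest coordinate) is refined with every recombinant carrier.
    """
    cfg = config or PipelineConfig()
    genotypes_qc, qc_report = qc_filter_markers(
        genotypes,
        call_rate_min=cfg.qc.call_rate_min,
        maf_min=cfg.qc.maf_min,
        hwe_p_min=cfg.qc.hwe_p_min,
    )
    # the association scan runs on QC'd markers; the homozygosity stages
    # keep every position-known marker (a family-monomorphic marker is
    # uninformative for association yet still delimits shared segments)
    pos_known = (
        (genotypes.markers["bp"] > 0)
        & ~genotypes.markers["chrom"].astype(str).isin(("0", ""))
    ).to_numpy()
    genotypes_pos = genotypes.subset(marker_mask=pos_known)
    origins = infer_founder_origin(
        pedigree,
        genotypes_pos,
        error_rate=cfg.assoc.hmm_error_rate,
        posterior_threshold=cfg.assoc.posterior_threshold,
        cm_per_mb=cfg.assoc.cm_per_mb,
    )
    origins_qc = origins.subset_markers(genotypes_qc.markers["id"].tolist())
    phenotype = pd.Series(
        pedigree.table["phenotype"].to_numpy(), index=pedigree.table["iid"].to_numpy()
    )
    assoc = origin_association_scan(
        origins_qc,
        phenotype,
        genotypes=genotypes_qc,
        alpha=cfg.assoc.alpha,
        max_unknown_frac=cfg.assoc.max_unknown_frac,
        method=cfg.assoc.method,
        f2_ids=pedigree.ids_of(generation="F2"),
    )
    top = assoc.top_marker()
    top_chrom, top_bp = str(top["chrom"]), int(top["bp"])
    chrom_mask = (genotypes_pos.markers["chrom"].astype(str) == top_chrom).to_numpy()
    geno_chrom = genotypes_pos.subset(marker_mask=chrom_mask)
    affected = pedigree.affected_ids()
    segments = shared_homozygosity_scan(
        geno_chrom,
        affected,
        min_markers=cfg.finemap.min_markers,
        matching=cfg.finemap.matching,
        origins=origins,
        bridge_markers=cfg.finemap.bridge_markers,
    )
    if not segments:
        raise ValueError("no shared homozygous segment among affected individuals")

    # the shared-by-state segment must also be shared by DESCENT from the
    # carrier founder line: the analysis checks that the haplotype was
    # inherited from the line-B founder, so the candidate segment is the
    # one overlapping the longest stretch where every affected is
    # homozygous for line-B origin.  Falls back to the association peak
    # when origins leave no such stretch.
    core = _descent_core(origins, geno_chrom, affected)
    anchor_bp = (core[0] + core[1]) // 2 if core is not None else top_bp

    def dist_to_anchor(iv: Interval) -> int:
        if iv.contains(anchor_bp):
            return 0
        return min(abs(iv.start_bp - anchor_bp), abs(iv.end_bp - anchor_bp))

    ibd_interval, haplotype = min(
        segments, key=lambda seg: (dist_to_anchor(seg[0]), -seg[0].n_markers)
    )
    # constrain the state-shared segment to its descent-supported part
    if core is not None:
        lo = max(ibd_interval.start_bp, core[0])
        hi = min(ibd_interval.end_bp, core[1])
        if lo <= hi:
            in_core = (
                (geno_chrom.markers["bp"] >= lo) & (geno_chrom.markers["bp"] <= hi)
            ).to_numpy()
            n_core = int(in_core.sum())
            if n_core >= cfg.finemap.min_markers:
                sub = geno_chrom.markers.loc[in_core]
                ibd_interval = Interval(
                    chrom=ibd_interval.chrom,
                    start_bp=int(sub["bp"].iloc[0]),
                    end_bp=int(sub["bp"].iloc[-1]),
                    n_markers=n_core,
                    provenance="ibd_scan",
                    start_marker=str(sub["id"].iloc[0]),
                    end_marker=str(sub["id"].iloc[-1]),
                )
    carriers = find_carriers(pedigree, origins, geno_chrom, ibd_interval, haplotype)
    refined = refine_by_carrier_recombinants(
        ibd_interval,
        geno_chrom,
        origins,
        carriers,
        haplotype,
        boundary=cfg.finemap.boundary,
        anchor_bp=anchor_bp,
    )
    return MappingResult(
        qc_report=qc_report,
        origins=origins,
        association=assoc,
        ibd_interval=ibd_interval,
        disease_haplotype=haplotype,
        carrier_ids=carriers,
        refined_interval=refined,
    )
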