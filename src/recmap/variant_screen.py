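"""Variant-site QC, the recessive exclusion cascade, and allied checks.

The cascade mirrors how a fully penetrant recessive causal variant must
behave in a trio of one affected offspring and two unaffected carrier
parents: it is homozygous-alt in the affected, heterozygous in both
parents, Mendelian-consistent, and protein-altering.  Surviving
variants are then screened against a panel of presumed non-carriers:
anything segregating there at alt-allele frequency above the threshold
cannot be the cause of a disorder never seen in those populations.

A missing genotype at the sample a step evaluates removes the variant
with that step (conservative: never silently passes).
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import GT_HET, GT_HOMALT, GT_HOMREF, GT_MISSING
from .types import AFFECTED, UNAFFECTED, FilterTrace, Pedigree

PROTEIN_ALTERING = ("coding_nonsyn", "coding_truncating")


def _apply_step(
    variants: pd.DataFrame, trace: FilterTrace, name: str, keep: pd.Series
) -> pd.DataFrame:
    out = variants.loc[keep]
    trace.add(name, len(variants), int((~keep).sum()), out["id"].tolist())
    return out


def variant_site_qc(
    variants: pd.DataFrame,
    depth_min: float = 6,
    depth_max: float = 70,
    min_spacing_bp: int = 5,
    quality_min: float = 20,
) -> tuple[pd.DataFrame, FilterTrace]:
    """Depth-band, spacing and quality filters on called sites.

    Bounds are inclusive: depth 6 and 70 pass, 5 and 71 fail.  The
    spacing step removes a variant whose distance to the previous seen
    variant (in position order, among depth survivors) is below
    ``min_spacing_bp``; the previous variant counts whether or not it
    was itself removed for spacing.
    """
    trace = FilterTrace()
    if variants.empty:
        return variants, trace
    pos = variants["pos"].to_numpy()
    chrom = variants["chrom"].to_numpy()
    same = chrom[1:] == chrom[:-1]
    if np.any(same & (np.diff(pos) <= 0)):
        raise ValueError("variants must be sorted by position within chromosome")

    keep = (variants["depth"] >= depth_min) & (variants["depth"] <= depth_max)
    variants = _apply_step(variants, trace, "depth", keep)

    if len(variants):
        pos = variants["pos"].to_numpy()
        chrom = variants["chrom"].to_numpy()
        dist_ok = np.ones(len(variants), dtype=bool)
        dist_ok[1:] = (chrom[1:] != chrom[:-1]) | (np.diff(pos) >= min_spacing_bp)
        keep = pd.Series(dist_ok, index=variants.index)
    else:
        keep = pd.Series(dtype=bool)
    variants = _apply_step(variants, trace, "spacing", keep)

    keep = variants["qual"] >= quality_min
    variants = _apply_step(variants, trace, "quality", keep)
    return variants, trace


def mendelian_recessive_filter(
    variants: pd.DataFrame, affected_id: str, sire_id: str, dam_id: str
) -> tuple[pd.DataFrame, FilterTrace]:
    """Four-step exclusion cascade for a recessive causal variant.

    Steps, in order: (1) remove variants not homozygous-alt in the
    affected (heterozygous calls, reference calls, missing);
    (2) remove variants homozygous-alt in a parent (an unaffected
    obligate carrier cannot be homozygous mutant); (3) remove variants
    inconsistent with Mendelian transmission (a homozygous-reference
    parent cannot have transmitted the alt allele); (4) remove variants
    outside protein-altering classes.
    """
    for col in (f"gt_{affected_id}", f"gt_{sire_id}", f"gt_{dam_id}"):
        if col not in variants.columns:
            raise ValueError(f"sample column {col!r} absent")
    trace = FilterTrace()
    if variants.empty:
        for name in ("not_homalt_in_affected", "parent_homalt", "mendelian_inconsistent", "noncoding"):
            trace.add(name, 0, 0, [])
        return variants, trace
    aff = variants[f"gt_{affected_id}"]
    sire = variants[f"gt_{sire_id}"]
    dam = variants[f"gt_{dam_id}"]

    variants = _apply_step(variants, trace, "not_homalt_in_affected", aff == GT_HOMALT)
    sire, dam = sire.loc[variants.index], dam.loc[variants.index]
    parent_eval = (sire != GT_MISSING) & (dam != GT_MISSING)
    variants = _apply_step(
        variants, trace, "parent_homalt", parent_eval & (sire != GT_HOMALT) & (dam != GT_HOMALT)
    )
    sire, dam = sire.loc[variants.index], dam.loc[variants.index]
    # affected is homalt: both parents must carry at least one alt allele
    variants = _apply_step(
        variants, trace, "mendelian_inconsistent", (sire != GT_HOMREF) & (dam != GT_HOMREF)
    )
    variants = _apply_step(
        variants, trace, "noncoding", variants["func_class"].isin(PROTEIN_ALTERING)
    )
    return variants, trace


def panel_alt_frequency(variants: pd.DataFrame, panel_samples: list[str]) -> pd.Series:
    """Alt-allele frequency across the panel, ignoring missing calls."""
    alt = pd.Series(0.0, index=variants.index)
    called = pd.Series(0.0, index=variants.index)
    for s in panel_samples:
        g = variants[f"gt_{s}"]
        alt += (g == GT_HET) * 1.0 + (g == GT_HOMALT) * 2.0
        called += (g != GT_MISSING) * 2.0
    freq = alt / called.replace(0.0, np.nan)
    return freq.fillna(0.0)


def population_screen(
    variants: pd.DataFrame,
    panel_samples: list[str],
    seg_freq_threshold: float = 0.1,
) -> tuple[pd.DataFrame, FilterTrace]:
    """Remove variants segregating in the non-carrier panel.

    Variants with panel alt frequency strictly above the threshold are
    removed; frequency zero is retained; frequencies in (0, threshold]
    are retained with ``panel_flag == "ambiguous"``.
    """
    if not panel_samples:
        raise ValueError("empty panel")
    trace = FilterTrace()
    if variants.empty:
        trace.add("panel_screen", 0, 0, [])
        return variants, trace
    freq = panel_alt_frequency(variants, panel_samples)
    keep = freq <= seg_freq_threshold
    out = variants.loc[keep].copy()
    out["panel_alt_freq"] = freq.loc[keep]
    out["panel_flag"] = np.where(freq.loc[keep] > 0, "ambiguous", "absent")
    trace.add("panel_screen", len(variants), int((~keep).sum()), out["id"].tolist())
    return out, trace


def cosegregation_check(
    pedigree: Pedigree, genotypes_at_variant: dict[str, str]
) -> tuple[bool, pd.DataFrame]:
    """Check perfect recessive cosegregation of one variant in a family.

    Passes iff every affected individual is homozygous-alt, every
    obligate carrier (parent of an affected) is heterozygous, and no
    unaffected individual is homozygous-alt.  Returns the pass flag and
    a genotype x phenotype crosstab.
    """
    ped = pedigree.table
    obligate: set[str] = set()
    for row in ped[ped["phenotype"] == AFFECTED].itertuples(index=False):
        gt = genotypes_at_variant.get(row.iid)
        if gt is None or gt == GT_MISSING:
            raise ValueError(f"missing genotype for affected individual {row.iid!r}")
        obligate.update(p for p in (row.sire, row.dam) if p != "0")
    passes = True
    rows = []
    for row in ped.itertuples(index=False):
        gt = genotypes_at_variant.get(row.iid, GT_MISSING)
        rows.append({"iid": row.iid, "phenotype": row.phenotype, "genotype": gt})
        if row.phenotype == AFFECTED and gt != GT_HOMALT:
            passes = False
        if row.iid in obligate and gt != GT_HET:
            passes = False
        if row.phenotype == UNAFFECTED and gt == GT_HOMALT:
            passes = False
    counts = pd.crosstab(
        pd.Series([r["genotype"] for r in rows], name="genotype"),
        pd.Series([r["phenotype"] for r in rows], name="phenotype"),
    )
    return passes, counts


def insilico_rflp(
    amplicon_sequence: str,
    recognition_site: str = "CCCGGG",
    cut_offset: int = 3,
    cut_reverse: bool = True,
) -> list[int]:
    """Fragment lengths from an in-silico restriction digest.

    Cuts after ``cut_offset`` bases of every occurrence of the
    recognition site; occurrences on the reverse strand are also cut
    (no-op for palindromic sites such as SmaI's CCCGGG).  Fragments are
    returned 5'->3' and always sum to the sequence length.
    """
    seq = amplicon_sequence.upper()
    if not seq or set(seq) - set("ACGT"):
        raise ValueError("sequence must be non-empty over {A,C,G,T}")
    site = recognition_site.upper()
    if not (0 <= cut_offset <= len(site)):
        raise ValueError("cut offset outside recognition site")
    cuts: set[int] = set()
    for m in re.finditer(f"(?={re.escape(site)})", seq):
        cuts.add(m.start() + cut_offset)
    site_rc = str(Seq(site).reverse_complement())
    if cut_reverse and site_rc != site:
        # bottom-strand occurrences; a palindromic site is the same binding
        # event as the forward hit, so it is not cut twice
        for m in re.finditer(f"(?={re.escape(site_rc)})", seq):
            cuts.add(m.start() + (len(site) - cut_offset))
    points = sorted(c for c in cuts if 0 < c < len(seq))
    bounds = [0] + points + [len(seq)]
    return [b - a for a, b in zip(bounds[:-1], bounds[1:])]


def predict_truncation(
    cds_sequence: str, variant: tuple[int, str, str]
) -> tuple[int, int | None]:
    """Apply a CDS edit and locate any premature stop codon.

    ``variant`` is (1-based CDS position, deleted bases, inserted bases).
    Returns (protein length after the edit, 1-based residue index at
    which translation terminates) — the second element is None when the
    edit introduces no premature stop relative to the unedited protein.
    """
    cds = cds_sequence.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if not cds.startswith("ATG"):
        raise ValueError("CDS must start with ATG")
    pos, deleted, inserted = variant
    deleted, inserted = deleted.upper(), inserted.upper()
    if not (1 <= pos <= len(cds)):
        raise ValueError("variant position beyond CDS")
    if cds[pos - 1 : pos - 1 + len(deleted)] != deleted:
        raise ValueError("deleted bases do not match the CDS")
    edited = cds[: pos - 1] + inserted + cds[pos - 1 + len(deleted) :]

    def first_stop(seq: str) -> int | None:
        prot = str(Seq(seq[: len(seq) - len(seq) % 3]).translate())
        hit = prot.find("*")
        return hit + 1 if hit >= 0 else None

    orig_stop = first_stop(cds)
    orig_len = (orig_stop - 1) if orig_stop is not None else len(cds) // 3
    new_stop = first_stop(edited)
    new_len = (new_stop - 1) if new_stop is not None else len(edited) // 3
    premature = new_stop is not None and new_len < orig_len
    return new_len, (new_stop if premature else None)
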