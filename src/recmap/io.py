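"""Readers and writers for the plain-text formats the pipeline touches.

PED/MAP follow the PLINK text conventions (phenotype 1 = unaffected,
2 = affected, 0/-9 = unknown; genotype ``0 0`` = missing).  The VCF
reader handles the v4.x subset with per-sample GT plus site-level depth
and quality; multiallelic records are rejected or split per
``multiallelic=``.  Count tables, ranked gene lists and intervals travel
as TSV/BED/JSON.

Intervals are 1-based closed internally and converted to 0-based
half-open on BED write.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .types import (
    AFFECTED,
    MISSING,
    UNAFFECTED,
    UNKNOWN,
    GenotypeMatrix,
    Interval,
    Pedigree,
)

VALID_ALLELES = {"A", "C", "G", "T", "0"}

_PHEN_FROM_PED = {"1": UNAFFECTED, "2": AFFECTED, "0": UNKNOWN, "-9": UNKNOWN}
_PHEN_TO_PED = {UNAFFECTED: "1", AFFECTED: "2", UNKNOWN: "0"}

GT_HOMREF = "homref"
GT_HET = "het"
GT_HOMALT = "homalt"
GT_MISSING = "missing"


# ---------------------------------------------------------------------------
# PED / MAP


def _derive_generations(rows: list[dict]) -> None:
    """Assign F0/F1/F2 labels from parentage depth."""
    depth: dict[str, int] = {}

    ids = {r["iid"] for r in rows}
    for r in rows:
        if r["sire"] == "0" and r["dam"] == "0":
            depth[r["iid"]] = 0
    changed = True
    while changed:
        changed = False
        for r in rows:
            if r["iid"] in depth:
                continue
            d = []
            for p in (r["sire"], r["dam"]):
                if p in depth:
                    d.append(depth[p])
                elif p not in ids:
                    d.append(-1)  # parent outside the file: treat as founder-level
            if len(d) == 2:
                depth[r["iid"]] = max(d) + 1
                changed = True
    for r in rows:
        r["generation"] = f"F{min(depth.get(r['iid'], 0), 2)}"


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> tuple[Pedigree, GenotypeMatrix]:
    """Read a PLINK-style text PED/MAP pair.

    Markers are returned sorted by (chromosome, position); genotypes are
    coded as counts of the B allele (the alphabetically later allele seen
    at the marker) with ``MISSING`` for ``0 0`` calls.
    """
    map_rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValueError(f"{map_path}:{ln}: expected 4 MAP columns, got {len(parts)}")
            chrom, mid, cm, bp = parts
            map_rows.append({"id": mid, "chrom": chrom, "cm": float(cm), "bp": int(bp)})
    markers = pd.DataFrame(map_rows)
    if markers.empty:
        raise ValueError("empty MAP file")
    if markers["id"].duplicated().any():
        dup = markers.loc[markers["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate marker id {dup!r}")
    order = np.lexsort((markers["bp"].to_numpy(), markers["chrom"].to_numpy()))
    markers = markers.iloc[order].reset_index(drop=True)
    n_markers = len(markers)

    ped_rows: list[dict] = []
    alleles_raw: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise ValueError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_markers} columns, got {len(parts)}"
                )
            fid, iid, sire, dam, sex, phen = parts[:6]
            if phen not in _PHEN_FROM_PED:
                raise ValueError(f"{ped_path}:{ln}: unknown phenotype code {phen!r}")
            ped_rows.append(
                {
                    "fid": fid,
                    "iid": iid,
                    "sire": sire,
                    "dam": dam,
                    "sex": int(sex),
                    "phenotype": _PHEN_FROM_PED[phen],
                }
            )
            pair_list = []
            geno = parts[6:]
            for j in range(n_markers):
                a1, a2 = geno[2 * j], geno[2 * j + 1]
                for a in (a1, a2):
                    if a not in VALID_ALLELES:
                        raise ValueError(f"{ped_path}:{ln}: allele symbol {a!r} invalid")
                if ("0" in (a1, a2)) and a1 != a2:
                    raise ValueError(f"{ped_path}:{ln}: half-missing genotype {a1} {a2}")
                pair_list.append((a1, a2))
            alleles_raw.append(pair_list)
    if not ped_rows:
        raise ValueError("empty PED file")
    iids = [r["iid"] for r in ped_rows]
    if len(set(iids)) != len(iids):
        raise ValueError("duplicate individual id in PED")

    # PED genotype columns are in original MAP order; reorder to sorted order.
    inv = np.empty(n_markers, dtype=int)
    inv[order] = np.arange(n_markers)  # original index -> sorted position
    n_ind = len(ped_rows)
    dosage = np.full((n_ind, n_markers), MISSING, dtype=np.int8)
    allele_a = [None] * n_markers
    allele_b = [None] * n_markers
    for j_orig in range(n_markers):
        j = inv[j_orig]
        observed = sorted(
            {a for pairs in alleles_raw for a in pairs[j_orig] if a != "0"}
        )
        if len(observed) > 2:
            raise ValueError(f"marker {markers['id'].iloc[j]!r} has >2 alleles")
        a = observed[0] if observed else None
        b = observed[1] if len(observed) == 2 else None
        allele_a[j], allele_b[j] = a, b
        for i in range(n_ind):
            a1, a2 = alleles_raw[i][j_orig]
            if a1 == "0":
                continue
            dosage[i, j] = (a1 == b) + (a2 == b) if b is not None else 0

    _derive_generations(ped_rows)
    ped_table = pd.DataFrame(ped_rows)[["iid", "sire", "dam", "sex", "generation", "phenotype"]]
    markers = markers.assign(allele_a=allele_a, allele_b=allele_b)[
        ["id", "chrom", "cm", "bp", "allele_a", "allele_b"]
    ]
    return Pedigree(ped_table), GenotypeMatrix(markers, iids, dosage)


def write_ped_map(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    ped_path: str | Path,
    map_path: str | Path,
    fid: str = "FAM1",
) -> None:
    with open(map_path, "w") as fh:
        for m in genotypes.markers.itertuples(index=False):
            fh.write(f"{m.chrom}\t{m.id}\t{m.cm:g}\t{m.bp}\n")
    ped = pedigree.table.set_index("iid")
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(genotypes.individuals):
            row = ped.loc[iid]
            fields = [fid, iid, row["sire"], row["dam"], str(int(row["sex"])), _PHEN_TO_PED[row["phenotype"]]]
            for j, m in enumerate(genotypes.markers.itertuples(index=False)):
                d = genotypes.dosage[i, j]
                a, b = m.allele_a, m.allele_b
                if d == MISSING or a is None:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [a, a]
                elif d == 1:
                    fields += [a, b]
                else:
                    fields += [b, b]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Minimal VCF


_GT_CODE = {0: GT_HOMREF, 1: GT_HET, 3: GT_HOMALT, 2: GT_MISSING}


def read_vcf_min(path: str | Path, multiallelic: str = "error") -> pd.DataFrame:
    """Read a minimal VCF into a flat variant table.

    Returns one row per biallelic site with columns ``chrom, pos, id, ref,
    alt, qual, depth, gene, func_class`` plus one genotype column
    ``gt_<sample>`` per sample holding ``homref/het/homalt/missing``.
    ``depth`` comes from INFO/DP (or the summed sample depths), ``gene``
    and ``func_class`` from the INFO keys ``GENE`` and ``FC``.  The sample
    list is stored in ``df.attrs["samples"]``.
    """
    if multiallelic not in ("error", "split"):
        raise ValueError(f"multiallelic={multiallelic!r} unknown")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    for rec in vcf:
        alts = rec.ALT
        if len(alts) == 0:
            continue
        if len(alts) > 1 and multiallelic == "error":
            raise ValueError(f"multiallelic record at {rec.CHROM}:{rec.POS}")
        gts = rec.gt_types  # 0 homref, 1 het, 2 unknown, 3 homalt
        for alt_i, alt in enumerate(alts):
            row = {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "ref": rec.REF,
                "alt": alt,
                "qual": float(rec.QUAL) if rec.QUAL is not None else float("nan"),
                "depth": float(rec.INFO.get("DP", np.nan)),
                "gene": rec.INFO.get("GENE", ""),
                "func_class": rec.INFO.get("FC", "noncoding"),
            }
            if len(alts) > 1:
                row["id"] = f"{row['id']}_{alt_i + 1}"
                # on split, genotypes are interpreted against this alt only;
                # calls involving another alt become missing
                codes = []
                for s_i in range(len(samples)):
                    gt = rec.genotypes[s_i]
                    calls = [g for g in gt[:-1]]
                    if any(c < 0 for c in calls):
                        codes.append(GT_MISSING)
                    elif any(c not in (0, alt_i + 1) for c in calls):
                        codes.append(GT_MISSING)
                    else:
                        codes.append(_GT_CODE[{0: 0, 1: 1, 2: 3}[sum(c == alt_i + 1 for c in calls)]])
                for s, c in zip(samples, codes):
                    row[f"gt_{s}"] = c
            else:
                if np.isnan(row["depth"]):
                    depths = rec.gt_depths
                    row["depth"] = float(np.sum(depths[depths >= 0])) if depths is not None else np.nan
                for s, g in zip(samples, gts):
                    row[f"gt_{s}"] = _GT_CODE[int(g)]
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["samples"] = samples
    return df


_GT_TO_VCF = {GT_HOMREF: "0/0", GT_HET: "0/1", GT_HOMALT: "1/1", GT_MISSING: "./."}


def write_vcf_min(variants: pd.DataFrame, path: str | Path, samples: list[str] | None = None) -> None:
    """Write a variant table in the minimal VCF subset (GT only per sample)."""
    if samples is None:
        samples = variants.attrs.get("samples")
    if samples is None:
        samples = [c[3:] for c in variants.columns if c.startswith("gt_")]
    chroms = list(dict.fromkeys(variants["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
        fh.write('##INFO=<ID=FC,Number=1,Type=String,Description="Functional class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for row in variants.itertuples(index=False):
            info = f"DP={int(row.depth)};GENE={row.gene};FC={row.func_class}"
            qual = "." if pd.isna(row.qual) else f"{row.qual:g}"
            gts = "\t".join(_GT_TO_VCF[getattr(row, f"gt_{s}")] for s in samples)
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t{qual}\tPASS\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Count tables, ranked lists, FASTA, intervals


def read_counts(path: str | Path):
    """Read a gene-level count TSV: gene_id, length_bp, count_<s1>, count_<s2>."""
    from .expression import CountTable

    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if cols[:2] != ["gene_id", "length_bp"]:
        raise ValueError("count table must start with columns gene_id, length_bp")
    count_cols = [c for c in cols[2:] if c.startswith("count_")]
    if len(count_cols) != 2:
        raise ValueError("count table must carry exactly two count_<sample> columns")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in count table")
    if (df["length_bp"] <= 0).any():
        raise ValueError("gene length must be >= 1")
    if (df[count_cols] < 0).to_numpy().any():
        raise ValueError("negative counts")
    samples = [c[len("count_"):] for c in count_cols]
    table = df.rename(columns={count_cols[0]: "x", count_cols[1]: "y"})
    return CountTable(table=table[["gene_id", "length_bp", "x", "y"]], samples=(samples[0], samples[1]))


def write_counts(count_table, path: str | Path) -> None:
    df = count_table.table.rename(
        columns={"x": f"count_{count_table.samples[0]}", "y": f"count_{count_table.samples[1]}"}
    )
    df.to_csv(path, sep="\t", index=False)


def read_ranked_list(path: str | Path, source: str | None = None):
    """Read a ranked gene list TSV (gene_id, score); ties keep input order."""
    from .prioritize import RankedList

    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["gene_id", "score"]:
        raise ValueError("ranked list must have columns gene_id, score")
    df = df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    return RankedList(source=source or str(path), table=df)


def write_ranked_list(ranked, path: str | Path) -> None:
    ranked.table.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> uppercase-sequence mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_bed(intervals: list[Interval], path: str | Path) -> None:
    """Write intervals as BED (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start_bp - 1}\t{iv.end_bp}\t{iv.provenance}\n")


def write_intervals_json(intervals: list[Interval], path: str | Path) -> None:
    doc = [
        {
            "chrom": iv.chrom,
            "start_bp": iv.start_bp,
            "end_bp": iv.end_bp,
            "n_markers": iv.n_markers,
            "provenance": iv.provenance,
            "start_marker": iv.start_marker,
            "end_marker": iv.end_marker,
        }
        for iv in intervals
    ]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
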