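"""Shared fixtures: tiny hand-built pedigrees, genotype matrices and files."""

import numpy as np
import pandas as pd
import pytest

from recmap import GenotypeMatrix, Pedigree
from recmap.types import AFFECTED, UNAFFECTED


def make_genotypes(dosage, positions=None, chrom="1", individuals=None):
    """GenotypeMatrix from a dosage list-of-lists (individuals x markers)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_ind, n_mark = dosage.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(n_mark)]
    if individuals is None:
        individuals = [f"I{i + 1}" for i in range(n_ind)]
    markers = pd.DataFrame(
        {
            "id": [f"m{j + 1}" for j in range(n_mark)],
            "chrom": chrom,
            "cm": [p / 1e6 for p in positions],
            "bp": positions,
            "allele_a": "A",
            "allele_b": "C",
        }
    )
    return GenotypeMatrix(markers, list(individuals), dosage)


def make_pedigree(n_f2=4, affected=()):
    rows = [
        {"iid": "F0_A", "sire": "0", "dam": "0", "sex": 1, "generation": "F0", "phenotype": UNAFFECTED},
        {"iid": "F0_B", "sire": "0", "dam": "0", "sex": 2, "generation": "F0", "phenotype": UNAFFECTED},
        {"iid": "F1_1", "sire": "F0_A", "dam": "F0_B", "sex": 1, "generation": "F1", "phenotype": UNAFFECTED},
        {"iid": "F1_2", "sire": "F0_A", "dam": "F0_B", "sex": 2, "generation": "F1", "phenotype": UNAFFECTED},
    ]
    for i in range(n_f2):
        iid = f"F2_{i + 1}"
        rows.append(
            {
                "iid": iid,
                "sire": "F1_1",
                "dam": "F1_2",
                "sex": 1 + i % 2,
                "generation": "F2",
                "phenotype": AFFECTED if iid in affected else UNAFFECTED,
            }
        )
    return Pedigree(pd.DataFrame(rows))


@pytest.fixture
def toy_pedigree():
    return make_pedigree(n_f2=4, affected=("F2_1",))


def write_vcf_text(path, records, samples=("affected", "sire", "dam")):
    """Write a small literal VCF for reader tests."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=18>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="gene">\n')
        fh.write('##INFO=<ID=FC,Number=1,Type=String,Description="class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="gq">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for rec in records:
            fh.write(rec + "\n")
    return path


def make_digest_fixture(total=891, cut_at=438, site="CCCGGG", offset=3, seed=0):
    """Random sequence of ``total`` bp with exactly one cut site so the
    digest yields fragments [cut_at, total - cut_at]."""
    rng = np.random.default_rng(seed)
    site_start = cut_at - offset  # 0-based
    while True:
        seq = "".join(rng.choice(list("ACGT"), size=total))
        seq = seq[:site_start] + site + seq[site_start + len(site):]
        if seq.count(site) == 1:
            return seq
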