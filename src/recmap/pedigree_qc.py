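"""Segregation-ratio testing and SNP marker quality control.

Marker QC mirrors chip-genotyping practice for an intercross: markers are
removed when call rate < 0.90, minor allele frequency < 0.05, the
Hardy-Weinberg chi-square p-value < 1e-6, or the genomic position is
unknown.  Values exactly at a threshold are kept.  Note that an F2 of a
full-sib mating deviates from Hardy-Weinberg proportions by design; the
1e-6 cut-off is lenient enough that only genotyping artifacts fail it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import MISSING, AFFECTED, UNAFFECTED, GenotypeMatrix, Pedigree


def segregation_test(
    pedigree: Pedigree, expected_ratio: tuple[float, float] = (3, 1)
) -> tuple[float, int, float]:
    """Pearson goodness-of-fit of F2 (unaffected, affected) counts.

    Defaults to the 3:1 ratio expected for a fully penetrant autosomal
    recessive in an F1 x F1 intercross.  Returns (chi_square, df, p).
    """
    f2 = pedigree.table[pedigree.table["generation"] == "F2"]
    n_unaff = int((f2["phenotype"] == UNAFFECTED).sum())
    n_aff = int((f2["phenotype"] == AFFECTED).sum())
    n = n_unaff + n_aff
    if n == 0:
        raise ValueError("no phenotyped F2 individuals")
    ru, ra = expected_ratio
    expected = np.array([ru, ra], dtype=float) / (ru + ra) * n
    observed = np.array([n_unaff, n_aff], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    df = 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def hwe_chi_square_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Hardy-Weinberg Pearson chi-square p (1 df, no continuity correction)."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    p_b = (2 * n_bb + n_ab) / (2 * n)
    if p_b in (0.0, 1.0):
        return 1.0  # monomorphic: trivially consistent
    exp = np.array([(1 - p_b) ** 2, 2 * p_b * (1 - p_b), p_b**2]) * n
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, 1))


@dataclass
class QcReport:
    """Per-marker QC metrics; ``kept`` is True iff every criterion passed."""

    table: pd.DataFrame  # id, call_rate, maf, hwe_p, position_known, kept, reason

    def removed_ids(self) -> list[str]:
        return self.table.loc[~self.table["kept"], "id"].tolist()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def qc_filter_markers(
    genotypes: GenotypeMatrix,
    call_rate_min: float = 0.90,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-6,
    hwe_rows: list[str] | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove markers failing call-rate / MAF / HWE / position criteria.

    ``hwe_rows`` optionally restricts the individuals entering the HWE
    test (default: all genotyped individuals).  Boundary semantics are
    strict inequalities for removal: a marker exactly at a threshold is
    kept.  The operation is idempotent.
    """
    if genotypes.n_markers == 0:
        raise ValueError("no markers")
    dos = genotypes.dosage
    hwe_dos = dos
    if hwe_rows is not None:
        hwe_dos = dos[[genotypes.individual_index(i) for i in hwe_rows], :]
    n_ind = dos.shape[0]
    rows = []
    keep_mask = np.zeros(genotypes.n_markers, dtype=bool)
    for j, m in enumerate(genotypes.markers.itertuples(index=False)):
        col = dos[:, j]
        called = col != MISSING
        call_rate = called.sum() / n_ind
        if called.any():
            p_b = col[called].mean() / 2.0
            maf = min(p_b, 1.0 - p_b)
        else:
            maf = 0.0
        hcol = hwe_dos[:, j]
        hcalled = hcol != MISSING
        hwe_p = hwe_chi_square_p(
            int((hcol[hcalled] == 0).sum()),
            int((hcol[hcalled] == 1).sum()),
            int((hcol[hcalled] == 2).sum()),
        )
        position_known = bool(m.bp > 0 and str(m.chrom) not in ("0", ""))
        reasons = []
        if call_rate < call_rate_min:
            reasons.append("call_rate")
        if maf < maf_min:
            reasons.append("maf")
        if hwe_p < hwe_p_min:
            reasons.append("hwe")
        if not position_known:
            reasons.append("position")
        kept = not reasons
        keep_mask[j] = kept
        rows.append(
            {
                "id": m.id,
                "call_rate": call_rate,
                "maf": maf,
                "hwe_p": hwe_p,
                "position_known": position_known,
                "kept": kept,
                "reason": ",".join(reasons),
            }
        )
    report = QcReport(pd.DataFrame(rows))
    return genotypes.subset(marker_mask=keep_mask), report


def differential_missingness_test(genotypes: GenotypeMatrix, phenotype: pd.Series) -> pd.Series:
    """Fisher exact p per marker for phenotype-associated missingness.

    ``phenotype`` maps individual id to ``affected``/``unaffected``
    (others are dropped).  The 2x2 table per marker is
    (missing, non-missing) x (affected, unaffected).
    """
    phen = phenotype.reindex(genotypes.individuals)
    aff = (phen == AFFECTED).to_numpy()
    unaff = (phen == UNAFFECTED).to_numpy()
    if aff.sum() == 0 or unaff.sum() == 0:
        raise ValueError("need both phenotype classes")
    use = aff | unaff
    dos = genotypes.dosage[use, :]
    is_aff = aff[use]
    pvals = []
    for j in range(genotypes.n_markers):
        miss = dos[:, j] == MISSING
        table = [
            [int((miss & is_aff).sum()), int((miss & ~is_aff).sum())],
            [int((~miss & is_aff).sum()), int((~miss & ~is_aff).sum())],
        ]
        pvals.append(float(stats.fisher_exact(table, alternative="two-sided")[1]))
    return pd.Series(pvals, index=genotypes.markers["id"].tolist(), name="test_missing_p")
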