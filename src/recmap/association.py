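"""Founder-origin inference and the per-marker association scan.

In a two-founder full-sib F2, each F2 chromosome is a mosaic of
founder-line-A and founder-line-B segments.  Origins are inferred per
individual with a four-state hidden Markov model over the ordered pair
of gamete origins: transitions follow the Haldane map (recombination
fraction ``0.5 * (1 - exp(-2d))`` per gamete for map distance ``d``
Morgans) and emissions come from the founder genotypes (a line's
alt-allele probability at a marker is half the founder's dosage, so
markers fixed for alternate alleles in the two founders force the
origin).  Posterior-decoded origins below the confidence threshold are
labelled unknown.

The scan regresses the binary phenotype on line-B origin dosage (0/1/2)
per marker and reports the slope t statistic with a Bonferroni threshold
``alpha / N`` over the ``N`` markers actually tested; a Welch two-group
variant (homozygous line-A origin vs homozygous line-B origin) is
available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import AFFECTED, MISSING, UNAFFECTED, GenotypeMatrix, Pedigree

ORIGIN_A = 0
ORIGIN_B = 1
ORIGIN_UNKNOWN = -1


@dataclass
class FounderOriginMatrix:
    """Per individual x marker ordered pair of founder-line origins.

    ``origins`` is int8 of shape (n_individuals, n_markers, 2) over
    {0 = line A, 1 = line B, -1 = unknown}; the pair order is
    (gamete from sire, gamete from dam).  Note that for dosage data the
    two gametes of an F2 are not individually identifiable (both F1
    parents carry one chromosome of each line), so only the line-B
    dosage is a fully identified quantity.
    """

    individuals: list[str]
    marker_ids: list[str]
    origins: np.ndarray
    dosage_calls: np.ndarray | None = None

    def subset_markers(self, marker_ids: list[str]) -> "FounderOriginMatrix":
        cols = [self.marker_ids.index(m) for m in marker_ids]
        return FounderOriginMatrix(
            individuals=list(self.individuals),
            marker_ids=list(marker_ids),
            origins=self.origins[:, cols, :].copy(),
            dosage_calls=None if self.dosage_calls is None else self.dosage_calls[:, cols].copy(),
        )

    def b_dosage(self) -> np.ndarray:
        """Count of line-B gametes (0/1/2); NaN where unassignable.

        When the matrix was posterior-decoded, dosage comes from the
        dosage-class posterior (identifiable even where the ordered
        gamete assignment is not); otherwise it is derived from the
        ordered origins.
        """
        if self.dosage_calls is not None:
            return self.dosage_calls
        known = (self.origins != ORIGIN_UNKNOWN).all(axis=2)
        dos = self.origins.sum(axis=2).astype(float)
        dos[~known] = np.nan
        return dos


def _haldane_r(d_morgans: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))


def infer_founder_origin(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    error_rate: float = 0.01,
    posterior_threshold: float = 0.95,
    cm_per_mb: float = 1.0,
) -> FounderOriginMatrix:
    """Infer founder-line origins for every individual in the pedigree.

    F0 individuals are homozygous for their own line label (line A = the
    F0 sire of the F1s, line B = the F0 dam) and F1s carry one chromosome
    of each line; F2 origins are posterior-decoded from the HMM.
    """
    founders = pedigree.founders()
    if len(founders) != 2:
        raise ValueError(f"need exactly 2 F0 founders, found {len(founders)}")
    f1s = pedigree.ids_of(generation="F1")
    if not f1s:
        raise ValueError("pedigree has no F1 generation")
    sire_f0, dam_f0 = pedigree.parents_of(f1s[0])
    if sire_f0 not in founders or dam_f0 not in founders:
        raise ValueError("F1 parents are not the F0 founders")

    n_markers = genotypes.n_markers
    markers = genotypes.markers
    dos = genotypes.dosage

    def line_freq(f0_id: str) -> np.ndarray:
        row = dos[genotypes.individual_index(f0_id), :].astype(float)
        p = row / 2.0
        p[row == MISSING] = 0.5
        return p

    p_alt = np.stack([line_freq(sire_f0), line_freq(dam_f0)])  # (2, m)

    # state order: (A,A), (A,B), (B,A), (B,B)
    state_pairs = [(0, 0), (0, 1), (1, 0), (1, 1)]
    em_true = np.empty((n_markers, 4, 3))
    for s, (o1, o2) in enumerate(state_pairs):
        p1, p2 = p_alt[o1], p_alt[o2]
        em_true[:, s, 0] = (1 - p1) * (1 - p2)
        em_true[:, s, 1] = p1 * (1 - p2) + (1 - p1) * p2
        em_true[:, s, 2] = p1 * p2
    e = error_rate
    em = (1 - e) * em_true + (e / 2.0) * (1 - em_true)

    # per-gap transition matrices from map distance (cM if present, else bp)
    cm = markers["cm"].to_numpy(dtype=float)
    if np.all(cm == 0):
        cm = markers["bp"].to_numpy(dtype=float) / 1e6 * cm_per_mb
    chrom = markers["chrom"].to_numpy()
    d = np.diff(cm) / 100.0
    d[d < 0] = 0.0
    new_chrom = chrom[1:] != chrom[:-1]
    r = _haldane_r(d)
    r[new_chrom] = 0.5  # unlinked across chromosome boundaries
    # 4-state transition = per-gamete 2x2 Kronecker product
    trans = np.empty((n_markers - 1, 4, 4))
    for s, (a1, a2) in enumerate(state_pairs):
        for t, (b1, b2) in enumerate(state_pairs):
            p1 = np.where(a1 == b1, 1 - r, r)
            p2 = np.where(a2 == b2, 1 - r, r)
            trans[:, s, t] = p1 * p2

    origins = np.full((genotypes.n_individuals, n_markers, 2), ORIGIN_UNKNOWN, dtype=np.int8)
    dosage_calls = np.full((genotypes.n_individuals, n_markers), np.nan)
    ped = pedigree.table.set_index("iid")

    f2_rows = []
    for i, iid in enumerate(genotypes.individuals):
        if iid not in ped.index:
            continue
        gen = ped.loc[iid, "generation"]
        if gen == "F0":
            lab = ORIGIN_A if iid == sire_f0 else ORIGIN_B
            origins[i, :, :] = lab
            dosage_calls[i, :] = 2 * lab
        elif gen == "F1":
            origins[i, :, 0] = ORIGIN_A
            origins[i, :, 1] = ORIGIN_B
            dosage_calls[i, :] = 1.0
        else:
            f2_rows.append(i)

    if f2_rows:
        obs = dos[f2_rows, :]  # (k, m)
        k = len(f2_rows)
        # emission likelihood per individual/marker/state; missing -> 1
        lik = np.ones((k, n_markers, 4))
        valid = obs != MISSING
        # gather: lik[i,j,s] = em[j, s, obs[i,j]]
        for s in range(4):
            lik[:, :, s] = np.where(valid, em[np.arange(n_markers)[None, :], s, np.clip(obs, 0, 2)], 1.0)

        # scaled forward-backward shared across individuals
        alpha = np.empty((k, n_markers, 4))
        scale = np.empty((k, n_markers))
        a = lik[:, 0, :] * 0.25
        scale[:, 0] = a.sum(axis=1)
        alpha[:, 0, :] = a / scale[:, 0][:, None]
        for j in range(1, n_markers):
            a = (alpha[:, j - 1, :] @ trans[j - 1]) * lik[:, j, :]
            scale[:, j] = a.sum(axis=1)
            alpha[:, j, :] = a / scale[:, j][:, None]
        beta = np.empty((k, n_markers, 4))
        beta[:, -1, :] = 1.0
        for j in range(n_markers - 2, -1, -1):
            b = (beta[:, j + 1, :] * lik[:, j + 1, :]) @ trans[j].T
            beta[:, j, :] = b / scale[:, j + 1][:, None]
        post = alpha * beta
        post = post / post.sum(axis=2, keepdims=True)

        thr = posterior_threshold
        # line-B dosage classes: P(0) = (A,A); P(1) = (A,B)+(B,A); P(2) = (B,B)
        p_dos = np.stack(
            [post[:, :, 0], post[:, :, 1] + post[:, :, 2], post[:, :, 3]], axis=2
        )
        best = p_dos.argmax(axis=2).astype(float)
        best[p_dos.max(axis=2) < thr] = np.nan
        dosage_calls[f2_rows, :] = best

        # ordered per-gamete marginals; unassignable where the two gametes
        # cannot be told apart (heterozygous-origin stretches)
        p_g1_b = post[:, :, 2] + post[:, :, 3]
        p_g2_b = post[:, :, 1] + post[:, :, 3]
        for g, p_b in enumerate((p_g1_b, p_g2_b)):
            call = np.full(p_b.shape, ORIGIN_UNKNOWN, dtype=np.int8)
            call[p_b >= thr] = ORIGIN_B
            call[p_b <= 1 - thr] = ORIGIN_A
            origins[np.array(f2_rows)[:, None], np.arange(n_markers)[None, :], g] = call

    return FounderOriginMatrix(
        individuals=list(genotypes.individuals),
        marker_ids=markers["id"].tolist(),
        origins=origins,
        dosage_calls=dosage_calls,
    )


@dataclass
class AssociationResult:
    """Per-marker scan results with the Bonferroni threshold alpha/N."""

    table: pd.DataFrame  # id, chrom, bp, n_used, t, p, significant
    n_tests: int
    alpha: float

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_tests

    def significant_ids(self) -> list[str]:
        return self.table.loc[self.table["significant"], "id"].tolist()

    def top_marker(self) -> pd.Series:
        tested = self.table.dropna(subset=["p"])
        return tested.loc[tested["p"].idxmin()]


def origin_association_scan(
    origins: FounderOriginMatrix,
    phenotype: pd.Series,
    genotypes: GenotypeMatrix | None = None,
    alpha: float = 0.05,
    max_unknown_frac: float = 0.5,
    method: str = "trend",
    f2_ids: list[str] | None = None,
) -> AssociationResult:
    """Scan markers for association between founder origin and phenotype.

    ``phenotype`` maps individual id to affected/unaffected; individuals
    outside both classes are ignored.  ``f2_ids`` restricts the scan to
    the segregating generation (recommended: F0/F1 origins are constant
    by construction).  Markers with unknown origin in more than
    ``max_unknown_frac`` of the scanned individuals, or with constant
    origin dosage, are skipped and excluded from N.
    """
    if method not in ("trend", "welch"):
        raise ValueError(f"method={method!r} unknown")
    ids = f2_ids if f2_ids is not None else origins.individuals
    rows_idx = [origins.individuals.index(i) for i in ids]
    phen = phenotype.reindex(ids)
    y_all = np.where(phen == AFFECTED, 1.0, np.where(phen == UNAFFECTED, 0.0, np.nan))
    if np.nanstd(y_all) == 0 or np.all(np.isnan(y_all)):
        raise ValueError("phenotype constant or absent")
    dos_all = origins.b_dosage()[rows_idx, :]
    n_markers = len(origins.marker_ids)

    if genotypes is not None:
        meta = genotypes.markers.set_index("id").loc[origins.marker_ids]
        chroms = meta["chrom"].tolist()
        bps = meta["bp"].tolist()
    else:
        chroms = [""] * n_markers
        bps = [0] * n_markers

    recs = []
    for j in range(n_markers):
        d = dos_all[:, j]
        mask = ~np.isnan(d) & ~np.isnan(y_all)
        n_used = int(mask.sum())
        rec = {
            "id": origins.marker_ids[j],
            "chrom": chroms[j],
            "bp": bps[j],
            "n_used": n_used,
            "t": np.nan,
            "p": np.nan,
        }
        if n_used == 0 or 1 - n_used / len(ids) > max_unknown_frac:
            recs.append(rec)
            continue
        x, y = d[mask], y_all[mask]
        if np.ptp(x) == 0:
            recs.append(rec)
            continue
        if method == "trend":
            res = stats.linregress(x, y)
            if res.stderr == 0:
                t = np.inf if res.slope != 0 else 0.0
                p = 0.0 if res.slope != 0 else 1.0
            else:
                t = res.slope / res.stderr
                p = res.pvalue
        else:
            g0, g2 = y[x == 0], y[x == 2]
            if len(g0) < 2 or len(g2) < 2:
                recs.append(rec)
                continue
            t, p = stats.ttest_ind(g2, g0, equal_var=False)
        rec["t"], rec["p"] = float(t), float(p)
        recs.append(rec)

    table = pd.DataFrame(recs)
    n_tests = int(table["p"].notna().sum())
    if n_tests == 0:
        raise ValueError("no testable markers")
    thr = alpha / n_tests
    table["significant"] = table["p"].notna() & (table["p"] <= thr)
    return AssociationResult(table=table, n_tests=n_tests, alpha=alpha)
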