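"""Synthetic inputs with planted truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* ``simulate_f2_cross`` — a two-founder full-sib F2 intercross on one
  chromosome.  Meioses place crossovers as a Poisson process under the
  Haldane map (default 1 cM/Mb, no interference).  The causal mutation
  rides on a single founder-line-B haplotype; with full penetrance an F2
  is affected iff it inherited two copies of that haplotype at the
  causal position.  Chip noise is a dosage-flip error plus independent
  missingness.
* ``simulate_trio_variants`` — capture-resequencing calls for one
  affected offspring and its two carrier parents plus a 24-animal panel,
  with one planted protein-truncating variant that satisfies the full
  recessive exclusion cascade and background variants in configurable
  category proportions.
* ``simulate_counts`` — two-library digital expression counts under
  Poisson sampling with planted fold changes.
* ``simulate_ranked_lists`` — correlated ranked gene lists with planted
  signal genes.

All generators are pure functions of (seed, parameters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GT_HET, GT_HOMALT, GT_HOMREF
from .types import AFFECTED, MISSING, UNAFFECTED, GenotypeMatrix, Interval, Pedigree

# founder haplotype labels: 0,1 = line A chromosomes; 2,3 = line B chromosomes.
# Label 2 (the first line-B chromosome) carries the causal mutation.
_MUTANT_HAP = 2


@dataclass
class SimTruth:
    """Planted truth serialized alongside simulated outputs.

    Only the fields relevant to the generating function are populated.
    ``origins`` holds founder-line labels (0 = line A, 1 = line B) per F2
    individual x marker x gamete.
    """

    causal_chrom: str | None = None
    causal_bp: int | None = None
    causal_variant_id: str | None = None
    carrier_copies: dict[str, int] = field(default_factory=dict)
    affected_ids: list[str] = field(default_factory=list)
    f2_ids: list[str] = field(default_factory=list)
    origins: np.ndarray | None = None
    crossovers: dict[str, list[int]] = field(default_factory=dict)
    de_log2fc: dict[str, float] = field(default_factory=dict)
    signal_genes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "causal_chrom": self.causal_chrom,
            "causal_bp": self.causal_bp,
            "causal_variant_id": self.causal_variant_id,
            "carrier_copies": self.carrier_copies,
            "affected_ids": self.affected_ids,
            "f2_ids": self.f2_ids,
            "origins": None if self.origins is None else self.origins.tolist(),
            "crossovers": self.crossovers,
            "de_log2fc": self.de_log2fc,
            "signal_genes": self.signal_genes,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("origins") is not None:
            doc["origins"] = np.asarray(doc["origins"], dtype=np.int8)
        return cls(**doc)


# ---------------------------------------------------------------------------
# F2 intercross


def _meiosis(
    alleles: np.ndarray,  # (2, n_markers)
    labels: np.ndarray,  # (2, n_markers)
    labels_at_causal: tuple[int, int],
    positions_bp: np.ndarray,
    chrom_length_bp: int,
    causal_bp: int,
    morgans: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, int, list[int]]:
    """One gamete from a chromosome pair; crossovers Poisson (Haldane)."""
    n_co = rng.poisson(morgans)
    co = np.sort(rng.integers(1, chrom_length_bp + 1, size=n_co))
    start = int(rng.integers(2))
    parity = np.searchsorted(co, positions_bp, side="left") % 2
    which = (start + parity) % 2
    idx = np.arange(len(positions_bp))
    g_alleles = alleles[which, idx]
    g_labels = labels[which, idx]
    which_c = (start + np.searchsorted(co, causal_bp, side="left") % 2) % 2
    return g_alleles, g_labels, labels_at_causal[int(which_c)], co.tolist()


def simulate_f2_cross(
    seed: int,
    n_f2: int = 75,
    chrom_length_bp: int = 100_000_000,
    n_markers: int = 1000,
    founder_divergence: float = 0.3,
    genotype_error_rate: float = 0.002,
    missing_rate: float = 0.02,
    causal_bp: int | None = None,
    cm_per_mb: float = 1.0,
    chrom: str = "18",
) -> tuple[Pedigree, GenotypeMatrix, SimTruth]:
    """Simulate a full-sib F2 intercross segregating a recessive locus.

    Two divergent founders (per-marker line allele frequencies follow a
    Balding-Nichols model with F_ST = ``founder_divergence``) produce two
    F1s, which are full-sib mated to give ``n_f2`` offspring.  The causal
    mutation sits on one chromosome of the line-B founder at
    ``causal_bp`` (default: mid-chromosome); an F2 is affected iff both
    of its gametes descend from that chromosome there.
    """
    if n_markers < 2:
        raise ValueError("n_markers must be >= 2")
    if causal_bp is None:
        causal_bp = chrom_length_bp // 2
    if not (1 <= causal_bp <= chrom_length_bp):
        raise ValueError("causal_bp outside chromosome")
    rng = np.random.default_rng(seed)

    positions = np.sort(rng.choice(np.arange(1, chrom_length_bp + 1), size=n_markers, replace=False))
    morgans = chrom_length_bp / 1e6 * cm_per_mb / 100.0

    p_anc = rng.uniform(0.1, 0.9, size=n_markers)
    f = founder_divergence
    if f <= 0:
        p_line = np.stack([p_anc, p_anc])
    elif f >= 1:
        p_line = np.stack([(rng.random(n_markers) < p_anc).astype(float) for _ in range(2)])
    else:
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        p_line = np.stack([rng.beta(a, b), rng.beta(a, b)])

    # founder haplotypes: line A -> labels 0,1; line B -> labels 2,3
    founder_haps = np.stack(
        [(rng.random(n_markers) < p_line[k // 2]).astype(np.int8) for k in range(4)]
    )

    def f0_chrom_pair(line: int):
        labs = np.array([2 * line, 2 * line + 1], dtype=np.int8)
        alleles = founder_haps[labs]
        labels = np.repeat(labs[:, None], n_markers, axis=1)
        return alleles, labels, (int(labs[0]), int(labs[1]))

    f0a = f0_chrom_pair(0)
    f0b = f0_chrom_pair(1)

    crossovers: dict[str, list[int]] = {}

    def make_f1(name: str):
        pat = _meiosis(*f0a, positions, chrom_length_bp, causal_bp, morgans, rng)
        # the maternal gamete must carry the mutant line-B chromosome at the
        # causal position, else the family could not segregate the disorder
        while True:
            mat = _meiosis(*f0b, positions, chrom_length_bp, causal_bp, morgans, rng)
            if mat[2] == _MUTANT_HAP:
                break
        crossovers[f"{name}.pat"] = pat[3]
        crossovers[f"{name}.mat"] = mat[3]
        alleles = np.stack([pat[0], mat[0]])
        labels = np.stack([pat[1], mat[1]])
        return alleles, labels, (pat[2], mat[2])

    f1_sire = make_f1("F1_1")
    f1_dam = make_f1("F1_2")

    individuals = ["F0_A", "F0_B", "F1_1", "F1_2"] + [f"F2_{i + 1:03d}" for i in range(n_f2)]
    n_ind = len(individuals)
    dosage = np.zeros((n_ind, n_markers), dtype=np.int8)
    dosage[0] = f0a[0].sum(axis=0)
    dosage[1] = f0b[0].sum(axis=0)
    dosage[2] = f1_sire[0].sum(axis=0)
    dosage[3] = f1_dam[0].sum(axis=0)

    origins = np.zeros((n_f2, n_markers, 2), dtype=np.int8)
    carrier_copies: dict[str, int] = {"F0_A": 0, "F0_B": 1, "F1_1": 1, "F1_2": 1}
    phenotypes = {}
    for i in range(n_f2):
        iid = individuals[4 + i]
        g1 = _meiosis(*f1_sire, positions, chrom_length_bp, causal_bp, morgans, rng)
        g2 = _meiosis(*f1_dam, positions, chrom_length_bp, causal_bp, morgans, rng)
        crossovers[f"{iid}.pat"] = g1[3]
        crossovers[f"{iid}.mat"] = g2[3]
        dosage[4 + i] = g1[0] + g2[0]
        origins[i, :, 0] = g1[1] // 2
        origins[i, :, 1] = g2[1] // 2
        copies = int(g1[2] == _MUTANT_HAP) + int(g2[2] == _MUTANT_HAP)
        carrier_copies[iid] = copies
        phenotypes[iid] = AFFECTED if copies == 2 else UNAFFECTED

    # chip noise: dosage flip, then independent missingness
    if genotype_error_rate > 0:
        err = rng.random(dosage.shape) < genotype_error_rate
        shift = rng.integers(1, 3, size=dosage.shape)
        dosage = np.where(err, (dosage + shift) % 3, dosage).astype(np.int8)
    if missing_rate > 0:
        dosage[rng.random(dosage.shape) < missing_rate] = MISSING

    rows = [
        {"iid": "F0_A", "sire": "0", "dam": "0", "sex": 1, "generation": "F0", "phenotype": UNAFFECTED},
        {"iid": "F0_B", "sire": "0", "dam": "0", "sex": 2, "generation": "F0", "phenotype": UNAFFECTED},
        {"iid": "F1_1", "sire": "F0_A", "dam": "F0_B", "sex": 1, "generation": "F1", "phenotype": UNAFFECTED},
        {"iid": "F1_2", "sire": "F0_A", "dam": "F0_B", "sex": 2, "generation": "F1", "phenotype": UNAFFECTED},
    ]
    for i in range(n_f2):
        iid = individuals[4 + i]
        rows.append(
            {
                "iid": iid,
                "sire": "F1_1",
                "dam": "F1_2",
                "sex": int(1 + (i % 2)),
                "generation": "F2",
                "phenotype": phenotypes[iid],
            }
        )
    pedigree = Pedigree(pd.DataFrame(rows))

    markers = pd.DataFrame(
        {
            "id": [f"M{j + 1:05d}" for j in range(n_markers)],
            "chrom": chrom,
            "cm": positions / 1e6 * cm_per_mb,
            "bp": positions,
            "allele_a": "A",
            "allele_b": "C",
        }
    )
    genotypes = GenotypeMatrix(markers, individuals, dosage)
    truth = SimTruth(
        causal_chrom=chrom,
        causal_bp=int(causal_bp),
        carrier_copies=carrier_copies,
        affected_ids=[i for i in individuals[4:] if phenotypes[i] == AFFECTED],
        f2_ids=individuals[4:],
        origins=origins,
        crossovers=crossovers,
    )
    return pedigree, genotypes, truth


# ---------------------------------------------------------------------------
# Trio + panel variant calls

_DEFAULT_CATEGORY_PROBS = {
    "het_affected": 0.30,       # heterozygous in the affected: fails step 1
    "parent_homalt": 0.15,      # a parent homozygous-alt: fails step 2
    "trio_inconsistent": 0.10,  # homalt child of homref x homref: fails step 3
    "noncoding": 0.25,          # trio-compliant but non-coding: fails step 4
    "coding_survivor": 0.15,    # survives steps 1-4, removed by the panel screen
    "qc_fail": 0.05,            # out-of-band depth or low quality
}


def simulate_trio_variants(
    seed: int,
    interval: Interval,
    n_background: int = 100,
    planted_effect: str = "coding_truncating",
    category_probs: dict[str, float] | None = None,
    panel_size: int = 24,
) -> tuple[pd.DataFrame, SimTruth]:
    """Trio + panel variant calls with one planted causal variant.

    The planted variant is homozygous-alt in the affected offspring,
    heterozygous in both parents, protein-truncating, and absent from the
    panel; with default proportions roughly 15% of background variants
    survive the Mendelian cascade but segregate in the panel at allele
    frequency > 0.1 and fall to the population screen.  Per-site depths
    are drawn inside the callable band (N(45, 10) clipped to [10, 70])
    — unique post-deduplication depth, not raw coverage.
    """
    if interval.length_bp < 10:
        raise ValueError("interval too short")
    rng = np.random.default_rng(seed)
    probs = dict(_DEFAULT_CATEGORY_PROBS if category_probs is None else category_probs)
    cats = list(probs)
    pvec = np.array([probs[c] for c in cats], dtype=float)
    pvec = pvec / pvec.sum()

    # positions on a >=6 bp grid so only deliberate fodder trips the spacing rule
    grid = np.arange(interval.start_bp, interval.end_bp + 1, 6)
    n_total = n_background + 1
    if len(grid) < n_total:
        raise ValueError("interval too short for requested variant count")
    pos = np.sort(rng.choice(grid, size=n_total, replace=False))
    planted_idx = int(np.argmin(np.abs(pos - (interval.start_bp + interval.end_bp) // 2)))

    panel = [f"P{k + 1:02d}" for k in range(panel_size)]
    bases = np.array(list("ACGT"))
    genes = [f"gene{k + 1:02d}" for k in range(8)]
    rows = []
    for i, p in enumerate(pos):
        ref, alt = rng.choice(bases, size=2, replace=False)
        row = {
            "chrom": interval.chrom,
            "pos": int(p),
            "id": f"var{i + 1:04d}",
            "ref": str(ref),
            "alt": str(alt),
            "qual": float(np.clip(rng.normal(60, 10), 25, 99)),
            "depth": float(int(np.clip(rng.normal(45, 10), 10, 70))),
            "gene": genes[i % len(genes)],
            "func_class": "coding_syn",
        }
        if i == planted_idx:
            row.update(
                id="var_planted",
                gene="geneT",
                func_class=planted_effect,
                gt_affected=GT_HOMALT,
                gt_sire=GT_HET,
                gt_dam=GT_HET,
            )
            for s in panel:
                row[f"gt_{s}"] = GT_HOMREF
        else:
            cat = cats[int(rng.choice(len(cats), p=pvec))]
            if cat == "het_affected":
                row.update(gt_affected=GT_HET, gt_sire=rng.choice([GT_HET, GT_HOMREF]), gt_dam=GT_HET)
            elif cat == "parent_homalt":
                row.update(gt_affected=GT_HOMALT, gt_sire=GT_HOMALT, gt_dam=GT_HET)
            elif cat == "trio_inconsistent":
                row.update(gt_affected=GT_HOMALT, gt_sire=GT_HOMREF, gt_dam=GT_HOMREF)
            elif cat == "noncoding":
                row.update(gt_affected=GT_HOMALT, gt_sire=GT_HET, gt_dam=GT_HET, func_class="noncoding")
            elif cat == "coding_survivor":
                row.update(
                    gt_affected=GT_HOMALT,
                    gt_sire=GT_HET,
                    gt_dam=GT_HET,
                    func_class=str(rng.choice(["coding_nonsyn", "coding_truncating"], p=[0.8, 0.2])),
                )
            elif cat == "qc_fail":
                row.update(gt_affected=GT_HOMALT, gt_sire=GT_HET, gt_dam=GT_HET)
                mode = rng.choice(["low_depth", "high_depth", "low_qual"])
                if mode == "low_depth":
                    row["depth"] = float(rng.integers(1, 6))
                elif mode == "high_depth":
                    row["depth"] = float(rng.integers(71, 160))
                else:
                    row["qual"] = float(rng.integers(2, 20))
            else:
                raise ValueError(f"unknown category {cat!r}")
            if cat == "coding_survivor":
                # cascade survivors segregate in the panel at realized alt
                # frequency > 0.1; condition the draw on that property
                freq = rng.uniform(0.15, 0.5)
                while True:
                    gs = rng.binomial(2, freq, size=panel_size)
                    if gs.sum() > 0.1 * 2 * panel_size:
                        break
            else:
                freq = rng.uniform(0.0, 0.3)
                gs = rng.binomial(2, freq, size=panel_size)
            for s, g in zip(panel, gs):
                row[f"gt_{s}"] = (GT_HOMREF, GT_HET, GT_HOMALT)[int(g)]
        rows.append(row)

    df = pd.DataFrame(rows)
    df.attrs["samples"] = ["affected", "sire", "dam"] + panel
    df.attrs["panel_samples"] = panel
    truth = SimTruth(
        causal_chrom=interval.chrom,
        causal_bp=int(pos[planted_idx]),
        causal_variant_id="var_planted",
    )
    return df, truth


# ---------------------------------------------------------------------------
# Two-library counts


def simulate_counts(
    seed: int,
    n_genes: int = 2000,
    library_sizes: tuple[int, int] = (2_000_000, 2_000_000),
    gene_length_range: tuple[int, int] = (200, 5000),
    n_de: int = 100,
    log2fc: float = 2.0,
):
    """Poisson two-library counts with ``n_de`` planted fold changes.

    Per-gene rates are proportional to expression x length; the first
    library is scaled to its target size and DE genes multiply the
    second-library rate by ``2**(+-log2fc)`` (random sign), so the
    realized second-library total drifts with the planted signal exactly
    as sequencing depth would.
    """
    from .expression import CountTable

    if n_de > n_genes:
        raise ValueError("n_de > n_genes")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(gene_length_range[0], gene_length_range[1] + 1, size=n_genes)
    expr = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base = expr * lengths
    lam1 = base / base.sum() * library_sizes[0]
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    fc = np.ones(n_genes)
    fc[de_idx] = 2.0 ** (signs * log2fc)
    lam2 = base / base.sum() * library_sizes[1] * fc
    x = rng.poisson(lam1)
    y = rng.poisson(lam2)
    gene_ids = [f"g{j + 1:05d}" for j in range(n_genes)]
    table = pd.DataFrame({"gene_id": gene_ids, "length_bp": lengths, "x": x, "y": y})
    truth = SimTruth(
        de_log2fc={gene_ids[j]: float(s * log2fc) for j, s in zip(de_idx, signs)}
    )
    return CountTable(table=table, samples=("wildtype", "mutant")), truth


# ---------------------------------------------------------------------------
# Correlated ranked lists


def simulate_ranked_lists(
    seed: int,
    n_genes: int = 200,
    n_lists: int = 3,
    signal_genes: int | list[str] = 10,
    concordance: float = 0.9,
    signal_boost: float = 3.0,
):
    """Ranked gene lists sharing a latent score with planted signal genes.

    Each list's score is ``c * base + sqrt(1 - c^2) * noise`` with
    ``c = concordance``; signal genes receive ``signal_boost`` on the
    shared base score.  ``concordance=1`` gives identical lists,
    ``concordance=0`` independent ones.
    """
    from .prioritize import RankedList

    if not (0.0 <= concordance <= 1.0):
        raise ValueError("concordance must be in [0, 1]")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{j + 1:04d}" for j in range(n_genes)]
    if isinstance(signal_genes, int):
        signal = list(rng.choice(gene_ids, size=signal_genes, replace=False))
    else:
        signal = list(signal_genes)
        if set(signal) - set(gene_ids):
            raise ValueError("signal genes outside universe")
    base = rng.normal(size=n_genes)
    boost = np.isin(gene_ids, signal) * signal_boost
    base = base + boost
    lists = []
    c = concordance
    for k in range(n_lists):
        noise = rng.normal(size=n_genes)
        score = c * base + np.sqrt(max(0.0, 1.0 - c**2)) * noise
        df = pd.DataFrame({"gene_id": gene_ids, "score": score})
        df = df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
        lists.append(RankedList(source=f"list{k + 1}", table=df))
    truth = SimTruth(signal_genes=sorted(signal))
    return lists, truth
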