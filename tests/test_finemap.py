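"""Shared-homozygosity scanning and recombinant refinement."""

import numpy as np
import pytest

import recmap
from recmap import Interval, MISSING
from recmap.association import ORIGIN_UNKNOWN, FounderOriginMatrix
from recmap.finemap import (
    interval_length_mb,
    refine_by_carrier_recombinants,
    shared_homozygosity_scan,
)

from conftest import make_genotypes


def _origins_with_dosage(individuals, marker_ids, dosage):
    dosage = np.asarray(dosage, dtype=float)
    origins = np.full((len(individuals), len(marker_ids), 2), ORIGIN_UNKNOWN, dtype=np.int8)
    return FounderOriginMatrix(list(individuals), list(marker_ids), origins, dosage)


class TestScan:
    def test_toy_matrix_single_run(self):
        # 3 affecteds homozygous-identical at markers 2-4 only
        dosage = [
            [1, 2, 0, 2, 1],
            [0, 2, 0, 2, 0],
            [2, 2, 0, 2, 1],
        ]
        gm = make_genotypes(dosage)
        segs = shared_homozygosity_scan(gm, ["I1", "I2", "I3"], bridge_markers=0)
        assert len(segs) == 1
        iv, hap = segs[0]
        assert (iv.start_bp, iv.end_bp) == (2000, 4000)
        assert iv.n_markers == 3
        assert hap.dosages == [2, 0, 2]

    def test_single_affected_gives_its_homozygous_runs(self):
        gm = make_genotypes([[2, 2, 1, 0, 0]])
        segs = shared_homozygosity_scan(gm, ["I1"], bridge_markers=0)
        spans = sorted((iv.start_bp, iv.end_bp) for iv, _ in segs)
        assert spans == [(1000, 2000), (4000, 5000)]

    def test_missing_compatible_vs_strict(self):
        dosage = [[2, MISSING, 2], [2, 2, 2]]
        gm = make_genotypes(dosage)
        segs = shared_homozygosity_scan(gm, ["I1", "I2"])
        assert (segs[0][0].start_bp, segs[0][0].end_bp) == (1000, 3000)
        strict = shared_homozygosity_scan(gm, ["I1", "I2"], matching="strict", min_markers=1, bridge_markers=0)
        assert all(iv.n_markers == 1 for iv, _ in strict)

    def test_bridges_isolated_discordant_marker(self):
        dosage = [
            [2, 2, 1, 2, 2],
            [2, 2, 2, 2, 2],
        ]
        gm = make_genotypes(dosage)
        segs = shared_homozygosity_scan(gm, ["I1", "I2"], bridge_markers=1)
        iv, hap = segs[0]
        assert (iv.start_bp, iv.end_bp) == (1000, 5000)
        assert hap.dosages[2] is None  # bridged marker has no resolved allele
        assert iv.n_markers == 4  # bridged marker not counted

    def test_invariant_to_affected_order(self):
        rng = np.random.default_rng(3)
        gm = make_genotypes(rng.integers(0, 3, size=(5, 30)))
        a = shared_homozygosity_scan(gm, ["I1", "I2", "I3"])
        b = shared_homozygosity_scan(gm, ["I3", "I1", "I2"])
        assert [(iv.start_bp, iv.end_bp) for iv, _ in a] == [
            (iv.start_bp, iv.end_bp) for iv, _ in b
        ]

    def test_no_affected_errors(self):
        gm = make_genotypes([[1, 1]])
        with pytest.raises(ValueError, match="affected"):
            shared_homozygosity_scan(gm, [])

    def test_seeded_cross_top_segment_contains_locus(self):
        hits = 0
        for seed in range(1, 6):
            ped, geno, truth = recmap.simulate_f2_cross(
                seed=seed, n_f2=75, genotype_error_rate=0.0, missing_rate=0.0
            )
            segs = shared_homozygosity_scan(geno, truth.affected_ids)
            hits += any(iv.contains(truth.causal_bp) for iv, _ in segs[:3])
        assert hits >= 4


def _refine_fixture():
    """10-marker interval; carrier C1's line-B chromosome is normal over
    markers 1-4 (homozygous-normal genotype), heterozygous elsewhere."""
    marker_dosage = {
        "affected": [2] * 10,
        "C1": [0, 0, 0, 0, 1, 1, 1, 1, 1, 1],
        "C2": [1, 1, 1, 1, 1, 1, 1, 1, 0, 0],
    }
    individuals = list(marker_dosage)
    gm = make_genotypes([marker_dosage[i] for i in individuals], individuals=individuals)
    segs = shared_homozygosity_scan(gm, ["affected"], bridge_markers=0)
    iv, hap = segs[0]
    origins = _origins_with_dosage(
        individuals, gm.markers["id"].tolist(), [[2] * 10, [1] * 10, [1] * 10]
    )
    return gm, origins, iv, hap


class TestRefine:
    def test_carrier_trims_normal_haplotype_segment(self):
        gm, origins, iv, hap = _refine_fixture()
        refined = refine_by_carrier_recombinants(iv, gm, origins, ["C1"], hap)
        assert refined.start_bp == 5000  # refined interval starts at marker 5
        assert refined.end_bp == iv.end_bp
        assert refined.provenance == "refined"

    def test_no_carriers_returns_interval_unchanged(self):
        gm, origins, iv, hap = _refine_fixture()
        refined = refine_by_carrier_recombinants(iv, gm, origins, [], hap)
        assert (refined.start_bp, refined.end_bp) == (iv.start_bp, iv.end_bp)

    def test_two_carriers_trim_opposite_ends(self):
        gm, origins, iv, hap = _refine_fixture()
        refined = refine_by_carrier_recombinants(iv, gm, origins, ["C1", "C2"], hap)
        assert (refined.start_bp, refined.end_bp) == (5000, 8000)

    def test_refinement_never_widens_and_is_contained(self):
        gm, origins, iv, hap = _refine_fixture()
        refined = refine_by_carrier_recombinants(iv, gm, origins, ["C1", "C2"], hap)
        assert iv.start_bp <= refined.start_bp <= refined.end_bp <= iv.end_bp

    def test_emptying_refinement_errors(self):
        gm, origins, iv, hap = _refine_fixture()
        # a "carrier" homozygous-normal everywhere contradicts the data
        bad = _origins_with_dosage(
            ["affected", "C1", "C2"], gm.markers["id"].tolist(), [[2] * 10, [0] * 10, [1] * 10]
        )
        with pytest.raises(ValueError, match="inconsistent"):
            refine_by_carrier_recombinants(iv, gm, bad, ["C1"], hap)

    def test_midpoint_boundary_extends_into_gap(self):
        gm, origins, iv, hap = _refine_fixture()
        inner = refine_by_carrier_recombinants(iv, gm, origins, ["C1"], hap, boundary="inner")
        mid = refine_by_carrier_recombinants(iv, gm, origins, ["C1"], hap, boundary="midpoint")
        assert mid.start_bp == (4000 + 5000) // 2
        assert mid.start_bp < inner.start_bp

    def test_truth_known_carriers_shrink_and_keep_locus(self):
        contains = 0
        ratios = []
        for seed in range(1, 11):
            ped, geno, truth = recmap.simulate_f2_cross(
                seed=seed, n_f2=75, genotype_error_rate=0.0, missing_rate=0.0
            )
            res = recmap.map_recessive_locus(ped, geno)
            carriers = [
                i for i, c in truth.carrier_copies.items() if c == 1 and i.startswith("F2")
            ] + ["F1_1", "F1_2"]
            assert len(carriers) >= 5
            chrom_geno = geno.subset(
                marker_mask=(geno.markers["chrom"] == "18").to_numpy()
            )
            refined = refine_by_carrier_recombinants(
                res.ibd_interval,
                chrom_geno,
                res.origins,
                carriers,
                res.disease_haplotype,
                anchor_bp=(res.ibd_interval.start_bp + res.ibd_interval.end_bp) // 2,
            )
            contains += refined.contains(truth.causal_bp)
            assert refined.length_bp <= res.ibd_interval.length_bp
            ratios.append(refined.length_bp / res.ibd_interval.length_bp)
        assert contains >= 9
        assert np.median(ratios) < 1.0


class TestIntervalLength:
    def test_printed_critical_region_is_two_megabases(self):
        iv = Interval(chrom="18", start_bp=48_877_373, end_bp=50_901_463)
        assert interval_length_mb(iv) == pytest.approx(2.024091, abs=1e-6)
        assert round(interval_length_mb(iv), 1) == 2.0

    def test_single_base_interval(self):
        iv = Interval(chrom="1", start_bp=100, end_bp=100)
        assert interval_length_mb(iv) == pytest.approx(1e-6)

    def test_linearity_under_span_doubling(self):
        a = Interval(chrom="1", start_bp=1, end_bp=1000)
        b = Interval(chrom="1", start_bp=1, end_bp=2000)
        assert interval_length_mb(b) == pytest.approx(
            2 * interval_length_mb(a), rel=1e-3
        )
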