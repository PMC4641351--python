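"""Informative alleles, concordance, dating, and the windowed genome scan."""

import itertools

import numpy as np
import pandas as pd
import pytest

from xpr1popgen.haplotypes import phase_homozygote_anchored
from xpr1popgen.introgression import (
    APPROXIMATE,
    LOWER_BOUND,
    DatingCalibration,
    MsatTable,
    RecombinationMap,
    ScanTrack,
    date_by_new_mutations,
    detect_outlier_region,
    find_informative_alleles,
    genotype_concordance,
    tract_length_age,
    windowed_scan,
)
from xpr1popgen.io import write_vcf


def small_msat(donor_freqs, other_freqs, n=10):
    """Two-population single-locus table with given allele frequencies."""
    rows = []
    for pop, freqs in (("donor", donor_freqs), ("other", other_freqs)):
        alleles = [a for a, f in freqs.items() for _ in range(int(round(f * 2 * n)))]
        for i in range(n):
            rows.append((f"{pop}{i}", pop, "msX", alleles[2 * i], alleles[2 * i + 1]))
    geno = pd.DataFrame(rows, columns=["sample_id", "population_id", "locus_id", "size1", "size2"])
    loci = pd.DataFrame({"locus_id": ["msX"], "chrom": ["chr1"], "pos": [1], "offset_bp": [0]})
    return MsatTable(loci=loci, genotypes=geno)


class TestInformativeAlleles:
    def test_fixture_informative_alleles(self, bundle):
        found = find_informative_alleles(
            bundle.msat, "Ira_AH", exclude_populations=["Fra_MC1", "Fra_MC2"]
        )
        assert [(a.locus_id, a.allele_size) for a in found] == [("ms6", 265), ("ms8", 157)]
        assert all(a.donor_frequency >= 0.5 for a in found)
        assert all(a.max_nondonor_frequency <= 0.05 for a in found)

    def test_shared_allele_rejected(self):
        msat = small_msat({265: 0.9, 263: 0.1}, {265: 0.4, 261: 0.6})
        assert find_informative_alleles(msat, "donor") == []

    def test_absent_elsewhere_selected(self):
        msat = small_msat({265: 0.9, 263: 0.1}, {261: 1.0})
        found = find_informative_alleles(msat, "donor")
        assert [(a.locus_id, a.allele_size) for a in found] == [("msX", 265)]

    def test_thresholds_hold_on_recount(self, rng):
        for _ in range(20):
            sizes = 200 + 2 * rng.integers(0, 8, size=(3, 2 * 8))
            rows = []
            for p, pop in enumerate(("donor", "otherA", "otherB")):
                for i in range(8):
                    rows.append((f"{pop}{i}", pop, "ms1", sizes[p, 2 * i], sizes[p, 2 * i + 1]))
            msat = MsatTable(
                loci=pd.DataFrame({"locus_id": ["ms1"], "chrom": ["c"], "pos": [1], "offset_bp": [0]}),
                genotypes=pd.DataFrame(rows, columns=["sample_id", "population_id", "locus_id", "size1", "size2"]),
            )
            for a in find_informative_alleles(msat, "donor", f_donor_min=0.4, f_other_max=0.1):
                donor = sizes[0]
                others = sizes[1:]
                assert (donor == a.allele_size).mean() >= 0.4
                assert max((o == a.allele_size).mean() for o in others) <= 0.1

    def test_missing_donor_is_an_error(self, bundle):
        with pytest.raises(ValueError, match="donor"):
            find_informative_alleles(bundle.msat, "Atlantis")


class TestConcordance:
    def test_thirteen_to_one_pattern(self, bundle, phased):
        catalogue, assignment = phased
        informative = find_informative_alleles(
            bundle.msat, "Ira_AH", exclude_populations=["Fra_MC1", "Fra_MC2"]
        )
        target = catalogue.label_for(bundle.haplotypes["III"].alleles)
        conc = genotype_concordance(
            bundle.msat, assignment, target, informative,
            populations=["Fra_MC1", "Fra_MC2"],
        )
        assert conc["n_homozygote_samples"] == 7
        assert conc["novel_allele_fraction"] == pytest.approx(1 / 14)
        assert conc["per_locus_fraction"] == {
            "ms6": pytest.approx(1 / 14), "ms8": pytest.approx(1 / 14)
        }

    def test_marginals_conserved(self, bundle, phased):
        catalogue, assignment = phased
        informative = find_informative_alleles(
            bundle.msat, "Ira_AH", exclude_populations=["Fra_MC1", "Fra_MC2"]
        )
        target = catalogue.label_for(bundle.haplotypes["III"].alleles)
        conc = genotype_concordance(bundle.msat, assignment, target, informative)
        assigned = {s for s, st in assignment.status.items() if st == "ASSIGNED"}
        rows = bundle.msat.genotypes[bundle.msat.genotypes["sample_id"].isin(assigned)]
        for locus, tab in conc["crosstabs"].items():
            n_alleles = 2 * (rows["locus_id"] == locus).sum()
            assert tab.to_numpy().sum() == n_alleles

    def test_planted_fraction_recovered(self):
        # 8 homozygotes, 16 chromosomes, exactly 4 carrying a novel size
        from xpr1popgen.haplotypes import ASSIGNED, HaplotypeAssignment
        from xpr1popgen.introgression import InformativeAllele

        samples = [f"h{i}" for i in range(8)]
        assignment = HaplotypeAssignment(
            status={s: ASSIGNED for s in samples},
            pairs={s: ("T", "T") for s in samples},
        )
        rows = []
        for i, s in enumerate(samples):
            a1 = 263 if i < 4 else 265  # four novel alleles out of sixteen
            rows.append((s, "pop", "ms6", a1, 265))
        msat = MsatTable(
            loci=pd.DataFrame({"locus_id": ["ms6"], "chrom": ["c"], "pos": [1], "offset_bp": [0]}),
            genotypes=pd.DataFrame(rows, columns=["sample_id", "population_id", "locus_id", "size1", "size2"]),
        )
        conc = genotype_concordance(
            msat, assignment, "T", [InformativeAllele("ms6", 265, 0.9, 0.0)]
        )
        assert conc["novel_allele_fraction"] == pytest.approx(0.25)

    def test_no_homozygotes_yields_null_with_warning(self, bundle, phased):
        catalogue, assignment = phased
        from xpr1popgen.introgression import InformativeAllele

        vi = catalogue.label_for(bundle.haplotypes["VI"].alleles)
        with pytest.warns(UserWarning, match="fraction undefined"):
            conc = genotype_concordance(
                bundle.msat, assignment, vi,
                [InformativeAllele("ms6", 265, 0.9, 0.0)],
                populations=["Fra_MC1", "Fra_MC2"],
            )
        assert conc["novel_allele_fraction"] is None


class TestDating:
    def test_published_arithmetic(self):
        cal = DatingCalibration(anchors=[(0.05, 1200.0)], mode="nearest_anchor")
        est = date_by_new_mutations(0.07, cal)
        assert est.generations == 1200.0
        assert est.years == pytest.approx(400.0)
        assert 200 <= est.years <= 900  # "several hundred years"

    def test_zero_fraction_is_a_lower_bound(self):
        cal = DatingCalibration(anchors=[(0.05, 1200.0)])
        est = date_by_new_mutations(0.0, cal)
        assert est.generations == 0.0
        assert LOWER_BOUND in est.flags

    def test_linear_mode_proportional(self):
        cal = DatingCalibration(anchors=[(0.05, 1200.0)], mode="linear")
        est = date_by_new_mutations(0.10, cal)
        assert est.generations == pytest.approx(2400.0)
        assert est.years == pytest.approx(800.0)

    @pytest.mark.parametrize("mode", ["nearest_anchor", "linear"])
    def test_monotone_in_fraction(self, mode):
        cal = DatingCalibration(
            anchors=[(0.02, 400.0), (0.05, 1200.0), (0.2, 4000.0)], mode=mode
        )
        fr = np.linspace(0.0, 0.5, 40)
        gens = [cal.generations_for(f) for f in fr]
        assert all(b >= a for a, b in zip(gens, gens[1:]))

    def test_empty_calibration_rejected(self):
        with pytest.raises(ValueError):
            DatingCalibration(anchors=[])


class TestWindowedScan:
    def test_closed_form_pi_and_empty_windows(self, tmp_path, rng):
        n, nsites = 20, 50
        hap = np.zeros((n, nsites), dtype=int)
        for j in range(nsites):
            hap[rng.choice(n, 10, replace=False), j] = 1
        positions = np.sort(rng.choice(np.arange(1, 10_001), nsites, replace=False))
        samples = [f"s{i}" for i in range(10)]
        path = tmp_path / "scan.vcf"
        write_vcf(path, hap, positions, samples, contig_length=20_000)
        track = windowed_scan(str(path), samples, window_bp=1000)
        assert len(track.windows) == 20
        per_site = 2 * 10 * 10 / (20 * 19)
        for _, w in track.windows.iterrows():
            assert w["pi_per_site"] == pytest.approx(w["S"] * per_site / 1000, abs=1e-12)
            if w["S"] == 0:
                assert w["pi_per_site"] == 0.0 and pd.isna(w["tajima_d"])

    def test_window_count_arithmetic(self, tmp_path):
        hap = np.array([[0, 1], [1, 0]])
        write_vcf(tmp_path / "w.vcf", hap, [5, 10], ["s0"], contig_length=1_000_000)
        track = windowed_scan(str(tmp_path / "w.vcf"), ["s0"], window_bp=1000)
        assert len(track.windows) == 1000

    def test_pi_conservation_against_pair_counting(self, tmp_path, rng):
        n, nsites = 12, 40
        hap = (rng.random((n, nsites)) < rng.uniform(0.1, 0.9, nsites)).astype(int)
        positions = np.sort(rng.choice(np.arange(1, 7001), nsites, replace=False))
        samples = [f"s{i}" for i in range(6)]
        path = tmp_path / "c.vcf"
        write_vcf(path, hap, positions, samples, contig_length=7000)
        track = windowed_scan(str(path), samples, window_bp=1000)
        widths = track.windows["end"] - track.windows["start"]
        total = float((track.windows["pi_per_site"] * widths).sum())
        brute = np.mean(
            [(hap[a] != hap[b]).sum() for a, b in itertools.combinations(range(n), 2)]
        )
        assert total == pytest.approx(float(brute), abs=1e-9)

    def test_multiallelic_records_skipped(self, tmp_path):
        path = tmp_path / "m.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n##contig=<ID=chr1,length=2000>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\n")
            fh.write("chr1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t0|1\t1|2\n")
            fh.write("chr1\t200\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\n")
        track = windowed_scan(str(path), ["s0", "s1"], window_bp=1000)
        assert track.skipped_records == 1
        assert track.windows["S"].sum() == 1

    def test_unknown_samples_rejected(self, tmp_path):
        hap = np.array([[0, 1], [1, 0]])
        write_vcf(tmp_path / "u.vcf", hap, [5, 10], ["s0"])
        with pytest.raises(ValueError, match="named samples"):
            windowed_scan(str(tmp_path / "u.vcf"), ["who"], window_bp=1000)


def synthetic_track(n_windows, elevated, window=1000, chrom="chr1",
                    base_pi=5e-4, hi_pi=3e-3, base_d=-0.5, hi_d=1.8):
    rows = []
    for w in range(n_windows):
        hot = elevated[0] <= w < elevated[1]
        rows.append((chrom, w * window, (w + 1) * window, 5,
                     hi_pi if hot else base_pi, hi_d if hot else base_d))
    return ScanTrack(
        windows=pd.DataFrame(
            rows, columns=["chrom", "start", "end", "S", "pi_per_site", "tajima_d"]
        ),
        n_chromosomes=20,
    )


class TestRegionCalling:
    def test_flat_track_gives_no_region(self):
        track = synthetic_track(100, (0, 0), hi_pi=0, hi_d=0, base_d=0.0)
        call = detect_outlier_region(track, ("chr1", 40_000, 42_000))
        assert call.empty

    def test_planted_300kb_block(self):
        # 300 elevated windows of 10,000 around the focal gene
        track = synthetic_track(10_000, (4850, 5150))
        call = detect_outlier_region(track, ("chr1", 4_999_000, 5_001_000))
        assert abs(call.span_bp - 300_000) <= 1000

    def test_megabase_block_is_ten_times_larger(self):
        track = synthetic_track(30_000, (13_500, 16_500))
        call = detect_outlier_region(
            track, ("chr1", 14_999_000, 15_001_000), pi_quantile=0.85
        )
        small = synthetic_track(10_000, (4850, 5150))
        small_call = detect_outlier_region(small, ("chr1", 4_999_000, 5_001_000))
        assert call.span_bp >= 10 * small_call.span_bp

    def test_bitwise_reproducible(self):
        track = synthetic_track(5000, (2400, 2700))
        a = detect_outlier_region(track, ("chr1", 2_500_000, 2_510_000))
        b = detect_outlier_region(track, ("chr1", 2_500_000, 2_510_000))
        assert (a.chrom, a.start, a.end, a.span_bp) == (b.chrom, b.start, b.end, b.span_bp)

    def test_focal_interval_outside_track_is_an_error(self):
        track = synthetic_track(100, (10, 20))
        with pytest.raises(ValueError):
            detect_outlier_region(track, ("chr1", 500_000, 600_000))


class TestTractLengthAge:
    def test_consistent_with_several_hundred_years(self):
        est = tract_length_age(300_000, RecombinationMap(0.5), donor_fraction=1e-6)
        assert est.generations == pytest.approx(667, rel=0.01)
        assert est.years == pytest.approx(222, rel=0.01)
        assert APPROXIMATE in est.flags
        # same order of magnitude as the 400-year mutation-clock estimate
        assert 100 <= est.years <= 1000

    def test_doubling_rate_halves_generations(self):
        g1 = tract_length_age(300_000, RecombinationMap(0.5), 0.1).generations
        g2 = tract_length_age(300_000, RecombinationMap(1.0), 0.1).generations
        assert g2 == pytest.approx(g1 / 2)

    def test_zero_span_rejected(self):
        with pytest.raises(ValueError):
            tract_length_age(0, RecombinationMap(0.5), 0.1)
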