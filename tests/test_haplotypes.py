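"""Phasing, cataloguing, variant classification and inheritance checks."""

import itertools
import warnings

import numpy as np
import pytest

from xpr1popgen.haplotypes import (
    AMBIGUOUS,
    ASSIGNED,
    DiploidGenotypes,
    IupacProfile,
    Site,
    SnpPanel,
    catalogue_haplotypes,
    check_parental_composite,
    classify_site,
    phase_homozygote_anchored,
)


def mini_panel(n_sites: int) -> SnpPanel:
    sites = [
        Site(f"m{i}", "frag", "chr1", 1000 + 10 * i, "A", "G", "noncoding")
        for i in range(n_sites)
    ]
    return SnpPanel(sites=sites, surveyed_length_bp=max(n_sites, 100))


def geno_from_pair(panel, v1, v2):
    return {
        s.site_id: tuple(sorted((v1[i], v2[i]))) for i, s in enumerate(panel.sites)
    }


def vec(panel, alt_at):
    return tuple("G" if i in alt_at else "A" for i in range(len(panel)))


def enumerate_phasings(genotype_vec):
    """All unordered haplotype pairs consistent with a fully-called genotype."""
    het = [i for i, (a, b) in enumerate(genotype_vec) if a != b]
    out = set()
    for mask in range(2 ** max(len(het), 1)):
        h1 = [p[0] for p in genotype_vec]
        h2 = [p[1] for p in genotype_vec]
        for k, i in enumerate(het):
            if (mask >> k) & 1:
                h1[i], h2[i] = h2[i], h1[i]
        out.add(frozenset((tuple(h1), tuple(h2))))
    return out


class TestPhasing:
    def test_homozygote_is_its_own_phase(self):
        panel = mini_panel(3)
        hap = vec(panel, {0, 1, 2})
        g = DiploidGenotypes(
            individuals=[("a", "pop")], calls={"a": geno_from_pair(panel, hap, hap)}
        )
        catalogue, assignment = phase_homozygote_anchored(g, panel)
        assert assignment.status["a"] == ASSIGNED
        assert len(catalogue.haplotypes) == 1
        assert catalogue.haplotypes[0].alleles == hap

    def test_heterozygote_resolved_by_known_pair(self):
        # two anchor homozygotes make (h1, h2) the unique known resolution of
        # a triple heterozygote, out of the 2^(3-1) = 4 abstract phasings
        panel = mini_panel(3)
        h1, h2 = vec(panel, set()), vec(panel, {0, 1, 2})
        g = DiploidGenotypes(
            individuals=[("hom1", "p"), ("hom2", "p"), ("het", "p")],
            calls={
                "hom1": geno_from_pair(panel, h1, h1),
                "hom2": geno_from_pair(panel, h2, h2),
                "het": geno_from_pair(panel, h1, h2),
            },
        )
        catalogue, assignment = phase_homozygote_anchored(g, panel)
        assert assignment.status["het"] == ASSIGNED
        labels = {catalogue.label_for(h1), catalogue.label_for(h2)}
        assert set(assignment.pairs["het"]) == labels
        assert len(enumerate_phasings(list(geno_from_pair(panel, h1, h2).values()))) == 4

    def test_two_novel_resolutions_stay_ambiguous(self):
        # genotype consistent with (known1, novelX) and with (known2, novelY):
        # no unique parsimonious resolution, so the sample must be dropped
        panel = mini_panel(3)
        h_iii = vec(panel, {0})
        h_iiia = vec(panel, {0, 1})
        het = vec(panel, {0, 1, 2})  # pairs as (IIIa, {0,2}-novel) or (III, {0,1,2}... )
        g = DiploidGenotypes(
            individuals=[("a1", "p"), ("a2", "p"), ("odd", "p")],
            calls={
                "a1": geno_from_pair(panel, h_iii, h_iii),
                "a2": geno_from_pair(panel, h_iiia, h_iiia),
                "odd": geno_from_pair(panel, h_iii, het),
            },
        )
        _, assignment = phase_homozygote_anchored(g, panel)
        assert assignment.status["odd"] == AMBIGUOUS

    def test_site_absent_from_panel_is_an_error(self):
        panel = mini_panel(2)
        g = DiploidGenotypes(
            individuals=[("a", "p")], calls={"a": {"nope": ("A", "A")}}
        )
        with pytest.raises(KeyError):
            phase_homozygote_anchored(g, panel)

    def test_all_missing_individual_is_ambiguous_with_warning(self):
        panel = mini_panel(2)
        g = DiploidGenotypes(
            individuals=[("a", "p")], calls={"a": {"m0": (".", "."), "m1": (".", ".")}}
        )
        with pytest.warns(UserWarning, match="no called sites"):
            _, assignment = phase_homozygote_anchored(g, panel)
        assert assignment.status["a"] == AMBIGUOUS

    def test_round_trip_recovery_on_random_datasets(self, rng):
        """Constructed genotypes: assignments reproduce every genotype, and
        match the generating pair whenever brute-force enumeration over all
        phase configurations says that pair is the unique resolution."""
        for _ in range(30):
            m = int(rng.integers(2, 9))
            panel = mini_panel(m)
            k = int(rng.integers(2, 6))
            pool = {tuple(vec(panel, set())), tuple(vec(panel, set(range(m))))}
            while len(pool) < k:
                pool.add(vec(panel, set(np.flatnonzero(rng.integers(0, 2, m)))))
            pool = sorted(pool)
            n_ind = int(rng.integers(4, 12))
            truth = {}
            calls = {}
            inds = []
            for i in range(n_ind):
                pair = (pool[rng.integers(k)], pool[rng.integers(k)])
                sid = f"i{i:02d}"
                inds.append((sid, "p"))
                truth[sid] = frozenset(pair)
                calls[sid] = geno_from_pair(panel, *pair)
            g = DiploidGenotypes(individuals=inds, calls=calls)
            catalogue, assignment = phase_homozygote_anchored(g, panel)
            by_label = {h.label: h.alleles for h in catalogue.haplotypes}
            for sid, _ in inds:
                if assignment.status[sid] != ASSIGNED:
                    continue
                a, b = assignment.pairs[sid]
                va, vb = by_label[a], by_label[b]
                # exact genotype reproduction at every site
                assert geno_from_pair(panel, va, vb) == calls[sid]
                gv = [calls[sid][s.site_id] for s in panel.sites]
                if len(enumerate_phasings(gv)) == 1:
                    assert frozenset((va, vb)) == truth[sid]

    def test_assignment_determinism(self, bundle):
        from xpr1popgen.fixtures import make_survey_fixture

        b2 = make_survey_fixture(1)
        c1, a1 = phase_homozygote_anchored(bundle.genotypes, bundle.panel)
        c2, a2 = phase_homozygote_anchored(b2.genotypes, b2.panel)
        assert a1.pairs == a2.pairs
        assert [h.alleles for h in c1.haplotypes] == [h.alleles for h in c2.haplotypes]


class TestCatalogue:
    def test_frequencies_sum_to_one(self, phased):
        catalogue, _ = phased
        freqs = catalogue.frequencies()
        assert np.allclose(freqs.sum(axis=0), 1.0, atol=1e-12)

    def test_direct_count_example(self):
        panel = mini_panel(2)
        h1, h2 = vec(panel, set()), vec(panel, {0, 1})
        g = DiploidGenotypes(
            individuals=[("x", "p"), ("y", "p"), ("z", "p")],
            calls={
                "x": geno_from_pair(panel, h1, h1),
                "y": geno_from_pair(panel, h1, h2),
                "z": geno_from_pair(panel, h2, h2),  # anchor so h2 is known
            },
        )
        catalogue, assignment = phase_homozygote_anchored(g, panel)
        sub = catalogue.counts["p"]
        assert sub[catalogue.label_for(h1)] == 3
        assert sub[catalogue.label_for(h2)] == 3
        recounted = catalogue_haplotypes(assignment, g, catalogue)
        assert recounted.counts.equals(catalogue.counts)

    def test_recount_requires_assigned_individuals(self, phased, bundle):
        from xpr1popgen.haplotypes import HaplotypeAssignment

        catalogue, _ = phased
        empty = HaplotypeAssignment(status={}, pairs={})
        with pytest.raises(ValueError):
            catalogue_haplotypes(empty, bundle.genotypes, catalogue)


class TestClassifySite:
    def test_synonymous_glutamate_wobble(self):
        s = Site("x", "f", "chr1", 10, "A", "G", "synonymous", codon="GAA", codon_pos=3)
        assert classify_site(s) == "synonymous"

    def test_nonsynonymous_asn_to_lys(self):
        # the ECL3 variant: AAT (Asn) -> AAA (Lys) at codon position 3
        s = Site("x", "f", "chr1", 10, "T", "A", "nonsynonymous", codon="AAT",
                 codon_pos=3, aa_pos=503)
        assert classify_site(s) == "nonsynonymous"

    def test_indel_and_noncoding(self):
        indel = Site("x", "f", "chr1", 10, "ACTT", "A", "indel")
        assert classify_site(indel) == "indel"
        nc = Site("y", "f", "chr1", 20, "T", "C", "noncoding")
        assert classify_site(nc) == "noncoding"

    def test_malformed_codon_rejected(self):
        s = Site("x", "f", "chr1", 10, "A", "G", "synonymous", codon="GAAA", codon_pos=3)
        with pytest.raises(ValueError, match="length 3"):
            classify_site(s)

    def test_declared_classes_agree_with_translation(self, bundle):
        """Every panel site's declared class is reproduced by codon translation."""
        for site in bundle.panel.sites:
            assert classify_site(site) == site.variant_class

    def test_panel_class_tally(self, bundle):
        from collections import Counter

        tally = Counter(s.variant_class for s in bundle.panel.sites)
        assert tally["nonsynonymous"] == 8
        assert tally["synonymous"] == 9
        assert tally["indel"] == 2


class TestParentalComposite:
    def test_ambiguity_code_subset(self):
        res = check_parental_composite(
            IupacProfile("p1", "AR"), IupacProfile("p2", "AG"), IupacProfile("o", "AG")
        )
        assert res["composite"] and res["violating_positions"] == []

    def test_violation_reported_with_position(self):
        res = check_parental_composite(
            IupacProfile("p1", "AA"), IupacProfile("p2", "AA"), IupacProfile("o", "AC")
        )
        assert not res["composite"]
        assert res["violating_positions"] == [2]

    def test_constructed_offspring_always_composite(self, rng):
        """Offspring built per-position from parental alleles: 1000/1000 composite."""
        bases = "ACGT"
        for _ in range(1000):
            p1 = "".join(rng.choice(list(bases), 50))
            p2 = "".join(rng.choice(list(bases), 50))
            off = "".join(a if rng.random() < 0.5 else b for a, b in zip(p1, p2))
            res = check_parental_composite(
                IupacProfile("p1", p1), IupacProfile("p2", p2), IupacProfile("o", off)
            )
            assert res["composite"]

    def test_length_mismatch_and_bad_codes(self):
        with pytest.raises(ValueError):
            check_parental_composite(
                IupacProfile("a", "AAA"), IupacProfile("b", "AA"), IupacProfile("c", "AAA")
            )
        with pytest.raises(ValueError):
            IupacProfile("bad", "A?A")
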