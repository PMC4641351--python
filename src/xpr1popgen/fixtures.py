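"""Deterministic reconstruction of the population-survey dataset.

The published survey reports, for each of twelve population samples, the
number of variable sites and haplotypes, nucleotide diversity, and
neutrality statistics, plus a microsatellite cross-tab for the
introgression analysis — but not the per-individual genotypes.  This module
rebuilds a dataset with exactly that statistical structure: a 21-site panel
(8 nonsynonymous SNPs, 9 synonymous SNPs, 2 indels, 2 noncoding SNPs), 13
distinct haplotypes across the population samples, per-population haplotype
counts matching every printed variable-sites/haplotypes row, and a
microsatellite table in which the donor-informative alleles (ms6 allele
265, ms8 allele 157) show the 13:1 pattern among recipient homozygotes.

The reconstruction is a synthetic stand-in for the deposited supplementary
tables: individual-level pairings, the identity of minor Fra_MC haplotypes,
and all allele sizes other than the informative ones are choices consistent
with, but not stated by, the survey.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haplotypes import DiploidGenotypes, Haplotype, SnpPanel, Site
from .introgression import DatingCalibration, MsatTable

__all__ = ["SurveyFixture", "make_survey_fixture", "build_panel", "HAPLOTYPE_SITES"]

SURVEYED_LENGTH_BP = 507
CHROM = "chr1"

# (site_id, fragment, pos, ref, alt, class, codon, codon_pos, aa_pos)
_SITE_DEFS = [
    ("s01", "exon4", 155_401_110, "C", "T", "nonsynonymous", "GCT", 2, 164),
    ("s02", "exon4", 155_401_128, "A", "G", "nonsynonymous", "AGA", 1, 170),
    ("s03", "exon4", 155_401_145, "A", "G", "synonymous", "GAA", 3, 175),
    ("s04", "exon4", 155_401_190, "T", "C", "noncoding", None, None, None),
    ("s05", "ECL3_1", 155_419_201, "T", "A", "nonsynonymous", "AAT", 3, 503),
    ("s07", "ECL3_1", 155_419_213, "C", "T", "nonsynonymous", "CGT", 1, 507),
    ("s15", "ECL3_1", 155_419_260, "G", "A", "noncoding", None, None, None),
    ("s06", "ECL3_2", 155_420_330, "G", "A", "synonymous", "CTG", 3, 520),
    ("s10", "ECL3_2", 155_420_360, "C", "A", "nonsynonymous", "ACC", 2, 510),
    ("s08", "ECL4_1", 155_433_402, "T", "A", "nonsynonymous", "GAT", 3, 564),
    ("s09", "ECL4_1", 155_433_420, "ACTT", "A", "indel", None, None, None),
    ("s11", "ECL4_1", 155_433_441, "C", "T", "synonymous", "GGC", 3, 570),
    ("s12", "ECL4_1", 155_433_456, "C", "T", "synonymous", "TCC", 3, 575),
    ("s14", "ECL4_2", 155_434_501, "G", "A", "nonsynonymous", "ATG", 3, 590),
    ("s16", "ECL4_2", 155_434_516, "G", "A", "synonymous", "CCG", 3, 595),
    ("s17", "ECL4_2", 155_434_530, "GTT", "G", "indel", None, None, None),
    ("s18", "ECL4_2", 155_434_548, "T", "G", "nonsynonymous", "TTT", 3, 601),
    ("s19", "ECL4_2", 155_434_560, "T", "C", "synonymous", "ACT", 3, 605),
    ("s20", "ECL4_2", 155_434_575, "A", "G", "synonymous", "GTA", 3, 610),
    ("s21", "ECL4_2", 155_434_590, "A", "G", "synonymous", "CGA", 3, 615),
    ("s22", "ECL4_2", 155_434_605, "A", "G", "synonymous", "TTA", 3, 620),
]

# 13 population haplotypes as sets of alt-carrying sites; "I" is the
# reference pattern.  IIb, IIIb, VIa and VIb are reconstructed minor
# variants needed to satisfy the printed sites/haplotypes rows.
HAPLOTYPE_SITES: dict[str, frozenset] = {
    "I": frozenset(),
    "Ia": frozenset({"s04"}),
    "II": frozenset({"s01", "s02", "s03"}),
    "IIa": frozenset({"s01", "s02", "s03", "s15"}),
    "IIb": frozenset({"s01", "s02"}),
    "III": frozenset({"s01", "s02", "s03", "s05"}),
    "IIIa": frozenset({"s01", "s02", "s03", "s05", "s06"}),
    "IIIb": frozenset({"s01", "s02", "s03", "s05", "s14", "s16"}),
    "IV": frozenset({"s05"}),
    "V": frozenset({"s07", "s08", "s09"}),
    "VI": frozenset({"s08", "s09", "s10"}),
    "VIa": frozenset({"s08", "s09", "s10", "s12"}),
    "VIb": frozenset({"s08", "s09", "s10", "s11"}),
}

# Sister-species outgroup haplotypes (outside the 13-haplotype catalogue).
OUTGROUP_SITES = {
    "CAS": frozenset({"s17", "s18", "s19", "s20"}),
    "SPRE": frozenset({"s07", "s21"}),
    "SPIC": frozenset({"s10", "s22"}),
}

# Diploid composition per population sample: (hap1, hap2, n_animals).
# Chromosome totals reproduce the survey's variable-sites/haplotypes rows
# (e.g. Ger_CB 21:1, Ira_AH 23:1, Fra_LO 14:10, MUS-KAZ 21:2:1).
POPULATIONS: dict[str, list[tuple[str, str, int]]] = {
    "Fra_NA": [("I", "I", 7), ("II", "II", 2), ("I", "II", 3)],
    "Fra_LO": [("I", "I", 5), ("II", "II", 3), ("I", "II", 4)],
    "Fra_DB": [("I", "I", 8), ("II", "II", 2), ("I", "II", 2)],
    "Fra_AN": [("I", "I", 6), ("II", "II", 3), ("I", "II", 3)],
    "Fra_ES": [("I", "I", 6), ("II", "II", 3), ("I", "II", 3)],
    "Fra_MC1": [
        ("III", "III", 3), ("III", "IIIa", 1), ("I", "IIIa", 1), ("III", "IIIb", 1),
        ("I", "I", 3), ("II", "II", 1), ("I", "II", 2),
    ],
    "Fra_MC2": [
        ("III", "III", 4), ("II", "III", 1), ("I", "I", 2), ("I", "Ia", 1),
        ("II", "II", 2), ("II", "IIa", 1), ("I", "IIb", 1),
    ],
    "Ger_CB": [("I", "I", 10), ("I", "II", 1)],
    "Ger_SL": [("I", "I", 9), ("II", "II", 1), ("I", "II", 2)],
    "Ira_AH": [("III", "III", 11), ("III", "IV", 1)],
    "MUS-CR": [("V", "V", 12)],
    "MUS-KAZ": [("VI", "VI", 10), ("VIa", "VIa", 1), ("VI", "VIb", 1)],
}

# Microsatellite design: nine loci within 200 kb around the gene; the
# donor-informative alleles are ms6 = 265 and ms8 = 157.
MSAT_OFFSETS = [-95_000, -71_000, -48_000, -24_000, -6_000, 11_000, 36_000, 62_000, 95_000]
FOCAL_GENE_POS = 155_418_000
INFORMATIVE = {"ms6": 265, "ms8": 157}
EUROPEAN_ALLELES = {"ms6": (261, 263), "ms8": (137, 139)}
SHARED_ALLELES = (200, 202)  # the seven non-informative loci in every population


def build_panel() -> SnpPanel:
    sites = [
        Site(sid, frag, CHROM, pos, ref, alt, cls, codon, cpos, aa)
        for sid, frag, pos, ref, alt, cls, codon, cpos, aa in _SITE_DEFS
    ]
    return SnpPanel(sites=sites, surveyed_length_bp=SURVEYED_LENGTH_BP)


def _vector(panel: SnpPanel, alt_sites: frozenset) -> tuple[str, ...]:
    return tuple(s.alt if s.site_id in alt_sites else s.ref for s in panel.sites)


@dataclass
class SurveyFixture:
    """The reconstructed survey bundle."""

    panel: SnpPanel
    genotypes: DiploidGenotypes
    haplotypes: dict[str, Haplotype]  # true label -> haplotype
    true_counts: pd.DataFrame  # label x population chromosome counts
    msat: MsatTable
    outgroups: dict[str, Haplotype]
    calibration: DatingCalibration = field(
        default_factory=lambda: DatingCalibration(anchors=[(0.05, 1200.0)])
    )
    donor_population: str = "Ira_AH"
    recipient_populations: tuple = ("Fra_MC1", "Fra_MC2")
    target_haplotype: str = "III"


def make_survey_fixture(seed: int = 0) -> SurveyFixture:
    """Build the deterministic survey reconstruction.

    The seed only shuffles which sample id receives which diploid
    configuration within each population; all counts, haplotypes and the
    informative-allele pattern are fixed.  Regeneration with the same seed
    is byte-identical.
    """
    rng = np.random.default_rng(seed)
    panel = build_panel()
    haps = {lab: Haplotype(lab, _vector(panel, s)) for lab, s in HAPLOTYPE_SITES.items()}
    outgroups = {lab: Haplotype(lab, _vector(panel, s)) for lab, s in OUTGROUP_SITES.items()}

    individuals: list[tuple[str, str]] = []
    calls: dict[str, dict[str, tuple[str, str]]] = {}
    pairing: dict[str, tuple[str, str]] = {}
    counts = pd.DataFrame(0, index=sorted(HAPLOTYPE_SITES), columns=sorted(POPULATIONS), dtype=int)

    for pop, config in POPULATIONS.items():
        pairs = [(h1, h2) for h1, h2, n in config for _ in range(n)]
        order = rng.permutation(len(pairs))
        for i, j in enumerate(order):
            h1, h2 = pairs[j]
            sid = f"{pop}_{i + 1:02d}"
            individuals.append((sid, pop))
            v1, v2 = haps[h1].alleles, haps[h2].alleles
            calls[sid] = {
                site.site_id: tuple(sorted((v1[k], v2[k])))
                for k, site in enumerate(panel.sites)
            }
            pairing[sid] = tuple(sorted((h1, h2)))
            counts.loc[h1, pop] += 1
            counts.loc[h2, pop] += 1

    genotypes = DiploidGenotypes(individuals=individuals, calls=calls)
    msat = _build_msat(pairing, genotypes)
    return SurveyFixture(
        panel=panel,
        genotypes=genotypes,
        haplotypes=haps,
        true_counts=counts,
        msat=msat,
        outgroups=outgroups,
    )


def _build_msat(pairing: dict, genotypes: DiploidGenotypes) -> MsatTable:
    """Microsatellite genotypes for the donor, recipient and reference pools.

    Among the seven III/III recipient homozygotes, 13 of 14 chromosomes
    carry the informative allele at each informative locus and exactly one
    carries a one-step neighbour (a new mutation): one at ms6 in the first
    Fra_MC1 homozygote, one at ms8 in the first Fra_MC2 homozygote.
    """
    loci = pd.DataFrame(
        {
            "locus_id": [f"ms{i + 1}" for i in range(9)],
            "chrom": CHROM,
            "pos": [FOCAL_GENE_POS + off for off in MSAT_OFFSETS],
            "offset_bp": MSAT_OFFSETS,
        }
    )
    msat_pops = ["Ira_AH", "Fra_MC1", "Fra_MC2", "Fra_NA", "Ger_CB"]
    rows = []
    mutant_given = {"ms6": False, "ms8": False}
    mutant_pop = {"ms6": "Fra_MC1", "ms8": "Fra_MC2"}

    for sid, pop in genotypes.individuals:
        if pop not in msat_pops:
            continue
        h1, h2 = pairing[sid]
        for i, locus in enumerate(loci["locus_id"]):
            if locus in INFORMATIVE:
                donor_allele = INFORMATIVE[locus]
                euro = EUROPEAN_ALLELES[locus]
                if pop == "Ira_AH":
                    # high-frequency informative allele, one-step variants rare
                    a1 = donor_allele if sid.endswith(("01", "02", "03", "04", "05",
                                                      "06", "07", "08", "09", "10", "11")) else donor_allele + 2
                    a2 = donor_allele if not sid.endswith("12") else donor_allele + 2
                elif pop in ("Fra_MC1", "Fra_MC2"):
                    a1 = _mc_allele(h1, donor_allele, euro)
                    a2 = _mc_allele(h2, donor_allele, euro)
                    if (
                        h1 == h2 == "III"
                        and not mutant_given[locus]
                        and pop == mutant_pop[locus]
                    ):
                        a2 = donor_allele - 2  # the single new mutation
                        mutant_given[locus] = True
                else:
                    a1, a2 = euro[0], euro[1]
            else:
                a1, a2 = SHARED_ALLELES
            rows.append((sid, pop, locus, a1, a2))

    genotab = pd.DataFrame(
        rows, columns=["sample_id", "population_id", "locus_id", "size1", "size2"]
    )
    return MsatTable(loci=loci, genotypes=genotab)


def _mc_allele(hap: str, donor_allele: int, euro: tuple) -> int:
    # chromosomes of the Iranian haplotype lineage carry the Iranian allele
    return donor_allele if hap.startswith("III") else euro[0]
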