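#!/usr/bin/env python
"""Detect and date the introgression of the Iranian haplotype.

Chain: donor-informative microsatellite alleles (high in Ira_AH, absent
elsewhere outside the recipient) -> cross-tab against phased haplotype
genotypes in the recipient -> novel-allele fraction among III/III
homozygotes -> age in generations/years under the published calibration
(a new allele reaches 5% frequency in about 1,200 generations; 3
generations per year).  Finding: 1 novel allele out of 14 chromosomes at
each informative locus (7%), dating the introgression to roughly 1,200
generations or about 400 years — several hundred years ago.
"""

import json
from dataclasses import asdict
from pathlib import Path

from xpr1popgen import io as xio
from xpr1popgen.fixtures import make_survey_fixture
from xpr1popgen.haplotypes import phase_homozygote_anchored
from xpr1popgen.introgression import (
    RecombinationMap,
    date_by_new_mutations,
    find_informative_alleles,
    genotype_concordance,
    tract_length_age,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    bundle = make_survey_fixture(seed=1)
    catalogue, assignment = phase_homozygote_anchored(bundle.genotypes, bundle.panel)

    informative = find_informative_alleles(
        bundle.msat,
        bundle.donor_population,
        exclude_populations=list(bundle.recipient_populations),
    )
    print("informative alleles:",
          [(a.locus_id, a.allele_size, round(a.donor_frequency, 3)) for a in informative])

    target = catalogue.label_for(bundle.haplotypes[bundle.target_haplotype].alleles)
    conc = genotype_concordance(
        bundle.msat, assignment, target, informative,
        populations=list(bundle.recipient_populations),
    )
    fraction = conc["novel_allele_fraction"]
    print(f"novel-allele fraction among {target}/{target} homozygotes: "
          f"{conc['n_novel']}/{conc['n_alleles']} = {100 * fraction:.0f}%")

    mutation_clock = date_by_new_mutations(fraction, bundle.calibration)
    print(f"mutation clock: {mutation_clock.generations:.0f} generations "
          f"= {mutation_clock.years:.0f} years")

    # recombination clock for a few-hundred-kb introgressed region
    recomb_clock = tract_length_age(300_000, RecombinationMap(0.5), donor_fraction=0.19)
    print(f"recombination clock (300 kb tract): {recomb_clock.generations:.0f} "
          f"generations = {recomb_clock.years:.0f} years (approximate)")

    RESULTS.mkdir(exist_ok=True)
    xio.write_json(
        {
            "informative_alleles": [asdict(a) for a in informative],
            "novel_allele_fraction": fraction,
            "per_locus_fraction": conc["per_locus_fraction"],
            "mutation_clock": asdict(mutation_clock),
            "recombination_clock": asdict(recomb_clock),
        },
        RESULTS / "introgression_dating.json",
    )
    print(f"wrote {RESULTS / 'introgression_dating.json'}")


if __name__ == "__main__":
    main()
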