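"""Haplotype reconstruction from diploid multi-fragment genotypes.

The five sequenced Xpr1 fragments lie within 40 kb and segregate as a single
linked locus, so specific alleles are only ever observed together in
homozygous animals.  Phasing therefore proceeds the way it was done by hand:
homozygotes (and individuals heterozygous at a single site) resolve
trivially and seed a set of known haplotypes; remaining individuals are
resolved against that set, admitting a novel complement only when no
resolution into two known haplotypes exists (Clark-style parsimony).
Individuals with no unique resolution are flagged AMBIGUOUS and excluded
from downstream statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

MISSING = "."

VARIANT_CLASSES = ("nonsynonymous", "synonymous", "noncoding", "indel")


@dataclass(frozen=True)
class Site:
    """One variable site of the sequenced panel.

    ``pos`` is 1-based on the reference assembly.  ``codon``/``codon_pos``
    give the reference codon (coding strand, 5'->3') and the 1-based
    position of the site within it; they are required for coding sites and
    absent for noncoding sites and indels.
    """

    site_id: str
    fragment_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    codon: Optional[str] = None
    codon_pos: Optional[int] = None
    aa_pos: Optional[int] = None

    def __post_init__(self):
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.variant_class!r}")
        if self.variant_class == "indel" and self.codon is not None:
            raise ValueError(f"indel site {self.site_id} must not carry codon context")


@dataclass
class SnpPanel:
    """The ordered variable-site panel plus total surveyed length L (bp).

    L is the denominator that converts per-sequence diversity to per-site
    diversity; it is a property of the sequencing design, not of the panel
    of variable sites, and must always be supplied by the caller.
    """

    sites: list[Site]
    surveyed_length_bp: int = 507

    def __post_init__(self):
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("site_ids must be unique")
        by_frag: dict[str, int] = {}
        for s in self.sites:
            prev = by_frag.get(s.fragment_id)
            if prev is not None and s.pos <= prev:
                raise ValueError(
                    f"positions must strictly increase within fragment {s.fragment_id}"
                )
            by_frag[s.fragment_id] = s.pos
        if self.surveyed_length_bp < len(self.sites):
            raise ValueError("surveyed length shorter than the number of sites")
        self._index = {s.site_id: i for i, s in enumerate(self.sites)}

    def __len__(self) -> int:
        return len(self.sites)

    def index_of(self, site_id: str) -> int:
        return self._index[site_id]


@dataclass(frozen=True)
class Haplotype:
    label: str
    alleles: tuple[str, ...]


@dataclass
class HaplotypeCatalogue:
    """Distinct haplotypes plus per-population chromosome counts."""

    panel: SnpPanel
    haplotypes: list[Haplotype]
    counts: pd.DataFrame  # index: label, columns: population_id, values: chromosome counts

    def __post_init__(self):
        labels = [h.label for h in self.haplotypes]
        if len(set(labels)) != len(labels):
            raise ValueError("haplotype labels must be unique")
        for h in self.haplotypes:
            if len(h.alleles) != len(self.panel):
                raise ValueError(f"haplotype {h.label} length != panel size")

    def frequencies(self) -> pd.DataFrame:
        """Per-population haplotype frequencies (columns sum to 1)."""
        return self.counts / self.counts.sum(axis=0)

    def population_counts(self, population_id: str) -> dict[str, int]:
        col = self.counts[population_id]
        return {label: int(c) for label, c in col.items() if c > 0}

    def label_for(self, alleles: Sequence[str]) -> Optional[str]:
        """Label of the catalogued haplotype with this allele vector, if any."""
        target = tuple(alleles)
        for h in self.haplotypes:
            if h.alleles == target:
                return h.label
        return None


@dataclass
class DiploidGenotypes:
    """Per-individual unordered allele pairs at panel sites.

    ``calls[sample_id][site_id]`` is an unordered pair (a1, a2) with "."
    marking a missing allele.
    """

    individuals: list[tuple[str, str]]  # (sample_id, population_id)
    calls: dict[str, dict[str, tuple[str, str]]]

    def __post_init__(self):
        for sid, pop in self.individuals:
            if not pop:
                raise ValueError(f"individual {sid} has an empty population_id")
            if sid not in self.calls:
                raise ValueError(f"no calls for individual {sid}")

    @property
    def sample_ids(self) -> list[str]:
        return [sid for sid, _ in self.individuals]

    def population_of(self, sample_id: str) -> str:
        for sid, pop in self.individuals:
            if sid == sample_id:
                return pop
        raise KeyError(sample_id)


ASSIGNED = "ASSIGNED"
AMBIGUOUS = "AMBIGUOUS"


@dataclass
class HaplotypeAssignment:
    """Per-sample phasing outcome: an unordered haplotype-label pair, or AMBIGUOUS."""

    status: dict[str, str]  # sample_id -> ASSIGNED | AMBIGUOUS
    pairs: dict[str, tuple[str, str]]  # only for ASSIGNED samples

    def assigned_samples(self) -> list[str]:
        return [s for s, st in self.status.items() if st == ASSIGNED]


# ---------------------------------------------------------------------------
# Phasing


def _genotype_vector(
    calls: Mapping[str, tuple[str, str]], panel: SnpPanel
) -> list[tuple[str, str]]:
    """Per-site unordered pairs in panel order; validates site ids and alleles."""
    for site_id in calls:
        if site_id not in panel._index:
            raise KeyError(f"site {site_id!r} called in genotypes but absent from panel")
    vec = []
    for site in panel.sites:
        pair = calls.get(site.site_id, (MISSING, MISSING))
        for a in pair:
            if a not in (site.ref, site.alt, MISSING):
                raise ValueError(
                    f"allele {a!r} at site {site.site_id} is neither ref, alt nor missing"
                )
        vec.append(tuple(sorted(pair)))
    return vec


def _het_sites(vec) -> list[int]:
    return [i for i, (a, b) in enumerate(vec) if a != b and MISSING not in (a, b)]


def _n_missing(vec) -> int:
    return sum(1 for a, b in vec if MISSING in (a, b))


def _complement(hap: tuple[str, ...], vec) -> Optional[tuple[str, ...]]:
    """The chromosome forced by pairing ``hap`` with genotype ``vec``.

    Missing sites are unconstrained and returned as MISSING.  Returns None
    if ``hap`` is inconsistent with the genotype.
    """
    comp = []
    for i, pair in enumerate(vec):
        if MISSING in pair:
            comp.append(MISSING)
        elif hap[i] == pair[0]:
            comp.append(pair[1])
        elif hap[i] == pair[1]:
            comp.append(pair[0])
        else:
            return None
    return tuple(comp)


def phase_homozygote_anchored(
    genotypes: DiploidGenotypes, panel: SnpPanel
) -> tuple[HaplotypeCatalogue, HaplotypeAssignment]:
    """Phase diploid genotypes under the single-linked-locus assumption.

    Algorithm: (1) individuals heterozygous at <= 1 site (and fully called)
    resolve trivially and seed the known set; (2) iterate to fixpoint over
    unresolved individuals in a fixed order (ascending heterozygosity, ties
    by sample_id): if exactly one resolution into two known haplotypes
    exists, take it; if none exists but exactly one known anchor forces a
    (fully determined) novel complement, admit the complement; (3) anything
    still unresolved, or resolvable in more than one way, is AMBIGUOUS.
    """
    if not genotypes.individuals:
        raise ValueError("no individuals to phase")

    vecs: dict[str, list[tuple[str, str]]] = {}
    status: dict[str, str] = {}
    pairs: dict[str, tuple[str, str]] = {}
    known: dict[tuple[str, ...], str] = {}  # allele vector -> provisional key
    first_seen: dict[tuple[str, ...], int] = {}
    order_counter = 0

    def admit(hap: tuple[str, ...]) -> None:
        nonlocal order_counter
        if hap not in known:
            known[hap] = f"H{len(known) + 1}"
            first_seen[hap] = order_counter
            order_counter += 1

    for sid, _pop in genotypes.individuals:
        vecs[sid] = _genotype_vector(genotypes.calls[sid], panel)

    # processing order: ascending heterozygosity, ties lexicographic
    ordered = sorted(genotypes.sample_ids, key=lambda s: (len(_het_sites(vecs[s])), s))

    unresolved: list[str] = []
    for sid in ordered:
        vec = vecs[sid]
        if _n_missing(vec) == len(vec):
            warnings.warn(f"individual {sid} has no called sites; AMBIGUOUS")
            status[sid] = AMBIGUOUS
            continue
        het = _het_sites(vec)
        if len(het) <= 1 and _n_missing(vec) == 0:
            h1 = tuple(pair[0] for pair in vec)
            h2 = tuple(pair[1] for pair in vec)
            admit(h1)
            admit(h2)
            status[sid] = ASSIGNED
            pairs[sid] = (h1, h2)  # provisional: store vectors, labelled later
        else:
            unresolved.append(sid)

    # fixpoint resolution against the known set
    progress = True
    while progress:
        progress = False
        still = []
        for sid in unresolved:
            vec = vecs[sid]
            known_known: set[frozenset] = set()
            known_novel: dict[frozenset, tuple] = {}
            for hap in known:
                comp = _complement(hap, vec)
                if comp is None:
                    continue
                if comp in known:
                    known_known.add(frozenset((hap, comp)) if hap != comp else frozenset((hap,)))
                elif MISSING not in comp:
                    key = frozenset((hap, comp)) if hap != comp else frozenset((hap,))
                    known_novel[key] = (hap, comp)
            if len(known_known) == 1:
                members = next(iter(known_known))
                pair = tuple(members) * 2 if len(members) == 1 else tuple(members)
                status[sid] = ASSIGNED
                pairs[sid] = (pair[0], pair[1])
                progress = True
            elif len(known_known) == 0 and len(known_novel) == 1:
                hap, comp = next(iter(known_novel.values()))
                admit(comp)
                status[sid] = ASSIGNED
                pairs[sid] = (hap, comp)
                progress = True
            else:
                still.append(sid)
        unresolved = still

    for sid in unresolved:
        status[sid] = AMBIGUOUS

    # final labelling: descending global chromosome count, ties by first-seen order
    hap_count: dict[tuple[str, ...], int] = {}
    for sid in pairs:
        for hap in pairs[sid]:
            hap_count[hap] = hap_count.get(hap, 0) + 1
    ranked = sorted(hap_count, key=lambda h: (-hap_count[h], first_seen[h]))
    roman_free_labels = [f"H{i + 1}" for i in range(len(ranked))]
    label_of = dict(zip(ranked, roman_free_labels))

    pops = sorted({pop for _, pop in genotypes.individuals})
    counts = pd.DataFrame(0, index=roman_free_labels, columns=pops, dtype=int)
    for sid, pop in genotypes.individuals:
        if status.get(sid) == ASSIGNED:
            for hap in pairs[sid]:
                counts.loc[label_of[hap], pop] += 1

    catalogue = HaplotypeCatalogue(
        panel=panel,
        haplotypes=[Haplotype(label_of[h], h) for h in ranked],
        counts=counts,
    )
    assignment = HaplotypeAssignment(
        status=status,
        pairs={
            sid: tuple(sorted((label_of[p[0]], label_of[p[1]])))
            for sid, p in pairs.items()
        },
    )
    return catalogue, assignment


def catalogue_haplotypes(
    assignment: HaplotypeAssignment,
    genotypes: DiploidGenotypes,
    catalogue: HaplotypeCatalogue,
) -> HaplotypeCatalogue:
    """Recount a catalogue from an assignment (frequencies sum to 1 per population).

    Provided as the explicit cataloguing step when an assignment has been
    edited (e.g. samples removed); raises if nothing is ASSIGNED.
    """
    assigned = assignment.assigned_samples()
    if not assigned:
        raise ValueError("no ASSIGNED individuals to catalogue")
    pops = sorted({genotypes.population_of(s) for s in assigned})
    labels = [h.label for h in catalogue.haplotypes]
    counts = pd.DataFrame(0, index=labels, columns=pops, dtype=int)
    for sid in assigned:
        pop = genotypes.population_of(sid)
        for label in assignment.pairs[sid]:
            counts.loc[label, pop] += 1
    return HaplotypeCatalogue(panel=catalogue.panel, haplotypes=catalogue.haplotypes, counts=counts)


# ---------------------------------------------------------------------------
# Variant classification


def classify_site(site: Site, genetic_code: int = 1) -> str:
    """Classify a site as nonsynonymous / synonymous / noncoding / indel.

    Coding sites must carry a strand-normalised codon context (reference
    codon on the coding strand with the site's 1-based position within it);
    the reference and alternate codons are translated and compared.  A
    length-changing allele is an indel; a site without codon context is
    noncoding.
    """
    if len(site.ref) != len(site.alt):
        return "indel"
    if site.codon is None:
        return "noncoding"
    if len(site.codon) != 3:
        raise ValueError(f"codon context for {site.site_id} is not length 3")
    if not (1 <= (site.codon_pos or 0) <= 3):
        raise ValueError(f"codon position for {site.site_id} must be 1..3")
    if site.codon[site.codon_pos - 1].upper() != site.ref.upper():
        raise ValueError(
            f"reference codon of {site.site_id} disagrees with the ref allele"
        )
    alt_codon = (
        site.codon[: site.codon_pos - 1] + site.alt + site.codon[site.codon_pos:]
    )
    aa_ref = str(Seq(site.codon).translate(table=genetic_code))
    aa_alt = str(Seq(alt_codon).translate(table=genetic_code))
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


# ---------------------------------------------------------------------------
# Parental-composite check on IUPAC consensus profiles


@dataclass(frozen=True)
class IupacProfile:
    """A per-position IUPAC consensus sequence of an (unphased) individual."""

    sample_id: str
    sequence: str

    def __post_init__(self):
        bad = [c for c in self.sequence.upper() if c not in ambiguous_dna_values]
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {sorted(set(bad))} in {self.sample_id}")

    def allele_sets(self) -> list[frozenset]:
        return [frozenset(ambiguous_dna_values[c]) for c in self.sequence.upper()]


def check_parental_composite(
    parent1: IupacProfile, parent2: IupacProfile, offspring: IupacProfile
) -> dict:
    """Is the offspring profile a combination of the parental sequences?

    True iff at every position the offspring's allele set (IUPAC expansion)
    is a subset of the union of the two parental allele sets.  1-based
    violating positions are reported otherwise.
    """
    if not (len(parent1.sequence) == len(parent2.sequence) == len(offspring.sequence)):
        raise ValueError("profiles must have equal length")
    p1, p2, off = parent1.allele_sets(), parent2.allele_sets(), offspring.allele_sets()
    violations = [
        i + 1 for i, (a, b, o) in enumerate(zip(p1, p2, off)) if not o <= (a | b)
    ]
    return {"composite": not violations, "violating_positions": violations}
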