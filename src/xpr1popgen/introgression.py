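"""Microsatellite-based introgression detection, dating, and genome scans.

An introgressed haplotype is recognised by *informative alleles*: allele
sizes at microsatellite loci flanking the focal gene that are at high
frequency in the candidate donor population but rare or absent elsewhere.
Cross-tabulating those alleles against the focal-gene haplotype genotypes
of the recipient population yields the fraction of chromosomes that carry
the donor haplotype but no longer the donor microsatellite allele — new
stepwise mutations since the introgression, which date the event.  A second,
independent clock is the physical extent of the donor tract, which shrinks
under recombination as roughly 1/(g (1-alpha)) Morgans after g generations.

Windowed diversity scans over VCF data locate the introgressed region as a
run of windows with elevated nucleotide diversity and Tajima's D.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .neutrality import SiteFrequencySpectrum, tajimas_d

__all__ = [
    "MsatTable",
    "InformativeAllele",
    "DatingCalibration",
    "IntrogressionEstimate",
    "RecombinationMap",
    "ScanTrack",
    "RegionCall",
    "find_informative_alleles",
    "genotype_concordance",
    "date_by_new_mutations",
    "windowed_scan",
    "detect_outlier_region",
    "tract_length_age",
]


@dataclass
class MsatTable:
    """Microsatellite genotypes: per (sample, locus) an unordered pair of
    integer allele sizes in bp, plus per-sample population ids and locus
    positions."""

    loci: pd.DataFrame  # columns: locus_id, chrom, pos, offset_bp
    genotypes: pd.DataFrame  # columns: sample_id, population_id, locus_id, size1, size2

    def __post_init__(self):
        sizes = self.genotypes[["size1", "size2"]].to_numpy()
        if (sizes <= 0).any() or not np.issubdtype(sizes.dtype, np.integer):
            raise ValueError("allele sizes must be positive integers")

    @property
    def populations(self) -> list[str]:
        return sorted(self.genotypes["population_id"].unique())

    def allele_frequencies(self, population_id: str) -> pd.DataFrame:
        """Long table locus_id, allele_size, frequency within one population."""
        g = self.genotypes[self.genotypes["population_id"] == population_id]
        long = pd.concat(
            [
                g[["locus_id", "size1"]].rename(columns={"size1": "allele_size"}),
                g[["locus_id", "size2"]].rename(columns={"size2": "allele_size"}),
            ]
        )
        freq = (
            long.groupby(["locus_id", "allele_size"]).size().rename("count").reset_index()
        )
        totals = long.groupby("locus_id").size().rename("total")
        freq = freq.join(totals, on="locus_id")
        freq["frequency"] = freq["count"] / freq["total"]
        return freq


@dataclass(frozen=True)
class InformativeAllele:
    locus_id: str
    allele_size: int
    donor_frequency: float
    max_nondonor_frequency: float


@dataclass
class DatingCalibration:
    """Anchors mapping a novel-allele frequency f to an age in generations.

    ``nearest_anchor`` picks the anchor closest to f on a log scale and
    returns its G unchanged — with the single in-survey anchor
    (f=0.05 -> 1200 generations) this reproduces the published arithmetic.
    ``linear`` interpolates G piecewise-linearly in f between anchors
    (proportionally through the origin below the first anchor, and by
    extrapolation of the last segment above the last one).
    """

    anchors: list[tuple[float, float]]  # (frequency, generations), sorted by f
    mode: str = "nearest_anchor"
    generations_per_year: float = 3.0

    def __post_init__(self):
        if not self.anchors:
            raise ValueError("calibration needs at least one anchor")
        if self.mode not in ("nearest_anchor", "linear"):
            raise ValueError(f"unknown calibration mode {self.mode!r}")
        for f, g in self.anchors:
            if not (0.0 < f < 1.0):
                raise ValueError(f"anchor frequency {f} outside (0, 1)")
            if g <= 0:
                raise ValueError(f"anchor age {g} must be positive")
        self.anchors = sorted(self.anchors)

    def generations_for(self, fraction: float) -> float:
        if fraction == 0.0:
            return 0.0
        if self.mode == "nearest_anchor":
            f0, g0 = min(self.anchors, key=lambda a: abs(math.log(fraction) - math.log(a[0])))
            return g0
        fs = [a[0] for a in self.anchors]
        gs = [a[1] for a in self.anchors]
        if len(fs) == 1 or fraction <= fs[0]:
            return fraction * gs[0] / fs[0]
        if fraction >= fs[-1]:
            if len(fs) == 1:
                return fraction * gs[0] / fs[0]
            slope = (gs[-1] - gs[-2]) / (fs[-1] - fs[-2])
            return gs[-1] + slope * (fraction - fs[-1])
        return float(np.interp(fraction, fs, gs))


LOWER_BOUND = "LOWER_BOUND"
APPROXIMATE = "APPROXIMATE"


@dataclass
class IntrogressionEstimate:
    novel_allele_fraction: Optional[float]
    generations: float
    years: float
    method: str  # new_mutation | tract_length
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class RecombinationMap:
    """Uniform recombination rate, cM/Mb."""

    rate_cm_per_mb: float

    def __post_init__(self):
        if self.rate_cm_per_mb <= 0:
            raise ValueError("recombination rate must be positive")

    def morgans(self, span_bp: float) -> float:
        return span_bp * self.rate_cm_per_mb / 1e8


# ---------------------------------------------------------------------------
# Informative alleles and concordance


def find_informative_alleles(
    msat: MsatTable,
    donor_pop: str,
    f_donor_min: float = 0.5,
    f_other_max: float = 0.05,
    exclude_populations: Sequence[str] = (),
) -> list[InformativeAllele]:
    """Alleles at high frequency in the donor and rare/absent elsewhere.

    The recipient focal population must be listed in ``exclude_populations``
    so that the introgressed allele it carries does not disqualify itself.
    Returned in deterministic order (locus, then size).
    """
    pops = msat.populations
    if donor_pop not in pops:
        raise ValueError(f"donor population {donor_pop!r} absent from the table")
    donor_rows = msat.genotypes[msat.genotypes["population_id"] == donor_pop]
    if donor_rows["sample_id"].nunique() < 2:
        raise ValueError("donor population needs at least 2 individuals")
    other_pops = [p for p in pops if p != donor_pop and p not in exclude_populations]
    donor_freq = msat.allele_frequencies(donor_pop)
    other_freqs = {p: msat.allele_frequencies(p) for p in other_pops}
    out = []
    for _, row in donor_freq.iterrows():
        if row["frequency"] < f_donor_min:
            continue
        locus, size = row["locus_id"], int(row["allele_size"])
        worst = 0.0
        for p, freq in other_freqs.items():
            hit = freq[(freq["locus_id"] == locus) & (freq["allele_size"] == size)]
            if not hit.empty:
                worst = max(worst, float(hit["frequency"].iloc[0]))
        if worst <= f_other_max:
            out.append(
                InformativeAllele(
                    locus_id=locus,
                    allele_size=size,
                    donor_frequency=float(row["frequency"]),
                    max_nondonor_frequency=worst,
                )
            )
    out.sort(key=lambda a: (a.locus_id, a.allele_size))
    return out


def genotype_concordance(
    msat: MsatTable,
    assignment,
    target_haplotype: str,
    informative: Sequence[InformativeAllele],
    populations: Optional[Sequence[str]] = None,
) -> dict:
    """Cross-tabulate microsatellite alleles by focal haplotype genotype.

    Returns a dict with a per-locus cross-tab (allele sizes x haplotype
    genotypes, counting chromosomes), and the novel-allele fraction among
    chromosomes of target-haplotype homozygotes: per informative locus, the
    share of their alleles that differ from the informative allele, plus the
    pooled fraction over loci.  ``populations`` restricts the tabulation
    (e.g. to the recipient population, whose homozygotes define the
    new-mutation fraction; the donor's own homozygotes must not dilute it).
    """
    from .haplotypes import ASSIGNED  # local import to avoid a cycle

    geno = msat.genotypes
    if populations is not None:
        geno = geno[geno["population_id"].isin(list(populations))]
    shared = [
        s
        for s in geno["sample_id"].unique()
        if assignment.status.get(s) == ASSIGNED
    ]
    if not shared:
        raise ValueError("no samples shared between the msat table and the assignment")
    geno_label = {
        s: "/".join(assignment.pairs[s]) for s in shared
    }
    rows = geno[geno["sample_id"].isin(shared)]

    crosstabs: dict[str, pd.DataFrame] = {}
    for locus, sub in rows.groupby("locus_id"):
        long = pd.concat(
            [
                sub[["sample_id", "size1"]].rename(columns={"size1": "allele_size"}),
                sub[["sample_id", "size2"]].rename(columns={"size2": "allele_size"}),
            ]
        )
        long["genotype"] = long["sample_id"].map(geno_label)
        crosstabs[str(locus)] = pd.crosstab(long["allele_size"], long["genotype"])

    homo_label = f"{target_haplotype}/{target_haplotype}"
    homo_samples = [s for s in shared if geno_label[s] == homo_label]
    per_locus: dict[str, Optional[float]] = {}
    novel = total = 0
    for ia in informative:
        sub = rows[(rows["locus_id"] == ia.locus_id) & rows["sample_id"].isin(homo_samples)]
        alleles = sub[["size1", "size2"]].to_numpy().ravel()
        if alleles.size == 0:
            per_locus[ia.locus_id] = None
            continue
        k = int((alleles != ia.allele_size).sum())
        per_locus[ia.locus_id] = k / alleles.size
        novel += k
        total += alleles.size
    if total == 0:
        warnings.warn(
            f"no {homo_label} homozygotes with microsatellite data; fraction undefined"
        )
        pooled = None
    else:
        pooled = novel / total
    return {
        "crosstabs": crosstabs,
        "per_locus_fraction": per_locus,
        "novel_allele_fraction": pooled,
        "n_homozygote_samples": len(homo_samples),
        "n_alleles": total,
        "n_novel": novel,
    }


def date_by_new_mutations(
    fraction: float, calibration: DatingCalibration
) -> IntrogressionEstimate:
    """Age of the introgression from the novel-microsatellite-allele fraction."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    flags = []
    if fraction == 0.0:
        flags.append(LOWER_BOUND)
    generations = calibration.generations_for(fraction)
    return IntrogressionEstimate(
        novel_allele_fraction=fraction,
        generations=generations,
        years=generations / calibration.generations_per_year,
        method="new_mutation",
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Windowed VCF scan


@dataclass
class ScanTrack:
    """Per-window diversity summaries; coordinates 0-based half-open."""

    windows: pd.DataFrame  # columns: chrom, start, end, S, pi_per_site, tajima_d
    n_chromosomes: int
    skipped_records: int = 0


def windowed_scan(
    vcf_path: str,
    population_samples: Sequence[str],
    window_bp: int = 1000,
    region: Optional[tuple[str, int, int]] = None,
) -> ScanTrack:
    """Successive non-overlapping windows of S, pi per site, and Tajima's D.

    Only biallelic SNP records are used; others are skipped and counted.
    ``region`` is (chrom, start, end), 0-based half-open; without it the
    span is taken from the VCF header contig length (or the last variant
    position, rounded up to a whole window).
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path, samples=list(population_samples))
    present = set(vcf.samples)
    missing_samples = [s for s in population_samples if s not in present]
    if len(missing_samples) == len(list(population_samples)):
        raise ValueError("none of the named samples are in the VCF header")
    n_chrom = 2 * len(vcf.samples)

    records = []
    skipped = 0
    chrom_seen = None
    for v in vcf:
        if region is not None and (
            v.CHROM != region[0] or not (region[1] < v.POS <= region[2])
        ):
            continue
        if chrom_seen is None:
            chrom_seen = v.CHROM
        elif region is None and v.CHROM != chrom_seen:
            raise ValueError("multi-contig VCF requires an explicit region")
        if len(v.ALT) != 1 or not v.is_snp:
            skipped += 1
            continue
        alleles = np.array([[g[0], g[1]] for g in v.genotypes], dtype=int).ravel()
        called = alleles[alleles >= 0]
        nc = called.size
        ac = int((called == 1).sum())
        if nc < 2 or ac == 0 or ac == nc:
            continue
        records.append((v.POS - 1, ac, nc))  # to 0-based

    if region is not None:
        chrom, start, end = region
    else:
        chrom = chrom_seen if chrom_seen is not None else "."
        start = 0
        end = None
        if chrom_seen is not None:
            lengths = dict(zip(vcf.seqnames, vcf.seqlens or []))
            end = lengths.get(chrom_seen)
        if not end:
            last = records[-1][0] + 1 if records else window_bp
            end = int(math.ceil(last / window_bp) * window_bp)

    n_windows = int(math.ceil((end - start) / window_bp))
    S = np.zeros(n_windows, dtype=int)
    pi_sum = np.zeros(n_windows)
    for pos0, ac, nc in records:
        w = (pos0 - start) // window_bp
        if 0 <= w < n_windows:
            S[w] += 1
            pi_sum[w] += 2.0 * ac * (nc - ac) / (nc * (nc - 1))

    rows = []
    for w in range(n_windows):
        ws = start + w * window_bp
        we = min(ws + window_bp, end)
        d = None
        if S[w] > 0 and n_chrom >= 4:
            # window D from its folded spectrum is equivalent to using the
            # window's pi and S directly
            d = _window_tajima_d(n_chrom, int(S[w]), float(pi_sum[w]))
        rows.append((chrom, ws, we, int(S[w]), pi_sum[w] / (we - ws), d))
    windows = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "S", "pi_per_site", "tajima_d"]
    )
    return ScanTrack(windows=windows, n_chromosomes=n_chrom, skipped_records=skipped)


def _window_tajima_d(n: int, S: int, pi: float) -> float:
    from .neutrality import neutrality_constants

    k = neutrality_constants(n)
    return (pi - S / k.a1) / math.sqrt(k.e1 * S + k.e2 * S * (S - 1))


@dataclass
class RegionCall:
    chrom: str
    start: int
    end: int
    span_bp: int
    evidence: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.span_bp == 0


def detect_outlier_region(
    track: ScanTrack,
    focal_interval: tuple[str, int, int],
    pi_quantile: float = 0.95,
    d_min: float = 0.5,
    max_gap_windows: int = 3,
) -> RegionCall:
    """Call the elevated-diversity region around a focal interval.

    Candidate windows have pi at or above the track-wide ``pi_quantile`` and
    Tajima's D >= ``d_min``.  The call is the maximal run of candidate
    windows that overlaps the focal interval, bridging runs of at most
    ``max_gap_windows`` non-candidate windows.  Deterministic given the
    track and thresholds.
    """
    chrom, fstart, fend = focal_interval
    win = track.windows
    on_chrom = win[win["chrom"] == chrom].reset_index(drop=True)
    if on_chrom.empty or fstart < on_chrom["start"].min() or fend > on_chrom["end"].max():
        raise ValueError("focal interval not covered by the scan track")
    pi_thr = float(on_chrom["pi_per_site"].quantile(pi_quantile))
    d = on_chrom["tajima_d"].to_numpy(dtype=float)  # None -> nan
    cand = (on_chrom["pi_per_site"].to_numpy() >= pi_thr) & ~np.isnan(d) & (d >= d_min)

    focal_idx = on_chrom.index[
        (on_chrom["start"] < fend) & (on_chrom["end"] > fstart)
    ].to_numpy()
    seed = [i for i in focal_idx if cand[i]]
    if not seed:
        return RegionCall(chrom=chrom, start=0, end=0, span_bp=0)

    lo, hi = min(seed), max(seed)
    # grow left
    i = lo - 1
    gap = 0
    while i >= 0:
        if cand[i]:
            lo, gap = i, 0
        else:
            gap += 1
            if gap > max_gap_windows:
                break
        i -= 1
    # grow right
    i = hi + 1
    gap = 0
    while i < len(cand):
        if cand[i]:
            hi, gap = i, 0
        else:
            gap += 1
            if gap > max_gap_windows:
                break
        i += 1
    start = int(on_chrom.loc[lo, "start"])
    end = int(on_chrom.loc[hi, "end"])
    block = on_chrom.loc[lo:hi]
    return RegionCall(
        chrom=chrom,
        start=start,
        end=end,
        span_bp=end - start,
        evidence={
            "pi_threshold": pi_thr,
            "mean_pi": float(block["pi_per_site"].mean()),
            "mean_d": float(block["tajima_d"].dropna().mean()),
            "n_windows": int(hi - lo + 1),
        },
    )


def tract_length_age(
    span_bp: int,
    recomb_map: RecombinationMap,
    donor_fraction: float,
    generations_per_year: float = 3.0,
) -> IntrogressionEstimate:
    """Order-of-magnitude age from the extent of the introgressed tract.

    Uses the expected-exponential-tract model E[l_Morgans] = 1/(g (1-alpha)),
    inverted to g = 1/(l (1-alpha)).  The observed span is the full tract,
    whose expectation is twice the one-sided exponential mean, so the
    estimate is biased toward younger ages by up to a factor ~2; it carries
    the APPROXIMATE flag and is meant to corroborate the mutation clock,
    not replace it.
    """
    if span_bp <= 0:
        raise ValueError("span must be positive")
    if not (0.0 < donor_fraction < 1.0):
        raise ValueError("donor fraction must lie strictly between 0 and 1")
    l_morgans = recomb_map.morgans(span_bp)
    generations = 1.0 / (l_morgans * (1.0 - donor_fraction))
    return IntrogressionEstimate(
        novel_allele_fraction=None,
        generations=generations,
        years=generations / generations_per_year,
        method="tract_length",
        flags=[APPROXIMATE],
    )
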