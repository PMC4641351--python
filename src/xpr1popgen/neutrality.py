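"""Site-frequency-spectrum neutrality statistics.

Implements the per-population summary statistics used to characterise
selection at the Xpr1 receptor locus: nucleotide diversity (pi), Watterson's
theta, Tajima's D, and Fu & Li's test statistics, both the outgroup-free
starred forms (D*, F*) and the outgroup-polarised forms (D, F).  Significance
is assessed by simulating the standard neutral coalescent conditioned on the
observed number of segregating sites.

Two published sets of variance constants circulate for the Fu & Li
statistics: the constants as printed in Fu & Li (1993) and the corrected
constants of Simonsen, Churchill & Aquadro (1995).  Both are implemented
behind the ``variant`` switch; ``fu_li_1993`` is the default because it is
the set used by DNAsp and reproduces published population-survey values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "SiteFrequencySpectrum",
    "NeutralityConstants",
    "NeutralityStats",
    "neutrality_constants",
    "sfs_from_haplotypes",
    "pairwise_diversity",
    "watterson_theta",
    "tajimas_d",
    "fu_li_star",
    "fu_li_outgroup",
    "neutrality_pvalue",
    "population_stats",
]

FU_LI_VARIANTS = ("fu_li_1993", "simonsen_1995")


@dataclass(frozen=True)
class SiteFrequencySpectrum:
    """Counts of segregating sites by allele-count class.

    ``counts`` maps an allele-count class ``i`` to the number of sites in
    that class.  For a polarized (unfolded) spectrum ``i`` is the derived
    allele count, 1 <= i <= n-1; for an unpolarized (folded) spectrum ``i``
    is the minor allele count, 1 <= i <= floor(n/2).
    """

    n: int
    counts: Mapping[int, int] = field(default_factory=dict)
    polarized: bool = False

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"need at least 2 chromosomes, got n={self.n}")
        hi = self.n - 1 if self.polarized else self.n // 2
        for i, c in self.counts.items():
            if not (1 <= i <= hi):
                raise ValueError(f"allele-count class {i} out of range [1, {hi}]")
            if c < 0 or c != int(c):
                raise ValueError(f"site count for class {i} must be a nonnegative integer")
        object.__setattr__(self, "counts", dict(self.counts))

    @property
    def S(self) -> int:
        """Number of segregating sites."""
        return sum(self.counts.values())

    @property
    def eta(self) -> int:
        """Total number of mutations (equals S for biallelic sites)."""
        return self.S

    @property
    def eta_s(self) -> int:
        """Singletons: sites where some allele is observed exactly once."""
        s = self.counts.get(1, 0)
        if self.polarized and self.n - 1 != 1:
            s += self.counts.get(self.n - 1, 0)
        return s

    @property
    def eta_e(self) -> int:
        """External (derived singleton) mutations; requires polarization."""
        if not self.polarized:
            raise ValueError("derived singletons require a polarized spectrum")
        return self.counts.get(1, 0)

    def folded(self) -> "SiteFrequencySpectrum":
        if not self.polarized:
            return self
        folded: dict[int, int] = {}
        for i, c in self.counts.items():
            j = min(i, self.n - i)
            folded[j] = folded.get(j, 0) + c
        return SiteFrequencySpectrum(self.n, folded, polarized=False)


@dataclass(frozen=True)
class NeutralityConstants:
    """Sample-size-dependent constants for Tajima's and Fu & Li's tests.

    All entries are pure functions of n (and, for the Fu & Li entries, of
    the published constants variant).
    """

    n: int
    variant: str
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    u_d_star: float
    v_d_star: float
    u_f_star: float
    v_f_star: float
    u_d: float
    v_d: float
    u_f: float
    v_f: float


def _harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i**power for i in range(1, n))


def neutrality_constants(n: int, variant: str = "fu_li_1993") -> NeutralityConstants:
    if n < 4:
        raise ValueError(f"constants require n >= 4, got {n}")
    if variant not in FU_LI_VARIANTS:
        raise ValueError(f"unknown Fu & Li constants variant {variant!r}")
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    an1 = a1 + 1.0 / n  # harmonic number a_{n+1}

    # Tajima (1989)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)

    cn = 2.0 * (n * a1 - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = cn + (n - 2) / (n - 1) ** 2 + (2.0 / (n - 1)) * (
        1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n
    )

    # D* variance constants (identical in both treatments once dn is used)
    v_d_star = ((n / (n - 1)) ** 2 * a2 + a1**2 * dn - 2 * n * a1 * (a1 + 1) / (n - 1) ** 2) / (
        a1**2 + a2
    )
    u_d_star = (n / (n - 1)) * (a1 - n / (n - 1)) - v_d_star

    if variant == "fu_li_1993":
        v_f_star = (
            (2 * n**3 + 110 * n**2 - 255 * n + 153) / (9.0 * n**2 * (n - 1))
            + 2 * (n - 1) * a1 / n**2
            - 8.0 * a2 / n
        ) / (a1**2 + a2)
        u_f_star = ((4 * n**2 + 19 * n + 3 - 12 * (n + 1) * an1) / (3.0 * n * (n - 1))) / a1 - v_f_star
    else:  # simonsen_1995
        v_f_star = (
            dn + 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1)) - (2.0 / (n - 1)) * (4 * a2 - 6 + 8.0 / n)
        ) / (a1**2 + a2)
        u_f_star = (
            n / (n - 1)
            + (n + 1) / (3.0 * (n - 1))
            - 4.0 / (n * (n - 1))
            + 2.0 * (n + 1) / (n - 1) ** 2 * (an1 - 2.0 * n / (n + 1))
        ) / a1 - v_f_star

    # Outgroup-polarised D and F (Fu & Li 1993, with the standard dn/cn forms)
    v_d = 1.0 + a1**2 / (a2 + a1**2) * (cn - (n + 1.0) / (n - 1))
    u_d = a1 - 1.0 - v_d
    v_f = (cn + 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1)) - 2.0 / (n - 1)) / (a1**2 + a2)
    u_f = (
        1.0
        + (n + 1) / (3.0 * (n - 1))
        - 4.0 * (n + 1) / (n - 1) ** 2 * (an1 - 2.0 * n / (n + 1))
    ) / a1 - v_f

    return NeutralityConstants(
        n=n, variant=variant, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2,
        u_d_star=u_d_star, v_d_star=v_d_star, u_f_star=u_f_star, v_f_star=v_f_star,
        u_d=u_d, v_d=v_d, u_f=u_f, v_f=v_f,
    )


def pairwise_diversity(sfs: SiteFrequencySpectrum) -> float:
    """Average number of pairwise differences per sequence (pi).

    pi = sum_i xi_i * 2 i (n-i) / (n (n-1)); identical to averaging
    per-pair difference counts over all C(n,2) chromosome pairs.
    """
    n = sfs.n
    if n < 2:
        raise ValueError("pairwise diversity requires n >= 2")
    return sum(c * 2.0 * i * (n - i) / (n * (n - 1)) for i, c in sfs.counts.items())


def watterson_theta(S: int, n: int) -> float:
    """Watterson's estimator theta_W = S / a1(n) (per sequence)."""
    if n < 2:
        raise ValueError("Watterson's theta requires n >= 2")
    if S == 0:
        return 0.0
    return S / _harmonic(n)


def tajimas_d(sfs: SiteFrequencySpectrum) -> Optional[float]:
    """Tajima's D.  Returns None (undefined) when S = 0."""
    S = sfs.S
    if S == 0:
        return None
    k = neutrality_constants(sfs.n)
    pi = pairwise_diversity(sfs)
    return (pi - S / k.a1) / math.sqrt(k.e1 * S + k.e2 * S * (S - 1))


def fu_li_star(
    sfs: SiteFrequencySpectrum, variant: str = "fu_li_1993"
) -> Optional[tuple[float, float]]:
    """Fu & Li's D* and F* (outgroup-free).

    Singletons are alleles observed exactly once in the sample, regardless
    of ancestral state.  Returns None when S = 0.
    """
    eta = sfs.eta
    if eta == 0:
        return None
    n = sfs.n
    k = neutrality_constants(n, variant)
    eta_s = sfs.eta_s
    pi = pairwise_diversity(sfs)
    d_star = ((n / (n - 1)) * eta - k.a1 * eta_s) / math.sqrt(
        k.u_d_star * eta + k.v_d_star * eta**2
    )
    f_star = (pi - ((n - 1) / n) * eta_s) / math.sqrt(k.u_f_star * eta + k.v_f_star * eta**2)
    return d_star, f_star


def fu_li_outgroup(sfs: SiteFrequencySpectrum) -> Optional[tuple[float, float]]:
    """Fu & Li's D and F with outgroup polarization (eta_e = derived singletons)."""
    if not sfs.polarized:
        raise ValueError("Fu & Li's D/F require a polarized spectrum")
    eta = sfs.eta
    if eta == 0:
        return None
    n = sfs.n
    k = neutrality_constants(n)
    eta_e = sfs.eta_e
    pi = pairwise_diversity(sfs)
    d = (eta - k.a1 * eta_e) / math.sqrt(k.u_d * eta + k.v_d * eta**2)
    f = (pi - eta_e) / math.sqrt(k.u_f * eta + k.v_f * eta**2)
    return d, f


# ---------------------------------------------------------------------------
# Building spectra from haplotype catalogues


def sfs_from_haplotypes(
    catalogue,
    population_counts: Mapping[str, int],
    outgroup=None,
    include_indels: bool = False,
) -> SiteFrequencySpectrum:
    """Site frequency spectrum for one population from a haplotype catalogue.

    ``population_counts`` maps haplotype label -> number of chromosomes in
    the population.  Sites monomorphic in the population are excluded; indel
    sites are excluded by default (they distinguish haplotypes but are not
    nucleotide-diversity sites).  If ``outgroup`` (a Haplotype) is given the
    spectrum is polarized by the outgroup allele; a site where the outgroup
    carries an allele not segregating in the population is folded with a
    warning.
    """
    haps = {h.label: h for h in catalogue.haplotypes}
    labels = []
    for label, c in population_counts.items():
        if c < 0 or c != int(c):
            raise ValueError(f"chromosome count for {label!r} must be a nonnegative integer")
        if label not in haps:
            raise KeyError(f"haplotype {label!r} not in catalogue")
        if c > 0:
            labels.append(label)
    n = int(sum(population_counts.values()))
    panel = catalogue.panel
    counts: dict[int, int] = {}
    polarized = outgroup is not None
    for j, site in enumerate(panel.sites):
        if site.variant_class == "indel" and not include_indels:
            continue
        alt_count = sum(
            population_counts[lab] for lab in labels if haps[lab].alleles[j] == site.alt
        )
        if alt_count == 0 or alt_count == n:
            continue  # monomorphic in this population
        if polarized:
            og = outgroup.alleles[j]
            if og == site.ref:
                cls = alt_count
            elif og == site.alt:
                cls = n - alt_count
            else:
                warnings.warn(
                    f"outgroup allele {og!r} at site {site.site_id} absent from "
                    "the population; site left unpolarized (folded)"
                )
                cls = min(alt_count, n - alt_count)
        else:
            cls = min(alt_count, n - alt_count)
        counts[cls] = counts.get(cls, 0) + 1
    return SiteFrequencySpectrum(n=n, counts=counts, polarized=polarized)


# ---------------------------------------------------------------------------
# Significance by conditional coalescent simulation


def _simulate_null_sfs(n: int, S: int, rng: np.random.Generator) -> SiteFrequencySpectrum:
    """One draw of a folded SFS under the standard coalescent, conditioned on S.

    A Kingman genealogy is simulated and S mutations are dropped on branches
    with probability proportional to branch length (the fixed-S null of
    Hudson 1993).
    """
    # active lineages: number of descendant leaves and birth time
    desc = [1] * n
    birth = [0.0] * n
    t = 0.0
    branch_desc: list[int] = []
    branch_len: list[float] = []
    k = n
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        for idx in (i, j):
            branch_desc.append(desc[idx])
            branch_len.append(t - birth[idx])
        merged = desc[i] + desc[j]
        # remove j first (j > i)
        del desc[j], birth[j]
        del desc[i], birth[i]
        desc.append(merged)
        birth.append(t)
        k -= 1
    w = np.asarray(branch_len)
    hits = rng.multinomial(S, w / w.sum())
    counts: dict[int, int] = {}
    for d, m in zip(branch_desc, hits):
        if m and d < n:
            cls = min(d, n - d)
            counts[cls] = counts.get(cls, 0) + int(m)
    return SiteFrequencySpectrum(n=n, counts=counts, polarized=False)


_STATISTICS = {
    "tajima_d": lambda sfs: tajimas_d(sfs),
    "fu_li_d_star": lambda sfs: fu_li_star(sfs)[0],
    "fu_li_f_star": lambda sfs: fu_li_star(sfs)[1],
}


def neutrality_pvalue(
    statistic_name: str,
    observed: float,
    n: int,
    S: int,
    reps: int = 10000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Two-tailed p-value under the fixed-S standard-coalescent null.

    p = (r + 1) / (reps + 1) where r counts replicates with
    |statistic| >= |observed|.  Deterministic given ``seed``.
    """
    if S < 1:
        raise ValueError("p-values require at least one segregating site")
    if reps < 100:
        raise ValueError("reps < 100 gives meaningless p-values")
    if statistic_name not in _STATISTICS:
        raise KeyError(f"unknown statistic {statistic_name!r}")
    stat = _STATISTICS[statistic_name]
    if rng is None:
        rng = np.random.default_rng(seed)
    r = 0
    for _ in range(reps):
        sim = stat(_simulate_null_sfs(n, S, rng))
        if sim is not None and abs(sim) >= abs(observed):
            r += 1
    return (r + 1) / (reps + 1)


# ---------------------------------------------------------------------------
# Per-population summary


@dataclass
class NeutralityStats:
    """The per-population statistics of a survey table row."""

    n: int
    S: int
    eta: int
    eta_s: int
    pi_per_sequence: float
    pi_per_site: Optional[float]
    theta_w: float
    tajima_d: Optional[float]
    fu_li_d_star: Optional[float]
    fu_li_f_star: Optional[float]
    fu_li_d: Optional[float] = None
    fu_li_f: Optional[float] = None
    p_values: dict = field(default_factory=dict)


def population_stats(
    sfs: SiteFrequencySpectrum,
    surveyed_length_bp: Optional[int] = None,
    variant: str = "fu_li_1993",
    pvalue_reps: int = 0,
    seed: Optional[int] = None,
) -> NeutralityStats:
    """Compute the full statistics row for one population.

    ``surveyed_length_bp`` (L) converts pi per sequence to pi per site; it is
    a required input of the survey design, never assumed.  With
    ``pvalue_reps`` > 0, coalescent p-values are attached for Tajima's D and
    Fu & Li's D*/F*.
    """
    S = sfs.S
    pi = pairwise_diversity(sfs)
    d = tajimas_d(sfs) if S else None
    star = fu_li_star(sfs, variant) if S else None
    og = fu_li_outgroup(sfs) if (S and sfs.polarized) else None
    stats = NeutralityStats(
        n=sfs.n,
        S=S,
        eta=sfs.eta,
        eta_s=sfs.eta_s,
        pi_per_sequence=pi,
        pi_per_site=(pi / surveyed_length_bp) if surveyed_length_bp else None,
        theta_w=watterson_theta(S, sfs.n),
        tajima_d=d,
        fu_li_d_star=star[0] if star else None,
        fu_li_f_star=star[1] if star else None,
        fu_li_d=og[0] if og else None,
        fu_li_f=og[1] if og else None,
    )
    if pvalue_reps and S:
        rng = np.random.default_rng(seed)
        for name in ("tajima_d", "fu_li_d_star", "fu_li_f_star"):
            obs = getattr(stats, name if name != "tajima_d" else "tajima_d")
            if obs is not None:
                stats.p_values[name] = neutrality_pvalue(
                    name, obs, sfs.n, S, reps=pvalue_reps, rng=rng
                )
    return stats
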