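"""Forward Wright-Fisher simulator for the introgression study design.

Simulates a diploid, randomly mating population carrying (i) a focal
haplotype block (the receptor locus) and (ii) a panel of linked
microsatellites under the symmetric stepwise mutation model, embedded in a
recombining region.  An introgression pulse replaces a fraction alpha of
gene copies with donor chromosomes at a configurable time before present;
donor-ancestry tracts are tracked explicitly so that the dating estimators
can be validated against ground truth.

Time runs forward in discrete generations; gametes receive Poisson-many
crossovers placed uniformly on the region.  All randomness flows from a
single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .haplotypes import DiploidGenotypes, Site, SnpPanel
from .introgression import (
    DatingCalibration,
    MsatTable,
    RecombinationMap,
    date_by_new_mutations,
    find_informative_alleles,
    genotype_concordance,
    tract_length_age,
)

import pandas as pd

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_forward",
    "simulate_msat_drift",
    "calibrate_by_simulation",
    "recover_age",
    "simulation_panel",
]

NATIVE, DONOR = 0, 1


def simulation_panel(chrom: str = "chrSim", base_pos: int = 100_000) -> tuple[SnpPanel, dict]:
    """A minimal 3-site panel distinguishing the native and donor haplotypes."""
    sites = [
        Site(f"sv{i + 1}", "simfrag", chrom, base_pos + 40 * i, "A", "G", "noncoding")
        for i in range(3)
    ]
    panel = SnpPanel(sites=sites, surveyed_length_bp=507)
    vectors = {
        NATIVE: tuple(s.ref for s in sites),
        DONOR: tuple(s.alt for s in sites),
    }
    return panel, vectors


@dataclass
class SimConfig:
    """Forward-simulation parameters.

    Rates: ``msat_mu`` is per locus per generation (one +/-1-repeat step,
    equal probability each direction, ``step_bp`` bp per repeat);
    ``recomb_rate_cm_per_mb`` is uniform over ``region_bp``.  The pulse
    replaces ``donor_fraction`` of gene copies ``pulse_time`` generations
    before present.  ``selection_coefficient`` gives additive viability
    selection on the donor focal haplotype (a hook; default neutral).
    """

    seed: int
    diploid_n: int = 1000
    n_generations: int = 700
    sample_size: int = 12
    population_id: str = "sim_pop"
    region_bp: int = 200_000
    focal_pos: int = 100_000
    recomb_rate_cm_per_mb: float = 0.5
    n_msat_loci: int = 9
    msat_positions: Optional[list[int]] = None
    msat_mu: float = 5e-4
    step_bp: int = 2
    native_msat_sizes: Optional[list[int]] = None
    donor_msat_offset_bp: int = 84
    pulse_time: Optional[int] = None
    donor_fraction: float = 0.0
    selection_coefficient: float = 0.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.msat_mu < 0 or self.recomb_rate_cm_per_mb < 0:
            raise ValueError("rates must be nonnegative")
        if not (0.0 <= self.donor_fraction <= 1.0):
            raise ValueError("donor fraction must lie in [0, 1]")
        if self.pulse_time is not None and self.pulse_time >= self.n_generations:
            raise ValueError("pulse must fall within the simulated generations")
        if self.sample_size > self.diploid_n:
            raise ValueError("cannot sample more individuals than the population holds")
        if self.msat_positions is None:
            # loci spread over a 200 kb window centred on the focal locus
            # (clipped to the region), mirroring the genotyped design
            half = min(100_000, self.region_bp // 2 - 1)
            self.msat_positions = [
                int(self.focal_pos - half + (2 * half) * i / (self.n_msat_loci - 1))
                for i in range(self.n_msat_loci)
            ]
        self.n_msat_loci = len(self.msat_positions)
        if self.native_msat_sizes is None:
            self.native_msat_sizes = [151 + 4 * i for i in range(self.n_msat_loci)]
        if len(self.native_msat_sizes) != self.n_msat_loci:
            raise ValueError("one founder size per msat locus required")

    @property
    def donor_msat_sizes(self) -> list[int]:
        return [s + self.donor_msat_offset_bp for s in self.native_msat_sizes]

    @property
    def morgans(self) -> float:
        return self.region_bp * self.recomb_rate_cm_per_mb / 1e8


@dataclass
class SimTruth:
    """Ground truth recorded for the sampled chromosomes."""

    pulse_time: Optional[int]
    donor_fraction: float
    donor_tracts: list[Optional[tuple[float, float]]]  # per sampled chromosome
    donor_focal_sample_freq: float
    novel_mutation_count: int  # donor-background msat alleles differing from the donor founder
    n_donor_allele_obs: int


class _Engine:
    """One Wright-Fisher population: marker arrays plus ancestry segments."""

    def __init__(self, config: SimConfig, rng: np.random.Generator, founder: int = NATIVE):
        self.cfg = config
        self.rng = rng
        n2 = 2 * config.diploid_n
        sizes = config.native_msat_sizes if founder == NATIVE else config.donor_msat_sizes
        self.markers = np.empty((n2, 1 + config.n_msat_loci), dtype=np.int64)
        self.markers[:, 0] = founder
        self.markers[:, 1:] = np.asarray(sizes, dtype=np.int64)
        self.marker_pos = np.array([config.focal_pos] + list(config.msat_positions), dtype=float)
        self.anc: Optional[list] = None  # lazily enabled at the pulse

    def enable_ancestry(self, origin: int = NATIVE) -> None:
        seg = ((0.0, float(self.cfg.region_bp), origin),)
        self.anc = [seg] * (2 * self.cfg.diploid_n)

    def step(self) -> None:
        cfg, rng = self.cfg, self.rng
        n = cfg.diploid_n
        n2 = 2 * n
        if cfg.selection_coefficient != 0.0:
            copies = (self.markers[0::2, 0] == DONOR).astype(float) + (
                self.markers[1::2, 0] == DONOR
            )
            w = (1.0 + cfg.selection_coefficient) ** copies
            p = w / w.sum()
            parents = rng.choice(n, size=n2, p=p)
        else:
            parents = rng.integers(0, n, size=n2)
        which = rng.integers(0, 2, size=n2)
        src = 2 * parents + which
        ncx = rng.poisson(cfg.morgans, size=n2) if cfg.morgans > 0 else np.zeros(n2, dtype=int)

        new_markers = self.markers[src].copy()
        new_anc = [self.anc[s] for s in src] if self.anc is not None else None

        for g in np.nonzero(ncx)[0]:
            cx = np.sort(rng.uniform(0.0, cfg.region_bp, size=ncx[g]))
            a = src[g]
            b = 2 * parents[g] + 1 - which[g]
            # markers: parity of crossovers left of each marker position
            k = np.searchsorted(cx, self.marker_pos)
            odd = (k % 2).astype(bool)
            new_markers[g, odd] = self.markers[b, odd]
            if new_anc is not None:
                new_anc[g] = _splice(self.anc[a], self.anc[b], cx, float(cfg.region_bp))

        if cfg.msat_mu > 0 and cfg.n_msat_loci > 0:
            cells = n2 * cfg.n_msat_loci
            nmut = rng.binomial(cells, cfg.msat_mu)
            if nmut:
                flat = rng.choice(cells, size=nmut, replace=False)
                rows, cols = flat // cfg.n_msat_loci, flat % cfg.n_msat_loci
                steps = rng.choice((-cfg.step_bp, cfg.step_bp), size=nmut)
                np.add.at(new_markers, (rows, 1 + cols), steps)

        self.markers = new_markers
        self.anc = new_anc

    def pulse(self, donor_markers: np.ndarray) -> None:
        """Replace a fraction of gene copies with donor chromosomes."""
        cfg, rng = self.cfg, self.rng
        n2 = 2 * cfg.diploid_n
        k = int(round(cfg.donor_fraction * n2))
        if k == 0:
            return
        if self.anc is None:
            self.enable_ancestry(NATIVE)
        idx = rng.choice(n2, size=k, replace=False)
        pick = rng.integers(0, donor_markers.shape[0], size=k)
        self.markers[idx] = donor_markers[pick]
        self.markers[idx, 0] = DONOR
        donor_seg = ((0.0, float(cfg.region_bp), DONOR),)
        for i in idx:
            self.anc[int(i)] = donor_seg


def _splice(a, b, cx, region: float):
    """Child ancestry segments: alternate between parents a and b at crossovers."""
    segs: list[tuple[float, float, int]] = []
    bounds = [0.0, *map(float, cx), region]
    cur, oth = a, b
    for lo, hi in zip(bounds, bounds[1:]):
        if hi <= lo:
            cur, oth = oth, cur
            continue
        for s, e, o in cur:
            if e <= lo or s >= hi:
                continue
            ns, ne = max(s, lo), min(e, hi)
            if segs and segs[-1][2] == o and segs[-1][1] == ns:
                segs[-1] = (segs[-1][0], ne, o)
            else:
                segs.append((ns, ne, o))
        cur, oth = oth, cur
    return tuple(segs)


def _donor_tract(segments, focal_pos: float) -> Optional[tuple[float, float]]:
    """The donor-ancestry segment containing the focal position, if any."""
    if segments is None:
        return None
    for s, e, o in segments:
        if s <= focal_pos < e:
            return (s, e) if o == DONOR else None
    return None


def simulate_forward(
    config: SimConfig, donor_config: Optional[SimConfig] = None
) -> tuple[DiploidGenotypes, MsatTable, SimTruth]:
    """Run the forward simulation and emit sampled tables plus ground truth.

    Without ``donor_config`` the pulse introduces copies of the donor
    *founder* chromosome.  With it, a donor population is co-simulated and
    the pulse draws from its state at the pulse generation; the returned
    tables then contain both populations' samples.
    """
    rng = np.random.default_rng(config.seed)
    recipient = _Engine(config, rng, founder=NATIVE)
    donor = None
    if donor_config is not None:
        donor = _Engine(donor_config, np.random.default_rng(donor_config.seed), founder=DONOR)

    pulse_gen = None
    if config.pulse_time is not None and config.donor_fraction > 0:
        pulse_gen = config.n_generations - config.pulse_time

    def donor_pool() -> np.ndarray:
        if donor is not None:
            return donor.markers
        pool = np.empty((1, 1 + config.n_msat_loci), dtype=np.int64)
        pool[0, 0] = DONOR
        pool[0, 1:] = np.asarray(config.donor_msat_sizes, dtype=np.int64)
        return pool

    if pulse_gen == 0:
        recipient.pulse(donor_pool())
    for t in range(1, config.n_generations + 1):
        recipient.step()
        if donor is not None:
            donor.step()
        if pulse_gen == t:
            recipient.pulse(donor_pool())

    genotypes_rows: list[tuple[str, str]] = []
    calls: dict[str, dict[str, tuple[str, str]]] = {}
    msat_rows = []
    panel, vectors = simulation_panel()

    tracts: list[Optional[tuple[float, float]]] = []
    donor_focal = 0
    novel = 0
    donor_obs = 0
    donor_sizes = np.asarray(config.donor_msat_sizes, dtype=np.int64)

    def emit_sample(engine: _Engine, cfg: SimConfig, record_truth: bool) -> None:
        nonlocal donor_focal, novel, donor_obs
        chosen = engine.rng.choice(cfg.diploid_n, size=cfg.sample_size, replace=False)
        for i, ind in enumerate(np.sort(chosen)):
            sid = f"{cfg.population_id}_{i:03d}"
            genotypes_rows.append((sid, cfg.population_id))
            c1, c2 = engine.markers[2 * ind], engine.markers[2 * ind + 1]
            v1, v2 = vectors[int(c1[0])], vectors[int(c2[0])]
            calls[sid] = {
                site.site_id: tuple(sorted((v1[j], v2[j])))
                for j, site in enumerate(panel.sites)
            }
            for L in range(cfg.n_msat_loci):
                msat_rows.append(
                    (sid, cfg.population_id, f"ms{L + 1}", int(c1[1 + L]), int(c2[1 + L]))
                )
            if record_truth:
                for chrom_idx in (2 * ind, 2 * ind + 1):
                    seg = engine.anc[chrom_idx] if engine.anc is not None else None
                    tract = _donor_tract(seg, cfg.focal_pos) if seg else None
                    tracts.append(tract)
                    is_donor_focal = (
                        tract is not None
                        if seg is not None
                        else engine.markers[chrom_idx, 0] == DONOR
                    )
                    if is_donor_focal:
                        donor_focal += 1
                        sizes = engine.markers[chrom_idx, 1:]
                        novel += int((sizes != donor_sizes).sum())
                        donor_obs += sizes.size

    emit_sample(recipient, config, record_truth=True)
    if donor is not None:
        emit_sample(donor, donor_config, record_truth=False)

    genotypes = DiploidGenotypes(individuals=genotypes_rows, calls=calls)
    loci = pd.DataFrame(
        {
            "locus_id": [f"ms{L + 1}" for L in range(config.n_msat_loci)],
            "chrom": "chrSim",
            "pos": config.msat_positions,
            "offset_bp": [p - config.focal_pos for p in config.msat_positions],
        }
    )
    msat = MsatTable(
        loci=loci,
        genotypes=pd.DataFrame(
            msat_rows, columns=["sample_id", "population_id", "locus_id", "size1", "size2"]
        ),
    )
    n_sampled_chroms = 2 * config.sample_size
    truth = SimTruth(
        pulse_time=config.pulse_time,
        donor_fraction=config.donor_fraction,
        donor_tracts=tracts,
        donor_focal_sample_freq=donor_focal / n_sampled_chroms,
        novel_mutation_count=novel,
        n_donor_allele_obs=donor_obs,
    )
    return genotypes, msat, truth


# ---------------------------------------------------------------------------
# Fast microsatellite-only drift (no recombination, no ancestry)


def simulate_msat_drift(
    diploid_n: int,
    mu: float,
    generations: int,
    n_loci: int = 9,
    step_bp: int = 2,
    founder_bp: int = 151,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Stepwise-mutation drift of unlinked msat copies; returns sizes (2N, loci).

    Gene copies resample uniformly each generation (haploid Wright-Fisher,
    equivalent to random mating for unlinked neutral loci).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n2 = 2 * diploid_n
    sizes = np.full((n2, n_loci), founder_bp, dtype=np.int64)
    cells = n2 * n_loci
    for _ in range(generations):
        sizes = sizes[rng.integers(0, n2, size=n2)]
        nmut = rng.binomial(cells, mu)
        if nmut:
            flat = rng.choice(cells, size=nmut, replace=False)
            steps = rng.choice((-step_bp, step_bp), size=nmut)
            np.add.at(sizes, (flat // n_loci, flat % n_loci), steps)
    return sizes


def calibrate_by_simulation(
    mu: float,
    grid_generations: Sequence[int] = (75, 150, 300, 600, 1200, 2400),
    reps: int = 6,
    diploid_n: int = 200,
    n_loci: int = 9,
    step_bp: int = 2,
    seed: int = 0,
    generations_per_year: float = 3.0,
) -> DatingCalibration:
    """Build a G(f) calibration by simulating the stepwise-mutation process.

    For each grid age g, the mean fraction of gene copies whose allele
    differs from the founder is recorded as the anchor frequency.  The mean
    fraction depends only on mu and g (every line of descent spans exactly g
    generations; population size affects variance, not the mean), so a small
    population with several replicates suffices.
    """
    rng = np.random.default_rng(seed)
    founder_bp = 151
    anchors = []
    for g in grid_generations:
        fr = []
        for _ in range(reps):
            sizes = simulate_msat_drift(
                diploid_n, mu, g, n_loci=n_loci, step_bp=step_bp,
                founder_bp=founder_bp, rng=rng,
            )
            fr.append(float((sizes != founder_bp).mean()))
        f = float(np.mean(fr))
        if 0.0 < f < 1.0:
            anchors.append((f, float(g)))
    if not anchors:
        raise ValueError("calibration grid produced no usable anchors")
    return DatingCalibration(
        anchors=anchors, mode="linear", generations_per_year=generations_per_year
    )


# ---------------------------------------------------------------------------
# End-to-end parameter recovery


@dataclass
class RecoveryReport:
    true_generations: int
    estimates: pd.DataFrame  # per replicate: mutation, tract, combined, flags
    median_relative_error: Optional[float]
    bias: Optional[float]
    n_flagged: int


def recover_age(
    config: SimConfig,
    estimator_settings: Optional[dict] = None,
    replicates: int = 20,
    seed: int = 0,
) -> RecoveryReport:
    """Simulate, run the full dating chain, and report recovery accuracy.

    Per replicate: co-simulate donor and recipient populations, find the
    donor-informative microsatellite alleles, phase the recipient sample,
    cross-tabulate, date by new mutations (against a calibration regenerated
    from the simulator at matching mu), date by the true donor-tract span,
    and combine the two clocks by geometric mean.  Replicates where an
    estimator is undefined (e.g. no donor homozygotes sampled) are flagged,
    never dropped silently.
    """
    from .haplotypes import phase_homozygote_anchored

    if replicates < 10:
        raise ValueError("need at least 10 replicates for a recovery report")
    if config.pulse_time is None:
        raise ValueError("recovery requires an introgression pulse in the config")
    settings = dict(estimator_settings or {})
    f_donor_min = settings.get("f_donor_min", 0.5)
    f_other_max = settings.get("f_other_max", 0.05)
    donor_generations = settings.get("donor_generations", config.n_generations)

    ss = np.random.SeedSequence(seed)
    cal_seed, *rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(replicates + 1)]
    calibration = calibrate_by_simulation(
        mu=config.msat_mu,
        step_bp=config.step_bp,
        n_loci=config.n_msat_loci,
        seed=cal_seed,
    )
    rec_map = RecombinationMap(config.recomb_rate_cm_per_mb)
    panel, vectors = simulation_panel()

    rows = []
    for r, rseed in enumerate(rep_seeds):
        rs = np.random.SeedSequence(rseed).spawn(2)
        rep_cfg = replace(config, seed=int(rs[0].generate_state(1)[0] % 2**31))
        donor_cfg = replace(
            config,
            seed=int(rs[1].generate_state(1)[0] % 2**31),
            population_id="donor",
            pulse_time=None,
            donor_fraction=0.0,
            n_generations=donor_generations,
        )
        genotypes, msat, truth = simulate_forward(rep_cfg, donor_config=donor_cfg)

        flags = []
        g_mut = g_tract = combined = None
        fraction = None
        try:
            informative = find_informative_alleles(
                msat,
                donor_pop="donor",
                f_donor_min=f_donor_min,
                f_other_max=f_other_max,
                exclude_populations=[rep_cfg.population_id],
            )
            if not informative:
                flags.append("NO_INFORMATIVE_ALLELES")
            catalogue, assignment = phase_homozygote_anchored(genotypes, panel)
            target = catalogue.label_for(vectors[DONOR])
            if target is None:
                flags.append("DONOR_HAPLOTYPE_ABSENT")
            if informative and target is not None:
                conc = genotype_concordance(
                    msat, assignment, target, informative,
                    populations=[rep_cfg.population_id],
                )
                fraction = conc["novel_allele_fraction"]
                if fraction is None:
                    flags.append("NO_DONOR_HOMOZYGOTES")
                else:
                    g_mut = date_by_new_mutations(fraction, calibration).generations
        except (ValueError, KeyError) as exc:
            flags.append(f"ESTIMATOR_ERROR:{exc}")

        spans = [e - s for t in truth.donor_tracts if t is not None for s, e in [t]]
        alpha_hat = truth.donor_focal_sample_freq
        if spans and 0.0 < alpha_hat < 1.0:
            g_tract = tract_length_age(
                int(np.median(spans)), rec_map, alpha_hat
            ).generations
        elif not spans:
            flags.append("NO_DONOR_TRACTS")

        if g_mut is not None and g_mut > 0 and g_tract is not None:
            combined = float(np.sqrt(g_mut * g_tract))
        elif g_tract is not None:
            combined = g_tract
        elif g_mut is not None and g_mut > 0:
            combined = g_mut

        rows.append(
            {
                "replicate": r,
                "novel_fraction": fraction,
                "g_mutation": g_mut,
                "g_tract": g_tract,
                "g_combined": combined,
                "flags": ";".join(flags),
            }
        )

    est = pd.DataFrame(rows)
    g_true = float(config.pulse_time)
    valid = est["g_combined"].dropna()
    rel_err = ((valid - g_true).abs() / g_true).median() if len(valid) else None
    bias = ((valid - g_true) / g_true).median() if len(valid) else None
    return RecoveryReport(
        true_generations=config.pulse_time,
        estimates=est,
        median_relative_error=None if rel_err is None else float(rel_err),
        bias=None if bias is None else float(bias),
        n_flagged=int((est["flags"] != "").sum()),
    )
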