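"""Readers and writers for the pipeline's tabular formats.

Conventions: TSV with header lines and "." as the missing-allele marker;
panel and VCF positions 1-based; BED and scan-track coordinates 0-based
half-open.  All writers produce files that round-trip byte-identically
through their matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .haplotypes import (
    DiploidGenotypes,
    Haplotype,
    HaplotypeCatalogue,
    IupacProfile,
    MISSING,
    Site,
    SnpPanel,
)
from .introgression import MsatTable, RegionCall, ScanTrack


# -- panel ------------------------------------------------------------------

_PANEL_COLS = ["site_id", "fragment_id", "chrom", "pos", "ref", "alt",
               "variant_class", "codon", "codon_pos", "aa_pos"]


def write_panel(panel: SnpPanel, path) -> None:
    rows = []
    for s in panel.sites:
        rows.append([s.site_id, s.fragment_id, s.chrom, s.pos, s.ref, s.alt,
                     s.variant_class, s.codon or ".",
                     s.codon_pos if s.codon_pos is not None else ".",
                     s.aa_pos if s.aa_pos is not None else "."])
    df = pd.DataFrame(rows, columns=_PANEL_COLS)
    df.to_csv(path, sep="\t", index=False)
    with open(path, "a") as fh:
        fh.write(f"#surveyed_length_bp={panel.surveyed_length_bp}\n")


def read_panel(path) -> SnpPanel:
    length = None
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip()]
    for ln in lines:
        if ln.startswith("#surveyed_length_bp="):
            length = int(ln.strip().split("=", 1)[1])
    import io as _io

    df = pd.read_csv(_io.StringIO("".join(ln for ln in lines if not ln.startswith("#"))),
                     sep="\t", dtype=str)
    sites = []
    for _, r in df.iterrows():
        sites.append(Site(
            site_id=r["site_id"], fragment_id=r["fragment_id"], chrom=r["chrom"],
            pos=int(r["pos"]), ref=r["ref"], alt=r["alt"],
            variant_class=r["variant_class"],
            codon=None if r["codon"] == "." else r["codon"],
            codon_pos=None if r["codon_pos"] == "." else int(r["codon_pos"]),
            aa_pos=None if r["aa_pos"] == "." else int(r["aa_pos"]),
        ))
    if length is None:
        raise ValueError(f"panel file {path} lacks the #surveyed_length_bp footer")
    return SnpPanel(sites=sites, surveyed_length_bp=length)


# -- genotypes --------------------------------------------------------------


def write_genotypes(genotypes: DiploidGenotypes, panel: SnpPanel, path) -> None:
    rows = []
    for sid, pop in genotypes.individuals:
        for site in panel.sites:
            a1, a2 = genotypes.calls[sid].get(site.site_id, (MISSING, MISSING))
            rows.append([sid, pop, site.site_id, a1, a2])
    pd.DataFrame(rows, columns=["sample_id", "population_id", "site_id",
                                "allele1", "allele2"]).to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> DiploidGenotypes:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"genotype table {path} is empty")
    individuals, seen = [], set()
    calls: dict[str, dict[str, tuple[str, str]]] = {}
    for _, r in df.iterrows():
        sid, pop = r["sample_id"], r["population_id"]
        if sid not in seen:
            seen.add(sid)
            individuals.append((sid, pop))
            calls[sid] = {}
        calls[sid][r["site_id"]] = (r["allele1"], r["allele2"])
    return DiploidGenotypes(individuals=individuals, calls=calls)


# -- haplotype catalogue ----------------------------------------------------


def write_catalogue(catalogue: HaplotypeCatalogue, path) -> None:
    pops = list(catalogue.counts.columns)
    rows = []
    for h in catalogue.haplotypes:
        rows.append([h.label, "".join(a if len(a) == 1 else f"[{a}]" for a in h.alleles),
                     ",".join(h.alleles)]
                    + [int(catalogue.counts.loc[h.label, p]) for p in pops])
    pd.DataFrame(rows, columns=["label", "pattern", "alleles"] + pops).to_csv(
        path, sep="\t", index=False)


# -- microsatellites --------------------------------------------------------


def write_msat(msat: MsatTable, path, loci_path=None) -> None:
    msat.genotypes.to_csv(path, sep="\t", index=False)
    if loci_path is not None:
        msat.loci.to_csv(loci_path, sep="\t", index=False)


def read_msat(path, loci_path=None) -> MsatTable:
    geno = pd.read_csv(path, sep="\t", dtype={"size1": int, "size2": int})
    if loci_path is not None:
        loci = pd.read_csv(loci_path, sep="\t")
    else:
        loci = pd.DataFrame({"locus_id": sorted(geno["locus_id"].unique())})
        loci["chrom"] = "."
        loci["pos"] = 0
        loci["offset_bp"] = 0
    return MsatTable(loci=loci, genotypes=geno)


# -- stats table ------------------------------------------------------------


def stats_table(rows: dict) -> pd.DataFrame:
    """Survey-shaped report: population rows, Table-1-style columns.

    ``rows`` maps population_id -> (NeutralityStats, n_haplotypes).
    Stars mark statistics with a computed p-value below 0.05; they are
    only appended when p-values were actually computed.
    """
    out = []
    for pop, (st, n_hap) in rows.items():
        def fmt(value, pname):
            if value is None:
                return "n.a."
            s = f"{value:.2f}"
            p = st.p_values.get(pname)
            return s + ("*" if p is not None and p < 0.05 else "")

        out.append({
            "population_id": pop,
            "n_chromosomes": st.n,
            "variable_sites": st.S,
            "haplotypes": n_hap,
            "pi_per_site_x1000": "n.a." if st.pi_per_site is None else f"{st.pi_per_site * 1000:.2f}",
            "tajima_D": fmt(st.tajima_d, "tajima_d"),
            "fu_li_F_star": fmt(st.fu_li_f_star, "fu_li_f_star"),
        })
    return pd.DataFrame(out)


# -- scan / regions ---------------------------------------------------------


def write_scan_track(track: ScanTrack, path) -> None:
    df = track.windows.copy()
    df["tajima_d"] = df["tajima_d"].map(lambda v: "." if v is None or pd.isna(v) else f"{v:.6f}")
    df["pi_per_site"] = df["pi_per_site"].map(lambda v: f"{v:.8g}")
    df.to_csv(path, sep="\t", index=False)


def write_region_bed(calls: Iterable[RegionCall], path, name="introgression_region") -> None:
    with open(path, "w") as fh:
        for c in calls:
            if not c.empty:
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{name}\t{c.span_bp}\n")


# -- profiles / misc --------------------------------------------------------


def read_profiles(fasta_path) -> list[IupacProfile]:
    return [IupacProfile(sample_id=rec.id, sequence=str(rec.seq))
            for rec in SeqIO.parse(str(fasta_path), "fasta")]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_vcf(
    path,
    haplotypes,  # (n_chromosomes, n_sites) 0/1 array
    positions: Sequence[int],  # 1-based
    samples: Sequence[str],
    chrom: str = "chr1",
    contig_length: Optional[int] = None,
) -> None:
    """Write a minimal uncompressed VCF with phased GT fields.

    Chromosome 2i and 2i+1 form sample i.  Intended for generating scan
    inputs from simulated haplotypes.
    """
    import numpy as np

    hap = np.asarray(haplotypes)
    if hap.shape[0] != 2 * len(samples):
        raise ValueError("need two chromosome rows per sample")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_length:
            fh.write(f"##contig=<ID={chrom},length={contig_length}>\n")
        else:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, pos in enumerate(positions):
            gts = "\t".join(
                f"{hap[2 * i, j]}|{hap[2 * i + 1, j]}" for i in range(len(samples))
            )
            fh.write(f"{chrom}\t{pos}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")
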