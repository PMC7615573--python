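"""Readers and writers for the plain-text formats the pipeline speaks.

EIGENSTRAT geno/snp/ind triplets are the native interchange format for
f-statistics work; VCF covers diploid panels; pileup counts travel as a
long-format TSV (chrom, pos, sample, nA, nC, nG, nT); recombination maps
as TSV (chrom, pos, genetic_pos_cM).  Internally positions stay 1-based;
only BED export converts to 0-based half-open intervals.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotype import (
    MISSING,
    GenotypeMatrix,
    PileupCounts,
    make_sample_sheet,
    make_site_table,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Structured parse failure naming the offending file and line."""

    def __init__(self, path, line_no, message):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


# ---------------------------------------------------------------------
# EIGENSTRAT
# ---------------------------------------------------------------------

def read_eigenstrat(geno_path, snp_path, ind_path, ploidy="infer") -> GenotypeMatrix:
    """Read an EIGENSTRAT geno/snp/ind triplet.

    The geno file holds one row per site, one digit per sample
    (alt-allele dose; 9 = missing).  The snp file columns are
    id, chrom, genetic_pos (Morgans), pos, ref, alt; the ind file
    id, sex, population.

    ploidy: "infer" marks a sample diploid iff it carries any dose-2
    call, haploid otherwise; pass an explicit array to override (the
    format itself does not record ploidy).
    """
    snp = pd.read_csv(
        snp_path,
        sep=r"\s+",
        header=None,
        names=["site_id", "chrom", "genetic_pos", "pos", "ref", "alt"],
        dtype={"site_id": str, "chrom": str},
    )
    ind = pd.read_csv(
        ind_path,
        sep=r"\s+",
        header=None,
        names=["sample_id", "sex", "population"],
        dtype=str,
    )
    n_samples = len(ind)
    rows = []
    with open(geno_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if len(line) != n_samples:
                raise ParseError(
                    geno_path,
                    line_no,
                    f"row has {len(line)} genotypes, expected {n_samples}",
                )
            try:
                rows.append([int(c) for c in line])
            except ValueError:
                raise ParseError(geno_path, line_no, f"non-digit genotype in {line!r}")
    if len(rows) != len(snp):
        raise ParseError(
            geno_path,
            len(rows),
            f"{len(rows)} genotype rows but {len(snp)} snp records",
        )
    calls = np.asarray(rows, dtype=np.int8)
    calls[calls == 9] = MISSING
    sites = make_site_table(
        snp["chrom"],
        snp["pos"],
        snp["ref"],
        snp["alt"],
        site_id=snp["site_id"],
        genetic_pos=snp["genetic_pos"].astype(float),
    )
    samples = make_sample_sheet(ind["sample_id"], ind["population"])
    if isinstance(ploidy, str) and ploidy == "infer":
        ploidy = np.where((calls == 2).any(axis=0), 2, 1).astype(np.int8)
    return GenotypeMatrix(sites, samples, calls, np.asarray(ploidy, dtype=np.int8))


def write_eigenstrat(matrix: GenotypeMatrix, geno_path, snp_path, ind_path) -> None:
    """Write a GenotypeMatrix as an EIGENSTRAT triplet (9 = missing)."""
    out = matrix.calls.astype(np.int16).copy()
    out[out == MISSING] = 9
    with open(geno_path, "w") as fh:
        for row in out:
            fh.write("".join(str(int(v)) for v in row) + "\n")
    gp = (
        matrix.sites["genetic_pos"]
        if "genetic_pos" in matrix.sites
        else pd.Series(np.zeros(len(matrix.sites)))
    )
    with open(snp_path, "w") as fh:
        for (_, s), g in zip(matrix.sites.iterrows(), gp):
            fh.write(
                f"{s.site_id}\t{s.chrom}\t{g:.6f}\t{s.pos}\t{s.ref}\t{s.alt}\n"
            )
    with open(ind_path, "w") as fh:
        for _, s in matrix.samples.iterrows():
            fh.write(f"{s.sample_id}\tU\t{s.population}\n")


# ---------------------------------------------------------------------
# VCF (diploid biallelic SNPs)
# ---------------------------------------------------------------------

def read_vcf(vcf_path, sample_subset=None) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF into a diploid matrix.

    Multi-allelic records and indels are skipped (the count is logged);
    diploid GT maps to alt dose 0/1/2 and ``./.`` to missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in vcf.samples]
        if missing:
            raise KeyError(
                f"samples {missing} not in VCF; available: {list(vcf.samples)}"
            )
        vcf.set_samples(list(sample_subset))
    sample_ids = list(vcf.samples)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        gt = var.gt_types.astype(np.int8)  # 0/1/2, 3 = unknown
        gt[gt == 3] = MISSING
        rows.append(gt)
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {vcf_path}")
    sites = make_site_table(chroms, poss, refs, alts)
    samples = make_sample_sheet(sample_ids, ["pop"] * len(sample_ids))
    return GenotypeMatrix(sites, samples, np.asarray(rows, dtype=np.int8))


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, vcf_path) -> None:
    """Write a diploid GenotypeMatrix as an uncompressed VCF 4.2 file."""
    if (matrix.ploidy != 2).any():
        raise ValueError("write_vcf requires an all-diploid matrix")
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, grp in matrix.sites.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples["sample_id"])
            + "\n"
        )
        for i, (_, s) in enumerate(matrix.sites.iterrows()):
            gts = "\t".join(_GT_STRINGS[int(v)] for v in matrix.calls[i])
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.site_id}\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------
# pileup counts TSV
# ---------------------------------------------------------------------

def read_pileup(tsv_path, sites: pd.DataFrame | None = None) -> PileupCounts:
    """Read a long-format pileup TSV (chrom, pos, sample, nA, nC, nG, nT).

    If a site table is given, counts are aligned to it (absent rows mean
    zero coverage) and its ref/alt annotation is kept; otherwise sites
    are taken from the file in sorted order with placeholder A/C alleles.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str, "sample": str})
    required = {"chrom", "pos", "sample", "nA", "nC", "nG", "nT"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"pileup TSV missing columns {sorted(required - set(df.columns))}"
        )
    samples = sorted(df["sample"].unique())
    if sites is None:
        uniq = (
            df[["chrom", "pos"]]
            .drop_duplicates()
            .sort_values(["chrom", "pos"])
            .reset_index(drop=True)
        )
        sites = make_site_table(
            uniq["chrom"], uniq["pos"], ["A"] * len(uniq), ["C"] * len(uniq)
        )
    key = {(c, p): i for i, (c, p) in enumerate(zip(sites["chrom"], sites["pos"]))}
    counts = np.zeros((len(sites), len(samples), 4), dtype=np.int32)
    samp_idx = {s: j for j, s in enumerate(samples)}
    vals = df[["nA", "nC", "nG", "nT"]].to_numpy(dtype=np.int32)
    for row, (c, p, s) in enumerate(zip(df["chrom"], df["pos"], df["sample"])):
        i = key.get((str(c), int(p)))
        if i is not None:
            counts[i, samp_idx[s]] = vals[row]
    return PileupCounts(sites, samples, counts)


def write_pileup(pileup: PileupCounts, tsv_path) -> None:
    """Write pileup counts as a long-format TSV, one row per site x sample."""
    recs = []
    for j, s in enumerate(pileup.samples):
        c = pileup.counts[:, j, :]
        recs.append(
            pd.DataFrame(
                {
                    "chrom": pileup.sites["chrom"],
                    "pos": pileup.sites["pos"],
                    "sample": s,
                    "nA": c[:, 0],
                    "nC": c[:, 1],
                    "nG": c[:, 2],
                    "nT": c[:, 3],
                }
            )
        )
    pd.concat(recs).sort_values(["chrom", "pos", "sample"]).to_csv(
        tsv_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------
# recombination map & BED
# ---------------------------------------------------------------------

def read_recombination_map_table(tsv_path) -> pd.DataFrame:
    """Read a map TSV (chrom, pos, genetic_pos_cM) without interpretation."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "genetic_pos_cM"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"map TSV missing columns {sorted(required - set(df.columns))}"
        )
    return df


def write_bed(intervals: pd.DataFrame, bed_path, extra_columns=()) -> None:
    """Write intervals as BED (0-based half-open).

    ``intervals`` must carry 1-based inclusive ``start``/``end`` bp
    columns alongside ``chrom``; the conversion to BED coordinates
    happens here and only here.
    """
    with open(bed_path, "w") as fh:
        for _, row in intervals.iterrows():
            extra = "".join(f"\t{row[c]}" for c in extra_columns)
            fh.write(f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}{extra}\n")
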