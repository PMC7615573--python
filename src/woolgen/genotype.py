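"""Core genotype data model shared by every analysis stage.

The central container is :class:`GenotypeMatrix`: a site table, a sample
sheet, and a sites x samples call matrix.  Calls are integer allele doses
(haploid 0/1, diploid 0/1/2) with a single reserved missing sentinel that
every downstream operation must handle explicitly -- silently treating
missing data as the reference allele biases allele frequencies and hence
every f-statistic built on them.

Positions are 1-based throughout (the EIGENSTRAT/VCF convention); BED
exports convert to 0-based half-open at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reserved sentinel for a missing call.  Never 0.
MISSING: int = -1

BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

SAMPLE_ROLES = ("focal", "panel", "outgroup")


def is_transversion(ref, alt) -> np.ndarray:
    """Vectorised purine<->pyrimidine test for allele pairs.

    A site is a transversion iff its two alleles are not {A,G} and not
    {C,T}.  Transversions are immune to post-mortem C->T / G->A
    deamination damage, which is why ancient-DNA statistics restrict to
    them.
    """
    ref = np.asarray(ref, dtype="U1")
    alt = np.asarray(alt, dtype="U1")
    ref_pur = np.isin(ref, list(_PURINES))
    alt_pur = np.isin(alt, list(_PURINES))
    return ref_pur != alt_pur


def make_site_table(
    chrom,
    pos,
    ref,
    alt,
    site_id=None,
    genetic_pos=None,
) -> pd.DataFrame:
    """Assemble and validate a site table.

    Columns: site_id, chrom, pos (1-based int), ref, alt,
    is_transversion, and optionally genetic_pos (Morgans).  Positions
    must be strictly increasing within each chromosome and alleles must
    be distinct single nucleotides.
    """
    chrom = np.asarray(chrom, dtype=str)
    pos = np.asarray(pos, dtype=np.int64)
    ref = np.char.upper(np.asarray(ref, dtype="U1"))
    alt = np.char.upper(np.asarray(alt, dtype="U1"))
    n = len(pos)
    if not (len(chrom) == len(ref) == len(alt) == n):
        raise ValueError("site table columns have unequal lengths")
    if site_id is None:
        site_id = np.array([f"{c}_{p}" for c, p in zip(chrom, pos)])
    bad = ~(np.isin(ref, BASES) & np.isin(alt, BASES))
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(f"non-ACGT allele at site index {i}: {ref[i]}/{alt[i]}")
    if (ref == alt).any():
        i = int(np.flatnonzero(ref == alt)[0])
        raise ValueError(f"ref == alt at site index {i}")
    df = pd.DataFrame(
        {
            "site_id": np.asarray(site_id, dtype=str),
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "is_transversion": is_transversion(ref, alt),
        }
    )
    if genetic_pos is not None:
        df["genetic_pos"] = np.asarray(genetic_pos, dtype=float)
    for _, grp in df.groupby("chrom", sort=False):
        p = grp["pos"].to_numpy()
        if (np.diff(p) <= 0).any():
            raise ValueError(
                f"positions not strictly increasing on chrom {grp['chrom'].iloc[0]}"
            )
    return df


def make_sample_sheet(sample_id, population, role=None) -> pd.DataFrame:
    """Assemble a sample sheet (sample_id, population, role)."""
    sample_id = np.asarray(sample_id, dtype=str)
    population = np.asarray(population, dtype=str)
    if len(sample_id) != len(population):
        raise ValueError("sample_id and population lengths differ")
    if len(set(sample_id)) != len(sample_id):
        raise ValueError("sample_ids are not unique")
    if (population == "").any():
        raise ValueError("empty population label")
    if role is None:
        role = np.full(len(sample_id), "panel")
    role = np.asarray(role, dtype=str)
    unknown = set(role) - set(SAMPLE_ROLES)
    if unknown:
        raise ValueError(f"unknown sample roles: {sorted(unknown)}")
    return pd.DataFrame(
        {"sample_id": sample_id, "population": population, "role": role}
    )


@dataclass
class GenotypeMatrix:
    """Sites x samples allele-dose matrix with population labels.

    ``calls[i, j]`` is the alt-allele dose of sample j at site i:
    0/1 for haploid samples, 0/1/2 for diploid samples, or ``MISSING``.
    ``ploidy[j]`` declares each sample's ploidy (1 or 2), so a matrix
    may mix pseudo-haploid ancient samples with diploid modern ones.
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    calls: np.ndarray
    ploidy: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.ploidy is None:
            self.ploidy = np.full(len(self.samples), 2, dtype=np.int8)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int8)
        self.validate()

    # -- structure ----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if len(self.ploidy) != len(self.samples):
            raise ValueError("ploidy length != number of samples")
        if not np.isin(self.ploidy, (1, 2)).all():
            raise ValueError("ploidy must be 1 or 2")
        ok = self.calls == MISSING
        ok |= (self.calls >= 0) & (self.calls <= self.ploidy[None, :])
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"call {self.calls[i, j]} out of range for ploidy "
                f"{self.ploidy[j]} at site {i}, sample {j}"
            )

    def sample_index(self, sample_id: str) -> int:
        idx = np.flatnonzero(self.samples["sample_id"].to_numpy() == sample_id)
        if len(idx) == 0:
            avail = ", ".join(self.samples["sample_id"])
            raise KeyError(f"sample {sample_id!r} not found; available: {avail}")
        return int(idx[0])

    def population_columns(self, population: str) -> np.ndarray:
        cols = np.flatnonzero(self.samples["population"].to_numpy() == population)
        if len(cols) == 0:
            avail = ", ".join(sorted(set(self.samples["population"])))
            raise KeyError(
                f"population {population!r} not found; available: {avail}"
            )
        return cols

    def subset_sites(self, mask_or_index) -> "GenotypeMatrix":
        sites = self.sites.iloc[mask_or_index].reset_index(drop=True)
        return GenotypeMatrix(
            sites, self.samples.copy(), self.calls[mask_or_index], self.ploidy
        )

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        cols = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(
            self.sites.copy(),
            self.samples.iloc[cols].reset_index(drop=True),
            self.calls[:, cols],
            self.ploidy[cols],
        )


@dataclass
class PileupCounts:
    """Per-site, per-sample read base counts (A, C, G, T order).

    ``counts`` has shape (n_sites, n_samples, 4).  A total of zero at a
    site means no coverage there, which is normal at ~3x depth.
    """

    sites: pd.DataFrame  # shares the SiteTable schema (chrom, pos, ref, alt)
    samples: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim == 2:
            self.counts = self.counts[:, None, :]
        if self.counts.shape != (len(self.sites), len(self.samples), 4):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.sites)}, {len(self.samples)}, 4)"
            )
        if (self.counts < 0).any():
            raise ValueError("negative read counts")

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(
                f"sample {sample!r} not in pileup; available: {self.samples}"
            ) from None

    def mean_coverage(self, sample=None) -> float:
        if sample is None:
            return float(self.counts.sum() / (len(self.sites) * len(self.samples)))
        j = self.sample_index(sample)
        return float(self.counts[:, j, :].sum() / len(self.sites))


# ---------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------

def pseudo_haploid_call(pileup: PileupCounts, sample: str, rng) -> np.ndarray:
    """Random-read haploid calls for one sample.

    At each site, reads supporting bases other than the declared ref/alt
    are dropped; one read is then drawn uniformly at random among the
    remainder and determines the call (0=ref, 1=alt).  Zero supporting
    reads give ``MISSING``.  This is the standard way to genotype
    low-coverage ancient genomes without a likelihood model, and the
    uniform draw makes ties reproducible under a seeded RNG.
    """
    rng = np.random.default_rng(rng)
    j = pileup.sample_index(sample)
    ref_idx = np.array([BASE_INDEX[b] for b in pileup.sites["ref"]])
    alt_idx = np.array([BASE_INDEX[b] for b in pileup.sites["alt"]])
    rows = np.arange(len(pileup.sites))
    n_ref = pileup.counts[rows, j, ref_idx].astype(np.int64)
    n_alt = pileup.counts[rows, j, alt_idx].astype(np.int64)
    total = n_ref + n_alt
    calls = np.full(len(rows), MISSING, dtype=np.int8)
    covered = total > 0
    u = rng.random(len(rows))
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(covered, n_alt / np.maximum(total, 1), 0.0)
    calls[covered] = (u[covered] < p_alt[covered]).astype(np.int8)
    return calls


def filter_transversions(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Retain transversion sites only; idempotent."""
    mask = matrix.sites["is_transversion"].to_numpy()
    if not mask.any():
        raise ValueError(
            "no transversion sites survive filtering; "
            "pass transversions_only=False to keep transitions"
        )
    return matrix.subset_sites(mask)


def population_frequencies(matrix: GenotypeMatrix, population: str):
    """Per-site alt-allele frequency and non-missing allele count.

    Returns ``(freq, n_alleles)`` arrays of length n_sites.  Haploid
    samples contribute one allele, diploid samples two.  Sites with no
    data in the population get ``freq = nan`` and ``n_alleles = 0``.
    """
    cols = matrix.population_columns(population)
    sub = matrix.calls[:, cols]
    ploidy = matrix.ploidy[cols]
    present = sub != MISSING
    n_alleles = (present * ploidy[None, :]).sum(axis=1)
    alt = np.where(present, sub, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return freq, n_alleles
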