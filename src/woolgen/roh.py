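"""Low-coverage heterozygosity and runs of homozygosity (ROH).

At ~3x depth genotypes cannot be called confidently, so heterozygosity
is estimated by drawing two reads (without replacement) at each site
with at least two allele-supporting reads: two draws from a true
heterozygote mismatch half the time, so twice the genome-wide mismatch
fraction estimates the per-site heterozygosity.  The same per-window
mismatch rate drives ROH calling: windows far below the genome-wide
median heterozygosity are runs of homozygosity, and the genome fraction
in long tracts (>= 2.5 Mbp by default) summarizes recent inbreeding.

All of this is restricted to transversion sites upstream, which removes
post-mortem deamination damage from the signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import BASE_INDEX, PileupCounts

logger = logging.getLogger(__name__)

DEFAULT_L_MIN = 2_500_000
DEFAULT_WINDOW = 1_000_000
DEFAULT_THRESHOLD_FRACTION = 0.25
DEFAULT_MIN_SITES = 20


@dataclass
class HetEstimate:
    het_rate: float
    n_sites_used: int
    method: str = "two-read draw, x2 correction"

    def __post_init__(self):
        if not 0.0 <= self.het_rate <= 1.0:
            raise ValueError(f"het_rate {self.het_rate} outside [0, 1]")


@dataclass
class RohProfile:
    """ROH tracts plus the fraction of assayable genome in long tracts.

    ``tracts`` columns: chrom, start, end (1-based inclusive bp), length
    (= end - start + 1, the tract span), assayable_bp (sum of assayable
    ROH window lengths inside the span; bridged unassayable gaps do not
    count), mean_het.  ``f_roh`` is the assayable bp inside tracts whose
    span >= L_min, divided by the total assayable window length.
    """

    tracts: pd.DataFrame
    f_roh: float
    l_min: int
    assayable_length: int
    total_window_length: int = 0

    def __post_init__(self):
        if not 0.0 <= self.f_roh <= 1.0:
            raise ValueError(f"f_roh {self.f_roh} outside [0, 1]")


# ---------------------------------------------------------------------

def downsample_pileup(pileup: PileupCounts, target_mean_coverage: float, rng,
                      sample=None) -> PileupCounts:
    """Binomially thin reads so each sample's mean depth hits the target.

    Every read is kept independently with probability target/current,
    computed per sample so that samples of different depths become
    directly comparable after thinning.
    """
    rng = np.random.default_rng(rng)
    samples = pileup.samples if sample is None else [sample]
    counts = pileup.counts.copy()
    for s in samples:
        j = pileup.sample_index(s)
        current = pileup.mean_coverage(s)
        if target_mean_coverage > current + 1e-12:
            raise ValueError(
                f"target coverage {target_mean_coverage} exceeds current "
                f"{current:.3f} for sample {s!r}"
            )
        p = target_mean_coverage / current if current > 0 else 0.0
        if p >= 1.0:
            continue
        counts[:, j, :] = rng.binomial(pileup.counts[:, j, :], p)
    return PileupCounts(pileup.sites.copy(), list(pileup.samples), counts)


def _two_read_mismatch(pileup: PileupCounts, sample: str, rng,
                       transversions_only: bool = True):
    """Per-site two-read-draw mismatch indicators.

    Returns (site_index, mismatch_bool) over usable sites: transversion
    sites with >= 2 reads supporting the declared ref/alt alleles.  The
    draw is without replacement, so a 2x site never samples the same
    read twice; the number of alt reads among the two draws is
    hypergeometric.
    """
    rng = np.random.default_rng(rng)
    j = pileup.sample_index(sample)
    sites = pileup.sites
    ref_idx = np.array([BASE_INDEX[b] for b in sites["ref"]])
    alt_idx = np.array([BASE_INDEX[b] for b in sites["alt"]])
    rows = np.arange(len(sites))
    n_ref = pileup.counts[rows, j, ref_idx].astype(np.int64)
    n_alt = pileup.counts[rows, j, alt_idx].astype(np.int64)
    usable = (n_ref + n_alt) >= 2
    if transversions_only and "is_transversion" in sites:
        usable &= sites["is_transversion"].to_numpy()
    idx = np.flatnonzero(usable)
    # draws of 2 reads without replacement: alt count ~ Hypergeometric
    k_alt = rng.hypergeometric(n_alt[idx], n_ref[idx], 2)
    return idx, k_alt == 1


def estimate_heterozygosity(pileup: PileupCounts, sample: str, rng,
                            transversions_only: bool = True,
                            error_rate: float | None = None) -> HetEstimate:
    """Global two-read heterozygosity for one sample.

    het = 2 x (fraction of usable sites whose two drawn reads mismatch).
    No sequencing-error floor is subtracted by default; if the caller
    supplies an error rate epsilon, 2 x 2eps(1-eps) is removed (two
    draws mismatch when exactly one read is erroneous).
    """
    idx, mism = _two_read_mismatch(pileup, sample, rng, transversions_only)
    if len(idx) == 0:
        raise ValueError(
            f"no usable site (>=2 allele-supporting reads) for sample {sample!r}"
        )
    het = 2.0 * float(mism.mean())
    method = "two-read draw, x2 correction"
    if error_rate is not None:
        het = max(het - 2.0 * 2.0 * error_rate * (1.0 - error_rate), 0.0)
        method += f", error floor eps={error_rate} subtracted"
    return HetEstimate(min(het, 1.0), int(len(idx)), method)


def window_het(pileup: PileupCounts, sample: str, rng,
               window_bp: int = DEFAULT_WINDOW, step_bp: int | None = None,
               min_sites: int = DEFAULT_MIN_SITES,
               chrom_lengths: dict | None = None,
               transversions_only: bool = True) -> pd.DataFrame:
    """Windowed two-read mismatch rates along the genome.

    Windows tile each chromosome from position 1 to its last site (or a
    supplied length).  Each usable site is drawn once and its mismatch
    indicator aggregated into every window containing it, so with
    step = window the windows partition sites exactly.  Windows with
    fewer than ``min_sites`` usable sites are flagged unassayable.

    Columns: chrom, start, end (1-based inclusive), n_usable, het,
    assayable.
    """
    if step_bp is None:
        step_bp = window_bp
    if step_bp <= 0 or window_bp <= 0 or step_bp > window_bp:
        raise ValueError("need 0 < step_bp <= window_bp")
    idx, mism = _two_read_mismatch(pileup, sample, rng, transversions_only)
    pos = pileup.sites["pos"].to_numpy()
    chrom = pileup.sites["chrom"].to_numpy()
    out = []
    for ch in pd.unique(chrom):
        sel = chrom[idx] == ch
        on_ch = idx[sel]
        m_ch = mism[sel]
        length = (
            int(chrom_lengths[ch]) if chrom_lengths else
            int(pos[chrom == ch].max())
        )
        starts = np.arange(1, length + 1, step_bp)
        ends = np.minimum(starts + window_bp - 1, length)
        if step_bp == window_bp:
            # non-overlapping: one bincount pass over sites
            nw = len(starts)
            wi = (pos[on_ch] - 1) // window_bp
            n_us = np.bincount(wi, minlength=nw)
            n_mm = np.bincount(wi, weights=m_ch.astype(float), minlength=nw)
            with np.errstate(invalid="ignore"):
                het_w = np.where(n_us > 0, 2.0 * n_mm / np.maximum(n_us, 1), np.nan)
            for s, e, n, h in zip(starts, ends, n_us, het_w):
                out.append((ch, int(s), int(e), int(n), float(h), n >= min_sites))
        else:
            for start, end in zip(starts, ends):
                in_w = (pos[on_ch] >= start) & (pos[on_ch] <= end)
                n = int(in_w.sum())
                het = 2.0 * float(m_ch[in_w].mean()) if n else np.nan
                out.append((ch, int(start), int(end), n, het, n >= min_sites))
    return pd.DataFrame(
        out, columns=["chrom", "start", "end", "n_usable", "het", "assayable"]
    )


def call_roh(window_stats: pd.DataFrame,
             threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
             l_min: int = DEFAULT_L_MIN) -> RohProfile:
    """Merge low-heterozygosity windows into ROH tracts.

    A window is ROH when its het falls below threshold_fraction times
    the genome-wide median het of assayable windows.  Adjacent ROH
    windows merge; unassayable windows bridge a tract without adding to
    its assayable length.  f_roh is computed over tracts whose span is
    at least l_min.
    """
    ws = window_stats
    assay = ws[ws["assayable"]]
    if len(assay) == 0:
        raise ValueError("no assayable windows")
    median_het = float(assay["het"].median())
    if median_het == 0.0:
        raise ValueError(
            "genome-wide median window het is 0 (degenerate input); "
            "inspect the raw window table instead of calling ROH"
        )
    cutoff = threshold_fraction * median_het
    tracts = []
    for ch, grp in ws.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        current = None  # [start, end, assayable_bp, het_sum, n_windows]
        pending_gap = []
        for _, w in grp.iterrows():
            wlen = int(w["end"]) - int(w["start"]) + 1
            if not w["assayable"]:
                if current is not None:
                    pending_gap.append(w)
                continue
            if w["het"] < cutoff:
                if current is None:
                    current = [int(w["start"]), int(w["end"]), wlen, w["het"], 1]
                else:
                    current[1] = int(w["end"])  # bridged gaps extend the span
                    current[2] += wlen
                    current[3] += w["het"]
                    current[4] += 1
                pending_gap = []
            else:
                if current is not None:
                    tracts.append((ch, *current))
                current = None
                pending_gap = []
        if current is not None:
            tracts.append((ch, *current))
    df = pd.DataFrame(
        tracts,
        columns=["chrom", "start", "end", "assayable_bp", "het_sum", "n_windows"],
    )
    if len(df):
        df["length"] = df["end"] - df["start"] + 1
        df["mean_het"] = df["het_sum"] / df["n_windows"]
    else:
        df["length"] = pd.Series(dtype=int)
        df["mean_het"] = pd.Series(dtype=float)
    df = df[["chrom", "start", "end", "length", "assayable_bp", "mean_het"]]
    assayable_length = int(
        (assay["end"] - assay["start"] + 1).sum()
    )
    long = df[df["length"] >= l_min]
    f_roh = float(long["assayable_bp"].sum() / assayable_length)
    total_window_length = int((ws["end"] - ws["start"] + 1).sum())
    logger.info(
        "call_roh: %d tracts (%d >= %.2g bp), f_roh=%.4f",
        len(df), len(long), float(l_min), f_roh,
    )
    return RohProfile(df.reset_index(drop=True), f_roh, int(l_min),
                      assayable_length, total_window_length)


def roh_summary(profile: RohProfile, sample: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": sample,
                "f_roh": profile.f_roh,
                "n_tracts": int((profile.tracts["length"] >= profile.l_min).sum()),
                "L_min": profile.l_min,
                "assayable_length": profile.assayable_length,
            }
        ]
    )
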