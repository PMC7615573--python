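"""f-statistics with weighted block-jackknife uncertainty.

Implements outgroup-f3, the ABBA-BABA D-statistic, f4, and the f4-ratio
admixture-proportion estimator on population allele frequencies, each as
a ratio of genome-wide block sums with delete-one-block jackknife
standard errors (blocks of 5 Mbp by default, well beyond the range of
linkage disequilibrium in dogs).

Conventions
-----------
outgroup_f3(O; A, B)   = mean over sites of (o - a)(o - b)
d_statistic(W, X, Y, Z) = sum (w - x)(y - z) / sum (w + x - 2wx)(y + z - 2yz)
f4(A, O; X, C)          = mean over sites of (a - o)(x - c)
f4_ratio                = f4(A, O; X, C) / f4(A, O; B, C), the proportion
                          of B-related ancestry in X under a one-pulse
                          mixture of B-like and C-like sources.

Every statistic uses complete cases across exactly the populations it
involves, so site counts legitimately differ between comparisons in a
panel scan.  Lowercase letters denote per-site alt-allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix, filter_transversions, population_frequencies

DEFAULT_BLOCK_SPAN = 5_000_000


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------
# blocks and the jackknife engine
# ---------------------------------------------------------------------

def assign_blocks(sites: pd.DataFrame, block_span: int = DEFAULT_BLOCK_SPAN) -> np.ndarray:
    """Assign each site to a contiguous genomic block of ~block_span bp.

    Blocks never cross chromosome boundaries and are numbered
    consecutively in site order.
    """
    if block_span <= 0:
        raise ValueError("block_span must be positive")
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    raw = pos // block_span
    # new block wherever chrom or bin changes
    new = np.ones(len(sites), dtype=bool)
    if len(sites) > 1:
        new[1:] = (chrom[1:] != chrom[:-1]) | (raw[1:] != raw[:-1])
    return np.cumsum(new) - 1


def block_jackknife(per_block_num, per_block_den, per_block_weights):
    """Weighted delete-one-block jackknife for a ratio of sums.

    The pooled estimate is sum(num)/sum(den); each pseudovalue deletes
    one block and recomputes the full ratio.  Weights (normally block
    site counts) enter through Busing's weighted jackknife variance,
    which is the standard genome-block formulation.

    Returns (estimate, se).
    """
    num = np.asarray(per_block_num, dtype=float)
    den = np.asarray(per_block_den, dtype=float)
    w = np.asarray(per_block_weights, dtype=float)
    keep = w > 0
    num, den, w = num[keep], den[keep], w[keep]
    g = len(w)
    if g < 2:
        raise InsufficientDataError(
            f"block jackknife needs >=2 blocks with nonzero weight, got {g}"
        )
    tot_num, tot_den, n = num.sum(), den.sum(), w.sum()
    if tot_den == 0:
        raise InsufficientDataError("zero denominator across all blocks")
    theta = tot_num / tot_den
    with np.errstate(divide="ignore", invalid="ignore"):
        loo = (tot_num - num) / (tot_den - den)
    # a block carrying the entire denominator leaves no delete-one ratio;
    # fall back to the pooled estimate for that pseudovalue
    loo = np.where(np.isfinite(loo), loo, theta)
    h = n / w
    theta_j = g * theta - ((1.0 - w / n) * loo).sum()
    tau = h * theta - (h - 1.0) * loo
    var = ((tau - theta_j) ** 2 / (h - 1.0)).sum() / g
    return float(theta), float(np.sqrt(max(var, 0.0)))


@dataclass
class FStatResult:
    """One f-statistic estimate with its jackknife uncertainty."""

    statistic: str
    estimate: float
    se: float
    z: float
    n_blocks: int
    n_sites: int
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "statistic": self.statistic,
            "estimate": self.estimate,
            "se": self.se,
            "z": self.z,
            "n_blocks": self.n_blocks,
            "n_sites": self.n_sites,
        }
        d.update({f"pop_{k}": v for k, v in self.config.items()})
        return d


def _ratio_result(statistic, num_site, den_site, blocks, config) -> FStatResult:
    nb = blocks.max() + 1
    per_num = np.bincount(blocks, weights=num_site, minlength=nb)
    per_den = np.bincount(blocks, weights=den_site, minlength=nb)
    weights = np.bincount(blocks, minlength=nb).astype(float)
    est, se = block_jackknife(per_num, per_den, weights)
    z = est / se if se > 0 else float("nan")
    return FStatResult(
        statistic, est, se, z, int((weights > 0).sum()), len(num_site), config
    )


# ---------------------------------------------------------------------
# the statistics
# ---------------------------------------------------------------------

def outgroup_f3(
    matrix: GenotypeMatrix,
    outgroup: str,
    pop_a: str,
    pop_b: str,
    block_span: int = DEFAULT_BLOCK_SPAN,
    transversions_only: bool = True,
) -> FStatResult:
    """f3(O; A, B): shared genetic drift of A and B relative to outgroup O.

    Larger values mean more shared ancestry between A and B since their
    divergence from O; ranking a panel of B's against a fixed A finds
    A's closest relatives.
    """
    f, blocks = _prepare_with_span(
        matrix, (outgroup, pop_a, pop_b), transversions_only, block_span
    )
    o, a, b = f[outgroup], f[pop_a], f[pop_b]
    num = (o - a) * (o - b)
    return _ratio_result(
        "f3", num, np.ones_like(num), blocks,
        {"O": outgroup, "A": pop_a, "B": pop_b},
    )


def d_statistic(
    matrix: GenotypeMatrix,
    w_pop: str,
    x_pop: str,
    y_pop: str,
    z_pop: str,
    block_span: int = DEFAULT_BLOCK_SPAN,
    transversions_only: bool = True,
) -> FStatResult:
    """ABBA-BABA D for the tree (((W, X), Y), Z-outgroup).

    Zero under the null of no gene flow between Y and either W or X;
    positive D indicates excess allele sharing between X and Y.  For
    haploid 0/1 calls the estimator reduces to
    (nABBA - nBABA) / (nABBA + nBABA).
    """
    f, blocks = _prepare_with_span(
        matrix, (w_pop, x_pop, y_pop, z_pop), transversions_only, block_span
    )
    w, x, y, z = f[w_pop], f[x_pop], f[y_pop], f[z_pop]
    # orientation: positive D = ABBA excess = excess sharing between X and Y
    # (so that D((PCD, focal), test, outgroup) > 0 flags gene flow into focal)
    num = (x - w) * (y - z)
    den = (w + x - 2 * w * x) * (y + z - 2 * y * z)
    if den.sum() == 0:
        raise InsufficientDataError(
            f"{len(num)} sites have data in all four populations but none is "
            "informative (no ABBA/BABA configuration)"
        )
    return _ratio_result(
        "D", num, den, blocks,
        {"W": w_pop, "X": x_pop, "Y": y_pop, "Z": z_pop},
    )


def f4(
    matrix: GenotypeMatrix,
    pop_a: str,
    outgroup: str,
    pop_x: str,
    pop_c: str,
    block_span: int = DEFAULT_BLOCK_SPAN,
    transversions_only: bool = True,
) -> FStatResult:
    """f4(A, O; X, C): drift shared between the (A,O) and (X,C) pairs."""
    f, blocks = _prepare_with_span(
        matrix, (pop_a, outgroup, pop_x, pop_c), transversions_only, block_span
    )
    a, o, x, c = f[pop_a], f[outgroup], f[pop_x], f[pop_c]
    num = (a - o) * (x - c)
    return _ratio_result(
        "f4", num, np.ones_like(num), blocks,
        {"A": pop_a, "O": outgroup, "X": pop_x, "C": pop_c},
    )


def f4_ratio(
    matrix: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    outgroup: str,
    pop_x: str,
    pop_c: str,
    block_span: int = DEFAULT_BLOCK_SPAN,
    transversions_only: bool = True,
) -> FStatResult:
    """Admixture proportion alpha = f4(A,O;X,C) / f4(A,O;B,C).

    Models X as a mixture of a B-related source (proportion alpha) and a
    C-related source (1 - alpha); A must be a clade with B relative to
    (O, X, C).  The ratio is jackknifed jointly: each pseudovalue
    deletes one block and recomputes the full ratio, which keeps the SE
    honest when numerator and denominator are correlated.
    """
    pops = (pop_a, pop_b, outgroup, pop_x, pop_c)
    f, blocks = _prepare_with_span(matrix, pops, transversions_only, block_span)
    a, b, o, x, c = f[pop_a], f[pop_b], f[outgroup], f[pop_x], f[pop_c]
    num = (a - o) * (x - c)
    den = (a - o) * (b - c)
    if abs(den.sum()) < 1e-9:
        raise InsufficientDataError(
            "uninformative reference quartet: |f4(A,O;B,C)| below numerical floor"
        )
    res = _ratio_result(
        "f4_ratio", num, den, blocks,
        {"A": pop_a, "B": pop_b, "O": outgroup, "X": pop_x, "C": pop_c},
    )
    res.config["ci_2se"] = (res.estimate - 2 * res.se, res.estimate + 2 * res.se)
    return res


def _prepare_with_span(matrix, populations, transversions_only, block_span):
    if transversions_only:
        matrix = filter_transversions(matrix)
    freqs, counts = {}, {}
    for p in set(populations):
        freqs[p], counts[p] = population_frequencies(matrix, p)
    mask = np.ones(matrix.n_sites, dtype=bool)
    for p in set(populations):
        mask &= counts[p] > 0
    if not mask.any():
        raise InsufficientDataError(
            f"no site has data in all of {sorted(set(populations))}"
        )
    blocks = assign_blocks(matrix.sites[mask].reset_index(drop=True), block_span)
    return {p: freqs[p][mask] for p in freqs}, blocks


def scan_panel(
    matrix: GenotypeMatrix,
    focal: str,
    panel_list,
    statistic_config: dict,
    block_span: int = DEFAULT_BLOCK_SPAN,
    transversions_only: bool = True,
) -> pd.DataFrame:
    """Run one statistic per panel population against a fixed focal.

    statistic_config selects the statistic and its fixed populations:
      {"stat": "f3", "outgroup": O}           -> f3(O; focal, panel)
      {"stat": "d", "w": W, "z": Z}           -> D(W, focal, panel, Z)

    Per-row failures are recorded in an ``error`` column and the scan
    continues.  Rows are sorted by estimate (descending; ties broken by
    panel label) so the closest relatives come first.
    """
    stat = statistic_config["stat"]
    rows = []
    for pop in panel_list:
        rec = {"panel": pop}
        try:
            if stat == "f3":
                r = outgroup_f3(
                    matrix, statistic_config["outgroup"], focal, pop,
                    block_span, transversions_only,
                )
            elif stat == "d":
                r = d_statistic(
                    matrix, statistic_config["w"], focal, pop,
                    statistic_config["z"], block_span, transversions_only,
                )
            else:
                raise ValueError(f"unknown scan statistic {stat!r}")
            rec.update(
                estimate=r.estimate, se=r.se, z=r.z,
                n_blocks=r.n_blocks, n_sites=r.n_sites, error="",
            )
        except (InsufficientDataError, KeyError, ValueError) as exc:
            rec.update(
                estimate=np.nan, se=np.nan, z=np.nan,
                n_blocks=0, n_sites=0, error=str(exc),
            )
        rows.append(rec)
    df = pd.DataFrame(
        rows,
        columns=["panel", "estimate", "se", "z", "n_blocks", "n_sites", "error"],
    )
    return df.sort_values(
        ["estimate", "panel"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)


def results_table(results) -> pd.DataFrame:
    """Tabulate FStatResults for TSV export."""
    rows = []
    for r in results:
        pops = ",".join(
            f"{k}={v}" for k, v in r.config.items() if isinstance(v, str)
        )
        rows.append(
            {
                "statistic": r.statistic,
                "pops": pops,
                "estimate": r.estimate,
                "se": r.se,
                "z": r.z,
                "n_blocks": r.n_blocks,
                "n_sites": r.n_sites,
            }
        )
    return pd.DataFrame(rows)
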