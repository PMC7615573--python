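"""Local-ancestry decoding and tract-length admixture dating.

A two-state hidden Markov model assigns each position of the focal
(pseudo-haploid) genome to one of two ancestral populations using panel
allele frequencies as emission probabilities.  Under a single admixture
pulse t generations ago with minor-ancestry fraction alpha, recombination
breaks the migrant chromosome segments so that minor-ancestry tract
lengths (in Morgans) are approximately Exponential with rate
(1 - alpha) * t; inverting the mean tract length therefore dates the
pulse, and a generation time (3 years for dogs) converts generations to
calendar years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import MISSING

logger = logging.getLogger(__name__)

ANCESTRIES = ("PCD", "EUR")  # state 0, state 1
DEFAULT_GENERATION_TIME = 3.0


class RecombinationMap:
    """Piecewise-linear physical <-> genetic map, in Morgans.

    Anchored at (pos bp, genetic_pos Morgans) pairs per chromosome with
    linear interpolation between anchors (and clamping beyond them).
    """

    def __init__(self, anchors: dict):
        self.anchors = {}
        for chrom, (pos, gen) in anchors.items():
            pos = np.asarray(pos, dtype=float)
            gen = np.asarray(gen, dtype=float)
            if len(pos) != len(gen) or len(pos) < 2:
                raise ValueError(f"chrom {chrom}: need >=2 map anchors")
            if (np.diff(pos) <= 0).any() or (np.diff(gen) < 0).any():
                raise ValueError(f"chrom {chrom}: map anchors not monotone")
            self.anchors[str(chrom)] = (pos, gen)

    @classmethod
    def uniform(cls, chrom_lengths: dict, cm_per_mb: float = 1.0) -> "RecombinationMap":
        rate = cm_per_mb / 100.0 / 1e6  # Morgans per bp
        return cls(
            {
                ch: (np.array([1.0, float(L)]), np.array([0.0, (L - 1) * rate]))
                for ch, L in chrom_lengths.items()
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RecombinationMap":
        """Build from a (chrom, pos, genetic_pos_cM) table; cM -> Morgans."""
        anchors = {}
        for ch, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("pos")
            anchors[str(ch)] = (
                grp["pos"].to_numpy(dtype=float),
                grp["genetic_pos_cM"].to_numpy(dtype=float) / 100.0,
            )
        return cls(anchors)

    def genetic_pos(self, chrom: str, pos) -> np.ndarray:
        if str(chrom) not in self.anchors:
            raise KeyError(f"chrom {chrom!r} not covered by recombination map")
        p, g = self.anchors[str(chrom)]
        return np.interp(np.asarray(pos, dtype=float), p, g)

    def total_morgans(self) -> float:
        return float(sum(g[-1] - g[0] for _, g in self.anchors.values()))


@dataclass
class AncestryTractSet:
    """Decoded ancestry segments tiling the assayed genome.

    ``tracts`` columns: chrom, start, end (1-based inclusive bp),
    ancestry ("PCD"/"EUR"), length_morgans.
    """

    tracts: pd.DataFrame
    posterior_eur_fraction: float
    eur_fraction_morgans: float
    alpha: float
    t_init: float

    def minor_lengths_morgans(self, minor: str = "EUR") -> np.ndarray:
        sel = self.tracts["ancestry"] == minor
        return self.tracts.loc[sel, "length_morgans"].to_numpy(dtype=float)


@dataclass
class AdmixtureDateResult:
    t_hat: float
    se_t: float
    alpha: float
    mean_tract_morgans: float
    n_tracts: int
    generation_time: float = DEFAULT_GENERATION_TIME
    years_before: float = field(init=False)

    def __post_init__(self):
        if self.t_hat <= 0:
            raise ValueError("t_hat must be positive")
        self.years_before = self.t_hat * self.generation_time

    def to_dict(self) -> dict:
        return {
            "t_hat": self.t_hat,
            "se_t": self.se_t,
            "alpha": self.alpha,
            "mean_tract_morgans": self.mean_tract_morgans,
            "n_tracts": self.n_tracts,
            "generation_time": self.generation_time,
            "years_before": self.years_before,
        }


# ---------------------------------------------------------------------
# HMM decode
# ---------------------------------------------------------------------

def _emission_logprobs(calls, freq, n_alleles):
    """log P(observed haploid call | panel) with a pseudocount.

    The panel alt frequency f from n sampled alleles is shrunk to
    (f*n + 0.5) / (n + 1), which keeps emissions finite when the panel
    is fixed for one allele.
    """
    p_alt = (freq * n_alleles + 0.5) / (n_alleles + 1.0)
    p_obs = np.where(calls == 1, p_alt, 1.0 - p_alt)
    return np.log(p_obs)


def _viterbi_two_state(log_e, switch_p, pi):
    """Viterbi path for a 2-state chain with per-step switch probabilities.

    log_e: (n, 2) emission log-probs; switch_p: (n-1,) probability mass
    leaving the current state, distributed to states by their stationary
    probabilities pi.
    """
    n = log_e.shape[0]
    stay = np.log((1.0 - switch_p)[:, None] + switch_p[:, None] * pi[None, :])
    move = np.log(switch_p[:, None] * pi[None, :])
    # transition log-matrix at step i: T[a, b] = stay if a == b else move (to b)
    delta = np.log(pi) + log_e[0]
    back = np.zeros((n, 2), dtype=np.int8)
    for i in range(1, n):
        s, m = stay[i - 1], move[i - 1]
        # candidates for arriving in state b: from b (stay) or from 1-b (move)
        cand0 = (delta[0] + s[0], delta[1] + m[0])
        cand1 = (delta[0] + m[1], delta[1] + s[1])
        b0 = 0 if cand0[0] >= cand0[1] else 1
        b1 = 0 if cand1[0] >= cand1[1] else 1
        delta = np.array([cand0[b0] + log_e[i, 0], cand1[b1] + log_e[i, 1]])
        back[i, 0], back[i, 1] = b0, b1
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def _posterior_two_state(log_e, switch_p, pi):
    """Forward-backward posterior P(state=EUR) per site (scaled)."""
    n = log_e.shape[0]
    e = np.exp(log_e - log_e.max(axis=1, keepdims=True))
    fwd = np.empty((n, 2))
    f = pi * e[0]
    fwd[0] = f / f.sum()
    for i in range(1, n):
        sp = switch_p[i - 1]
        trans = (1.0 - sp) * np.eye(2) + sp * np.tile(pi, (2, 1))
        f = (fwd[i - 1] @ trans) * e[i]
        fwd[i] = f / f.sum()
    bwd = np.empty((n, 2))
    bwd[-1] = 1.0
    for i in range(n - 2, -1, -1):
        sp = switch_p[i]
        trans = (1.0 - sp) * np.eye(2) + sp * np.tile(pi, (2, 1))
        b = trans @ (e[i + 1] * bwd[i + 1])
        bwd[i] = b / b.sum()
    post = fwd * bwd
    post /= post.sum(axis=1, keepdims=True)
    return post[:, 1]


def ancestry_hmm_decode(
    calls: np.ndarray,
    sites: pd.DataFrame,
    pcd_freq: np.ndarray,
    pcd_n: np.ndarray,
    eur_freq: np.ndarray,
    eur_n: np.ndarray,
    rec_map: RecombinationMap,
    alpha: float,
    t_init: float,
) -> AncestryTractSet:
    """Decode PCD vs EUR ancestry along a pseudo-haploid genome.

    Stationary state probabilities are (1 - alpha, alpha); between sites
    separated by d Morgans the chain leaves its state with probability
    1 - exp(-t_init * d) and re-draws it from the stationary
    distribution, the standard one-pulse ancestry-switch model.  The
    Viterbi path is segmented into tracts (breakpoints midway between
    flanking informative sites); the forward-backward posterior EUR
    fraction is reported alongside.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha outside [0, 1]")
    calls = np.asarray(calls)
    have_panel = (pcd_n > 0) & (eur_n > 0) & np.isfinite(pcd_freq) & np.isfinite(eur_freq)
    focal_ok = calls != MISSING
    usable = focal_ok & have_panel
    if focal_ok.sum() and have_panel[focal_ok].mean() < 0.5:
        raise ValueError(
            "panel frequencies missing at >50% of the focal genome's sites"
        )
    if usable.sum() == 0:
        raise ValueError("no usable site for ancestry decoding")
    pi = np.array([1.0 - alpha, alpha])
    rows = []
    post_acc, post_n = 0.0, 0
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    for ch in pd.unique(chrom_arr):
        m = usable & (chrom_arr == ch)
        if m.sum() == 0:
            continue
        pos = pos_arr[m]
        gen = rec_map.genetic_pos(ch, pos)
        log_e = np.column_stack(
            [
                _emission_logprobs(calls[m], pcd_freq[m], pcd_n[m]),
                _emission_logprobs(calls[m], eur_freq[m], eur_n[m]),
            ]
        )
        d = np.diff(gen)
        switch_p = np.clip(1.0 - np.exp(-t_init * d), 1e-12, 1.0 - 1e-12)
        if alpha in (0.0, 1.0):
            path = np.full(len(pos), int(alpha), dtype=np.int8)
            post = np.full(len(pos), float(alpha))
        else:
            path = _viterbi_two_state(log_e, switch_p, pi)
            post = _posterior_two_state(log_e, switch_p, pi)
        post_acc += post.sum()
        post_n += len(post)
        # segment the path into tracts with midpoints as breakpoints
        change = np.flatnonzero(path[1:] != path[:-1])
        bounds = np.concatenate([[0], change + 1, [len(path)]])
        for k in range(len(bounds) - 1):
            i0, i1 = bounds[k], bounds[k + 1] - 1
            start = pos[i0] if k == 0 else (pos[bounds[k] - 1] + pos[i0]) // 2 + 1
            end = pos[i1] if k == len(bounds) - 2 else (pos[i1] + pos[i1 + 1]) // 2
            g0, g1 = rec_map.genetic_pos(ch, [start, end])
            rows.append(
                (ch, int(start), int(end), ANCESTRIES[path[i0]], float(g1 - g0))
            )
    tracts = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "ancestry", "length_morgans"]
    )
    tot_m = tracts["length_morgans"].sum()
    eur_m = tracts.loc[tracts["ancestry"] == "EUR", "length_morgans"].sum()
    return AncestryTractSet(
        tracts,
        posterior_eur_fraction=float(post_acc / post_n),
        eur_fraction_morgans=float(eur_m / tot_m) if tot_m > 0 else float("nan"),
        alpha=alpha,
        t_init=t_init,
    )


# ---------------------------------------------------------------------
# dating
# ---------------------------------------------------------------------

def fit_tract_dating(
    tracts_or_lengths,
    alpha: float,
    rng=None,
    n_boot: int = 1000,
    generation_time: float = DEFAULT_GENERATION_TIME,
    length_floor_morgans: float = 0.0,
    min_tracts: int = 5,
) -> AdmixtureDateResult:
    """Date a one-pulse admixture from minor-ancestry tract lengths.

    Minor-ancestry tract lengths (Morgans) are modelled as Exponential
    with rate (1 - alpha) * t, giving the MLE
    t_hat = 1 / ((1 - alpha) * mean(length)).  If a length floor is
    applied (tracts below decoding resolution dropped), the mean is
    floor-corrected (for a left-truncated exponential,
    E[L | L > c] = c + 1/rate).  The SE is a nonparametric bootstrap
    over tracts.
    """
    if isinstance(tracts_or_lengths, AncestryTractSet):
        minor = "EUR" if alpha <= 0.5 else "PCD"
        lengths = tracts_or_lengths.minor_lengths_morgans(minor)
    else:
        lengths = np.asarray(tracts_or_lengths, dtype=float)
    if length_floor_morgans > 0:
        n_before = len(lengths)
        lengths = lengths[lengths >= length_floor_morgans]
        if n_before - len(lengths):
            logger.info(
                "fit_tract_dating: dropped %d tracts below the %.4g M floor",
                n_before - len(lengths), length_floor_morgans,
            )
    if len(lengths) < min_tracts:
        raise ValueError(
            f"insufficient tracts for dating: {len(lengths)} < {min_tracts}"
        )
    rng = np.random.default_rng(rng)

    def _t_hat(ls):
        mean_eff = ls.mean() - length_floor_morgans
        if mean_eff <= 0:
            return np.nan
        return 1.0 / ((1.0 - alpha) * mean_eff)

    t_hat = _t_hat(lengths)
    boots = np.array(
        [
            _t_hat(rng.choice(lengths, size=len(lengths), replace=True))
            for _ in range(n_boot)
        ]
    )
    se = float(np.nanstd(boots, ddof=1))
    return AdmixtureDateResult(
        t_hat=float(t_hat),
        se_t=se,
        alpha=alpha,
        mean_tract_morgans=float(lengths.mean()),
        n_tracts=int(len(lengths)),
        generation_time=generation_time,
    )


def generations_to_years(t: float, generation_time: float = DEFAULT_GENERATION_TIME) -> float:
    """Convert generations since admixture to calendar years."""
    if t < 0:
        raise ValueError("generations must be non-negative")
    return t * generation_time


def decode_and_date(
    calls,
    sites,
    pcd_freq,
    pcd_n,
    eur_freq,
    eur_n,
    rec_map,
    alpha,
    t_init: float = 10.0,
    rng=None,
    refine: bool = True,
    **dating_kwargs,
) -> tuple[AncestryTractSet, AdmixtureDateResult]:
    """Two-stage pipeline: decode with t_init, date, optionally re-decode.

    One refinement pass re-runs the decode with the estimated t, which
    removes most of the sensitivity to the initial guess.
    """
    tract_set = ancestry_hmm_decode(
        calls, sites, pcd_freq, pcd_n, eur_freq, eur_n, rec_map, alpha, t_init
    )
    date = fit_tract_dating(tract_set, alpha, rng=rng, **dating_kwargs)
    if refine:
        tract_set = ancestry_hmm_decode(
            calls, sites, pcd_freq, pcd_n, eur_freq, eur_n, rec_map, alpha,
            date.t_hat,
        )
        date = fit_tract_dating(tract_set, alpha, rng=rng, **dating_kwargs)
    return tract_set, date
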