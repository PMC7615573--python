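"""Synthetic data with known ground truth for every pipeline stage.

Population structure is simulated at the allele-frequency level with the
Balding-Nichols model: a branch with drift parameter F turns a parent
frequency p into a Beta(p(1-F)/F, (1-p)(1-F)/F) draw, whose mean is p
and variance F p (1-p) -- so branch drifts map directly onto expected
f-statistic values without any coalescent machinery.  The fixed
admixture graph mirrors the study design: an outgroup (gray fox), a
European breed clade (two sampled breeds A and B, whose common ancestor
is the true source of the focal dog's minor ancestry), and a
pre-colonial dog (PCD) clade providing both the focal dog's major
ancestry and an ancient reference population.

The focal genome is built as a one-pulse admixed haploid: ancestry
breakpoints fall as a Poisson process with rate t per Morgan along a
recombination map and each segment is European with probability alpha,
which makes minor-ancestry tract lengths Exponential with rate
(1-alpha) t -- the quantity the dating stage inverts.

Read-level data (Poisson depth, uniform error), planted zero-het ROH
tracts, and codon alignments evolved with per-gene omega on a fixed
canid tree complete the fixture set.  Every generator takes an explicit
seed and the ground truth is returned beside the data, never consumed
by inference code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dnds import _BASES, CODON_TO_AA, SENSE_CODONS, CodonAlignment
from .genotype import (
    MISSING,
    GenotypeMatrix,
    PileupCounts,
    make_sample_sheet,
    make_site_table,
)
from .tracts import RecombinationMap

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("A", "T"),
    ("C", "G"), ("C", "T"), ("G", "T"),
]


# ---------------------------------------------------------------------
# Balding-Nichols drift
# ---------------------------------------------------------------------

def simulate_frequencies(parent_freq, F: float, rng) -> np.ndarray:
    """One Balding-Nichols drift step: Beta draws around the parent.

    E[child] = parent and Var[child] = F * p * (1 - p).  F = 0 is the
    identity; F = 1 fixes each site to 1 with probability p, else 0.
    """
    rng = np.random.default_rng(rng)
    p = np.asarray(parent_freq, dtype=float)
    if not 0.0 <= F <= 1.0:
        raise ValueError("F outside [0, 1]")
    if F == 0.0:
        return p.copy()
    if F == 1.0:
        return (rng.random(p.shape) < p).astype(float)
    scale = (1.0 - F) / F
    return rng.beta(np.maximum(p * scale, 1e-12), np.maximum((1 - p) * scale, 1e-12))


# ---------------------------------------------------------------------
# admixture graph
# ---------------------------------------------------------------------

@dataclass
class AdmixtureGraphSpec:
    """Study-like admixture graph and genome layout.

    Drift parameters per branch of the fixed topology::

        root -(outgroup)-> GrayFox
        root -(dog)------> dog ancestor
        dog  -(split_eur)-> EUR ancestor -(breed)-> EurA, EurB
        dog  -(split_pcd)-> PCD ancestor -(breed)-> PCD_PaC
                            PCD ancestor -(source)-> PCD panel
        focal "Woolly" = one-pulse mix: EUR ancestor (alpha) x PCD panel
                         source (1 - alpha), t generations ago.
    """

    n_sites: int = 50_000
    chrom_lengths: dict = field(
        default_factory=lambda: {str(i): 100_000_000 for i in range(1, 21)}
    )
    cm_per_mb: float = 1.0
    alpha: float = 0.16
    t_admix: float = 11.0
    drifts: dict = field(
        default_factory=lambda: {
            "outgroup": 0.30,
            "dog": 0.02,
            "split_eur": 0.08,
            "split_pcd": 0.12,
            "breed": 0.03,
            "source": 0.02,
        }
    )
    panel_sizes: dict = field(
        default_factory=lambda: {
            "GrayFox": 2, "EurA": 4, "EurB": 4, "PCD_PaC": 2, "PCD": 4,
        }
    )
    ancestral_freq_range: tuple = (0.05, 0.95)
    focal_missing_rate: float = 0.03
    focal_name: str = "Woolly"
    #: draw the focal ancestry iid per site instead of as tracts --
    #: appropriate when sites are meant to be unlinked
    unlinked: bool = False

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha outside [0, 1]")
        if self.t_admix < 1:
            raise ValueError("t_admix must be >= 1 generation")
        for k, v in self.drifts.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"drift {k}={v} outside [0, 1]")


@dataclass
class SimulatedTruth:
    """Ground truth carried beside every simulated dataset."""

    alpha: float = float("nan")
    t_admix: float = float("nan")
    tracts: pd.DataFrame | None = None
    het_rate: float = float("nan")
    roh_tracts: pd.DataFrame | None = None
    gene_omega: dict | None = None

    def to_json(self, path) -> None:
        payload = {
            "alpha": self.alpha,
            "t_admix": self.t_admix,
            "het_rate": self.het_rate,
            "tracts": None if self.tracts is None else self.tracts.to_dict("list"),
            "roh_tracts": (
                None if self.roh_tracts is None else self.roh_tracts.to_dict("list")
            ),
            "gene_omega": self.gene_omega,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimulatedTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            alpha=d["alpha"],
            t_admix=d["t_admix"],
            tracts=None if d["tracts"] is None else pd.DataFrame(d["tracts"]),
            het_rate=d["het_rate"],
            roh_tracts=(
                None if d["roh_tracts"] is None else pd.DataFrame(d["roh_tracts"])
            ),
            gene_omega=d["gene_omega"],
        )


def _graph_frequencies(spec: AdmixtureGraphSpec, rng) -> dict:
    lo, hi = spec.ancestral_freq_range
    p0 = rng.uniform(lo, hi, spec.n_sites)
    d = spec.drifts
    p_dog = simulate_frequencies(p0, d["dog"], rng)
    p_eur_anc = simulate_frequencies(p_dog, d["split_eur"], rng)
    p_pcd_anc = simulate_frequencies(p_dog, d["split_pcd"], rng)
    return {
        "GrayFox": simulate_frequencies(p0, d["outgroup"], rng),
        "EurA": simulate_frequencies(p_eur_anc, d["breed"], rng),
        "EurB": simulate_frequencies(p_eur_anc, d["breed"], rng),
        "PCD_PaC": simulate_frequencies(p_pcd_anc, d["breed"], rng),
        "PCD": simulate_frequencies(p_pcd_anc, d["source"], rng),
        "_eur_source": p_eur_anc,
    }


def _site_layout(spec: AdmixtureGraphSpec, rng):
    """Random distinct site positions spread across chromosomes."""
    lengths = np.array(list(spec.chrom_lengths.values()), dtype=float)
    chrom_names = list(spec.chrom_lengths.keys())
    alloc = np.maximum(
        np.round(spec.n_sites * lengths / lengths.sum()).astype(int), 1
    )
    # trim or pad to the exact total
    while alloc.sum() > spec.n_sites:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < spec.n_sites:
        alloc[np.argmin(alloc)] += 1
    chroms, positions = [], []
    for name, L, k in zip(chrom_names, lengths, alloc):
        # distinct random positions without materializing a permutation
        pos = np.unique(rng.integers(1, int(L) + 1, size=int(k * 1.1) + 16))
        while len(pos) < k:
            pos = np.unique(
                np.concatenate([pos, rng.integers(1, int(L) + 1, size=k)])
            )
        if len(pos) > k:
            pos = np.sort(rng.choice(pos, size=k, replace=False))
        chroms.append(np.full(k, name))
        positions.append(pos)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), len(pos))
    ref = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    alt = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    return make_site_table(chrom, pos, ref, alt)


def _focal_ancestry(spec: AdmixtureGraphSpec, rec_map: RecombinationMap, rng):
    """One-pulse Markov ancestry along the map; returns truth tracts."""
    rows = []
    for ch, L in spec.chrom_lengths.items():
        g_end = float(rec_map.genetic_pos(ch, L))
        n_bp = rng.poisson(spec.t_admix * g_end)
        breaks_m = np.sort(rng.uniform(0.0, g_end, n_bp))
        edges_m = np.concatenate([[0.0], breaks_m, [g_end]])
        labels = (rng.random(len(edges_m) - 1) < spec.alpha).astype(int)
        p_anchor, g_anchor = rec_map.anchors[ch]
        edges_bp = np.interp(edges_m, g_anchor, p_anchor)
        for k in range(len(labels)):
            start = 1 if k == 0 else int(np.floor(edges_bp[k])) + 1
            end = int(np.floor(edges_bp[k + 1]))
            if end < start:
                continue
            rows.append(
                (
                    ch,
                    start,
                    end,
                    "EUR" if labels[k] else "PCD",
                    float(edges_m[k + 1] - edges_m[k]),
                )
            )
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "ancestry", "length_morgans"]
    )
    # merge adjacent same-label segments (iid labels can repeat)
    merged = []
    for ch, grp in df.groupby("chrom", sort=False):
        cur = None
        for rec in grp.itertuples(index=False):
            if cur is not None and rec.ancestry == cur[3]:
                cur[2] = rec.end
                cur[4] += rec.length_morgans
            else:
                if cur is not None:
                    merged.append(tuple(cur))
                cur = [rec.chrom, rec.start, rec.end, rec.ancestry,
                       rec.length_morgans]
        if cur is not None:
            merged.append(tuple(cur))
    return pd.DataFrame(
        merged, columns=["chrom", "start", "end", "ancestry", "length_morgans"]
    )


def simulate_admixed_genotypes(spec: AdmixtureGraphSpec, seed):
    """Full study-like genotype fixture.

    Returns (GenotypeMatrix, SimulatedTruth, RecombinationMap).  Panel
    samples are diploid binomial draws from their population frequency;
    the focal sample is a pseudo-haploid whose allele at each site is a
    Bernoulli draw from the frequency of its local ancestry's source
    population (EUR ancestor or PCD panel source), with a little
    missingness emulating uneven coverage.
    """
    rng = np.random.default_rng(seed)
    sites = _site_layout(spec, rng)
    rec_map = RecombinationMap.uniform(spec.chrom_lengths, spec.cm_per_mb)
    freqs = _graph_frequencies(spec, rng)
    truth_tracts = None if spec.unlinked else _focal_ancestry(spec, rec_map, rng)

    sample_ids, pops, roles, cols, ploidies = [], [], [], [], []
    for pop, n in spec.panel_sizes.items():
        p = freqs[pop]
        for i in range(n):
            sample_ids.append(f"{pop}_{i}")
            pops.append(pop)
            roles.append("outgroup" if pop == "GrayFox" else "panel")
            cols.append(rng.binomial(2, p).astype(np.int8))
            ploidies.append(2)

    # focal ancestry per site: iid when unlinked, else from the truth tracts
    if spec.unlinked:
        anc = (rng.random(len(sites)) < spec.alpha).astype(int)
    else:
        anc = np.zeros(len(sites), dtype=int)
        site_chrom = sites["chrom"].to_numpy()
        site_pos = sites["pos"].to_numpy()
        for ch, grp in truth_tracts.groupby("chrom", sort=False):
            on = site_chrom == ch
            idx = np.searchsorted(grp["end"].to_numpy(), site_pos[on])
            idx = np.minimum(idx, len(grp) - 1)
            anc[on] = (grp["ancestry"].to_numpy() == "EUR")[idx]
    p_focal = np.where(anc == 1, freqs["_eur_source"], freqs["PCD"])
    focal = (rng.random(len(sites)) < p_focal).astype(np.int8)
    miss = rng.random(len(sites)) < spec.focal_missing_rate
    focal[miss] = MISSING
    sample_ids.append(spec.focal_name)
    pops.append(spec.focal_name)
    roles.append("focal")
    cols.append(focal)
    ploidies.append(1)

    samples = make_sample_sheet(sample_ids, pops, roles)
    calls = np.column_stack(cols).astype(np.int8)
    matrix = GenotypeMatrix(sites, samples, calls, np.array(ploidies, dtype=np.int8))
    truth = SimulatedTruth(
        alpha=spec.alpha, t_admix=spec.t_admix, tracts=truth_tracts
    )
    return matrix, truth, rec_map


# ---------------------------------------------------------------------
# ROH planting and read simulation
# ---------------------------------------------------------------------

def plant_roh(chrom_lengths: dict, target_fraction: float, rng,
              length_range=(3_000_000, 15_000_000),
              max_attempts: int = 10_000) -> pd.DataFrame:
    """Sample non-overlapping zero-het tracts covering ~target_fraction.

    Tracts (uniform lengths within ``length_range``) are placed on
    length-weighted random chromosomes until the covered fraction
    reaches the target; the final tract may overshoot by less than one
    tract length.
    """
    rng = np.random.default_rng(rng)
    genome = float(sum(chrom_lengths.values()))
    if target_fraction <= 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    names = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in names], dtype=float)
    weights /= weights.sum()
    placed = {c: [] for c in names}
    total = 0
    attempts = 0
    while total < target_fraction * genome and attempts < max_attempts:
        attempts += 1
        ch = names[rng.choice(len(names), p=weights)]
        L = int(chrom_lengths[ch])
        tract_len = int(rng.integers(length_range[0], length_range[1] + 1))
        # truncate the final tract so the realized fraction lands on target
        deficit = int(np.ceil(target_fraction * genome - total))
        tract_len = min(tract_len, max(deficit, 1))
        if tract_len >= L:
            continue
        start = int(rng.integers(1, L - tract_len + 1))
        end = start + tract_len - 1
        if any(not (end < s or start > e) for s, e in placed[ch]):
            continue
        placed[ch].append((start, end))
        total += tract_len
    rows = [
        (ch, s, e) for ch, tr in placed.items() for s, e in sorted(tr)
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_diploid_sites(chrom_lengths: dict, het_rate: float, rng,
                           site_spacing: int = 200,
                           roh_tracts: pd.DataFrame | None = None):
    """Regularly spaced assayable sites with true diploid genotypes.

    Outside planted ROH tracts each site is heterozygous (ref/alt) with
    probability het_rate, else homozygous for a random allele; inside
    tracts every site is homozygous.  Returns (site table, genotype
    codes) with genotypes 0 = hom ref, 1 = het, 2 = hom alt.
    """
    rng = np.random.default_rng(rng)
    chroms, positions = [], []
    for ch, L in chrom_lengths.items():
        pos = np.arange(site_spacing, int(L), site_spacing, dtype=np.int64)
        chroms.append(np.full(len(pos), str(ch)))
        positions.append(pos)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)
    n = len(pos)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), n)
    ref = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    alt = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    sites = make_site_table(chrom, pos, ref, alt)
    in_roh = np.zeros(n, dtype=bool)
    if roh_tracts is not None:
        for rec in roh_tracts.itertuples(index=False):
            in_roh |= (
                (chrom == str(rec.chrom)) & (pos >= rec.start) & (pos <= rec.end)
            )
    het = (rng.random(n) < het_rate) & ~in_roh
    hom_alt = (rng.random(n) < 0.5) & ~het
    geno = np.where(het, 1, np.where(hom_alt, 2, 0)).astype(np.int8)
    return sites, geno


def simulate_reads(sites: pd.DataFrame, genotypes: np.ndarray,
                   mean_coverage: float, error_rate: float, rng,
                   sample: str = "Woolly") -> PileupCounts:
    """Poisson-depth read counts from true diploid genotypes.

    Depth is Poisson(mean_coverage); each read picks one of the two
    haplotype alleles uniformly and is flipped to a uniformly chosen
    other base with probability error_rate.
    """
    rng = np.random.default_rng(rng)
    n = len(sites)
    depth = rng.poisson(mean_coverage, n)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    ref_i = np.array([base_idx[b] for b in sites["ref"]])
    alt_i = np.array([base_idx[b] for b in sites["alt"]])
    # reads drawn from the alt haplotype: 0, depth, or Binomial(depth, 1/2)
    p_alt = np.where(genotypes == 1, 0.5, np.where(genotypes == 2, 1.0, 0.0))
    n_alt = rng.binomial(depth, p_alt)
    n_ref = depth - n_alt
    counts = np.zeros((n, 4), dtype=np.int32)
    for true_i, n_reads in ((ref_i, n_ref), (alt_i, n_alt)):
        if error_rate > 0:
            n_err = rng.binomial(n_reads, error_rate)
        else:
            n_err = np.zeros(n, dtype=np.int64)
        np.add.at(counts, (np.arange(n), true_i), n_reads - n_err)
        if error_rate > 0:
            # split errors uniformly over the three other bases
            e1 = rng.binomial(n_err, 1.0 / 3.0)
            e2 = rng.binomial(n_err - e1, 0.5)
            e3 = n_err - e1 - e2
            others = np.array(
                [[j for j in range(4) if j != t] for t in true_i]
            )
            for k, e in enumerate((e1, e2, e3)):
                np.add.at(counts, (np.arange(n), others[:, k]), e)
    return PileupCounts(sites, [sample], counts[:, None, :])


# ---------------------------------------------------------------------
# codon evolution
# ---------------------------------------------------------------------

#: canid tree used by the selection screen: (child, parent, branch length
#: in expected substitutions per nucleotide site).  Dog-internal branches
#: are short (conspecific divergence); the focal branch is where the
#: per-gene omega applies.
SCREEN_TREE = [
    ("GrayFox", "root", 0.020),
    ("Coyote", "root", 0.015),
    ("dog_anc", "root", 0.002),
    ("Breed1", "dog_anc", 0.0003),
    ("Breed2", "dog_anc", 0.0003),
    ("pcd_anc", "dog_anc", 0.0003),
    ("PCD_dog", "pcd_anc", 0.0003),
    ("Woolly", "pcd_anc", 0.010),
]
SCREEN_FOCAL = "Woolly"
SCREEN_COMPARATORS = ["PCD_dog", "Breed1", "Breed2"]
SCREEN_OUTGROUPS = ["Coyote", "GrayFox"]
BACKGROUND_OMEGA = 0.2


def screen_tree_newick() -> str:
    return (
        "(((Woolly:0.01,PCD_dog:0.0003):0.0003,Breed1:0.0003,Breed2:0.0003)"
        ":0.002,Coyote:0.015,GrayFox:0.02);"
    )


def _evolve_branch(seq: list, branch_len: float, omega: float, kappa: float, rng):
    """Evolve a codon sequence along one branch, in place on a copy.

    Substitutions are proposed per nucleotide at rate branch_len scaled
    by max(1, omega); transitions are kappa times likelier than each
    transversion; synonymous proposals are accepted with probability
    1/max(1, omega) and nonsynonymous ones with omega/max(1, omega), so
    the realized nonsyn:syn rate ratio is omega while the synonymous
    rate stays omega-independent.  Proposals creating stop codons are
    rejected.
    """
    seq = list(seq)
    n_nt = 3 * len(seq)
    boost = max(1.0, omega)
    n_prop = rng.poisson(branch_len * n_nt * boost)
    a_syn = 1.0 / boost
    a_nonsyn = omega / boost
    w_sum = kappa + 2.0
    for _ in range(n_prop):
        site = int(rng.integers(n_nt))
        ci, pos = divmod(site, 3)
        codon = seq[ci]
        old = codon[pos]
        u = rng.random() * w_sum
        if u < kappa:
            new = _TRANSITION[old]
        else:
            tv = [b for b in _BASES if b != old and b != _TRANSITION[old]]
            new = tv[0] if u < kappa + 1.0 else tv[1]
        mut = codon[:pos] + new + codon[pos + 1 :]
        if CODON_TO_AA[mut] == "*":
            continue
        syn = CODON_TO_AA[mut] == CODON_TO_AA[codon]
        accept = a_syn if syn else a_nonsyn
        if rng.random() < accept:
            seq[ci] = mut
    return seq


def simulate_codon_evolution(per_gene_omega, n_codons: int, seed,
                             tree=None, kappa: float = 2.0,
                             focal_branch: str = SCREEN_FOCAL,
                             background_omega: float = BACKGROUND_OMEGA):
    """Evolve codon alignments on the canid tree with per-gene focal omega.

    per_gene_omega maps gene_id -> omega applied on the focal branch;
    every other branch evolves with the background omega.  Returns
    (list of CodonAlignment, SimulatedTruth with gene_omega).
    """
    rng = np.random.default_rng(seed)
    tree = SCREEN_TREE if tree is None else tree
    children = {}
    for child, parent, bl in tree:
        children.setdefault(parent, []).append((child, bl))
    alignments = []
    for gene_id, omega in per_gene_omega.items():
        root_seq = [
            SENSE_CODONS[i]
            for i in rng.integers(0, len(SENSE_CODONS), n_codons)
        ]
        seqs = {}

        def _recurse(node, seq):
            for child, bl in children.get(node, []):
                w = omega if child == focal_branch else background_omega
                child_seq = _evolve_branch(seq, bl, w, kappa, rng)
                if child in children:
                    _recurse(child, child_seq)
                else:
                    seqs[child] = "".join(child_seq)

        _recurse("root", root_seq)
        alignments.append(CodonAlignment(gene_id, seqs))
    truth = SimulatedTruth(gene_omega=dict(per_gene_omega))
    return alignments, truth


def default_gene_omegas(n_genes: int = 200, frac_selected: float = 0.05,
                        selected_omega: float = 3.0,
                        background: float = 0.2, seed=0) -> dict:
    """Per-gene focal omegas: a small selected fraction at high omega."""
    rng = np.random.default_rng(seed)
    n_sel = int(round(n_genes * frac_selected))
    sel = set(rng.choice(n_genes, n_sel, replace=False).tolist())
    return {
        f"gene{i:04d}": (selected_omega if i in sel else background)
        for i in range(n_genes)
    }


# ---------------------------------------------------------------------
# study-like convenience fixture
# ---------------------------------------------------------------------

def make_study_like_dataset(seed, n_sites: int = 50_000,
                            chrom_lengths: dict | None = None,
                            het_rate: float = 0.002,
                            roh_fraction: float = 0.157,
                            coverage: float = 3.4,
                            n_genes: int = 200,
                            n_codons: int = 150,
                            site_spacing: int = 200) -> dict:
    """One seed, every fixture: the full study-like synthetic dataset.

    alpha = 0.16, t = 11 generations, ~3.4x focal coverage, 15.7%
    planted ROH, and 5% of genes at focal omega = 3.  Returns a dict
    with the genotype matrix, recombination map, pileup, planted-ROH
    truth, codon alignments, and all SimulatedTruth objects.
    """
    rng = np.random.default_rng(seed)
    spec = AdmixtureGraphSpec(n_sites=n_sites)
    if chrom_lengths is not None:
        spec.chrom_lengths = chrom_lengths
    matrix, admix_truth, rec_map = simulate_admixed_genotypes(
        spec, rng.integers(2**31)
    )
    roh_lengths = {"1": spec.chrom_lengths["1"], "2": spec.chrom_lengths["2"]}
    roh_truth = plant_roh(roh_lengths, roh_fraction, rng.integers(2**31))
    het_sites, geno = simulate_diploid_sites(
        roh_lengths, het_rate, rng.integers(2**31),
        site_spacing=site_spacing, roh_tracts=roh_truth,
    )
    pileup = simulate_reads(
        het_sites, geno, coverage, 0.0, rng.integers(2**31),
        sample=spec.focal_name,
    )
    omegas = default_gene_omegas(n_genes, seed=rng.integers(2**31))
    alignments, gene_truth = simulate_codon_evolution(
        omegas, n_codons, rng.integers(2**31)
    )
    truth = SimulatedTruth(
        alpha=spec.alpha,
        t_admix=spec.t_admix,
        tracts=admix_truth.tracts,
        het_rate=het_rate,
        roh_tracts=roh_truth,
        gene_omega=omegas,
    )
    return {
        "spec": spec,
        "matrix": matrix,
        "rec_map": rec_map,
        "pileup": pileup,
        "alignments": alignments,
        "truth": truth,
    }
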