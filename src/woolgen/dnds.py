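"""Lineage-specific dN/dS candidate-gene screen.

Expected synonymous/nonsynonymous site counts follow the Nei-Gojobori
(NG86) scheme: each of a codon's nine single-nucleotide mutations is
classified against the standard genetic code (mutations creating stop
codons count as nonsynonymous), S = synonymous/3 and N = 3 - S per
codon.  Substitutions are polarized onto the focal branch by strict
parsimony: the focal sample carries one state while every comparator
and outgroup shares the other.  Because a single branch rarely
accumulates synonymous changes within one gene, each gene's dN is
normalized by the genome-wide dS (omega_genome = dN / dS_genome) rather
than a per-gene dS.

A gene is a selection candidate when omega_genome clears a threshold
(1.5 by default) on the focal branch, the focal branch carries at least
one nonsynonymous change, and none of the comparator dogs carries any
nonsynonymous change in that gene -- a deliberately conservative rule
that excludes selection shared with other dog lineages.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 1.5
DEFAULT_MIN_CALLABLE = 0.8

_BASES = "ACGT"
CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = "*"
SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")


def count_sites_ng86(codon: str):
    """NG86 expected (N_sites, S_sites) for one codon.

    Each of the 9 single-nucleotide mutations is synonymous iff the
    amino acid is unchanged; mutations to stop codons are nonsynonymous.
    Returns None for codons with ambiguity (or stop codons), which
    contribute nothing.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        return None
    aa = CODON_TO_AA[codon]
    if aa == "*":
        return None
    syn = 0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            if CODON_TO_AA[mut] == aa:
                syn += 1
    s_sites = syn / 3.0
    return 3.0 - s_sites, s_sites


#: precomputed NG86 site counts for the 61 sense codons
NG86_SITES = {c: count_sites_ng86(c) for c in SENSE_CODONS}


def _classify_path(c_from: str, c_to: str):
    """Average syn/nonsyn counts over mutational pathways c_from -> c_to.

    For codons differing at k positions, all k! orders of the single
    steps are evaluated; pathways passing through a stop codon are
    excluded (all pathways are kept if every one hits a stop).  Returns
    (nonsyn, syn) fractional counts summing to k.
    """
    diff = [i for i in range(3) if c_from[i] != c_to[i]]
    paths = []
    for order in itertools.permutations(diff):
        cur = c_from
        steps = []
        through_stop = False
        for i in order:
            nxt = cur[:i] + c_to[i] + cur[i + 1 :]
            if CODON_TO_AA[nxt] == "*" and nxt != c_to:
                through_stop = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((through_stop, steps))
    valid = [s for ts, s in paths if not ts] or [s for _, s in paths]
    nonsyn = syn = 0.0
    for steps in valid:
        for a, b in steps:
            if CODON_TO_AA[a] == CODON_TO_AA[b]:
                syn += 1.0
            else:
                nonsyn += 1.0
    return nonsyn / len(valid), syn / len(valid)


# ---------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """In-frame codon alignment for one gene."""

    gene_id: str
    seqs: dict  # sample -> nucleotide string, length divisible by 3
    valid: bool = True
    invalid_reason: str = ""

    def __post_init__(self):
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.gene_id}: sequences have unequal lengths")
        (L,) = lengths
        if L % 3 != 0:
            raise ValueError(f"{self.gene_id}: length {L} not divisible by 3")
        self.seqs = {k: v.upper() for k, v in self.seqs.items()}
        for sample, seq in self.seqs.items():
            for j in range(0, L - 3, 3):  # internal codons only
                cod = seq[j : j + 3]
                if all(b in _BASES for b in cod) and CODON_TO_AA[cod] == "*":
                    self.valid = False
                    self.invalid_reason = (
                        f"internal stop codon in {sample} at codon {j // 3}"
                    )
                    return

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.seqs.values()))) // 3

    def codon(self, sample: str, k: int) -> str:
        return self.seqs[sample][3 * k : 3 * k + 3]

    def callable_fraction(self, sample: str) -> float:
        seq = self.seqs[sample]
        ok = sum(
            1
            for k in range(self.n_codons)
            if all(b in _BASES for b in seq[3 * k : 3 * k + 3])
        )
        return ok / self.n_codons if self.n_codons else 0.0


def read_codon_alignments(fasta_dir) -> list:
    """Read one CodonAlignment per FASTA file in a directory."""
    from pathlib import Path

    from Bio import SeqIO

    alns = []
    for path in sorted(Path(fasta_dir).glob("*.fa*")):
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        alns.append(CodonAlignment(path.stem, seqs))
    return alns


def write_codon_alignments(alignments, fasta_dir) -> None:
    from pathlib import Path

    out = Path(fasta_dir)
    out.mkdir(parents=True, exist_ok=True)
    for aln in alignments:
        with open(out / f"{aln.gene_id}.fasta", "w") as fh:
            for sample, seq in aln.seqs.items():
                fh.write(f">{sample}\n{seq}\n")


# ---------------------------------------------------------------------
# polarized branch counting
# ---------------------------------------------------------------------

def _branch_changes(aln, target, background):
    """Strict-parsimony substitution counts on the target's branch.

    A codon column is evaluated when every required sample is
    unambiguous and all background samples share one codon (which then
    serves as the ancestral state).  NG86 site totals accumulate over
    the background codon of evaluated columns, so
    N_sites + S_sites = 3 x evaluated codons.
    """
    nd = sd = 0.0
    n_sites = s_sites = 0.0
    n_eval = 0
    for k in range(aln.n_codons):
        tgt = aln.codon(target, k)
        if any(b not in _BASES for b in tgt):
            continue
        bgs = {aln.codon(s, k) for s in background}
        if len(bgs) != 1:
            continue
        (anc,) = bgs
        if any(b not in _BASES for b in anc):
            continue
        if CODON_TO_AA[anc] == "*" or CODON_TO_AA[tgt] == "*":
            continue
        sites = NG86_SITES.get(anc)
        if sites is None:
            continue
        n_eval += 1
        n_sites += sites[0]
        s_sites += sites[1]
        if tgt != anc:
            dn, ds = _classify_path(anc, tgt)
            nd += dn
            sd += ds
    return nd, sd, n_sites, s_sites, n_eval


@dataclass
class GeneDnDs:
    gene_id: str
    nd: float
    sd: float
    n_sites: float
    s_sites: float
    n_codons_evaluated: int
    comparator_nd: dict = field(default_factory=dict)
    omega_genome: float = float("nan")

    @property
    def dn(self) -> float:
        return self.nd / self.n_sites if self.n_sites > 0 else float("nan")


def polarize_focal_changes(aln: CodonAlignment, focal: str, comparators,
                           outgroups) -> GeneDnDs:
    """Per-gene focal-branch (Nd, Sd) plus per-comparator Nd.

    The focal branch carries a substitution iff the focal sample shows
    one state while all comparators and outgroups share the other.
    Comparator branches are polarized the same way, with the focal
    sample joining their background.
    """
    if focal not in aln.seqs:
        raise KeyError(f"focal sample {focal!r} absent from {aln.gene_id}")
    background = list(comparators) + list(outgroups)
    missing = [s for s in background if s not in aln.seqs]
    if missing:
        raise KeyError(f"samples {missing} absent from {aln.gene_id}")
    nd, sd, n_sites, s_sites, n_eval = _branch_changes(aln, focal, background)
    comp_nd = {}
    for comp in comparators:
        bg = [focal] + [c for c in comparators if c != comp] + list(outgroups)
        c_nd, _, _, _, _ = _branch_changes(aln, comp, bg)
        comp_nd[comp] = c_nd
    return GeneDnDs(aln.gene_id, nd, sd, n_sites, s_sites, n_eval, comp_nd)


def coverage_filter(alignments, required_samples,
                    min_callable_fraction: float = DEFAULT_MIN_CALLABLE):
    """Split genes into (retained, excluded-with-reason).

    A gene is retained iff it is frame-valid and every required sample's
    callable fraction is at least the cutoff.
    """
    retained, excluded = [], []
    for aln in alignments:
        if not aln.valid:
            excluded.append((aln.gene_id, f"frame violation: {aln.invalid_reason}"))
            continue
        missing = [s for s in required_samples if s not in aln.seqs]
        if missing:
            excluded.append((aln.gene_id, f"low coverage: samples {missing} absent"))
            continue
        low = [
            s
            for s in required_samples
            if aln.callable_fraction(s) < min_callable_fraction
        ]
        if low:
            excluded.append((aln.gene_id, f"low coverage: {','.join(low)}"))
        else:
            retained.append(aln)
    return retained, pd.DataFrame(excluded, columns=["gene_id", "reason"])


def genome_normalize(genes) -> float:
    """Genome-wide dS: sum of focal-branch Sd over sum of S_sites.

    Fills each gene's omega_genome = (Nd/N_sites) / dS_genome in place
    and returns dS_genome.
    """
    total_sd = sum(g.sd for g in genes)
    total_s = sum(g.s_sites for g in genes)
    if total_s == 0 or total_sd == 0:
        raise ValueError(
            "genome-wide dS is zero (degenerate input): cannot normalize"
        )
    ds_genome = total_sd / total_s
    for g in genes:
        g.omega_genome = g.dn / ds_genome if g.n_sites > 0 else float("nan")
    return ds_genome


@dataclass
class ScreenResult:
    candidates: list
    excluded: pd.DataFrame  # gene_id, reason
    table: pd.DataFrame
    ds_genome: float
    threshold: float

    def __post_init__(self):
        overlap = set(self.candidates) & set(self.excluded["gene_id"])
        if overlap:
            raise ValueError(f"genes both candidate and excluded: {overlap}")


def screen_candidates(genes, threshold: float = DEFAULT_THRESHOLD,
                      strict_inequality: bool = False,
                      low_coverage: pd.DataFrame | None = None) -> ScreenResult:
    """Apply the conservative lineage-specific selection rule.

    Candidate iff omega_genome >= threshold (or > with
    strict_inequality), the focal branch carries Nd >= 1, and every
    comparator's Nd is 0.  All other genes land in the exclusion table
    with a reason; pre-excluded low-coverage genes are carried through.
    """
    genes = sorted(genes, key=lambda g: g.gene_id)
    ds_genome = genome_normalize(genes)
    candidates, excluded, rows = [], [], []
    for g in genes:
        passes = (
            g.omega_genome > threshold
            if strict_inequality
            else g.omega_genome >= threshold
        )
        comp_nonzero = [c for c, v in g.comparator_nd.items() if v > 0]
        if not passes or g.nd < 1:
            verdict, reason = "excluded", "below threshold"
        elif comp_nonzero:
            verdict, reason = "excluded", "comparator nonzero dN"
        else:
            verdict, reason = "candidate", ""
        if verdict == "candidate":
            candidates.append(g.gene_id)
        else:
            excluded.append((g.gene_id, reason))
        row = {
            "gene_id": g.gene_id,
            "Nd": g.nd,
            "Sd": g.sd,
            "N_sites": g.n_sites,
            "S_sites": g.s_sites,
            "omega_genome": g.omega_genome,
            "verdict": verdict,
            "reason": reason,
        }
        for c, v in g.comparator_nd.items():
            row[f"Nd_{c}"] = v
        rows.append(row)
    exc = pd.DataFrame(excluded, columns=["gene_id", "reason"])
    if low_coverage is not None and len(low_coverage):
        exc = pd.concat([exc, low_coverage], ignore_index=True)
    return ScreenResult(
        candidates, exc, pd.DataFrame(rows), ds_genome, threshold
    )


# ---------------------------------------------------------------------
# known-variant lookup
# ---------------------------------------------------------------------

def lookup_known_variants(matrix, focal_sample: str,
                          variant_table: pd.DataFrame) -> pd.DataFrame:
    """Report the focal sample's state at a table of known variants.

    variant_table columns: gene, chrom, pos, ancestral, derived.  The
    verdict per row is "ancestral", "derived", "heterozygous", "other",
    or "missing" (position absent or call missing) -- a lookup, not an
    inference.
    """
    j = matrix.sample_index(focal_sample)
    key = {
        (c, int(p)): i
        for i, (c, p) in enumerate(
            zip(matrix.sites["chrom"], matrix.sites["pos"])
        )
    }
    out = []
    for _, row in variant_table.iterrows():
        i = key.get((str(row["chrom"]), int(row["pos"])))
        if i is None:
            state = "missing"
        else:
            call = int(matrix.calls[i, j])
            ref, alt = matrix.sites["ref"].iloc[i], matrix.sites["alt"].iloc[i]
            ploidy = int(matrix.ploidy[j])
            if call == -1:
                state = "missing"
            else:
                alleles = (
                    [ref] * (ploidy - call) + [alt] * call
                )
                anc, der = str(row["ancestral"]), str(row["derived"])
                uniq = set(alleles)
                if uniq == {anc}:
                    state = "ancestral"
                elif uniq == {der}:
                    state = "derived"
                elif uniq == {anc, der}:
                    state = "heterozygous"
                else:
                    state = "other"
        out.append(
            {
                "gene": row["gene"],
                "chrom": row["chrom"],
                "pos": row["pos"],
                "ancestral": row["ancestral"],
                "derived": row["derived"],
                "state": state,
            }
        )
    return pd.DataFrame(out)
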