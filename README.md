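# woolgen

Population-genomic toolkit for characterizing a low-coverage historic dog
genome against reference panels — built around the analyses needed to
reconstruct the ancestry and selection history of the extinct Coast Salish
woolly dog lineage from a single ~3.4x pelt-derived genome.

The package is aimed at ancient-DNA practitioners who need the full chain
of desk-scale analyses with testable ground truth:

- **f-statistics** (`woolgen.fstats`) — outgroup-f3 shared-drift scans,
  ABBA-BABA D-statistics, f4, and the f4-ratio admixture-proportion
  estimator, all computed as ratios of genome-block sums with weighted
  delete-one-block jackknife standard errors.
- **Ancestry tracts & admixture dating** (`woolgen.tracts`) — a two-state
  HMM that decodes pre-colonial dog (PCD) vs. European ancestry along a
  pseudo-haploid genome from panel allele frequencies, and a one-pulse
  exponential tract-length model that dates the admixture pulse.
- **Heterozygosity & ROH** (`woolgen.roh`) — two-read heterozygosity for
  low-coverage data, binomial read downsampling for cross-sample
  comparability, and windowed runs-of-homozygosity calling with the
  fraction of the genome in tracts ≥ 2.5 Mbp.
- **dN/dS selection screen** (`woolgen.dnds`) — NG86 site counting,
  strict-parsimony polarization of substitutions onto the focal branch,
  genome-normalized ω (per-gene dN over genome-wide dS), and a
  conservative candidate rule requiring clean comparator genomes.
- **Synthetic data with known truth** (`woolgen.simulate`) — Balding–
  Nichols allele-frequency drift on a fixed admixture graph, one-pulse
  tract-structured focal genomes, planted ROH, Poisson read simulation,
  and codon alignments evolved with per-gene ω on a canid tree.

## The statistics in brief

For per-site population alt-allele frequencies (o, a, b, w, x, y, z, c):

- outgroup-f3: `f3(O; A, B) = mean[(o − a)(o − b)]` — shared drift of A
  and B relative to outgroup O; bigger = closer.
- D-statistic: `D = Σ(x − w)(y − z) / Σ(w + x − 2wx)(y + z − 2yz)`,
  which reduces to `(nABBA − nBABA)/(nABBA + nBABA)` for haploid calls;
  positive D flags excess sharing between X and Y (gene flow).
- f4-ratio: `α̂ = f4(A, O; X, C) / f4(A, O; B, C)` — the fraction of
  B-related ancestry in an admixed X under a two-source mixture model.
- Tract dating: minor-ancestry tract lengths (Morgans) under a single
  pulse t generations ago are ~ Exponential(rate = (1 − α)·t), so
  `t̂ = 1 / ((1 − α) · mean length)`, with a bootstrap SE and a
  3-year-per-generation conversion to calendar years.
- Genome-normalized ω: `ω_genome = (Nd/N_sites) / (ΣSd/ΣS_sites)` on the
  focal branch; a gene is a selection candidate iff ω_genome ≥ 1.5,
  Nd ≥ 1, and every comparator dog shows dN = 0 in that gene.

## Worked example

```python
from woolgen import AdmixtureGraphSpec, f4_ratio, fit_tract_dating, generations_to_years
from woolgen.simulate import simulate_admixed_genotypes

# 100k unlinked sites; 10-diploid breed/outgroup panels, 5-diploid ancient panels
spec = AdmixtureGraphSpec(
    n_sites=100_000, alpha=0.16, unlinked=True,
    drifts={"outgroup": 0.05, "dog": 0.02, "split_eur": 0.05,
            "split_pcd": 0.05, "breed": 0.03, "source": 0.02},
    panel_sizes={"GrayFox": 10, "EurA": 10, "EurB": 10, "PCD_PaC": 5, "PCD": 5},
)
matrix, truth, rec_map = simulate_admixed_genotypes(spec, seed=42)
res = f4_ratio(matrix, "EurA", "EurB", "GrayFox", "Woolly", "PCD_PaC")
print(f"alpha_hat = {res.estimate:.3f} +/- {res.se:.3f} (1 SE), "
      f"{res.n_sites} sites in {res.n_blocks} blocks")

tract_spec = AdmixtureGraphSpec(n_sites=100_000, alpha=0.16, t_admix=11.0)
_, truth, _ = simulate_admixed_genotypes(tract_spec, seed=42)
eur = truth.tracts.query("ancestry == 'EUR'")["length_morgans"]
date = fit_tract_dating(eur.to_numpy(), alpha=0.16, rng=1)
print(f"t_hat = {date.t_hat:.1f} +/- {date.se_t:.1f} generations "
      f"(~{generations_to_years(date.t_hat):.0f} years before sampling)")
```

prints

```
alpha_hat = 0.149 +/- 0.046 (1 SE), 64606 sites in 400 blocks
t_hat = 10.5 +/- 1.8 generations (~32 years before sampling)
```

The focal genome was simulated with 16% European ancestry from a pulse
11 generations back: the f4-ratio recovers the mixture fraction within
one standard error (only transversion sites are used by default, hence
~65k of the 100k sites), and inverting the mean European tract length
dates the pulse to ~10.5 generations, about 32 years at a 3-year dog
generation time.

There is also a CLI for file-based runs:

```bash
woolgen simulate --preset study-like --seed 42 --out data/
woolgen fstats --geno data/panel.geno --snp data/panel.snp --ind data/panel.ind \
               --stat f3 --pops GrayFox,Woolly,PCD
woolgen run --seed 42 --out results/   # full simulate -> analyse pipeline
```

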