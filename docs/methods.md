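# Methods

This note records the models behind each module, the defaults that
matter, what the synthetic-data generator does and does not emulate, and
the numerical choices a maintainer would want spelled out.

## Data model

Genotypes live in a sites × samples integer matrix of alt-allele doses
(haploid 0/1, diploid 0/1/2) with a single reserved missing sentinel
(−1 internally, 9 in EIGENSTRAT). Missing data are never imputed to the
reference allele: allele frequencies divide by the number of observed
alleles only, because zero-imputation at low coverage would bias every
f-statistic toward the reference genome. Positions are 1-based
(EIGENSTRAT/VCF convention); BED export alone converts to 0-based
half-open. Alleles are used as written in the input — no strand flipping
or reference alignment — which is safe because the default analyses use
transversions only (a purine↔pyrimidine pair cannot be confused by
post-mortem C→T/G→A deamination, and strand ambiguity does not arise for
retained sites). Triallelic records and indels are dropped and counted.
Pseudo-haploid calls draw one read uniformly among the reads supporting
the site's two declared alleles, with an injectable seeded RNG so ties
are reproducible.

Whether to restrict the f-statistics to transversions is an open choice
at ~3.4x without damage rescaling; the default here is transversions-only
for every statistic (not just heterozygosity/ROH), with
`transversions_only=False` available where a caller has UDG-treated or
damage-corrected data.

## f-statistics

All four statistics are ratios of genome-wide sums, evaluated per
contiguous genomic block (default 5 Mbp, beyond the extent of dog
linkage disequilibrium) and combined as ratio-of-block-sums rather than
mean-of-block-ratios, which keeps unevenly informative blocks from
dominating. Standard errors are weighted delete-one-block jackknife
(Busing's formulation) with block site counts as weights; the f4-ratio
is jackknifed jointly — each pseudovalue deletes a block from numerator
and denominator together — because the two f4s share data and their
errors are strongly correlated. Each statistic uses complete cases
across exactly its own populations, so site counts differ legitimately
between rows of a panel scan.

The D-statistic is oriented so that positive values mean excess allele
sharing between the third population and the second (the admixed
focal), i.e. an ABBA excess when the outgroup carries the ancestral
state; for haploid 0/1 calls the estimator reduces exactly to
(nABBA − nBABA)/(nABBA + nBABA).

A small-sample caveat: the f4-ratio is a ratio estimator and carries an
upward bias of order var(denominator)/E[denominator]²; at 50k sites with
the drift scales used here that is about +0.01 on α. It shrinks with
site count and is dwarfed by the 1 SE interval.

## Heterozygosity and ROH

At ~3x coverage genotype calling is unreliable, so heterozygosity is
estimated without genotypes: at every transversion site with ≥2 reads on
the declared alleles, two reads are drawn *without replacement* (never
the same read twice at a 2x site); twice the mismatch fraction is the
per-site heterozygosity, since two draws from a true heterozygote
mismatch with probability ½. The estimator is exactly unbiased under
zero sequencing error regardless of the depth distribution. No error
floor is subtracted by default — the package has no error model — but an
optional ε subtracts 2·2ε(1−ε), the chance that exactly one of two
draws is erroneous. Downsampling thins every read independently with
probability target/current per sample, so samples of different depths
can be compared at a common coverage.

ROH calling: non-overlapping 1 Mbp windows (default), each needing ≥20
usable sites to be assayable; a window is ROH when its het falls below
0.25× the genome-wide median of assayable windows; adjacent ROH windows
merge, and unassayable windows bridge a tract without breaking it. A
tract records both its span (end − start + 1, compared against the
L_min = 2.5 Mbp threshold) and its assayable length (sum of assayable
ROH-window lengths). f_roh is assayable-length-in-long-tracts over total
assayable window length, which guarantees f_roh ≤ 1 even when bridged
gaps inflate spans, and makes f_roh monotone non-increasing in L_min.
The denominator is the assayable genome, not the full genome — with
dense data the two coincide. These window/threshold defaults were fixed
by design (planted-tract recovery at 3.4x) and are all configurable.
Known edge behaviour: a tract boundary inside a window is called only if
roughly three quarters of the window is homozygous, so recovered
fractions run ~0.5–1 percentage point low per handful of tracts.

## Ancestry tracts and admixture dating

Decoding is a two-state HMM along each chromosome over the focal
genome's non-missing sites. Stationary probabilities are (1 − α, α) for
(PCD, EUR); between consecutive sites separated by d Morgans the chain
switches with probability 1 − exp(−t·d) and re-draws the state from the
stationary distribution — the standard one-pulse switch process.
Emissions are the panel frequency of the observed allele with a
pseudocount, p = (f·n + 0.5)/(n + 1) for a panel of n alleles, keeping
emissions finite at fixed sites. The Viterbi path is segmented into
tracts with breakpoints midway between flanking informative sites; the
forward–backward posterior EUR fraction is reported alongside as a
tract-free check. Identical panels are a documented degenerate case: the
posterior collapses to α everywhere and tract calls carry no
information.

Dating is two-stage by design (decode with an initial t, date from
tract lengths, then one refinement decode at the estimated t) rather
than a joint likelihood — simpler, testable, and the refinement removes
most sensitivity to the initial guess. Only minor-ancestry tracts enter
the dating: under a single pulse their lengths are ~ Exponential with
rate (1 − α)·t, giving the MLE t̂ = 1/((1 − α)·mean length). If a
length floor is applied (tracts below decoding resolution dropped), the
left-truncated-exponential correction mean − floor replaces the mean,
which keeps the MLE unbiased. The SE is a nonparametric bootstrap over
tracts (default 1,000 resamples, seeded). Years-before = t̂ × generation
time, default 3 years per dog generation. At least 5 minor tracts are
required; a genome of ~20 Morgans at α = 0.16, t = 11 yields ~30.

## dN/dS selection screen

Expected site counts follow NG86: each codon's nine single-nucleotide
mutations are classified against the standard genetic code, S = syn/3,
N = 3 − S, with mutations to stop codons counted nonsynonymous and
alignments containing internal stops dropped. Substitutions are
polarized onto a branch by strict parsimony: a codon column counts only
when every required sample is unambiguous and all background samples
(comparators + outgroups) share one codon, which then serves as the
ancestral state; multi-hit codons average syn/nonsyn over all mutational
orders that avoid stop codons. N/S site totals accumulate over the
ancestral codons of evaluated columns, so N + S = 3 × evaluated codons
exactly.

Because a single branch rarely accumulates synonymous changes within one
gene (most genes have Sd = 0), per-gene ω is undefined; instead each
gene's dN is normalized by the genome-wide dS (ΣSd/ΣS_sites across all
retained genes) — a transparent counting-based stand-in for
likelihood-based branch models, adequate for ranking and thresholding.
The candidate rule is deliberately conservative: ω_genome ≥ 1.5 (the
comparison operator is configurable to strict >; only exact-boundary
genes differ), focal Nd ≥ 1, and dN = 0 in all three comparator dogs —
excluding selection shared with other dog lineages. Coverage filtering
requires every required sample ≥ 80% callable codons per gene (the
"sufficient coverage" notion is otherwise unspecified; 0.8 is the
declared default). The known-variant lookup is exactly that — a report
of the focal allele state at listed positions, with "missing" for
absent data, never an inference.

## Synthetic data

The generator produces every input with recorded truth, at the study's
stated conditions by default: admixture fraction α = 0.16 from a pulse
t = 11 generations back, ~3.4x focal coverage, 15.7% of the genome in
planted ROH, and 200 genes with 5% at focal-branch ω = 3.

Population structure is Balding–Nichols drift: a branch with parameter F
maps parent frequency p to Beta(p(1−F)/F, (1−p)(1−F)/F), preserving the
mean and adding variance F·p(1−p), so branch drifts translate directly
into expected f-statistics without coalescent machinery. The fixed graph
has an outgroup (gray fox), a European clade whose internal ancestor is
the *true* source of the focal minor ancestry (so the f4-ratio with the
two sampled breeds is consistent), and a PCD clade providing the focal
major-ancestry source and an ancient reference population. Default
drifts (outgroup 0.30, clade splits 0.08/0.12, terminal branches
0.02–0.03) give panels distinguishable enough for tract decoding;
ancestral frequencies are Uniform(0.05, 0.95). F = 1 fixes alleles with
probability p (the degenerate Balding–Nichols limit).

The focal haplotype is built as the one-pulse Markov process the dating
model assumes: breakpoints Poisson(t per Morgan) along a uniform
1 cM/Mb map, segments independently EUR with probability α — hence
EUR tract lengths Exponential((1−α)t) after merging. An `unlinked`
switch draws per-site ancestry iid instead, for statistics that assume
independent sites. Panel individuals are binomial draws from their
population frequency; the focal sample is haploid with ~3% missingness.
Reads are Poisson-depth with uniform base errors; planted ROH tracts
suppress heterozygous sites entirely, with the final tract truncated so
the realized fraction lands on target.

Codon alignments evolve on a fixed canid tree (two outgroups, three
comparator dogs with short conspecific branches, a longer focal branch
at 0.01 substitutions/site where the per-gene ω applies; ω = 0.2
elsewhere). Proposals are κ-biased (transitions 2× each transversion)
and accepted at relative rates syn : nonsyn = 1 : ω with the proposal
rate scaled by max(1, ω), so the synonymous clock is ω-independent.
Detection power note: at these settings a focal ω = 3 gene is recovered
with probability ≈ 0.85 per gene, so realized screen sensitivity over
the 10 selected genes fluctuates around that value.

What the generator does **not** emulate: linkage disequilibrium within
panels (frequencies are drawn independently per site), reference bias
and mapping artifacts, damage patterns (transversion filtering makes
them moot), non-uniform recombination maps (the map class accepts them;
the generator writes uniform ones), realistic dog demography, and the
scarcity of real PCD reference data — so passing tests demonstrate
correctness of the estimators under their stated models, not robustness
to every pathology of real ancient libraries. In particular the real
study's admixture-date uncertainty (±4.9 generations) reflects panel
limitations this generator does not reproduce, and no attempt is made to
match that SE.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed; a fixed seed reproduces
every output byte for byte (no timestamps are written, and output
headers embed version, seed, and the full parameter set). The test and
acceptance runs use desk-scale sizes chosen for stable statistics:
50–100k sites for f-statistics (20 replicate graphs for recovery
claims), 2 Gbp/20 Morgan genomes with 60–100k markers for decode-and-
date, 200 Mbp genomes at 200 bp marker spacing for heterozygosity/ROH,
and 200 genes × 150 codons for the screen. The end-to-end pipeline
(`woolgen run`) chains simulate → f-statistics → ROH → tracts → dN/dS
and aggregates everything into one JSON report.
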