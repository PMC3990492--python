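# Methods

## Problem and model

An admixed diploid genome is modeled as two independent mosaics of segments
drawn from K ancestral groups that mixed G generations ago with genome-wide
proportions θ (Σθ_k = 1). The observable used for inference is the ordered
sequence of group-specific variants (CSVs) the individual carries: alleles
present in exactly one group of a labeled reference panel and absent from
every other group. Because such alleles are essentially private to their
group, carrying one is direct, phase-free evidence of ancestry at that
position.

### Hidden Markov model

* **States.** All unordered ancestry pairs {A_i, A_j}, i ≤ j — K(K+1)/2
  states. The start state is silent; the first observation is scored against
  the random-pairing distribution (θ_i² for homozygous pairs, 2θ_iθ_j for
  heterozygous ones).
* **Transitions.** Over a gap of d bp each chromosome experiences at least
  one recombination with probability r = 1 − exp(−d·G·λ) (a Poisson-process
  count thresholded at ≥ 1). The haploid kernel is
  T(a→b) = (1−r)·1[a=b] + r·θ_b; the diploid matrix is the product of two
  independent haploid kernels collapsed onto unordered pairs, each
  off-diagonal target receiving the mass of both ordered versions. Rows sum
  to one by construction; the unit tests additionally verify every cell
  against a brute-force enumeration over ordered pairs.
* **Emissions.** A homozygous state {A_k, A_k} emits a group-k observation
  with probability 1 − (K−1)·ε_CSV and any other group with ε_CSV — the
  spurious-CSV floor. A heterozygous state {A_i, A_j} splits the compatible
  mass 1 − (K−2)·ε_CSV in proportion N_i : N_j, where N_k is the expected
  number of informative group-k CSVs per haplotype per megabase: the denser
  group is expected to contribute proportionally more observations on a
  mixed background. An alternative convention in which the *total*
  incompatible mass equals ε_CSV differs only at O(ε) and is switchable
  (`eps_mode="total"`).
* **Decoding.** Log-space forward–backward; each observation is assigned the
  state with the largest marginal posterior (ties, which occur only at exact
  float equality, resolve to the lowest state index and are logged). Ancestry
  at non-CSV variants is copied from the preceding CSV call; positions before
  the first CSV take the first call. Individuals with no observations (only
  possible on extremely sparse inputs) receive the a-priori most likely state
  and a warning.

### Parameters, units, defaults

| parameter | meaning | default | notes |
|---|---|---|---|
| θ | admixture proportions | per scenario | presets: AA 0.2/0.0/0.8, MEX 0.45/0.5/0.05, PUR 0.67/0.13/0.2 |
| G | generations since admixture | 6 (AA), 15 (MEX/PUR) | |
| λ (HMM) | crossover rate, per bp per generation | 10⁻¹⁵ | intentionally below the biological 10⁻⁸: nearby CSVs are strongly linked and the model carries no LD term, so transitions between adjacent CSVs are damped |
| λ (simulator) | crossover rate of the generative walk | 10⁻⁸ | biological scale |
| ε_CSV | spurious-CSV emission floor | 10⁻⁵ | per incompatible group |
| N_k | informative CSV density, per haplotype per Mb | estimated | leave-one-out on the panel, or supplied |
| ε_s | sequencing error per read | 0.01 | low-coverage mode |
| τ | dosage presence threshold | 0.6 | strict inequality d > τ |
| buffer | SNPs excluded around an inferred transition | 10 | counted in the harmonized analysis site set |
| n_iter | sample-aware refinement rounds | 4 | early stop when the CSV set stabilizes |

Distances are physical bp throughout (the rate constants are per bp); no
genetic map is used, and crossovers are laid down without interference.

## CSV discovery and densities

Presence is carrier count ≥ 1 (a configurable floor exists for robustness
experiments but the definition is plain presence/absence). Both alleles at a
site may qualify independently, so a fixed difference yields a ref-allele CSV
of the group fixed for the reference allele. A homozygous carrier produces
*one* observation: the emission model is defined over CSV identity, not copy
number, and collapsing is the conservative choice.

N_k and the spurious rate are estimated by holding each panel haplotype out
in turn, re-calling CSVs on the remainder, and counting the carried CSV
alleles by source group, normalized by span in megabases — the self-contained
analogue of training and evaluating on disjoint populations of the same
continental groups. When a disjoint target panel is available it is used
directly. Group-frequency bookkeeping is aligned by group *name* everywhere
(an early implementation aligned positionally and silently corrupted the
refinement; the tests now pin the alignment).

## Sample-aware refinement

After decoding a cohort, the per-group alternate-allele frequency at each
site is re-estimated from individuals called homozygous for that group there
— excluding sites within 10 analysis-set SNPs of one of that individual's
call transitions, where calls are least confident — and combined with the
running frequencies by element-wise maximum. The maximum is used because
frequencies act as *presence indicators* for CSV calling: presence evidence
from the sample can kill a spurious CSV of another group or create a new CSV,
while absence in the sample never erases reference presence. CSVs are then
re-called from the updated frequencies and the cohort re-decoded; four rounds
are the default operating point, with an early stop when the CSV set stops
changing (no frequency-convergence tolerance is applied). Hard calls, not
posterior-weighted ones, feed the update. A one-shot variant
(`update_from_provided_tracks`) accepts externally trusted tracks (e.g.
consensus calls) covering any subset of individuals or regions.

## Low-coverage mode

Read counts r = (ref, alt) at a site are converted to a genotype dosage
d = E[g | r] under prior P(g) = HWE(p̄) with p̄ = Σ_k θ_k p_k (the
admixture-weighted alternate frequency) and likelihood
Binomial(alt; depth, q(g)), q = (ε_s, ½, 1−ε_s) for g = 0, 1, 2. With no
reads d = 2p̄ exactly. The alternate allele is called present when d > 0.6;
the reference allele symmetrically when 2−d > 0.6. Zero-read sites yield no
observation, and sites with p̄ = 0 cannot produce an alternate observation
(their prior forbids presence). The presence pseudo-genotypes feed the same
observation and decoding machinery as hard genotypes, and p̄ uses the
current iteration's frequencies so the mode composes with refinement.

The Wahlund check compares genotype probabilities under complete population
separation (mixture of within-group HWE terms) against pooled HWE at the
averaged frequency: for a variant at 5% in one population, 0% in the other,
50/50 mixture, the heterozygote probabilities are 0.0475 vs 0.04875 — a
1.25×10⁻³ discrepancy, negligible at CSV-range frequencies, which justifies
the pooled-HWE prior.

## Sub-continental variants

sCSVs apply the same presence/absence definition across *all* populations of
all continents; sCSV sets therefore refine CSV sets and are pairwise disjoint
per allele. The naive assigner counts the sCSVs of each population carried on
a haplotype segment and assigns the strict maximum; ties and zero counts are
"unassigned" and scored as incorrect (the unassigned fraction is reported
separately). The leave-one-out profile matrix (held-out population × source
population) is reported raw (per Mb) and row-max-normalized. The random
segment sweep defaults to lengths of 0.05–30 Mb. Diploid sub-continental
decoding reuses the continental HMM unchanged on a population-level CSV
table.

## Synthetic data generator

The generator emulates the features of real reference panels that the method
actually consumes:

* **Sites.** Uniform unique positions over the chromosome; per-category
  counts are Poisson at the configured per-Mb densities. Allele pairs are
  drawn transition-style, never strand-ambiguous.
* **Shared variants** segregate in every population with independent
  frequencies from a configurable range.
* **Private variants** carry the alternate allele only in their owner
  population, at a frequency drawn from (0.02, 0.10] by default — the
  rare-skewed regime where group-private variation actually lives.
* **Spurious CSVs** are injected as pairs of truths: the site is private to
  its apparent owner *in the reference panel* (the hidden population's
  carriers are suppressed there) but truly segregates at low frequency
  (default 0.02) in a second population; the disjoint simulation panel
  carries it. The 0.02 default keeps the premise honest: a ~60-haplotype
  panel misses a 2% allele with probability ≈ 0.3, whereas missing a common
  allele would be implausible.
* **Haplotypes** are drawn independently per site; an optional first-order
  Markov knob (`ld_rho`) reuses the previous site's latent uniform to induce
  local LD. No coalescent structure, no realistic LD decay, no genetic map —
  so passing tests demonstrate correctness of the inference machinery under
  the model's own assumptions, not robustness to real-data LD, phasing error
  or panel mis-specification.
* **Admixed individuals** follow the exponential random walk described
  above; source haplotypes are drawn uniformly with replacement at each
  crossover, each simulated haploid enters exactly one diploid, and the walk
  optionally logs its raw exponential draws so distributional tests target
  the generative quantity directly rather than the right-censored visible
  segments.
* **Reads** are Poisson depth × binomial alternate counts with q as above.

The false-positive-rate study draws the weighted alternate frequency
log-uniformly (density ∝ 1/f) on [0.002, 0.05]: private variants are
overwhelmingly rare, and the floor corresponds to a single carrier chromosome
in a ~500-haplotype panel. Under this spectrum the presence-calling FPR at
τ = 0.6 stays below 0.0025 at every coverage from 1× to 30× (a uniform
frequency draw would roughly double the 1–2× rate, because common "rare"
variants — which real CSV spectra lack — let a single alternate read clear
the threshold).

## Evaluation

* **r²**: at each evaluation SNP and each ancestry k with θ_k > 0, the
  squared Pearson correlation across individuals between true and inferred
  diploid dosage of k (0/1/2); averaged over ancestries, then SNPs. Cells
  with zero variance on either side are excluded and counted. For K > 2 a
  scalar correlation on the pair index would be non-ordinal, hence the
  per-ancestry-dosage construction.
* **Haploid/diploid accuracy**: per (SNP, individual) cell, diploid requires
  the exact unordered pair; haploid scores the best pairing of labels (0, ½,
  1), so haploid ≥ diploid always.
* **Switch resolution**: distance from each true diploid switch to the
  nearest inferred switch, excluding (and counting) switches with no inferred
  neighbor within 500 kb.
* **Sweeps** re-run the full pipeline over coverage, cohort-size or
  iteration grids with fixed seeds and emit a tidy table.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on synthetic data:
parameter recovery uses a 20 Mb chromosome, 60 haplotypes per group and 50
diploids; the refinement study 10–12 Mb with 40 diploids and 5% injected
spurious sites; the FPR study 4×10⁵ site-individual pairs per coverage.
These sizes keep every check within a few minutes on one core while leaving
Monte-Carlo error well below the asserted margins. Decoding is log-space
with a per-column max-shift in the matrix-vector products — a single global
scale underflows once state masses spread beyond ~745 nats, which genuinely
occurs on long observation streams. Posterior rows renormalize to 1 within
10⁻⁹ at L = 10⁵. Argmax ties break to the lowest state index,
deterministically.

## Known limitations

* No LD model between CSVs: the λ = 10⁻¹⁵ damping is a pragmatic fix, and
  errors concentrate where linked CSVs disagree.
* The spurious-CSV emission floor is uniform across groups, although real
  spurious rates differ by an order of magnitude between groups; a
  group-specific floor is a natural extension.
* Sites absent from the reference panel are dropped from inference — they
  cannot be CSVs under the panel.
* The generator's independence assumptions (no coalescent LD, uniform
  positions) mean synthetic accuracies overstate real-data accuracy; the
  package's claims are about the correctness of the machinery, not field
  performance.
* Phasing, imputation, genetic-map distances, BAM parsing and external
  genotype likelihoods are out of scope; read counts and unphased genotypes
  are the input contracts.
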