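# lanccsv

Local ancestry inference in sequenced admixed genomes from
continent-specific variants (CSVs).

Recently admixed genomes — African Americans, Mexicans, Puerto Ricans — are
mosaics of chromosomal segments inherited from different continental groups.
Knowing the ancestry of both alleles at every locus (*local ancestry*) drives
admixture mapping, recombination-rate inference and demographic analysis.
Haplotype-based inference tools are accurate but expensive on full sequencing
data; `lanccsv` instead exploits a by-product of sequencing itself: the large
class of alleles observed in exactly one continental group of a reference
panel and absent from all others. Carrying such a variant is direct evidence
for ancestry from its source group, so local ancestry can be decoded from the
stream of CSVs an individual carries — requiring only allele frequencies per
group, not phased haplotypes.

## Model

For K ancestral groups, a per-individual hidden Markov model runs over the
individual's observed CSVs in position order. Hidden states are the
K(K+1)/2 unordered ancestry pairs {A_i, A_j}. Between consecutive CSVs
separated by d bp, each chromosome recombines with probability
r = 1 − exp(−d·G·λ), where G is the generations since admixture and λ the
crossover rate per bp per generation (default 10⁻¹⁵, deliberately far below
the biological 10⁻⁸ to damp unmodeled LD between nearby CSVs); on
recombination the new ancestry is drawn from the admixture proportions θ.
A homozygous state {A_k, A_k} emits group-k CSVs with probability
1 − (K−1)·ε_CSV and any other group's with ε_CSV (default 10⁻⁵); a
heterozygous state {A_i, A_j} splits the compatible mass in proportion to the
informative densities N_i : N_j, the expected CSVs carried per haplotype per
megabase, estimated from the panel by leave-one-out. Forward–backward
posterior decoding assigns each CSV the maximum-posterior ancestry pair, and
every other variant inherits the call of the preceding CSV.

Around this core the package provides:

- **CSV / sCSV discovery** (`call_csvs`) at continental or sub-continental
  population level, with density estimation and spurious-call accounting;
- **sample-aware refinement** (`iterate`): per-group allele frequencies are
  re-estimated from confidently called homozygous segments of the admixed
  cohort itself (skipping 10 SNPs around each inferred transition), combined
  with the reference by element-wise maximum, and the CSV set re-called —
  removing spurious CSVs and discovering new ones over (default) 4 rounds;
- **low-coverage mode** (`dosage`, `presence_genotypes`): posterior-mean
  genotype dosages from read counts under a Hardy–Weinberg prior at the
  admixture-weighted frequency, with presence called at dosage > 0.6;
- **an admixture simulator and synthetic-panel generator** with exact truth
  tracks, so every component is testable without external data;
- **evaluation metrics**: per-SNP ancestry-dosage r², haploid/diploid
  accuracy, switch-point resolution, and coverage/cohort/iteration sweeps.

## Worked example

```python
import lanccsv as lc

# three ancestral groups with population-private variant densities mirroring
# the European / Native-American / African contrast
spec = lc.SyntheticPanelSpec(
    populations=[lc.PopulationSpec("EUR", 60, 267.0),
                 lc.PopulationSpec("NAM", 60, 183.0),
                 lc.PopulationSpec("AFR", 60, 2050.0)],
    length_bp=10_000_000, shared_density=100.0)
ref_panel, sim_panel, truth = lc.generate_panel_pair(spec, seed=42)

model = lc.PRESETS["AA"]           # theta = (0.2, 0.0, 0.8), G = 6
genotypes, truth_tracks, _ = lc.simulate_admixed(sim_panel, model, 40, seed=7)

est = lc.CsvAncestryHMM(theta=model.theta, groups=model.groups,
                        generations=model.generations, n_iter=4)
calls = est.fit(ref_panel).predict(genotypes)
```

Evaluating the calls against the simulated truth prints:

```
informative CSV densities N_k (per haplotype per Mb): {'EUR': 15.73, 'NAM': 9.79, 'AFR': 120.05}
r2 = 0.993  haploid = 0.999  diploid = 0.998
 iteration  n_csvs  added  removed
         0   23708      0        0
         1   24476    768    0
         2   24476      0    0
```

The leave-one-out densities recover the generating private-variant rates;
the decoded diploid ancestry matches truth at 99.8% of evaluated SNP-individual
cells; and the sample-aware iterations discover 768 CSVs the (finite)
reference panel had missed before the set stabilizes.

The same pipeline is available from the shell:

```bash
lanc-csv simulate --preset AA --n 40 --seed 3 --out-prefix demo
lanc-csv infer --panel demo.panel.txt --labels demo.labels.tsv \
    --genotypes demo.vcf --theta 0.2,0,0.8 --generations 6 \
    --iterations 4 --out calls.bed
lanc-csv evaluate --truth demo.truth.bed --calls calls.bed --genotypes demo.vcf
```

plus `call-csvs`, `update-csvs`, `dosage`, `scsv-profile`, `scsv-assign`,
`scsv-enrich` and `run` (full pipeline from a YAML config).

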