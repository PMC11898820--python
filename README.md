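# henpop

SNP diversity statistics and marker–trait association for candidate-gene
studies in laying hens.

Candidate-gene studies in poultry genotype a few SNPs in a gene of interest
(here, the coding region of neuropeptide Y, a regulator of appetite and
reproduction) across a modest number of birds from several breeds, then ask
two questions: how variable is each marker within each breed, and do the
genotype classes differ in production traits? `henpop` packages that whole
workflow — for geneticists running or auditing such studies — as a tested
library plus a small CLI:

* **Discovery** — scan an aligned FASTA of the coding region for biallelic
  substitution sites ("g.130 A>G" naming, IUPAC two-base codes as Sanger
  heterozygotes) and emit a genotype table.
* **Diversity** — per breed and pooled, genotype/allele frequencies by gene
  counting (p = (2·n_hom + n_het)/2n), expected heterozygosity
  H_E = 2pq, polymorphism information content
  PIC = 1 − (p² + q²) − 2p²q², and the Hardy–Weinberg χ² goodness-of-fit
  test (df = 1 standard, df = 2 convention selectable).
* **Association** — for each locus × trait, the one-way fixed-effect model
  Y_ij = µ + G_i + e_ij fitted by least squares: LS means per genotype
  class, overall F test, pairwise comparisons (unadjusted, Bonferroni or
  Tukey–Kramer) and compact letter displays; plus a per-breed trait summary
  (mean ± SD with letters) and a Brown–Forsythe variance-homogeneity check.
* **Simulation** — a generator reproducing the reference study design
  (117 hens in 4 breeds, 7 SNPs, 8 egg-production traits) with
  configurable genotype frequencies, Hardy–Weinberg deviation F, and
  additive/dominance trait effects, used for calibration and power tests.

## Worked example

Per-breed diversity for the study's first SNP, from a genotype table:

```python
from henpop.datasets import counts_fixture_table
from henpop.popgen import diversity_table, round_half_up

table = counts_fixture_table()          # 117 hens, 4 breeds, 7 SNPs
report = diversity_table(table, df_convention="classes_minus_1")
row = report[(report.locus == "SNP1") & (report.population == "PH")].iloc[0]
for stat in ("p", "q", "pic", "he", "chi2"):
    print(stat, round_half_up(row[stat]))
print("in_hwe", row["in_hwe"])
```

prints

```
p 0.76
q 0.24
pic 0.3
he 0.36
chi2 23.08
in_hwe False
```

i.e. in the Pradu Hang Dum breed (n = 59) the reference allele A is at
frequency 0.76, the marker is reasonably informative (PIC 0.30, of a
biallelic maximum 0.375), expected heterozygosity is 0.36, and the
genotype counts deviate strongly from Hardy–Weinberg proportions
(χ² = 23.08, above the 5.99 critical value at df = 2) — a heterozygote
deficit typical of a selected, structured population.

The same pipeline from the shell, on a simulated study:

```sh
henpop all --seed 1 --outdir run/
# run/study/        genotypes.tsv, traits.tsv, truth.tsv, config.yaml
# run/diversity/    diversity.tsv + .md   (35 locus x population rows)
# run/association/  association.tsv + .md (56 locus x trait cells),
#                   breed_summary.tsv + .md
```

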