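# mirsnp-rewire

Polymorphisms inside mature microRNA sequences (miR-SNPs) can change which
genes a miRNA represses: a single base substitution — especially in the seed
(nucleotides 2–7 from the 5′ end) — can create, destroy, strengthen or weaken
target sites, and thereby move quantitative traits. This package re-implements,
as a tested and fully simulatable pipeline, the analysis used to find such
variants in a paternal half-sib beef-cattle cohort and to predict their
allele-specific rewiring of miRNA–target interactions, integrating genotype,
trait, mRNA and protein data.

It is aimed at quantitative/regulatory geneticists who want the whole chain —
variant annotation, kinship-aware association, RNA energetics, rewiring
classification — runnable end-to-end on synthetic data with known truth.

## What it computes

**Annotation.** SNVs are mapped into mature miRNAs (1-based position from the
5′ end; seed = positions 2–7) and filtered to the analysis set: MAF ≥ 0.01 and
miRNA expressed (cpm ≥ 0.5 in ≥ 50% of samples).

**Association.** For each (miR-SNP, phenotype) pair — phenotypes being traits,
log2(cpm+0.5) mRNA abundances, or log2 protein abundances — the univariate
mixed model

```
y = Wα + xβ + u + ε,   u ~ MVN(0, λτ⁻¹K),   ε ~ MVN(0, τ⁻¹Iₙ)
```

is fitted by maximum likelihood (K a centered genomic relationship matrix,
x the minor-allele dosage, W batch covariates). β = 0 is tested by a
likelihood-ratio test against χ²₁, Bonferroni-controlled at FWER 0.10 across
miR-SNPs — five miR-SNPs give the per-test threshold p < 0.02.

**Energetics.** A Zuker-style nearest-neighbor dynamic program folds each
pre-miRNA allele (stem–loop MFE); an RNAhybrid-style intermolecular dynamic
program finds the best miRNA:3′UTR hybrid per allele. Sites are called at
MFE ≤ −15 kcal/mol with p < 0.05 from a dinucleotide-shuffle Gumbel
calibration.

**Rewiring.** ΔMFE = MFE_major − MFE_minor (positive = the minor allele binds
more stably). Per transcript: *complete gain* (site for minor only), *complete
loss* (major only), *partial gain/loss* (both, by ΔMFE sign). A transcript is
nominated as a target only when its expression effect is significant and its
sign matches the energetics (stronger binding ⇒ repression).

**Synthetic data.** The generator reproduces the study conditions: 374 diploid
animals in 26 paternal half-sib families, miR-SNPs at MAFs 0.07/0.41/0.04,
phenotypes from the mixed model above, designed hairpin precursors, and 3′UTRs
with planted allele-specific sites — one transcript per rewiring class — whose
expression effects point the way the energetics predict.

## Worked example

```
python analysis/01_simulate_cohort.py
python analysis/02_annotate_mirsnps.py
python analysis/03_fit_associations.py
python analysis/04_fold_and_hybridize.py
python analysis/05_classify_rewiring.py
```

(or equivalently `mirsnp-rewire run-all --workdir results/demo_run --seed 1`).
The annotation step prints the filter funnel over the five simulated loci

```
filter funnel: {'n_variants': 5, 'n_in_mature': 5, 'n_after_maf': 4, 'n_analysis_set': 3}
variant_id     mirna   chrom  pos  position_in_mature region minor_allele      maf
   sim_rs1 sim-miR-1 chrSim1   43                  13 mature            A 0.073529
   sim_rs2 sim-miR-2 chrSim2   73                  10 mature            G 0.371658
   sim_rs3 sim-miR-3 chrSim3   36                   6   seed            C 0.056150
```

— one locus fails the expression filter, one the MAF filter, and the seed-SNP
locus sim-miR-3 survives with its variant at mature position 6. The energetics
step reports the allele effect on each precursor (e.g. `sim-miR-3-pre
delta MFE = +5.95` kcal/mol: the minor allele destabilizes the hairpin) and the
final step prints the rewiring calls:

```
 mirsnp transcript expression_layer  mfe_major  mfe_minor  delta_mfe rewiring_class  expression_beta  is_target
sim_rs3    GENE_CG             mRNA     -14.48     -23.00       8.52  complete_gain         -1.50976       True
sim_rs3    GENE_CL          protein     -20.83     -14.48      -6.35  complete_loss          1.49662       True
sim_rs3    GENE_PG             mRNA     -34.55     -43.07       8.52   partial_gain         -1.45477       True
sim_rs3    GENE_PL          protein     -40.90     -34.55      -6.35   partial_loss          1.84606       True

planted classes recovered: 5/5
targets nominated: 4
```

All four planted classes come back exactly, each with a significant expression
effect of the predicted sign (e.g. the complete-gain transcript is repressed,
β = −1.51 on the log2 scale, so it is nominated as a target).

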