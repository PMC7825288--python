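# Methods

This note documents the models, the numerical choices, and what the synthetic
data do and do not establish.

## Cohort and kinship model

The simulated design is a paternal half-sib cohort: `n_individuals` (default
374) progeny of `n_sires` (default 26) unrelated sires, each progeny with an
unrelated dam. Markers are unlinked; each sire carries two haplotypes drawn at
the marker's allele frequency, a progeny inherits one allele sampled per
marker from its sire plus one population allele. Family sharing is therefore
the only source of genetic covariance, which is exactly the structure the
mixed model's kinship term absorbs.

Two kinship matrices appear deliberately:

* the **pedigree (numerator-relationship) matrix** — diagonal 1, paternal half
  sibs 0.25 — is the generator's truth, verified in tests against a recursive
  tabular-method construction on the explicit pedigree;
* the **centered GRM** `K = CCᵀ/p` (C the column-centered dosage matrix over
  `p` background markers, default 5,000) is what the association stage uses,
  as a marker-based method would. The two agree only in expectation; the test
  suite requires their off-diagonal correlation to exceed 0.8 at the default
  marker count.

Realized allele frequencies at family-structured loci have variance well above
the binomial value (sire haplotypes are shared by ~14 progeny), so frequency
checks in the tests average over many markers or replicates rather than
asserting single-locus bands.

## Phenotype model and the mixed-model fit

Phenotypes are generated from, and fitted by, the same model:
`y = Wα + xβ + u + ε` with `u ~ N(0, σ²_g K)` and `ε ~ N(0, σ²_e I)`. The
polygenic term is drawn through a symmetric eigenfactorization of K;
eigenvalues in `[-1e-8, 0)` are clipped to zero and anything lower is a hard
error naming the offending eigenvalue. Default variance components for
simulated traits are σ²_g = 0.25, σ²_e = 0.75 (heritability 0.25, a realistic
value for fatty-acid-profile-like traits); the generator's trait scale is
standardized so planted β values are in phenotype SD units per allele copy.

The fit eigendecomposes K once per cohort, rotates `(y, W, x)` into the
eigenbasis, profiles the fixed effects and the residual variance analytically,
and maximizes the profile ML log-likelihood over `log10 λ ∈ [−5, 5]`
(λ = σ²_g/σ²_e) with a 21-point grid scan followed by bounded Brent refinement
to 1e-6, with explicit endpoint checks. ML rather than REML likelihoods feed
the LRT because the test compares nested fixed-effect models; REML is
available behind a flag. A 1e-8 ridge guards the normal equations against
rank deficiency after rotation. The spectral path is tested to 1e-8 against a
dense-inversion likelihood oracle and, at the fixture scale, against a
10⁴-point grid search.

Genotype dosage is coded as copies of the **minor** allele, so β̂ is the
minor-allele substitution effect; the sign convention propagates into the
rewiring consistency rule. Categorical covariates are reference-coded (first
level dropped, intercept kept); β̂ is invariant to this choice and a test
confirms equality with a cell-means parameterization. mRNA counts are analysed
as log2(cpm + 0.5), proteins as log2 abundance — the distribution-free choice
a practitioner would make when the upstream tool chain is unspecified — and
the generator plants expression effects on the same log2 scale. The Bonferroni
divisor defaults to the number of analysis-set miR-SNPs (the interpretation
under which FWER 0.10 over five variants yields the 0.02 per-test threshold);
it is configurable.

## RNA energy model

One nearest-neighbor model serves both dynamic programs. Watson–Crick/
Watson–Crick stack energies are the standard Turner-2004 values; G·U wobble
stacks are compiled best-effort values from the same family of tables, closed
programmatically under strand-reading symmetry (the table builder rejects
inconsistent entries). Loop costs are affine simplifications: hairpin
5.4 + 0.25/nt over the 3-nt minimum; bulge 3.8 + 0.30/nt; internal loop
2.0 + 0.40/nt + 0.30·|asymmetry|; multiloop 3.4 + 0.40/branch + 0.10/unpaired;
duplex initiation +4.09 kcal/mol. Dangles, coaxial stacking and special-loop
tables are intentionally out of scope, so numeric parity with RNAfold or
RNAhybrid is **not** a contract of this package. The contracts are: exact
agreement of both dynamic programs with exhaustive-enumeration oracles under
the same model (tested on hundreds of random instances), and sign/ordering
fidelity — a substitution that breaks a stack must destabilize, a complement
substitution must never destabilize.

The hairpin fold is a Zuker-style O(n³) program over nested structures
(interior loops capped at 30 nt per side) with a deterministic traceback
(stack, then 5′-most interior pair, then multiloop, then hairpin; exterior
prefers the 5′-most pair). Every traceback is rescored by an independent
loop-decomposition function and must reproduce the DP optimum.

The duplex program is intermolecular-only (no intramolecular pairs): monotone
chains of pairs between the miRNA (5′→3′) and the reversed target, with stack
steps and bulge/interior steps capped at 15 unpaired nt per side, one
initiation penalty, minimized over all target windows in one pass. Hybrids
that never drop below 0 kcal/mol are reported as "no hit".

Site significance replaces RNAhybrid's fixed `3utr_human` extreme-value
constants (not available from the source material) with a per-target
calibration: the target is dinucleotide-shuffled (Altschul–Erickson, exactly
preserving mono- and dinucleotide counts) `n_shuffles` times (default 200,
minimum 50), a Gumbel is fitted to the best-hit scores `s = −MFE`, and the
p-value is the fitted upper tail at the observed score. Because every shuffle
has the target's own length and composition, no length normalization is
required. Both alleles of a miR-SNP differ by one base, so one calibration per
(miRNA, target) pair serves both alleles. A site call requires
MFE ≤ −15 kcal/mol **and** p < 0.05 (both configurable; the boundary semantics
are ≤ and <).

## Rewiring classification

ΔMFE = MFE_major − MFE_minor, so positive values mean the minor allele binds
the target more stably. Classes: complete gain (site called for minor only),
complete loss (major only), partial gain/loss (both called, by ΔMFE sign),
none otherwise. Two edge decisions: ΔMFE for the complete classes is reported
from the best (possibly sub-threshold) energies when both exist but never
drives their classification; an exact ΔMFE = 0 with two called sites is "none"
(neither gain nor loss is defined) and is logged. Partial classes require
*both* alleles' sites to be called, since "a more/less stable site"
presupposes two sites. Consistency: gained/strengthened binding (complete gain
or ΔMFE > 0) requires β < 0; lost/weakened binding requires β > 0; β exactly 0
is never consistent. `is_target = consistent ∧ expression-significant`; mRNA
and protein evidence is evaluated per layer, never merged.

## The demonstration scenario

Five fixed miRNA loci (one on the minus strand) exercise the funnel: one locus
fails the expression filter, one the MAF filter, three survive. Precursors are
designed hairpins — mature + 8-nt A/G loop + reverse-complement arm with two
planted mismatches kept away from the SNP — so the designed stem is the
unambiguous MFE fold and the minor allele genuinely breaks a stack (observed
destabilizations +5 to +7.5 kcal/mol). Five transcripts planted against the
seed-SNP locus carry one rewiring class each: full-length complementary sites
for the partial classes (both alleles callable, ΔMFE = ±6–8.5 kcal/mol) and
12-nt SNP-centred half sites for the complete classes, whose mismatched-allele
energy (−14.5 kcal/mol) sits above the −15 call threshold by construction.

Two generator policies make class recovery a property of the design rather
than of the seed: planted sites are flanked by 20-nt poly-A dead zones —
longer than the duplex loop cap, so background sequence can never extend a
site's hybrid — and backgrounds are rejection-sampled (no ≥6-nt complementary
run to any expressed allele, and no background-only hybrid below
−12 kcal/mol). Expression effects are ±1.5 log2-units per allele copy, large
enough that the planted associations are detected with essentially unit power
at the sub-cohort sizes; the molecular layers are observed on nested
sub-cohorts (192 mRNA, 180 miRNA, 105 protein of 374), mirroring a realistic
multi-omic design.

What the synthetic data do **not** emulate: linkage disequilibrium beyond
family sharing, read-level noise (counts are gamma-Poisson with dispersion
0.1, proteins log-normal), imputation error, and real 3′UTR base composition.
Passing the end-to-end tests therefore demonstrates correctness of the
pipeline's logic and calibration under its own assumptions, not performance on
real sequencing data.

## Problem sizes and runtime policy

Defaults are desk-scale by design: 374 animals, 5,000 background markers,
200-nt UTRs, 200 shuffles per calibration; a full pipeline run takes well
under a minute on one CPU. The shared test fixture runs the pipeline at 200
animals/2,000 markers/100 shuffles, and the recovery and null-calibration
simulations use 600 and 1,000 replicates respectively — sizes chosen so Monte
Carlo error is small relative to the assertions they support. Everything is
seeded; identical seeds give byte-identical output bundles (manifests contain
no timestamps).

## Known limitations

* The wobble stack values are approximate; only ordering properties, not
  absolute energies, should be compared across energy models.
* The Gumbel fit uses maximum likelihood on 200 shuffle scores; p-values below
  ~1/200 are extrapolations of the fitted tail.
* The LRT's finite-sample type-I error at n≈150 runs slightly above nominal
  (observed ≈0.06 at 0.05), the usual behavior of ML variance-component
  testing at moderate n; the acceptance script reports the measured rate.
* `fold_hairpin` is exact only for sequences ≤ 200 nt (enforced), and the
  multiloop model is linear, so long precursors with complex branching are
  outside the validated envelope.
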