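"""The shipped demonstration cohort: five miRNA loci, five transcripts, truth.

This module wires every generator into one reproducible dataset whose planted
structure exercises the full analysis funnel:

=====  ====  ======  ========  =============================================
locus  MAF   strand  SNP pos   role
=====  ====  ======  ========  =============================================
m1     0.07    +       13      mature-region SNP, trait association planted
m2     0.41    -       10      mature-region SNP, trait association planted
m3     0.04    +        6      seed SNP; all four rewiring classes planted
m4     0.20    +        5      miRNA below the expression filter (dropped)
m5     0.005   +       16      expressed but below the MAF filter (dropped)
=====  ====  ======  ========  =============================================

The five transcripts planted against m3 carry one rewiring class each
(complete/partial gain/loss + a clean negative control) with expression
effects whose sign matches the energetic prediction, so the end-to-end
pipeline must recover exactly one transcript per class and the right target
verdicts.

Mature sequences are fixed constants: the class margins (site energies on
either side of the -15 kcal/mol call threshold) are properties of these
sequences, not of the seed. Planted sites are flanked by poly-A dead zones
longer than the duplex loop cap, so their hybrid energies cannot be changed
by the random background, and backgrounds are rejection-sampled until no
off-target allele finds a hybrid below -12 kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ..seq import revcomp_rna
from ..energy import duplex_mfe
from .expression import MRNA_BASE_MEAN, NB_DISPERSION, PROTEIN_BASE_LOG2, PROTEIN_SD_LOG2
from .io import write_fasta, write_gff3, write_manifest, write_table, write_vcf
from .locus import simulate_mirna_locus
from .phenotype import TraitSpec, simulate_phenotype
from .population import PopulationSpec, simulate_pedigree_genotypes
from .utr import random_clean_utr

# --- fixed locus designs ---------------------------------------------------

@dataclass(frozen=True)
class LocusDesign:
    name: str
    mature: str  # major allele
    snp_position: int  # 1-based in mature
    major: str
    minor: str
    strand: str
    maf: float
    expressed: bool


LOCI: tuple[LocusDesign, ...] = (
    LocusDesign("sim-miR-1", "UGCAGCUAAGCUCGGACUGCAU", 13, "C", "A", "+", 0.07, True),
    LocusDesign("sim-miR-2", "ACGGAUCCUGAGCAUGCUAGUU", 10, "G", "C", "-", 0.41, True),
    LocusDesign("sim-miR-3", "UCGACACGGUAGCAUGUCGAAU", 6, "A", "C", "+", 0.04, True),
    LocusDesign("sim-miR-4", "AGGCAUCGUAGCAUGGACCUAA", 5, "A", "C", "+", 0.20, False),
    LocusDesign("sim-miR-5", "CUGAUCGGAUCCAGUGCAAUGG", 16, "G", "A", "+", 0.005, True),
)

REWIRED_LOCUS = "sim-miR-3"
DEAD_ZONE = "A" * 20  # longer than the duplex loop cap: blocks site extension
HALF_SITE_WINDOW = 12
BG_ENERGY_CEILING = -12.0  # backgrounds must not hybridize below this
UTR_BG_LENGTH = 160

#: transcript -> (class planted, site allele, site kind, expression sign, layer)
TRANSCRIPTS: dict[str, tuple[str, str | None, str | None, int, str]] = {
    "GENE_CG": ("complete_gain", "minor", "half", -1, "mRNA"),
    "GENE_CL": ("complete_loss", "major", "half", +1, "protein"),
    "GENE_PG": ("partial_gain", "minor", "full", -1, "mRNA"),
    "GENE_PL": ("partial_loss", "major", "full", +1, "protein"),
    "GENE_NONE": ("none", None, None, 0, "mRNA"),
}

EXPRESSION_EFFECT_LOG2 = 1.5  # per minor-allele copy on the designated feature
N_NULL_MRNA = 20
N_NULL_PROTEIN = 10
N_BG_MIRNA = 40

# sub-cohorts mirroring the multi-omic design: molecular layers are observed
# on subsets of the genotyped cohort
N_MRNA_SAMPLES = 192
N_MIRNA_SAMPLES = 180
N_PROTEIN_SAMPLES = 105

TRAITS: dict[str, tuple[str, float]] = {
    # trait -> (locus carrying the planted allele-substitution effect, beta)
    "trait_a": ("sim-miR-1", 0.6),
    "trait_b": ("sim-miR-2", 0.4),
}


def minor_mature(d: LocusDesign) -> str:
    i = d.snp_position - 1
    return d.mature[:i] + d.minor + d.mature[i + 1 :]


def half_site(allele_seq: str, snp_position: int, window: int = HALF_SITE_WINDOW) -> str:
    """Reverse complement of a SNP-centred window of the mature sequence."""
    lo = max(0, min(len(allele_seq) - window, snp_position - 1 - window // 2))
    return revcomp_rna(allele_seq[lo : lo + window])


def _screened_background(
    avoid: tuple[str, ...], rng: np.random.Generator, length: int = UTR_BG_LENGTH
) -> str:
    """Clean background that, on its own, hybridizes no better than the
    ceiling with any allele sequence in ``avoid``."""
    for _ in range(200):
        bg = random_clean_utr(length, avoid, rng)
        worst = min(
            (h.mfe for m in avoid if (h := duplex_mfe(m, bg)) is not None),
            default=0.0,
        )
        if worst >= BG_ENERGY_CEILING:
            return bg
    raise RuntimeError("could not generate an energy-screened background")


def build_utrs(rng: np.random.Generator) -> dict[str, str]:
    """The five transcripts' 3'UTRs, sites isolated by poly-A dead zones."""
    focal = next(d for d in LOCI if d.name == REWIRED_LOCUS)
    alleles = {"major": focal.mature, "minor": minor_mature(focal)}
    avoid = tuple(
        s
        for d in LOCI
        if d.expressed and d.maf >= 0.01
        for s in (d.mature, minor_mature(d))
    )
    utrs: dict[str, str] = {}
    for name, (_cls, site_allele, kind, _sign, _layer) in TRANSCRIPTS.items():
        bg = _screened_background(avoid, rng)
        if kind is None:
            utrs[name] = bg[: UTR_BG_LENGTH // 2] + DEAD_ZONE + DEAD_ZONE + bg[UTR_BG_LENGTH // 2 :]
            continue
        seq = alleles[site_allele]
        site = half_site(seq, focal.snp_position) if kind == "half" else revcomp_rna(seq)
        utrs[name] = (
            bg[: UTR_BG_LENGTH // 2]
            + DEAD_ZONE
            + site
            + DEAD_ZONE
            + bg[UTR_BG_LENGTH // 2 :]
        )
    return utrs


# --- expression helpers ----------------------------------------------------

def _nb_counts(log2_mu: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    mu = 2.0 ** log2_mu
    lam = rng.gamma(1.0 / NB_DISPERSION, mu * NB_DISPERSION)
    return rng.poisson(lam)


def _batch_offsets(
    n_features: int, batches: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    levels = np.unique(batches)
    per = rng.normal(0.0, sd, size=(n_features, len(levels)))
    idx = np.searchsorted(levels, batches)
    return per[:, idx].T  # samples x features


# --- the full dataset -------------------------------------------------------

def build_demo_dataset(
    outdir: str | Path,
    seed: int = 0,
    n_individuals: int = 374,
    n_sires: int = 26,
    n_background_markers: int = 5000,
) -> dict:
    """Write every pipeline input under ``outdir`` and return the truth record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # genotypes + kinship truth
    pop = PopulationSpec(
        n_individuals=n_individuals,
        n_sires=n_sires,
        maf=tuple(d.maf for d in LOCI),
        n_background_markers=n_background_markers,
        seed=int(rng.integers(2**31 - 1)),
    )
    cohort = simulate_pedigree_genotypes(pop)
    samples = [f"NEL{i + 1:04d}" for i in range(n_individuals)]

    # loci and sequence files
    loci = [
        simulate_mirna_locus(
            d.mature,
            d.snp_position,
            (d.major, d.minor),
            name=d.name,
            chrom=f"chrSim{i + 1}",
            strand=d.strand,
        )
        for i, d in enumerate(LOCI)
    ]
    write_vcf(outdir / "genotypes.vcf", loci, cohort.genotypes, samples)
    write_gff3(outdir / "mirna.gff3", loci)
    write_fasta(outdir / "contigs.fasta", {l.chrom: l.contig_seq for l in loci})
    write_fasta(
        outdir / "matures.fasta",
        {l.name: l.mature_major for l in loci},
    )
    write_fasta(
        outdir / "mature_alleles.fasta",
        {
            f"{l.name}|{allele}": seq
            for l in loci
            for allele, seq in (("major", l.mature_major), ("minor", l.mature_minor))
        },
    )
    write_fasta(
        outdir / "precursor_alleles.fasta",
        {
            f"{l.precursor_name}|{allele}": seq
            for l in loci
            for allele, seq in (("major", l.precursor_major), ("minor", l.precursor_minor))
        },
    )
    utrs = build_utrs(rng)
    write_fasta(outdir / "utrs.fasta", utrs)

    # background markers for the GRM
    bg = pd.DataFrame(
        cohort.background,
        index=pd.Index(samples, name="sample"),
        columns=[f"bgSNP{i + 1}" for i in range(cohort.background.shape[1])],
    )
    bg.to_csv(outdir / "background_genotypes.tsv", sep="\t")

    # covariates
    cov = pd.DataFrame(
        {
            "contemporary_group": [f"cg{v + 1:02d}" for v in rng.integers(0, 19, n_individuals)],
            "flowcell_lane": [f"fl{v + 1:02d}" for v in rng.integers(0, 22, n_individuals)],
            "protein_run": [f"run{v + 1}" for v in rng.integers(0, 5, n_individuals)],
        },
        index=pd.Index(samples, name="sample"),
    )
    write_table(outdir / "covariates.tsv", cov)

    # quantitative traits
    locus_idx = {d.name: i for i, d in enumerate(LOCI)}
    cg_codes = pd.factorize(cov["contemporary_group"])[0]
    traits = {}
    for trait, (locus_name, beta) in TRAITS.items():
        spec = TraitSpec(
            beta_true=beta,
            var_polygenic=0.25,
            var_residual=0.75,
            batch_effects=tuple(rng.normal(0.0, 0.5, len(np.unique(cg_codes)))),
        )
        traits[trait] = simulate_phenotype(
            cohort.genotypes[:, locus_idx[locus_name]],
            cohort.kinship,
            spec,
            cg_codes,
            rng,
        )
    write_table(
        outdir / "phenotypes.tsv",
        pd.DataFrame(traits, index=pd.Index(samples, name="sample")).round(6),
    )

    # molecular layers are observed on sub-cohorts (capped at the cohort size)
    n_mir = min(N_MIRNA_SAMPLES, n_individuals)
    n_mrna = min(N_MRNA_SAMPLES, n_individuals)
    n_prot = min(N_PROTEIN_SAMPLES, n_individuals)

    # miRNA counts (expression filter input), on the miRNA sub-cohort
    mir_samples = samples[:n_mir]
    mir_features = [d.name for d in LOCI] + [f"sim-miR-bg{i + 1}" for i in range(N_BG_MIRNA)]
    log2_mu = np.full((n_mir, len(mir_features)), np.log2(200.0))
    for j, d in enumerate(LOCI):
        if not d.expressed:
            log2_mu[:, j] = np.log2(0.2)  # mostly zero counts: fails the filter
    mir_counts = _nb_counts(log2_mu, rng)
    write_table(
        outdir / "mirna_counts.tsv",
        pd.DataFrame(mir_counts.T, index=pd.Index(mir_features, name="mirna"), columns=mir_samples),
        index_label="mirna",
    )

    # mRNA counts: planted genotype effects on the scenario transcripts
    mrna_samples = samples[:n_mrna]
    g3 = cohort.genotypes[:n_mrna, locus_idx[REWIRED_LOCUS]].astype(float)
    mrna_feats = [t for t, v in TRANSCRIPTS.items() if v[4] == "mRNA"] + [
        f"GENE_NULL{i + 1}" for i in range(N_NULL_MRNA)
    ]
    log2_mu = np.full((n_mrna, len(mrna_feats)), np.log2(MRNA_BASE_MEAN))
    for j, feat in enumerate(mrna_feats):
        if feat in TRANSCRIPTS:
            sign = TRANSCRIPTS[feat][3]
            log2_mu[:, j] += sign * EXPRESSION_EFFECT_LOG2 * g3
    log2_mu += _batch_offsets(
        len(mrna_feats), pd.factorize(cov["flowcell_lane"][:n_mrna])[0], 0.3, rng
    )
    mrna_counts = _nb_counts(log2_mu, rng)
    write_table(
        outdir / "mrna_counts.tsv",
        pd.DataFrame(mrna_counts.T, index=pd.Index(mrna_feats, name="gene"), columns=mrna_samples),
        index_label="gene",
    )

    # protein abundances
    prot_samples = samples[:n_prot]
    gp = cohort.genotypes[:n_prot, locus_idx[REWIRED_LOCUS]].astype(float)
    prot_feats = [t for t, v in TRANSCRIPTS.items() if v[4] == "protein"] + [
        f"PROT_NULL{i + 1}" for i in range(N_NULL_PROTEIN)
    ]
    log2_ab = rng.normal(PROTEIN_BASE_LOG2, PROTEIN_SD_LOG2, size=(n_prot, len(prot_feats)))
    for j, feat in enumerate(prot_feats):
        if feat in TRANSCRIPTS:
            sign = TRANSCRIPTS[feat][3]
            log2_ab[:, j] += sign * EXPRESSION_EFFECT_LOG2 * gp
    log2_ab += _batch_offsets(
        len(prot_feats), pd.factorize(cov["protein_run"][:n_prot])[0], 0.3, rng
    )
    write_table(
        outdir / "protein_abundance.tsv",
        pd.DataFrame((2.0 ** log2_ab).round(4).T, index=pd.Index(prot_feats, name="protein"), columns=prot_samples),
        index_label="protein",
    )

    truth = {
        "seed": seed,
        "n_individuals": n_individuals,
        "n_sires": n_sires,
        "loci": [
            {
                "name": d.name,
                "maf": d.maf,
                "snp_position": d.snp_position,
                "strand": d.strand,
                "expressed": d.expressed,
                "in_analysis_set": d.expressed and d.maf >= 0.01,
            }
            for d in LOCI
        ],
        "traits": {t: {"locus": l, "beta": b} for t, (l, b) in TRAITS.items()},
        "rewired_locus": REWIRED_LOCUS,
        "transcript_classes": {
            t: {"class": v[0], "expression_sign": v[3], "layer": v[4], "is_target": v[0] != "none"}
            for t, v in TRANSCRIPTS.items()
        },
        "expression_effect_log2": EXPRESSION_EFFECT_LOG2,
    }
    write_manifest(outdir / "truth.json", truth)
    return truth
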