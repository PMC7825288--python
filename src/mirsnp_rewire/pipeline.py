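"""Pipeline orchestration: simulate -> annotate -> associate -> energetics -> rewire.

Every stage reads and writes plain files (TSV/FASTA/VCF/GFF3/JSON) under the
configured working directory, so stages are independently runnable; the final
manifest records the configuration, the seed and the analysis funnel (variants
-> miR-SNPs -> analysis set -> significant associations -> targets).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import annotation, lmm, rewiring
from .datagen import scenario
from .energy import (
    DEFAULT_MODEL,
    calibrate_pvalue,
    duplex_mfe,
    fold_hairpin,
    gumbel_pvalue,
    hairpin_delta_mfe,
    score_hit,
)
from .seq import dna_to_rna

log = logging.getLogger(__name__)

STAGES = ("simulate", "annotate", "associate", "energetics", "rewire")


@dataclass
class RunConfig:
    """All knobs of one pipeline run; round-trips losslessly through YAML."""

    workdir: str = "mirsnp_run"
    seed: int = 0
    # cohort scale
    n_individuals: int = 374
    n_sires: int = 26
    n_background_markers: int = 5000
    # analysis thresholds
    maf_min: float = 0.01
    cpm_min: float = 0.5
    sample_fraction: float = 0.5
    fwer: float = 0.10
    bonferroni_divisor: int | None = None  # default: number of miR-SNPs
    mfe_threshold: float = -15.0
    p_threshold: float = 0.05
    seed_region: tuple[int, int] = (2, 7)
    n_shuffles: int = 200

    def __post_init__(self) -> None:
        self.seed_region = tuple(self.seed_region)  # type: ignore[assignment]
        if not 0 < self.maf_min <= 0.5:
            raise ValueError("maf_min outside (0, 0.5]")
        if not 0 < self.fwer < 1:
            raise ValueError("fwer outside (0, 1)")
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction outside (0, 1]")
        if self.mfe_threshold > 0:
            raise ValueError("mfe_threshold must be <= 0")
        if self.n_shuffles < 50:
            raise ValueError("n_shuffles must be >= 50")

    # -- paths ---------------------------------------------------------------
    @property
    def data_dir(self) -> Path:
        return Path(self.workdir) / "data"

    @property
    def results_dir(self) -> Path:
        return Path(self.workdir) / "results"

    def path(self, name: str) -> Path:
        files = {
            "vcf": self.data_dir / "genotypes.vcf",
            "gff3": self.data_dir / "mirna.gff3",
            "matures": self.data_dir / "matures.fasta",
            "mature_alleles": self.data_dir / "mature_alleles.fasta",
            "precursor_alleles": self.data_dir / "precursor_alleles.fasta",
            "contigs": self.data_dir / "contigs.fasta",
            "utrs": self.data_dir / "utrs.fasta",
            "background": self.data_dir / "background_genotypes.tsv",
            "phenotypes": self.data_dir / "phenotypes.tsv",
            "covariates": self.data_dir / "covariates.tsv",
            "mirna_counts": self.data_dir / "mirna_counts.tsv",
            "mrna_counts": self.data_dir / "mrna_counts.tsv",
            "protein": self.data_dir / "protein_abundance.tsv",
            "truth": self.data_dir / "truth.json",
            "mirsnps": self.results_dir / "mirsnps.tsv",
            "dosages": self.results_dir / "mirsnp_dosages.tsv",
            "assoc": self.results_dir / "associations.tsv",
            "folds": self.results_dir / "premirna_folds.tsv",
            "hits": self.results_dir / "duplex_hits.tsv",
            "rewiring": self.results_dir / "rewiring.tsv",
            "summary": self.results_dir / "run_summary.json",
            "manifest": self.results_dir / "manifest.json",
        }
        return files[name]

    # -- config file round trip ----------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["seed_region"] = list(self.seed_region)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d["seed_region"] = list(self.seed_region)
        d.pop("workdir")  # parameters only: digest is location-independent
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# stages

def stage_simulate(cfg: RunConfig) -> dict:
    truth = scenario.build_demo_dataset(
        cfg.data_dir,
        seed=cfg.seed,
        n_individuals=cfg.n_individuals,
        n_sires=cfg.n_sires,
        n_background_markers=cfg.n_background_markers,
    )
    log.info("simulated cohort of %d under seed %d", cfg.n_individuals, cfg.seed)
    return truth


def stage_annotate(cfg: RunConfig) -> dict:
    counts = pd.read_csv(cfg.path("mirna_counts"), sep="\t", index_col=0)
    mirsnps, dosages, funnel = annotation.select_analysis_set(
        cfg.path("vcf"),
        cfg.path("gff3"),
        counts,
        cfg.path("matures"),
        maf_threshold=cfg.maf_min,
        min_cpm=cfg.cpm_min,
        min_fraction=cfg.sample_fraction,
        seed_bounds=cfg.seed_region,
    )
    cfg.results_dir.mkdir(parents=True, exist_ok=True)
    annotation.mirsnp_table(mirsnps).to_csv(cfg.path("mirsnps"), sep="\t", index=False)
    dosages.to_csv(cfg.path("dosages"), sep="\t", index_label="variant_id")
    log.info("analysis set: %d miR-SNPs (funnel %s)", len(mirsnps), funnel)
    return funnel


def _layers(cfg: RunConfig) -> list[tuple[str, pd.DataFrame, str]]:
    """(layer name, samples x features phenotype table, covariate column)."""
    traits = pd.read_csv(cfg.path("phenotypes"), sep="\t", index_col=0)
    mrna = pd.read_csv(cfg.path("mrna_counts"), sep="\t", index_col=0)
    prot = pd.read_csv(cfg.path("protein"), sep="\t", index_col=0)
    return [
        ("trait", traits, "contemporary_group"),
        ("mRNA", lmm.log2_cpm(mrna).T, "flowcell_lane"),
        ("protein", np.log2(prot).T, "protein_run"),
    ]


def stage_associate(cfg: RunConfig) -> pd.DataFrame:
    dosages = pd.read_csv(cfg.path("dosages"), sep="\t", index_col=0)
    covariates = pd.read_csv(cfg.path("covariates"), sep="\t", index_col=0)
    background = pd.read_csv(cfg.path("background"), sep="\t", index_col=0)
    kinship = lmm.grm(background.to_numpy(float))
    kin_df = pd.DataFrame(kinship, index=background.index, columns=background.index)

    n_tests = cfg.bonferroni_divisor or len(dosages)
    frames = []
    for layer, pheno, cov_col in _layers(cfg):
        samples = [s for s in pheno.index if s in dosages.columns]
        res = lmm.associate_all(
            dosages[samples],
            pheno.loc[samples],
            covariates.loc[samples, [cov_col]],
            kin_df.loc[samples, samples].to_numpy(),
            fwer=cfg.fwer,
            n_tests=n_tests,
        )
        res.insert(0, "layer", layer)
        frames.append(res)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(cfg.path("assoc"), sep="\t", index=False, float_format="%.6g")
    log.info(
        "associations: %d tests, %d significant at FWER %.2f / %d",
        len(out), int(out["significant"].sum()), cfg.fwer, n_tests,
    )
    return out


def _read_fasta(path: Path) -> dict[str, str]:
    return {rec.id: dna_to_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def stage_energetics(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    cfg.results_dir.mkdir(parents=True, exist_ok=True)
    # pre-miRNA stem-loop stability per allele
    precursors = _read_fasta(cfg.path("precursor_alleles"))
    fold_rows, folds = [], {}
    for name, seq in precursors.items():
        pre, allele = name.split("|")
        f = fold_hairpin(seq, DEFAULT_MODEL)
        folds[(pre, allele)] = f
        fold_rows.append(
            {"precursor": pre, "allele": allele, "mfe": round(f.mfe, 2), "structure": f.structure}
        )
    fold_df = pd.DataFrame(fold_rows, columns=["precursor", "allele", "mfe", "structure"])
    deltas = {
        pre: round(hairpin_delta_mfe(folds[(pre, "major")], folds[(pre, "minor")]), 2)
        for (pre, a) in folds if a == "major" and (pre, "minor") in folds
    }
    fold_df["delta_mfe_minor_vs_major"] = fold_df["precursor"].map(deltas)
    fold_df.to_csv(cfg.path("folds"), sep="\t", index=False)

    # allele-specific duplex scans against every 3'UTR
    mirsnps = pd.read_csv(cfg.path("mirsnps"), sep="\t")
    matures = _read_fasta(cfg.path("mature_alleles"))
    utrs = _read_fasta(cfg.path("utrs"))
    rng = np.random.default_rng(cfg.seed + 1)
    hit_rows = []
    for _, snp in mirsnps.iterrows():
        mir = snp["mirna"]
        for transcript, utr in utrs.items():
            # the null for this (miRNA, target) pair; the two alleles differ by
            # one base, so one calibration serves both
            loc, scale = calibrate_pvalue(
                matures[f"{mir}|major"], utr, DEFAULT_MODEL,
                n_shuffles=cfg.n_shuffles, seed=rng,
            )
            for allele in ("major", "minor"):
                hit = duplex_mfe(
                    matures[f"{mir}|{allele}"], utr, DEFAULT_MODEL,
                    mirna_id=f"{mir}|{allele}", target_id=transcript,
                )
                if hit is not None:
                    hit = score_hit(hit, loc, scale, cfg.mfe_threshold, cfg.p_threshold)
                hit_rows.append(
                    {
                        "variant_id": snp["variant_id"],
                        "mirna": mir,
                        "allele": allele,
                        "transcript": transcript,
                        "mfe": round(hit.mfe, 2) if hit else np.nan,
                        "window_start": hit.target_window[0] if hit else -1,
                        "window_end": hit.target_window[1] if hit else -1,
                        "p": round(hit.p_value, 6) if hit else np.nan,
                        "significant": bool(hit.significant) if hit else False,
                    }
                )
    hits_df = pd.DataFrame(
        hit_rows,
        columns=["variant_id", "mirna", "allele", "transcript",
                 "mfe", "window_start", "window_end", "p", "significant"],
    )
    hits_df.to_csv(cfg.path("hits"), sep="\t", index=False)
    log.info("energetics: %d folds, %d duplex scans", len(fold_df), len(hits_df))
    return fold_df, hits_df


def stage_rewire(cfg: RunConfig) -> pd.DataFrame:
    hits_df = pd.read_csv(cfg.path("hits"), sep="\t")
    assoc = pd.read_csv(cfg.path("assoc"), sep="\t")
    expr = assoc[assoc["layer"].isin(["mRNA", "protein"])]
    layers = dict(zip(expr["phenotype"], expr["layer"]))

    hits: dict[tuple[str, str, str], rewiring.DuplexHit | None] = {}
    for _, r in hits_df.iterrows():
        key = (r["variant_id"], r["transcript"], r["allele"])
        if np.isnan(r["mfe"]):
            hits[key] = None
        else:
            hits[key] = rewiring.DuplexHit(
                mirna=f"{r['mirna']}|{r['allele']}",
                target=r["transcript"],
                mfe=float(r["mfe"]),
                target_window=(int(r["window_start"]), int(r["window_end"])),
                pairing="",
                p_value=float(r["p"]),
                significant=bool(r["significant"]),
            )
    calls = rewiring.rewire_all(hits, expr.rename(columns={"phenotype": "phenotype"}), layers)
    calls.to_csv(cfg.path("rewiring"), sep="\t", index=False, float_format="%.6g")
    rewiring.write_summary(cfg.path("summary"), calls)
    log.info("rewiring: %s", rewiring.class_summary(calls))
    return calls


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage in order; the manifest aggregates the funnel counts."""
    cfg.data_dir.mkdir(parents=True, exist_ok=True)
    cfg.results_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_digest": cfg.digest(), "seed": cfg.seed, "stages": {}}
    try:
        stage_simulate(cfg)
        manifest["stages"]["simulate"] = "ok"
        funnel = stage_annotate(cfg)
        manifest["stages"]["annotate"] = "ok"
        assoc = stage_associate(cfg)
        manifest["stages"]["associate"] = "ok"
        stage_energetics(cfg)
        manifest["stages"]["energetics"] = "ok"
        calls = stage_rewire(cfg)
        manifest["stages"]["rewire"] = "ok"
    except Exception as exc:
        failed = STAGES[len(manifest["stages"])]
        raise RuntimeError(f"pipeline failed at stage '{failed}': {exc}") from exc

    manifest["funnel"] = {
        **funnel,
        "n_assoc_tests": int(len(assoc)),
        "n_significant_assoc": int(assoc["significant"].sum()),
        "n_rewiring_pairs": int(len(calls)),
        "n_targets": int(calls["is_target"].sum()),
    }
    manifest["per_class"] = rewiring.class_summary(calls)["per_class"]
    cfg.to_yaml(Path(cfg.workdir) / "config.yaml")
    Path(cfg.path("manifest")).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# --------------------------------------------------------------------------
# input validation

def validate_inputs(cfg: RunConfig) -> list[dict]:
    """Cross-file consistency report; entries carry severity error/warning/info."""
    report: list[dict] = []

    def entry(severity: str, message: str) -> None:
        report.append({"severity": severity, "message": message})

    from cyvcf2 import VCF

    vcf = VCF(str(cfg.path("vcf")))
    vcf_samples = list(vcf.samples)
    vcf_contigs = {rec.CHROM for rec in vcf}
    gff_contigs = {
        line.split("\t")[0]
        for line in Path(cfg.path("gff3")).read_text().splitlines()
        if line and not line.startswith("#")
    }
    fasta_contigs = set(_read_fasta(cfg.path("contigs")))

    for name, contigs in (("GFF3", gff_contigs), ("contig FASTA", fasta_contigs)):
        missing = vcf_contigs - contigs
        if missing:
            stripped = {c.removeprefix("chr") for c in contigs}
            if {c.removeprefix("chr") for c in missing} & stripped:
                entry(
                    "warning",
                    f"{name} contig naming differs only by 'chr' prefix for "
                    f"{sorted(missing)}; normalize contig names",
                )
            else:
                entry("error", f"VCF contigs {sorted(missing)} absent from {name}")

    pheno = pd.read_csv(cfg.path("phenotypes"), sep="\t", index_col=0)
    cov = pd.read_csv(cfg.path("covariates"), sep="\t", index_col=0)
    for name, idx in (("phenotypes", pheno.index), ("covariates", cov.index)):
        extra = set(idx) - set(vcf_samples)
        if extra:
            entry("error", f"{name} table has samples absent from the VCF: {sorted(extra)[:5]}")
    return report
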