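"""miR-SNP annotation and analysis-set filters.

Locates biallelic SNVs inside mature miRNA sequences, assigns the 1-based
position from the miRNA 5' end and the seed/mature region class (seed =
positions 2-7), and applies the two filters that define the analysis set:
minor allele frequency >= 0.01 and miRNA expression (cpm >= 0.5 in >= 50% of
samples).

File interfaces are 1-based (GFF3/VCF); in memory everything is 0-based
half-open, converted only in :mod:`mirsnp_rewire.coords`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF

from . import coords
from .seq import check_rna, dna_to_rna

log = logging.getLogger(__name__)

SEED_BOUNDS = (2, 7)  # 1-based inclusive positions from the miRNA 5' end


@dataclass(frozen=True)
class MatureMirna:
    """A mature miRNA with a strand-aware genomic interval (0-based half-open)."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str = ""  # RNA, 5'->3'; may be empty when no FASTA was supplied
    precursor_name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("empty mature interval")
        if self.sequence:
            check_rna(self.sequence)
            if len(self.sequence) != self.end - self.start:
                raise ValueError(
                    f"{self.name}: sequence length {len(self.sequence)} != "
                    f"interval length {self.end - self.start}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MiRSNP:
    """A biallelic SNV inside a mature miRNA."""

    variant_id: str
    chrom: str
    pos: int  # 0-based genomic position
    ref: str
    alt: str
    mirna: MatureMirna
    position_in_mature: int  # 1-based from the 5' end
    region: str  # {seed, mature}
    minor_allele: str
    maf: float

    def __post_init__(self) -> None:
        if not 1 <= self.position_in_mature <= self.mirna.length:
            raise ValueError("position_in_mature outside the mature sequence")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"MAF {self.maf} outside [0, 0.5]")


def position_in_mature(variant_pos: int, mirna: MatureMirna) -> int | None:
    """1-based offset of a 0-based genomic position from the miRNA 5' end,
    or None when the variant lies outside the mature interval."""
    if not mirna.start <= variant_pos < mirna.end:
        return None
    if mirna.strand == "+":
        return variant_pos - mirna.start + 1
    return mirna.end - variant_pos


def classify_region(
    position: int, seed_bounds: tuple[int, int] = SEED_BOUNDS
) -> str:
    """'seed' for positions within ``seed_bounds`` (default 2-7), else 'mature'."""
    if position < 1:
        raise ValueError(f"position {position} < 1")
    lo, hi = seed_bounds
    return "seed" if lo <= position <= hi else "mature"


def compute_maf(
    genotypes: Sequence[float] | np.ndarray, ref: str = "ref", alt: str = "alt"
) -> tuple[str, float]:
    """(minor allele, MAF) from 0/1/2 alt-dosages; missing values are NaN or
    negative. Ties (frequency exactly 0.5) report the alt allele as minor."""
    g = np.asarray(genotypes, float)
    g = g[np.isfinite(g) & (g >= 0)]
    if g.size == 0:
        raise ValueError("no non-missing genotypes")
    f_alt = g.sum() / (2 * g.size)
    if f_alt <= 0.5:
        return alt, f_alt
    return ref, 1.0 - f_alt


def filter_maf(variants: Iterable[MiRSNP], threshold: float = 0.01) -> list[MiRSNP]:
    """Retain variants with MAF >= threshold (removal rule is 'lower than')."""
    return [v for v in variants if v.maf >= threshold]


def cpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts-per-million. ``counts`` is features x samples; library sizes
    default to the column sums."""
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        bad = library_sizes.index[library_sizes <= 0].tolist()
        raise ValueError(f"non-positive library size for samples {bad}")
    return counts * 1e6 / library_sizes


def filter_expressed_mirnas(
    cpm_matrix: pd.DataFrame, min_cpm: float = 0.5, min_fraction: float = 0.5
) -> list[str]:
    """Names of miRNAs 'present' (cpm >= min_cpm) in >= min_fraction of samples."""
    frac = (cpm_matrix >= min_cpm).mean(axis=1)
    return list(cpm_matrix.index[frac >= min_fraction])


# ---------------------------------------------------------------------------
# file readers

def read_mature_mirnas(
    gff3_path: str | Path, mature_fasta: str | Path | None = None
) -> list[MatureMirna]:
    """Parse the miRBase GFF3 dialect (``miRNA`` features with ``Derives_from``
    pointing at a ``miRNA_primary_transcript``); sequences are attached from a
    mature-FASTA keyed by the Name attribute when provided."""
    seqs: dict[str, str] = {}
    if mature_fasta is not None:
        from Bio import SeqIO

        for rec in SeqIO.parse(str(mature_fasta), "fasta"):
            seqs[rec.id] = dna_to_rna(str(rec.seq))

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    precursors = {
        f.id: (f.attributes.get("Name") or [f.id])[0]
        for f in db.features_of_type("miRNA_primary_transcript")
    }
    out = []
    for f in db.features_of_type("miRNA"):
        name = (f.attributes.get("Name") or [f.id])[0]
        parents = f.attributes.get("Derives_from") or []
        if not parents or parents[0] not in precursors:
            warnings.warn(f"mature miRNA {name} has no parent precursor in the GFF3")
            pre = ""
        else:
            pre = precursors[parents[0]]
        start0, end0 = coords.to_internal(f.start, f.end)
        out.append(
            MatureMirna(
                name=name,
                chrom=f.seqid,
                start=start0,
                end=end0,
                strand=f.strand,
                sequence=seqs.get(name, ""),
                precursor_name=pre,
            )
        )
    return out


def read_genotype_matrix(
    vcf_path: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF into (variants, dosages).

    ``variants`` has one row per biallelic record (multi-allelic records are
    split) with columns chrom, pos (0-based), id, ref, alt; ``dosages`` is
    variants x samples with alt-allele dosage, NaN for missing.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    rows, dosage_rows = [], []
    for rec in vcf:
        gts = np.array([g[:2] for g in rec.genotypes], dtype=float)  # (n, 2)
        for ai, alt in enumerate(rec.ALT, start=1):
            dos = np.where(
                np.any(gts < 0, axis=1), np.nan, (gts == ai).sum(axis=1)
            )
            vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
            if len(rec.ALT) > 1:
                vid = f"{vid}:{alt}"
            rows.append(
                {
                    "chrom": rec.CHROM,
                    "pos": coords.point_to_internal(rec.POS),
                    "id": vid,
                    "ref": rec.REF,
                    "alt": alt,
                }
            )
            dosage_rows.append(dos)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    dosages = pd.DataFrame(dosage_rows, columns=samples)
    if len(variants):
        dosages.index = variants["id"]
    return variants, dosages


def select_analysis_set(
    vcf_path: str | Path,
    gff3_path: str | Path,
    mirna_counts: pd.DataFrame,
    mature_fasta: str | Path | None = None,
    maf_threshold: float = 0.01,
    min_cpm: float = 0.5,
    min_fraction: float = 0.5,
    seed_bounds: tuple[int, int] = SEED_BOUNDS,
) -> tuple[list[MiRSNP], pd.DataFrame, dict]:
    """The analysis set: SNVs inside mature miRNAs that pass the MAF filter and
    whose miRNA passes the expression filter.

    Returns (miR-SNPs ordered by (chrom, pos), minor-allele dosage matrix
    aligned to that order, funnel counts at each filter stage).
    """
    matures = read_mature_mirnas(gff3_path, mature_fasta)
    variants, dosages = read_genotype_matrix(vcf_path)
    expressed = set(filter_expressed_mirnas(cpm(mirna_counts), min_cpm, min_fraction))

    in_mature: list[MiRSNP] = []
    minor_dosages: dict[str, np.ndarray] = {}
    for i, var in variants.iterrows():
        if len(var["ref"]) != 1 or len(var["alt"]) != 1:
            continue  # SNVs only
        for mir in matures:
            if mir.chrom != var["chrom"]:
                continue
            pos_m = position_in_mature(var["pos"], mir)
            if pos_m is None:
                continue
            dos = dosages.iloc[i].to_numpy(float)
            minor, maf = compute_maf(dos, ref=var["ref"], alt=var["alt"])
            snp = MiRSNP(
                variant_id=var["id"],
                chrom=var["chrom"],
                pos=int(var["pos"]),
                ref=var["ref"],
                alt=var["alt"],
                mirna=mir,
                position_in_mature=pos_m,
                region=classify_region(pos_m, seed_bounds),
                minor_allele=minor,
                maf=maf,
            )
            in_mature.append(snp)
            # dosage of the *minor* allele, so downstream beta is per minor copy
            minor_dosages[snp.variant_id] = dos if minor == var["alt"] else 2 - dos

    after_maf = filter_maf(in_mature, maf_threshold)
    hits = [s for s in after_maf if s.mirna.name in expressed]
    for s in set(in_mature) - set(hits):
        log.info("miR-SNP %s (in %s) dropped by filters", s.variant_id, s.mirna.name)

    hits.sort(key=lambda s: (s.chrom, s.pos))
    dosage_df = pd.DataFrame(
        [minor_dosages[s.variant_id] for s in hits],
        index=[s.variant_id for s in hits],
        columns=dosages.columns if len(dosages) else [],
    )
    funnel = {
        "n_variants": int(len(variants)),
        "n_in_mature": len(in_mature),
        "n_after_maf": len(after_maf),
        "n_analysis_set": len(hits),
    }
    return hits, dosage_df, funnel


def mirsnp_table(mirsnps: Iterable[MiRSNP]) -> pd.DataFrame:
    """Flat TSV-ready table of annotated miR-SNPs."""
    return pd.DataFrame(
        [
            {
                "variant_id": s.variant_id,
                "mirna": s.mirna.name,
                "chrom": s.chrom,
                "pos": coords.point_to_vcf(s.pos),
                "position_in_mature": s.position_in_mature,
                "region": s.region,
                "minor_allele": s.minor_allele,
                "maf": round(s.maf, 6),
            }
            for s in mirsnps
        ],
        columns=[
            "variant_id", "mirna", "chrom", "pos",
            "position_in_mature", "region", "minor_allele", "maf",
        ],
    )
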