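"""Plain-text writers for the simulated inputs.

Every file the pipeline consumes is emitted here with fixed column order so a
fixed seed yields byte-identical output: VCF v4.2, GFF3 in the miRBase dialect
(``miRNA_primary_transcript`` / ``miRNA`` features with ``Derives_from``),
FASTA, TSV tables, and a JSON manifest recording the seed and true parameters.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .. import coords
from .locus import MirnaLocus

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_fasta(path: str | Path, records: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_vcf(
    path: str | Path,
    loci: Iterable[MirnaLocus],
    genotypes: np.ndarray,
    sample_names: list[str],
) -> None:
    """One biallelic SNV record per locus; genotypes are minor-allele dosages
    (columns of ``genotypes`` in locus order)."""
    loci = list(loci)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom, length in sorted({(l.chrom, len(l.contig_seq)) for l in loci}):
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_names)
    )
    order = sorted(range(len(loci)), key=lambda i: (loci[i].chrom, loci[i].snp_pos))
    for i in order:
        loc = loci[i]
        gts = "\t".join(_GT[int(g)] for g in genotypes[:, i])
        lines.append(
            f"{loc.chrom}\t{coords.point_to_vcf(loc.snp_pos)}\tsim_rs{i + 1}\t"
            f"{loc.ref_allele}\t{loc.alt_allele}\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_gff3(path: str | Path, loci: Iterable[MirnaLocus]) -> None:
    lines = ["##gff-version 3"]
    for loc in loci:
        ps, pe = coords.to_gff(loc.precursor_start, loc.precursor_end)
        ms, me = coords.to_gff(loc.mature_start, loc.mature_end)
        pid, mid = f"MI_{loc.precursor_name}", f"MIMAT_{loc.name}"
        lines.append(
            f"{loc.chrom}\t.\tmiRNA_primary_transcript\t{ps}\t{pe}\t.\t"
            f"{loc.strand}\t.\tID={pid};Name={loc.precursor_name}"
        )
        lines.append(
            f"{loc.chrom}\t.\tmiRNA\t{ms}\t{me}\t.\t{loc.strand}\t.\t"
            f"ID={mid};Name={loc.name};Derives_from={pid}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_table(path: str | Path, df: pd.DataFrame, index_label: str = "sample") -> None:
    df.to_csv(path, sep="\t", index=True, index_label=index_label)


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
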