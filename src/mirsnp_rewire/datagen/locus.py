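"""Designed miRNA loci: hairpin precursor, genomic embedding, variant record.

The precursor is a designed stem-loop: the mature sequence, an 8-nt loop
(``GAAA`` + 4 more unpaired-friendly bases), and the reverse complement of the
mature with two planted mismatches. The mismatches keep the designed stem the
unambiguous minimum-free-energy fold while leaving the position opposite the
SNP Watson-Crick paired, so the minor allele genuinely disrupts a stack.

Coordinates follow the package convention: 0-based half-open in memory, converted
at the GFF3/VCF writers only.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..seq import check_rna, dna_to_rna, revcomp_rna, rna_to_dna, revcomp_dna

LOOP = "GAAAGAAA"  # 8-nt hairpin loop, A/G only: pairs with nothing in the arms
FLANK = 30  # unpaired genomic padding on each side of the precursor


@dataclass(frozen=True)
class MirnaLocus:
    """One simulated miRNA gene with a biallelic SNP in its mature sequence."""

    name: str  # mature miRNA name
    precursor_name: str
    chrom: str
    strand: str  # '+' or '-'
    contig_seq: str  # DNA, the full simulated contig (flank+precursor+flank)
    precursor_start: int  # 0-based half-open genomic interval of the precursor
    precursor_end: int
    mature_start: int
    mature_end: int
    mature_major: str  # RNA, 5'->3'
    mature_minor: str
    precursor_major: str  # RNA, 5'->3'
    precursor_minor: str
    snp_pos: int  # 0-based genomic position of the SNP
    ref_allele: str  # DNA alleles as they appear on the forward genome strand
    alt_allele: str
    position_in_mature: int  # 1-based, truth for round-trip tests


def _mismatch_positions(mature_len: int, snp_position: int) -> tuple[int, int]:
    """Two 1-based mature positions for the planted arm mismatches, kept away
    from the SNP and from each other."""
    candidates = [4, mature_len - 3, 8, mature_len - 7, 11]
    picked: list[int] = []
    for c in candidates:
        if 1 <= c <= mature_len and abs(c - snp_position) > 1 and all(
            abs(c - p) > 2 for p in picked
        ):
            picked.append(c)
        if len(picked) == 2:
            return picked[0], picked[1]
    raise ValueError("could not place arm mismatches away from the SNP")


def design_precursor(mature_seq: str, snp_position: int) -> str:
    """Hairpin precursor (major allele): mature + loop + mismatched complement arm."""
    mature_seq = check_rna(mature_seq)
    n = len(mature_seq)
    arm = list(revcomp_rna(mature_seq))
    for p in _mismatch_positions(n, snp_position):
        # arm index opposite mature position p (1-based): reverse order
        i = n - p
        # the mature base itself never pairs with an identical base
        arm[i] = mature_seq[p - 1]
    return mature_seq + LOOP + "".join(arm)


def simulate_mirna_locus(
    mature_seq: str,
    snp_position_in_mature: int,
    alleles: tuple[str, str],
    *,
    name: str = "sim-miR-1",
    chrom: str = "chrSim1",
    strand: str = "+",
) -> MirnaLocus:
    """Build one locus; ``alleles`` is (major, minor) as RNA bases of the mature
    strand, ``mature_seq`` carries the major allele at the SNP position."""
    mature_seq = check_rna(mature_seq)
    n = len(mature_seq)
    if not 1 <= snp_position_in_mature <= n:
        raise ValueError(
            f"SNP position {snp_position_in_mature} outside mature 1..{n}"
        )
    major, minor = (check_rna(a) for a in alleles)
    if major == minor:
        raise ValueError("alleles must differ")
    if mature_seq[snp_position_in_mature - 1] != major:
        raise ValueError("mature_seq does not carry the major allele at the SNP")
    if strand not in "+-":
        raise ValueError(f"bad strand {strand!r}")

    pre_major = design_precursor(mature_seq, snp_position_in_mature)
    i = snp_position_in_mature - 1
    mature_minor = mature_seq[:i] + minor + mature_seq[i + 1 :]
    pre_minor = mature_minor + pre_major[n:]

    lp = len(pre_major)
    pre_start, pre_end = FLANK, FLANK + lp
    # mature occupies the 5' end of the precursor (plus strand) or its genomic
    # mirror (minus strand)
    if strand == "+":
        mat_start, mat_end = pre_start, pre_start + n
        snp_pos = mat_start + i
        genome_fwd = rna_to_dna(pre_major)
        ref, alt = rna_to_dna(major), rna_to_dna(minor)
    else:
        mat_start, mat_end = pre_end - n, pre_end
        snp_pos = mat_end - 1 - i
        genome_fwd = revcomp_dna(rna_to_dna(pre_major))
        ref, alt = revcomp_dna(rna_to_dna(major)), revcomp_dna(rna_to_dna(minor))

    # fixed non-pairing flanks keep the designed fold unambiguous
    flank_seq = ("CA" * FLANK)[:FLANK]
    contig = flank_seq + genome_fwd + flank_seq
    assert dna_to_rna(contig[snp_pos] if strand == "+" else revcomp_dna(contig[snp_pos])) == major

    return MirnaLocus(
        name=name,
        precursor_name=name + "-pre",
        chrom=chrom,
        strand=strand,
        contig_seq=contig,
        precursor_start=pre_start,
        precursor_end=pre_end,
        mature_start=mat_start,
        mature_end=mat_end,
        mature_major=mature_seq,
        mature_minor=mature_minor,
        precursor_major=pre_major,
        precursor_minor=pre_minor,
        snp_pos=snp_pos,
        ref_allele=ref,
        alt_allele=alt,
        position_in_mature=snp_position_in_mature,
    )
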