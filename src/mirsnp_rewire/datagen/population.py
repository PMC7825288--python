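"""Half-sib cohort simulation: genotypes and pedigree kinship.

The emulated design is a paternal half-sib beef-cattle cohort: ~374 steers sired by
~26 unrelated sires, each progeny having an unrelated dam drawn from the base
population. Markers are simulated without linkage (family sharing is the only source
of covariance), which is all the downstream kinship-aware association model uses.

Kinship truth is reported on the pedigree (numerator-relationship) scale: diagonal 1
for non-inbred animals, 0.5 for full sibs or parent-offspring, 0.25 for paternal half
sibs. The marker-based GRM estimated downstream agrees with this matrix only in
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class PopulationSpec:
    """Design of the simulated half-sib cohort.

    ``maf`` applies to the focal simulated miR-SNPs; ``n_background_markers``
    unlinked markers (MAF drawn uniform on [0.05, 0.5]) are simulated for the
    genomic relationship matrix.
    """

    n_individuals: int = 374
    n_sires: int = 26
    maf: tuple[float, ...] = (0.07, 0.41, 0.04)
    n_background_markers: int = 5000
    batch_levels: int = 19
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if not 0 < self.n_sires <= self.n_individuals:
            raise ValueError("need 0 < n_sires <= n_individuals")
        for f in self.maf:
            if not 0.0 < f <= 0.5:
                raise ValueError(f"MAF {f} outside (0, 0.5]")
        if self.n_background_markers < 0 or self.batch_levels < 1:
            raise ValueError("invalid marker or batch count")


@dataclass
class Cohort:
    """Simulated cohort: focal genotypes, background genotypes, pedigree truth."""

    sire_of: np.ndarray  # (n,) sire index per progeny
    genotypes: np.ndarray  # (n, n_mirsnp) 0/1/2 copies of the minor allele
    background: np.ndarray  # (n, n_background_markers) 0/1/2
    kinship: np.ndarray  # (n, n) pedigree numerator-relationship matrix
    mafs: np.ndarray = field(default_factory=lambda: np.empty(0))


def _family_assignment(n: int, n_sires: int, rng: np.random.Generator) -> np.ndarray:
    # balanced-as-possible families, then shuffled so family blocks are not contiguous
    sire_of = np.repeat(np.arange(n_sires), int(np.ceil(n / n_sires)))[:n]
    rng.shuffle(sire_of)
    return sire_of


def _drop_genotypes(
    sire_of: np.ndarray, mafs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw 0/1/2 minor-allele dosages under paternal half-sib inheritance.

    Each sire carries two haplotypes with per-marker allele frequency ``mafs``;
    a progeny receives one allele picked at random from its sire plus one
    population allele (the dam's gamete).
    """
    n, m = len(sire_of), len(mafs)
    n_sires = int(sire_of.max()) + 1
    sire_hap = rng.random((n_sires, 2, m)) < mafs  # minor-allele indicators
    pick = rng.integers(0, 2, size=(n, m))
    paternal = sire_hap[sire_of[:, None], pick, np.arange(m)[None, :]]
    maternal = rng.random((n, m)) < mafs
    return (paternal.astype(np.int8) + maternal.astype(np.int8)).astype(np.int8)


def pedigree_kinship(sire_of: np.ndarray) -> np.ndarray:
    """Expected-relationship matrix among progeny: 1 on the diagonal, 0.25 for
    paternal half sibs, 0 otherwise (sires and dams unrelated and non-inbred)."""
    same_sire = sire_of[:, None] == sire_of[None, :]
    kin = np.where(same_sire, 0.25, 0.0)
    np.fill_diagonal(kin, 1.0)
    return kin


def tabular_relationship(sires: list[int | None], dams: list[int | None]) -> np.ndarray:
    """Numerator relationship matrix by the recursive tabular method.

    Individuals must be ordered parents-before-offspring; ``None`` marks an
    unknown (base-population) parent. Kept general so it can serve as an
    independent check of :func:`pedigree_kinship` on arbitrary pedigrees.
    """
    n = len(sires)
    a = np.zeros((n, n))
    for i in range(n):
        s, d = sires[i], dams[i]
        a[i, i] = 1.0 + 0.5 * (a[s, d] if s is not None and d is not None else 0.0)
        for j in range(i):
            val = 0.0
            if s is not None:
                val += 0.5 * a[j, s]
            if d is not None:
                val += 0.5 * a[j, d]
            a[i, j] = a[j, i] = val
    return a


def simulate_pedigree_genotypes(spec: PopulationSpec) -> Cohort:
    """Simulate focal miR-SNP genotypes, background markers and pedigree kinship."""
    rng = np.random.default_rng(spec.seed)
    sire_of = _family_assignment(spec.n_individuals, spec.n_sires, rng)
    focal = _drop_genotypes(sire_of, np.asarray(spec.maf, float), rng)
    bg_maf = rng.uniform(0.05, 0.5, size=spec.n_background_markers)
    background = _drop_genotypes(sire_of, bg_maf, rng)
    return Cohort(
        sire_of=sire_of,
        genotypes=focal,
        background=background,
        kinship=pedigree_kinship(sire_of),
        mafs=np.asarray(spec.maf, float),
    )
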