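"""Molecular-phenotype simulation: mRNA counts and protein abundances.

mRNA features are negative-binomial counts (gamma-Poisson, dispersion 0.1) with
any planted genotype effect acting on the log2 scale — the same scale on which
the association module analyses counts (log2(cpm + 0.5)). Protein features are
log-normal with the effect on log2 abundance. One designated feature (index 0)
carries the effect; all others are null.
"""

from __future__ import annotations

import numpy as np

NB_DISPERSION = 0.1
MRNA_BASE_MEAN = 200.0
PROTEIN_BASE_LOG2 = 10.0
PROTEIN_SD_LOG2 = 0.5


def _nb_counts(mu: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    shape = 1.0 / NB_DISPERSION
    lam = rng.gamma(shape, mu * NB_DISPERSION)
    return rng.poisson(lam)


def simulate_expression(
    genotypes_at_mirsnp: np.ndarray,
    effect_sign: int,
    effect_size: float,
    n_features: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (mrna_counts, protein_abundance), both samples x features.

    ``effect_sign`` in {+1, -1, 0}; ``effect_size`` is the log2 change per copy
    of the minor allele carried by feature 0.
    """
    if effect_sign not in (-1, 0, 1):
        raise ValueError("effect_sign must be -1, 0 or +1")
    g = np.asarray(genotypes_at_mirsnp, float)
    n = len(g)
    shift = effect_sign * effect_size * g  # log2-scale genotype effect

    log2_mu = np.full((n, n_features), np.log2(MRNA_BASE_MEAN))
    log2_mu[:, 0] += shift
    counts = _nb_counts(2.0 ** log2_mu, rng)

    log2_prot = rng.normal(PROTEIN_BASE_LOG2, PROTEIN_SD_LOG2, size=(n, n_features))
    log2_prot[:, 0] += shift
    protein = 2.0 ** log2_prot
    return counts, protein
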