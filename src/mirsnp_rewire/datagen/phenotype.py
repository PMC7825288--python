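"""Phenotype simulation under the additive polygenic mixed model.

A trait vector is generated as

    y = W alpha + x beta + u + e,   u ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I)

with W a fixed-effects incidence matrix (batch/contemporary-group levels plus an
intercept), x the minor-allele dosage at one miR-SNP and K a symmetric PSD kinship
matrix. This is exactly the generative model the association module fits, so planted
effects are recoverable in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class TraitSpec:
    """Generative parameters for one quantitative trait.

    beta_true   allele-substitution effect per copy of the minor allele
    var_polygenic   variance of the polygenic term u (sigma_g^2)
    var_residual    variance of the residual e (sigma_e^2)
    batch_effects   fixed offsets, one per batch level (the first level is the
                    reference and its offset is usually 0)
    """

    beta_true: float = 0.0
    var_polygenic: float = 0.25
    var_residual: float = 0.75
    batch_effects: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.var_polygenic < 0 or self.var_residual < 0:
            raise ValueError("variance components must be non-negative")


def batch_incidence(batches: np.ndarray) -> np.ndarray:
    """Full incidence matrix (one column per level) for a vector of batch labels."""
    levels = np.unique(batches)
    return (batches[:, None] == levels[None, :]).astype(float)


def kinship_factor(kinship: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Symmetric factor L with L L' = K, via eigendecomposition.

    Eigenvalues in [-tol, 0) are clipped to 0; anything below -tol is a hard
    error because K is then not a valid covariance matrix.
    """
    kinship = np.asarray(kinship, float)
    if not np.allclose(kinship, kinship.T, atol=1e-10):
        raise ValueError("kinship matrix is not symmetric")
    w, v = np.linalg.eigh(kinship)
    if w.min() < -tol:
        raise ValueError(f"kinship is not PSD: eigenvalue {w.min():.6g} < 0")
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def simulate_phenotype(
    genotypes: np.ndarray,
    kinship: np.ndarray,
    trait: TraitSpec,
    batches: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one phenotype vector; with both variances 0 the result is exactly
    the fixed part W alpha + x beta (no RNG draws are consumed in that case)."""
    x = np.asarray(genotypes, float)
    n = len(x)
    w_mat = batch_incidence(np.asarray(batches))
    alpha = np.zeros(w_mat.shape[1])
    if trait.batch_effects:
        if len(trait.batch_effects) != w_mat.shape[1]:
            raise ValueError("batch_effects length does not match batch levels")
        alpha = np.asarray(trait.batch_effects, float)
    y = w_mat @ alpha + x * trait.beta_true
    if trait.var_polygenic > 0:
        factor = kinship_factor(kinship)
        y = y + np.sqrt(trait.var_polygenic) * (factor @ rng.standard_normal(n))
    if trait.var_residual > 0:
        y = y + np.sqrt(trait.var_residual) * rng.standard_normal(n)
    return y
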