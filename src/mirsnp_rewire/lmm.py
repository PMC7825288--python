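"""Kinship-aware linear mixed model association.

For each (miR-SNP, phenotype) pair the univariate model

    y = W alpha + x beta + u + e,
    u ~ MVN_n(0, lambda * tau^-1 * K),  e ~ MVN_n(0, tau^-1 * I_n)

is fitted by maximum likelihood, profiling alpha, beta and tau analytically in
the eigenbasis of K and maximizing over the variance ratio lambda by a
derivative-free search on log10(lambda) in [-5, 5]. Significance of beta is a
likelihood-ratio test against chi2 with 1 df, with Bonferroni control of the
family-wise error rate across miR-SNPs.

The eigendecomposition of K is computed once per cohort and reused across all
phenotypes, which is what makes dense phenotype screens (mRNA, protein) cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

LOG10_LAMBDA_BOUNDS = (-5.0, 5.0)
_GRID_POINTS = 21


def grm(markers: np.ndarray, exclude: list[int] | None = None) -> np.ndarray:
    """Centered genomic relationship matrix K = C C' / p, with C the
    column-centered dosage matrix and p the marker count after exclusions."""
    g = np.asarray(markers, float)
    if exclude:
        g = np.delete(g, exclude, axis=1)
    poly = g.std(axis=0) > 0
    if poly.sum() < 2:
        raise ValueError("need at least two polymorphic markers for the GRM")
    c = g[:, poly] - g[:, poly].mean(axis=0)
    return (c @ c.T) / poly.sum()


@dataclass
class KinshipEigen:
    """Eigendecomposition of K with eigenvalues clipped at zero."""

    values: np.ndarray
    vectors: np.ndarray

    @classmethod
    def from_kinship(cls, kinship: np.ndarray, tol: float = 1e-8) -> "KinshipEigen":
        kinship = np.asarray(kinship, float)
        if not np.allclose(kinship, kinship.T, atol=1e-8):
            raise ValueError("kinship matrix is not symmetric")
        w, v = np.linalg.eigh(kinship)
        if w.min() < -tol:
            raise ValueError(f"kinship not PSD: eigenvalue {w.min():.6g}")
        return cls(values=np.clip(w, 0.0, None), vectors=v)

    def rotate(self, a: np.ndarray) -> np.ndarray:
        return self.vectors.T @ a


@dataclass
class LmmFit:
    loglik: float
    lambda_hat: float
    tau_inv: float  # residual variance sigma_e^2 (ML)
    coefficients: np.ndarray  # [alpha..., beta] in design-column order
    beta: float | None
    se: float | None


def _profile_loglik(
    log10_lam: float, y_r: np.ndarray, x_r: np.ndarray, eig_values: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Profile log-likelihood at fixed lambda, after rotation into K's
    eigenbasis. Returns (loglik, coefficients, XtVinvX, rss_weighted/n)."""
    lam = 10.0 ** log10_lam
    n = len(y_r)
    d = lam * eig_values + 1.0
    w = 1.0 / d
    xtwx = (x_r * w[:, None]).T @ x_r
    xtwy = (x_r * w[:, None]).T @ y_r
    # ridge guards against rank deficiency after rotation
    coef = np.linalg.solve(xtwx + 1e-8 * np.eye(xtwx.shape[0]), xtwy)
    resid = y_r - x_r @ coef
    rss = float(resid @ (w * resid))
    if rss <= 0 or not np.isfinite(rss):
        raise FloatingPointError(f"non-finite likelihood at lambda={lam:.4g}")
    sigma2 = rss / n
    ll = -0.5 * (
        n * np.log(2 * np.pi) + n * np.log(sigma2) + np.log(d).sum() + n
    )
    return ll, coef, xtwx, sigma2


def fit_lmm(
    y: np.ndarray,
    covariates: np.ndarray,
    eig: KinshipEigen,
    x: np.ndarray | None = None,
    reml: bool = False,
    tol: float = 1e-6,
) -> LmmFit:
    """Maximum-likelihood fit; ``covariates`` must include the intercept column.

    With ``x`` given, its coefficient is the allele-substitution effect beta
    (last entry of ``coefficients``) with its standard error from the inverse
    weighted information.
    """
    y = np.asarray(y, float)
    design = np.asarray(covariates, float)
    if x is not None:
        design = np.column_stack([design, np.asarray(x, float)])
    if design.shape[0] != len(y) or len(y) != len(eig.values):
        raise ValueError("inconsistent dimensions")
    y_r = eig.rotate(y)
    x_r = eig.rotate(design)

    def objective(log10_lam: float) -> float:
        ll = _loglik_fn(log10_lam)
        return -ll

    if reml:
        p = design.shape[1]

        def _loglik_fn(log10_lam: float) -> float:
            ll, _, xtwx, sigma2 = _profile_loglik(log10_lam, y_r, x_r, eig.values)
            # REML adjustment on the profiled ML likelihood
            _sign, logdet = np.linalg.slogdet(xtwx)
            return ll + 0.5 * (p * np.log(2 * np.pi * sigma2) - logdet)
    else:

        def _loglik_fn(log10_lam: float) -> float:
            return _profile_loglik(log10_lam, y_r, x_r, eig.values)[0]

    lo, hi = LOG10_LAMBDA_BOUNDS
    grid = np.linspace(lo, hi, _GRID_POINTS)
    lls = [_loglik_fn(g) for g in grid]
    k = int(np.argmax(lls))
    a, b = grid[max(0, k - 1)], grid[min(_GRID_POINTS - 1, k + 1)]
    res = optimize.minimize_scalar(
        objective, bounds=(a, b), method="bounded", options={"xatol": tol}
    )
    candidates = [(float(-res.fun), float(res.x)), (lls[0], lo), (lls[-1], hi)]
    best_ll, best_lam = max(candidates)

    ll, coef, xtwx, sigma2 = _profile_loglik(best_lam, y_r, x_r, eig.values)
    ll = _loglik_fn(best_lam)
    beta = se = None
    if x is not None:
        cov = np.linalg.inv(xtwx) * sigma2
        beta = float(coef[-1])
        se = float(np.sqrt(cov[-1, -1]))
    return LmmFit(
        loglik=float(ll),
        lambda_hat=10.0 ** best_lam,
        tau_inv=float(sigma2),
        coefficients=coef,
        beta=beta,
        se=se,
    )


def lrt_test(loglik_null: float, loglik_alt: float) -> tuple[float, float]:
    """Likelihood-ratio statistic (clipped at 0) and chi2_1 upper-tail p-value."""
    if loglik_alt < loglik_null - 1e-6:
        # numerical search noise only; anything larger indicates a fit failure
        raise ValueError(
            f"alternative log-likelihood {loglik_alt} below null {loglik_null}"
        )
    lrt = max(0.0, 2.0 * (loglik_alt - loglik_null))
    return lrt, float(stats.chi2.sf(lrt, df=1))


def bonferroni_threshold(fwer: float, n_tests: int) -> float:
    """Per-test p-value threshold controlling the family-wise error rate."""
    if not 0 < fwer < 1:
        raise ValueError(f"FWER {fwer} outside (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return fwer / n_tests


def reference_incidence(covariates: pd.DataFrame) -> np.ndarray:
    """Intercept + reference-coded (first level dropped) categorical covariates."""
    n = len(covariates)
    cols = [np.ones(n)]
    for name in covariates.columns:
        levels = pd.unique(covariates[name])
        for lev in levels[1:]:
            cols.append((covariates[name] == lev).to_numpy(float))
    return np.column_stack(cols)


def log2_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(cpm + 0.5), the transform applied to mRNA counts before association."""
    lib = counts.sum(axis=0)
    return np.log2(counts * 1e6 / lib + 0.5)


def associate_all(
    dosages: pd.DataFrame,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame | None,
    kinship: np.ndarray,
    fwer: float = 0.10,
    n_tests: int | None = None,
    reml: bool = False,
) -> pd.DataFrame:
    """Fit the LMM for every (miR-SNP, phenotype) pair.

    ``dosages`` is miR-SNPs x samples (minor-allele coding); ``phenotypes`` is
    samples x phenotype columns, already on the analysis scale. The Bonferroni
    divisor defaults to the number of miR-SNPs.
    """
    samples = list(phenotypes.index)
    if list(dosages.columns) != samples:
        dosages = dosages[samples]
    if covariates is not None:
        w_mat = reference_incidence(covariates.loc[samples])
    else:
        w_mat = np.ones((len(samples), 1))
    eig = KinshipEigen.from_kinship(kinship)
    threshold = bonferroni_threshold(fwer, n_tests or len(dosages))

    rows = []
    for pheno in phenotypes.columns:
        y = phenotypes[pheno].to_numpy(float)
        if np.std(y) == 0:
            warnings.warn(f"phenotype {pheno!r} has zero variance; skipped")
            continue
        null_fit = fit_lmm(y, w_mat, eig, reml=reml)
        for snp_id in dosages.index:
            x = dosages.loc[snp_id].to_numpy(float)
            alt_fit = fit_lmm(y, w_mat, eig, x=x, reml=reml)
            lrt, p = lrt_test(null_fit.loglik, alt_fit.loglik)
            rows.append(
                {
                    "snp": snp_id,
                    "phenotype": pheno,
                    "n": len(y),
                    "beta": alt_fit.beta,
                    "se": alt_fit.se,
                    "lambda": alt_fit.lambda_hat,
                    "lrt": lrt,
                    "p": p,
                    "significant": p < threshold,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["snp", "phenotype", "n", "beta", "se", "lambda", "lrt", "p", "significant"],
    )
    return out.sort_values(["snp", "phenotype"], kind="stable").reset_index(drop=True)
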