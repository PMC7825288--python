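"""Independent oracles used by the test suite.

These deliberately avoid the implementation's dynamic programs and spectral
shortcuts: structures and hybrids are enumerated exhaustively and scored by
loop decomposition; mixed-model likelihoods are evaluated by explicit dense
covariance inversion.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from mirsnp_rewire.energy import EnergyModel, DEFAULT_MODEL, structure_energy
from mirsnp_rewire.seq import pairable


def enumerate_hairpin_mfe(seq: str, model: EnergyModel = DEFAULT_MODEL) -> float:
    """Minimum energy over *all* valid nested structures, by brute force."""
    n = len(seq)
    h = model.min_hairpin_unpaired

    @lru_cache(maxsize=None)
    def structs(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        if j - i + 1 <= 0:
            return ((),)
        out = list(structs(i + 1, j))
        for k in range(i + h + 1, j + 1):
            if pairable(seq[i], seq[k]):
                for left in structs(i + 1, k - 1):
                    for right in structs(k + 1, j):
                        out.append(((i, k),) + left + right)
        return tuple(out)

    best = 0.0
    for st in structs(0, n - 1):
        if not st:
            continue
        try:
            e = structure_energy(seq, list(st), model)
        except ValueError:  # interior loop beyond the model cap
            continue
        best = min(best, e)
    structs.cache_clear()
    return best


def enumerate_duplex_mfe(
    mirna: str, target: str, model: EnergyModel = DEFAULT_MODEL
) -> float | None:
    """Minimum energy over all intermolecular hybrids (monotone pair chains
    with per-side loop caps); None when no hybrid scores below zero."""
    rt = target[::-1]
    mlen, nlen = len(mirna), len(rt)
    cap = model.duplex_max_loop_side
    best: list[float | None] = [None]

    def rec(i: int, k: int, energy: float) -> None:
        if best[0] is None or energy < best[0]:
            best[0] = energy
        for i2 in range(i + 1, min(i + cap + 2, mlen)):
            for k2 in range(k + 1, min(k + cap + 2, nlen)):
                if not pairable(mirna[i2], rt[k2]):
                    continue
                if i2 == i + 1 and k2 == k + 1:
                    st = model.stack(mirna[i] + rt[k], mirna[i2] + rt[k2])
                    if st is not None:
                        rec(i2, k2, energy + st)
                else:
                    rec(i2, k2, energy + model.internal_or_bulge(i2 - i - 1, k2 - k - 1))

    for i in range(mlen):
        for k in range(nlen):
            if pairable(mirna[i], rt[k]):
                rec(i, k, model.duplex_init)
    if best[0] is None or best[0] >= 0:
        return None
    return best[0]


def dense_lmm_loglik(
    y: np.ndarray, design: np.ndarray, kinship: np.ndarray, lam: float
) -> float:
    """Profile (over coefficients and residual variance) ML log-likelihood at a
    fixed variance ratio, via explicit covariance inversion."""
    n = len(y)
    sigma = lam * kinship + np.eye(n)
    sigma_inv = np.linalg.inv(sigma)
    xtsx = design.T @ sigma_inv @ design
    coef = np.linalg.solve(xtsx, design.T @ sigma_inv @ y)
    resid = y - design @ coef
    rss = float(resid @ sigma_inv @ resid)
    s2 = rss / n
    sign, logdet = np.linalg.slogdet(sigma)
    return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


def parse_dot_bracket(structure: str) -> list[tuple[int, int]]:
    stack, pairs = [], []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            pairs.append((stack.pop(), i))
    assert not stack, "unbalanced dot-bracket"
    return sorted(pairs)


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))
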