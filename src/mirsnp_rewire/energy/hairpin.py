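"""Minimum-free-energy folding of a single RNA (Zuker-style, nested only).

The grammar matches :func:`structure_energy` exactly: every base pair closes a
hairpin loop, a stack, an interior loop/bulge, or a multiloop; exterior bases
are free. Interior loops are capped at ``model.max_loop`` unpaired bases per
side. The traceback is deterministic: at ties it prefers keeping a pair
(stack, then interior loop with 5'-most inner pair, then multiloop, then
hairpin loop), and in the exterior it prefers the 5'-most pairing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..seq import check_rna, pairable
from .params import DEFAULT_MODEL, EnergyModel

INF = float("inf")
_EPS = 1e-9

MAX_FOLD_LENGTH = 200


@dataclass(frozen=True)
class HairpinFold:
    sequence: str
    structure: str  # dot-bracket
    mfe: float  # kcal/mol, <= 0 (the open chain scores 0)


def structure_energy(
    seq: str, pairs: list[tuple[int, int]], model: EnergyModel = DEFAULT_MODEL
) -> float:
    """Energy of an explicit nested structure by loop decomposition.

    Independent of the dynamic program: walks the structure tree and sums
    hairpin/stack/interior/multiloop terms. Non-pairable or crossing pairs
    raise; used both as an internal consistency check on tracebacks and by
    enumeration oracles in the tests.
    """
    seq = check_rna(seq)
    pairs = sorted(pairs)
    partner = {}
    for i, j in pairs:
        if not (0 <= i < j < len(seq)):
            raise ValueError(f"bad pair {(i, j)}")
        if not pairable(seq[i], seq[j]):
            raise ValueError(f"non-pairable {(i, j)}: {seq[i]}-{seq[j]}")
        partner[i], partner[j] = j, i
    if len(partner) != 2 * len(pairs):
        raise ValueError("base in more than one pair")
    for (i, j) in pairs:
        for (k, l) in pairs:
            if i < k < j < l:
                raise ValueError(f"crossing pairs {(i, j)}, {(k, l)}")

    def children(i: int, j: int) -> tuple[list[tuple[int, int]], int]:
        kids, unpaired, k = [], 0, i + 1
        while k < j:
            if k in partner:
                kids.append((k, partner[k]))
                k = partner[k] + 1
            else:
                unpaired += 1
                k += 1
        return kids, unpaired

    total = 0.0
    for (i, j) in pairs:
        kids, unpaired = children(i, j)
        if not kids:
            if unpaired < model.min_hairpin_unpaired:
                raise ValueError(f"hairpin loop of {unpaired} < minimum")
            total += model.hairpin_loop(unpaired)
        elif len(kids) == 1:
            (k, l) = kids[0]
            l1, l2 = k - i - 1, j - l - 1
            if l1 == 0 and l2 == 0:
                e = model.stack(seq[i] + seq[j], seq[k] + seq[l])
                if e is None:
                    raise ValueError("unknown stack")
                total += e
            else:
                if max(l1, l2) > model.max_loop:
                    raise ValueError("interior loop beyond model cap")
                total += model.internal_or_bulge(l1, l2)
        else:
            total += (
                model.multiloop_offset
                + model.multiloop_branch * (len(kids) + 1)
                + model.multiloop_unpaired * unpaired
            )
    return total


def fold_hairpin(sequence: str, model: EnergyModel = DEFAULT_MODEL) -> HairpinFold:
    """MFE fold over nested structures; returns the open chain (energy 0) when
    no structure scores below zero."""
    seq = check_rna(sequence)
    n = len(seq)
    if n > MAX_FOLD_LENGTH:
        raise ValueError(f"sequence length {n} exceeds {MAX_FOLD_LENGTH}")
    if n == 0:
        return HairpinFold("", "", 0.0)
    m = model
    h = m.min_hairpin_unpaired

    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    can_pair = [
        [j > i and pairable(seq[i], seq[j]) for j in range(n)] for i in range(n)
    ]

    for span in range(h + 1, n):
        for i in range(0, n - span):
            j = i + span
            if can_pair[i][j]:
                best = m.hairpin_loop(j - i - 1)
                # stack / interior loops
                for k in range(i + 1, min(i + m.max_loop + 1, j) + 1):
                    if k >= j:
                        break
                    l1 = k - i - 1
                    for l in range(max(k + h + 1, j - m.max_loop - 1), j):
                        if V[k, l] == INF or not can_pair[k][l]:
                            continue
                        l2 = j - l - 1
                        if l1 == 0 and l2 == 0:
                            e = m.stack(seq[i] + seq[j], seq[k] + seq[l])
                            if e is not None:
                                best = min(best, e + V[k, l])
                        else:
                            best = min(best, m.internal_or_bulge(l1, l2) + V[k, l])
                # multiloop: closing pair + >=2 branches inside
                for k in range(i + 2, j - 1):
                    if WM[i + 1, k - 1] < INF and WM[k, j - 1] < INF:
                        best = min(
                            best,
                            m.multiloop_offset
                            + m.multiloop_branch
                            + WM[i + 1, k - 1]
                            + WM[k, j - 1],
                        )
                V[i, j] = best
            # WM
            wm = INF
            if V[i, j] < INF:
                wm = V[i, j] + m.multiloop_branch
            # INF + c stays INF, so unreachable states propagate safely
            wm = min(wm, WM[i + 1, j] + m.multiloop_unpaired)
            wm = min(wm, WM[i, j - 1] + m.multiloop_unpaired)
            for k in range(i + 1, j + 1):
                if WM[i, k - 1] < INF and WM[k, j] < INF:
                    wm = min(wm, WM[i, k - 1] + WM[k, j])
            WM[i, j] = wm

    W = np.zeros(n)
    choice_feasible = V < INF
    for j in range(n):
        best = W[j - 1] if j > 0 else 0.0
        for i in range(0, j):
            if choice_feasible[i][j]:
                left = W[i - 1] if i > 0 else 0.0
                best = min(best, left + V[i, j])
        if j >= 1 and choice_feasible[0][j]:
            best = min(best, V[0, j])
        W[j] = best

    mfe = min(0.0, float(W[n - 1]))
    pairs = _traceback(seq, V, WM, W, m) if mfe < 0 else []
    structure = ["."] * n
    for i, j in pairs:
        structure[i], structure[j] = "(", ")"
    # the traceback must rescore to the DP optimum
    if pairs:
        assert abs(structure_energy(seq, pairs, m) - mfe) < 1e-6
    return HairpinFold(seq, "".join(structure), mfe)


def _traceback(seq, V, WM, W, m) -> list[tuple[int, int]]:
    n = len(seq)
    h = m.min_hairpin_unpaired
    pairs: list[tuple[int, int]] = []
    stack: list[tuple[str, int, int]] = [("W", 0, n - 1)]
    while stack:
        kind, i, j = stack.pop()
        if kind == "W":
            if j < 0:
                continue
            # prefer the 5'-most pairing that achieves W[j]
            done = False
            for a in range(0, j):
                left = W[a - 1] if a > 0 else 0.0
                if V[a, j] < INF and abs(left + V[a, j] - W[j]) < _EPS:
                    pairs.append((a, j))
                    stack.append(("V", a, j))
                    if a > 0:
                        stack.append(("W", 0, a - 1))
                    done = True
                    break
            if not done and V[0, j] < INF and abs(V[0, j] - W[j]) < _EPS and j >= 1:
                pairs.append((0, j))
                stack.append(("V", 0, j))
                done = True
            if not done:
                stack.append(("W", 0, j - 1))
        elif kind == "V":
            target = V[i, j]
            # 1) stack
            if (
                i + 1 < j - 1
                and V[i + 1, j - 1] < INF
                and m.stack(seq[i] + seq[j], seq[i + 1] + seq[j - 1]) is not None
                and abs(m.stack(seq[i] + seq[j], seq[i + 1] + seq[j - 1]) + V[i + 1, j - 1] - target) < _EPS
            ):
                pairs.append((i + 1, j - 1))
                stack.append(("V", i + 1, j - 1))
                continue
            # 2) interior loop / bulge, 5'-most inner pair
            found = False
            for k in range(i + 1, min(i + m.max_loop + 1, j - 1) + 1):
                l1 = k - i - 1
                for l in range(j - 1, max(k + h, j - m.max_loop - 2), -1):
                    if l <= k or V[k, l] == INF:
                        continue
                    l2 = j - l - 1
                    if l1 == 0 and l2 == 0:
                        continue
                    if abs(m.internal_or_bulge(l1, l2) + V[k, l] - target) < _EPS:
                        pairs.append((k, l))
                        stack.append(("V", k, l))
                        found = True
                        break
                if found:
                    break
            if found:
                continue
            # 3) multiloop
            for k in range(i + 2, j - 1):
                if (
                    WM[i + 1, k - 1] < INF
                    and WM[k, j - 1] < INF
                    and abs(
                        m.multiloop_offset
                        + m.multiloop_branch
                        + WM[i + 1, k - 1]
                        + WM[k, j - 1]
                        - target
                    )
                    < _EPS
                ):
                    stack.append(("WM", i + 1, k - 1))
                    stack.append(("WM", k, j - 1))
                    found = True
                    break
            if found:
                continue
            # 4) hairpin loop: nothing more to trace
            assert abs(m.hairpin_loop(j - i - 1) - target) < _EPS
        else:  # WM
            target = WM[i, j]
            if V[i, j] < INF and abs(V[i, j] + m.multiloop_branch - target) < _EPS:
                pairs.append((i, j))
                stack.append(("V", i, j))
                continue
            done = False
            for k in range(i + 1, j + 1):
                if (
                    WM[i, k - 1] < INF
                    and WM[k, j] < INF
                    and abs(WM[i, k - 1] + WM[k, j] - target) < _EPS
                ):
                    stack.append(("WM", i, k - 1))
                    stack.append(("WM", k, j))
                    done = True
                    break
            if done:
                continue
            if WM[i + 1, j] < INF and abs(WM[i + 1, j] + m.multiloop_unpaired - target) < _EPS:
                stack.append(("WM", i + 1, j))
                continue
            assert WM[i, j - 1] < INF and abs(
                WM[i, j - 1] + m.multiloop_unpaired - target
            ) < _EPS
            stack.append(("WM", i, j - 1))
    return sorted(pairs)


def hairpin_delta_mfe(fold_major: HairpinFold | float, fold_minor: HairpinFold | float) -> float:
    """Stability change caused by the minor allele: MFE(minor) - MFE(major).
    Positive values mean the minor allele destabilizes the precursor."""
    major = fold_major.mfe if isinstance(fold_major, HairpinFold) else float(fold_major)
    minor = fold_minor.mfe if isinstance(fold_minor, HairpinFold) else float(fold_minor)
    return minor - major
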