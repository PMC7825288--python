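"""Intermolecular miRNA:target duplex minimum free energy.

RNAhybrid-style hybridization: the miRNA (5'->3') pairs antiparallel against a
window of the target, with stacked pairs, bulges and internal loops (capped at
``model.duplex_max_loop_side`` unpaired bases per side) and a single helix
initiation penalty. Intramolecular pairs are not allowed. The dynamic program
is exact over all hybrids under this grammar and is minimized over every
target window in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..seq import check_rna
from .params import DEFAULT_MODEL, EnergyModel

INF = float("inf")
_EPS = 1e-9

MAX_MIRNA_LENGTH = 30

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_PAIRS = ["AU", "UA", "CG", "GC", "GU", "UG"]
_PAIR_INDEX = {p: i for i, p in enumerate(_PAIRS)}


@dataclass(frozen=True)
class DuplexHit:
    """Best hybrid of one miRNA allele against one transcript's 3'UTR."""

    mirna: str
    target: str
    mfe: float  # kcal/mol
    target_window: tuple[int, int]  # 0-based half-open on the 5'->3' target
    pairing: str
    p_value: float | None = None
    significant: bool | None = None


def _pair_codes(mirna: str, rtarget: str) -> np.ndarray:
    """(M, N) matrix of pair indices (-1 where the bases cannot pair)."""
    table = np.full((4, 4), -1, dtype=np.int8)
    for p, idx in _PAIR_INDEX.items():
        table[_BASE_CODE[p[0]], _BASE_CODE[p[1]]] = idx
    mi = np.array([_BASE_CODE[b] for b in mirna])
    ti = np.array([_BASE_CODE[b] for b in rtarget])
    return table[mi[:, None], ti[None, :]]


def _stack_table(model: EnergyModel) -> np.ndarray:
    s = np.full((6, 6), INF)
    for (p1, p2), e in model.stack_energies.items():
        s[_PAIR_INDEX[p1], _PAIR_INDEX[p2]] = e
    return s


def _loop_costs(model: EnergyModel) -> np.ndarray:
    """cost[di, dj] of stepping from pair (i-di, k-dj) to (i, k), excluding the
    stack step (1, 1); index 0 is unused."""
    cap = model.duplex_max_loop_side + 1
    c = np.full((cap + 1, cap + 1), INF)
    for di in range(1, cap + 1):
        for dj in range(1, cap + 1):
            if di == 1 and dj == 1:
                continue
            c[di, dj] = model.internal_or_bulge(di - 1, dj - 1)
    return c


def duplex_mfe(
    mirna_seq: str,
    target_seq: str,
    model: EnergyModel = DEFAULT_MODEL,
    mirna_id: str = "mirna",
    target_id: str = "target",
) -> DuplexHit | None:
    """Best intermolecular hybrid, or None when no hybrid scores below zero."""
    mirna = check_rna(mirna_seq)
    target = check_rna(target_seq)
    if not mirna or not target:
        raise ValueError("empty sequence")
    if len(mirna) > MAX_MIRNA_LENGTH:
        raise ValueError(f"miRNA longer than {MAX_MIRNA_LENGTH} nt")
    mlen, nlen = len(mirna), len(target)
    rtarget = target[::-1]  # both strands now run 5'->3' in index order
    pid = _pair_codes(mirna, rtarget)
    stab = _stack_table(model)
    loop = _loop_costs(model)
    cap = model.duplex_max_loop_side + 1

    h = np.full((mlen, nlen), INF)
    for i in range(mlen):
        ok = pid[i] >= 0
        cand = np.full(nlen, INF)
        cand[ok] = model.duplex_init
        if i > 0:
            # stack step from (i-1, k-1)
            prev_ok = (pid[i - 1, :-1] >= 0) & ok[1:]
            if prev_ok.any():
                se = np.full(nlen - 1, INF)
                se[prev_ok] = stab[pid[i - 1, :-1][prev_ok], pid[i, 1:][prev_ok]]
                cand[1:] = np.minimum(cand[1:], h[i - 1, :-1] + se)
            # bulge / internal-loop steps
            for di in range(1, min(i, cap) + 1):
                prev = h[i - di]
                for dj in range(1, cap + 1):
                    if dj >= nlen:
                        break
                    c = loop[di, dj]
                    if c == INF:
                        continue
                    cand[dj:] = np.minimum(cand[dj:], prev[:-dj] + c)
        cand[~ok] = INF
        h[i] = cand

    best = float(h.min(initial=INF))
    if not best < 0.0:
        return None
    i, k = np.unravel_index(int(h.argmin()), h.shape)
    pairs = _traceback(h, int(i), int(k), pid, stab, loop, model)
    t_positions = [nlen - 1 - k for _, k in pairs]
    window = (min(t_positions), max(t_positions) + 1)
    return DuplexHit(
        mirna=mirna_id,
        target=target_id,
        mfe=best,
        target_window=window,
        pairing=_pairing_string(mirna, rtarget, pairs, nlen),
    )


def _traceback(h, i, k, pid, stab, loop, model) -> list[tuple[int, int]]:
    """Walk predecessors from the best end pair; deterministic (stack step
    first, then loop steps by ascending side lengths)."""
    cap = model.duplex_max_loop_side + 1
    pairs = [(i, k)]
    while True:
        target = h[i, k]
        if abs(target - model.duplex_init) < _EPS:
            break
        moved = False
        if i > 0 and k > 0 and pid[i - 1, k - 1] >= 0:
            se = stab[pid[i - 1, k - 1], pid[i, k]]
            if se < INF and abs(h[i - 1, k - 1] + se - target) < _EPS:
                i, k = i - 1, k - 1
                pairs.append((i, k))
                moved = True
        if not moved:
            for di in range(1, min(i, cap) + 1):
                for dj in range(1, min(k, cap) + 1):
                    c = loop[di, dj]
                    if c < INF and abs(h[i - di, k - dj] + c - target) < _EPS:
                        i, k = i - di, k - dj
                        pairs.append((i, k))
                        moved = True
                        break
                if moved:
                    break
        if not moved:  # pragma: no cover - would indicate a DP/traceback bug
            raise AssertionError("duplex traceback failed")
    return sorted(pairs)


def _pairing_string(mirna, rtarget, pairs, nlen) -> str:
    """Three-line hybrid sketch: miRNA 5'->3' on top, target 3'->5' below."""
    top, mid, bot = [], [], []
    (i0, k0) = pairs[0]
    pi, pk = i0 - 1, k0 - 1
    for (i, k) in pairs:
        gi, gk = i - pi - 1, k - pk - 1
        span = max(gi, gk)
        top.append(mirna[pi + 1 : i].rjust(span, "-"))
        bot.append(rtarget[pk + 1 : k].rjust(span, "-"))
        mid.append(" " * span)
        top.append(mirna[i])
        bot.append(rtarget[k])
        mid.append("|")
        pi, pk = i, k
    return (
        f"miRNA  5' {''.join(top)} 3'\n"
        f"          {''.join(mid)}\n"
        f"target 3' {''.join(bot)} 5'"
    )
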