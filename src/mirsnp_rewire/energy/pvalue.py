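"""Shuffle-calibrated significance of duplex energies.

The score of a miRNA against one target is s = -MFE of the best hybrid. Under
the null, extreme-value theory motivates a Gumbel law for s; location and scale
are estimated by refolding the miRNA against dinucleotide-shuffled versions of
the *same* target (Altschul-Erickson shuffle, preserving mono- and
dinucleotide composition and hence both length and stacking propensity). The
p-value of an observed MFE is the fitted Gumbel upper tail at -MFE. Because
every shuffle has the target's own length, no length normalization is needed.

A site is called when MFE <= -15 kcal/mol AND p < 0.05 (both configurable).
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
from scipy import stats

from ..seq import check_rna
from .duplex import DuplexHit, duplex_mfe
from .params import DEFAULT_MODEL, EnergyModel

MFE_THRESHOLD = -15.0
P_THRESHOLD = 0.05


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle: a uniform random sequence with exactly the
    same dinucleotide (and hence mononucleotide) counts as ``seq``."""
    seq = check_rna(seq)
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    first, last = seq[0], seq[-1]
    vertices = [v for v in edges if v != last]

    for _ in range(10000):
        # pick a candidate terminal edge for every non-final vertex, then keep
        # the pick only if those edges form an arborescence into `last`
        pick = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        ok = True
        for v in vertices:
            seen, cur = {v}, v
            while cur != last:
                cur = pick.get(cur)
                if cur is None or cur in seen or (cur != last and cur not in edges):
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover
        raise RuntimeError("dinucleotide shuffle failed to find an Eulerian order")

    ordered: dict[str, list[str]] = {}
    for v, lst in edges.items():
        rest = list(lst)
        if v in pick:
            rest.remove(pick[v])
        rng.shuffle(rest)
        ordered[v] = rest + ([pick[v]] if v in pick else [])

    out, cur = [first], first
    counts = defaultdict(int)
    for _ in range(len(seq) - 1):
        nxt = ordered[cur][counts[cur]]
        counts[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def _score(mirna_seq: str, target_seq: str, model: EnergyModel) -> float:
    hit = duplex_mfe(mirna_seq, target_seq, model)
    return -hit.mfe if hit is not None else 0.0


def calibrate_pvalue(
    mirna_seq: str,
    target_seq: str,
    model: EnergyModel = DEFAULT_MODEL,
    n_shuffles: int = 200,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Fit (location, scale) of the null Gumbel for this miRNA/target pair."""
    if n_shuffles < 50:
        raise ValueError("need at least 50 shuffles for a stable Gumbel fit")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    scores = np.array(
        [
            _score(mirna_seq, dinucleotide_shuffle(target_seq, rng), model)
            for _ in range(n_shuffles)
        ]
    )
    if np.ptp(scores) == 0:
        raise ValueError("degenerate shuffle score distribution (all equal)")
    loc, scale = stats.gumbel_r.fit(scores)
    return float(loc), float(scale)


def gumbel_pvalue(mfe: float, loc: float, scale: float) -> float:
    """Upper-tail probability of a score at least as extreme as -mfe."""
    return float(stats.gumbel_r.sf(-mfe, loc, scale))


def score_hit(
    hit: DuplexHit,
    loc: float,
    scale: float,
    mfe_threshold: float = MFE_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> DuplexHit:
    """Attach the calibrated p-value and significance flag to a hit."""
    p = gumbel_pvalue(hit.mfe, loc, scale)
    return DuplexHit(
        mirna=hit.mirna,
        target=hit.target,
        mfe=hit.mfe,
        target_window=hit.target_window,
        pairing=hit.pairing,
        p_value=p,
        significant=call_site(hit.mfe, p, mfe_threshold, p_threshold),
    )


def call_site(
    mfe: float,
    p_value: float,
    mfe_threshold: float = MFE_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> bool:
    """Site call: energy at or below the threshold AND p strictly below its."""
    return mfe <= mfe_threshold and p_value < p_threshold
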