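"""Allele-specific target rewiring: delta-MFE, gain/loss classes, consistency.

For each (miR-SNP, transcript) the duplex energies of the two alleles are
compared:

    delta_MFE = MFE(major) - MFE(minor)

so positive values mean the minor allele binds the target *more* stably. The
four-way classification uses the per-allele site calls:

    complete_gain  site for minor only
    complete_loss  site for major only
    partial_gain   sites for both, delta_MFE > 0
    partial_loss   sites for both, delta_MFE < 0
    none           no site for either allele (or an exact energy tie)

A transcript is nominated as a target only when its expression (mRNA or
protein) effect of the minor allele is significant and points the way the
energetics predict: more stable binding (positive delta_MFE, or a gained site)
must repress, less stable binding must de-repress.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .energy.duplex import DuplexHit

log = logging.getLogger(__name__)

CLASSES = ("complete_gain", "complete_loss", "partial_gain", "partial_loss", "none")


@dataclass(frozen=True)
class RewiringCall:
    mirsnp: str
    transcript: str
    expression_layer: str  # {mRNA, protein}
    mfe_major: float | None
    mfe_minor: float | None
    sig_major: bool
    sig_minor: bool
    delta_mfe: float | None
    rewiring_class: str
    expression_beta: float
    expression_p: float
    expression_significant: bool
    consistent: bool
    is_target: bool


def delta_mfe(mfe_major: float | None, mfe_minor: float | None) -> float | None:
    """MFE_major - MFE_minor; None when either allele has no hybrid at all."""
    if mfe_major is None or mfe_minor is None:
        return None
    return mfe_major - mfe_minor


def classify_rewiring(
    sig_major: bool, sig_minor: bool, delta: float | None
) -> str:
    """Four-way gain/loss class from the per-allele site calls."""
    if sig_minor and not sig_major:
        return "complete_gain"
    if sig_major and not sig_minor:
        return "complete_loss"
    if sig_major and sig_minor:
        if delta is None:
            raise ValueError("both sites called but delta_mfe undefined")
        if delta > 0:
            return "partial_gain"
        if delta < 0:
            return "partial_loss"
        log.info("delta_mfe == 0 with two called sites: no rewiring assigned")
        return "none"
    return "none"


def consistency_filter(
    rewiring_class: str,
    delta: float | None,
    expression_beta: float,
    expression_significant: bool,
) -> tuple[bool, bool]:
    """(consistent, is_target) for one classified pair.

    Stronger binding with the minor allele (gained site or positive delta_MFE)
    is consistent with *decreased* expression (beta < 0); weaker binding with
    *increased* expression (beta > 0). beta == 0 is never consistent.
    """
    if rewiring_class == "none":
        raise ValueError("consistency is undefined for class 'none'")
    if rewiring_class == "complete_gain":
        consistent = expression_beta < 0
    elif rewiring_class == "complete_loss":
        consistent = expression_beta > 0
    else:
        if delta is None or delta == 0:
            raise ValueError("partial class requires a nonzero delta_mfe")
        consistent = (expression_beta < 0) if delta > 0 else (expression_beta > 0)
    return consistent, consistent and expression_significant


def rewire_all(
    hits: Mapping[tuple[str, str, str], DuplexHit | None],
    assoc: pd.DataFrame,
    layers: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Combine allele-specific duplex hits with expression associations.

    ``hits`` maps (mirsnp, transcript, allele in {major, minor}) to the scored
    DuplexHit (or None for no hybrid); ``assoc`` is the association table with
    columns snp, phenotype, beta, p, significant; ``layers`` maps phenotype
    name -> {mRNA, protein} (default: everything mRNA). One row is produced
    per (mirsnp, transcript, layer) present in both inputs.
    """
    layers = dict(layers or {})
    pair_keys = sorted({(s, t) for (s, t, _a) in hits})
    missing = [
        (s, t, a)
        for (s, t) in pair_keys
        for a in ("major", "minor")
        if (s, t, a) not in hits
    ]
    if missing:
        raise ValueError(f"missing allele scans for {missing}")

    assoc_idx = assoc.set_index(["snp", "phenotype"])
    rows = []
    for snp, transcript in pair_keys:
        if (snp, transcript) not in assoc_idx.index:
            continue
        arow = assoc_idx.loc[(snp, transcript)]
        layer = layers.get(transcript, "mRNA")
        hmaj, hmin = hits[(snp, transcript, "major")], hits[(snp, transcript, "minor")]
        mfe_major = hmaj.mfe if hmaj is not None else None
        mfe_minor = hmin.mfe if hmin is not None else None
        sig_major = bool(hmaj.significant) if hmaj is not None else False
        sig_minor = bool(hmin.significant) if hmin is not None else False
        delta = delta_mfe(mfe_major, mfe_minor)
        cls = classify_rewiring(sig_major, sig_minor, delta)
        beta = float(arow["beta"])
        p = float(arow["p"])
        sig_expr = bool(arow["significant"])
        if cls == "none":
            consistent = is_target = False
        else:
            consistent, is_target = consistency_filter(cls, delta, beta, sig_expr)
        rows.append(
            RewiringCall(
                mirsnp=snp,
                transcript=transcript,
                expression_layer=layer,
                mfe_major=mfe_major,
                mfe_minor=mfe_minor,
                sig_major=sig_major,
                sig_minor=sig_minor,
                delta_mfe=delta,
                rewiring_class=cls,
                expression_beta=beta,
                expression_p=p,
                expression_significant=sig_expr,
                consistent=consistent,
                is_target=is_target,
            )
        )
    return pd.DataFrame(
        [vars(r) for r in rows],
        columns=[
            "mirsnp", "transcript", "expression_layer", "mfe_major", "mfe_minor",
            "sig_major", "sig_minor", "delta_mfe", "rewiring_class",
            "expression_beta", "expression_p", "expression_significant",
            "consistent", "is_target",
        ],
    )


def class_summary(calls: pd.DataFrame) -> dict:
    counts = calls["rewiring_class"].value_counts().to_dict()
    return {
        "per_class": {c: int(counts.get(c, 0)) for c in CLASSES},
        "n_targets": int(calls["is_target"].sum()),
    }


def write_summary(path: str | Path, calls: pd.DataFrame) -> None:
    Path(path).write_text(json.dumps(class_summary(calls), indent=2) + "\n")
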