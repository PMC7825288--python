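"""3'UTR simulation with planted allele-specific miRNA sites.

Two site designs are used downstream:

* a *full* site — the exact reverse complement of one allele's mature sequence —
  hybridizes strongly with both alleles (the other allele sees one internal
  mismatch), which is the substrate for the *partial* gain/loss classes;
* a *half* site — the reverse complement of a short SNP-centred window — stays
  below the site-calling energy threshold for the non-matching allele, which is
  the substrate for the *complete* gain/loss classes.

Background sequence is drawn uniformly and rejected while it contains a
complementary run of >= 6 nt to any sequence in ``avoid``, so planted sites are
the only callable ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..seq import RNA_BASES, check_rna, revcomp_rna


@dataclass(frozen=True)
class PlantedSiteSpec:
    target_allele: str = "minor"  # {major, minor}
    site_kind: str = "perfect_seed_match"  # {perfect_seed_match, partial_match, none}
    utr_length: int = 200

    def __post_init__(self) -> None:
        if self.target_allele not in ("major", "minor"):
            raise ValueError(f"bad target_allele {self.target_allele!r}")
        if self.site_kind not in ("perfect_seed_match", "partial_match", "none"):
            raise ValueError(f"bad site_kind {self.site_kind!r}")
        if self.utr_length < 1:
            raise ValueError("utr_length must be positive")


def _has_complementary_run(utr: str, mirna: str, k: int = 6) -> bool:
    """True if any k-mer of the UTR is the exact reverse complement of a
    k-mer of the miRNA."""
    rc = revcomp_rna(mirna)
    kmers = {rc[i : i + k] for i in range(len(rc) - k + 1)}
    return any(utr[i : i + k] in kmers for i in range(len(utr) - k + 1))


def random_clean_utr(
    length: int, avoid: tuple[str, ...], rng: np.random.Generator, k: int = 6
) -> str:
    """Uniform random RNA of ``length`` with no >=k-nt complementary run to any
    sequence in ``avoid``. Rejection sampling on 40-nt blocks keeps acceptance
    practical for long UTRs."""
    block = 40
    out: list[str] = []
    ctx = ""
    while sum(map(len, out)) < length:
        for _ in range(1000):
            cand = "".join(rng.choice(list(RNA_BASES), size=block))
            probe = ctx + cand
            if not any(_has_complementary_run(probe, m, k) for m in avoid):
                out.append(cand)
                ctx = cand[-(k - 1) :]
                break
        else:  # pragma: no cover - astronomically unlikely for k=6
            raise RuntimeError("rejection sampling failed to produce a clean UTR")
    return "".join(out)[:length]


def make_site(mirna_allele_seq: str, kind: str, window: int = 12) -> str:
    """Target-site sequence for one allele.

    ``perfect_seed_match`` -> reverse complement of the whole mature sequence;
    ``partial_match``      -> reverse complement of a central ``window``-nt
    stretch (seed-anchored half site).
    """
    mirna_allele_seq = check_rna(mirna_allele_seq)
    if kind == "perfect_seed_match":
        return revcomp_rna(mirna_allele_seq)
    if kind == "partial_match":
        n = len(mirna_allele_seq)
        lo = max(0, min(n - window, n // 2 - window // 2))
        return revcomp_rna(mirna_allele_seq[lo : lo + window])
    raise ValueError(f"no site for kind {kind!r}")


def simulate_utr_with_site(
    mirna_allele_seq: str,
    spec: PlantedSiteSpec,
    rng: np.random.Generator,
    avoid: tuple[str, ...] = (),
) -> str:
    """Generate a 3'UTR; for site kinds other than ``none`` the site for the
    given allele is embedded at the centre of an otherwise clean background."""
    mirna_allele_seq = check_rna(mirna_allele_seq)
    avoid = tuple(avoid) or (mirna_allele_seq,)
    if spec.site_kind == "none":
        return random_clean_utr(spec.utr_length, avoid, rng)
    site = make_site(mirna_allele_seq, spec.site_kind)
    if spec.utr_length < len(site):
        raise ValueError("utr_length shorter than the planted site")
    bg = random_clean_utr(spec.utr_length, avoid, rng)
    mid = (spec.utr_length - len(site)) // 2
    return bg[:mid] + site + bg[mid + len(site) :]
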