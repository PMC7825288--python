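"""Small sequence helpers shared across modules (RNA alphabet A/C/G/U)."""

from __future__ import annotations

RNA_BASES = "ACGU"
_COMP_RNA = str.maketrans("ACGU", "UGCA")
_COMP_DNA = str.maketrans("ACGT", "TGCA")

#: canonical pairs recognized by the energy model (Watson-Crick + G.U wobble)
PAIRABLE = frozenset(
    ["AU", "UA", "CG", "GC", "GU", "UG"]
)


def dna_to_rna(s: str) -> str:
    return s.upper().replace("T", "U")


def rna_to_dna(s: str) -> str:
    return s.upper().replace("U", "T")


def revcomp_rna(s: str) -> str:
    return s.upper().translate(_COMP_RNA)[::-1]


def revcomp_dna(s: str) -> str:
    return s.upper().translate(_COMP_DNA)[::-1]


def check_rna(s: str) -> str:
    s = s.upper()
    bad = set(s) - set(RNA_BASES)
    if bad:
        raise ValueError(f"non-RNA characters {sorted(bad)} in sequence")
    return s


def pairable(a: str, b: str) -> bool:
    return a + b in PAIRABLE
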