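"""Nearest-neighbor free-energy parameters (kcal/mol, 37 C).

Watson-Crick / Watson-Crick stack values are the standard Turner-2004
nearest-neighbor set; G.U wobble entries are compiled values from the same
family of tables. Loop costs are affine simplifications (initiation + slope per
unpaired nucleotide); multiloops are linear in branches and unpaired bases.
Exact agreement with RNAfold/RNAhybrid outputs is a non-goal — the model's
contracts are internal consistency (strand-reading symmetry, enforced below)
and correct ordering of structures under the same rules as the test oracles.

A stack is keyed (pair1, pair2) where pair1 = (seq[i], seq[j]) closes the stack
on the 5' side and pair2 = (seq[i+1], seq[j-1]) sits on top of it. Reading the
helix from the other strand maps (p1, p2) -> (rev(p2), rev(p1)) and must give
the same energy; the table is built from one representative per such class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# one representative per symmetry class ------------------------------------
_STACK_REPRESENTATIVES: dict[tuple[str, str], float] = {
    # Watson-Crick on Watson-Crick (Turner 2004)
    ("AU", "AU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CG", "UA"): -2.08,
    ("CG", "AU"): -2.11,
    ("GC", "UA"): -2.24,
    ("GC", "AU"): -2.35,
    ("CG", "GC"): -2.36,
    ("GC", "GC"): -3.26,
    ("GC", "CG"): -3.42,
    # stacks involving one or two G.U wobbles
    ("AU", "GU"): -0.55,
    ("AU", "UG"): -1.36,
    ("CG", "GU"): -1.41,
    ("CG", "UG"): -2.11,
    ("GC", "GU"): -1.53,
    ("GC", "UG"): -2.51,
    ("UA", "GU"): -1.00,
    ("UA", "UG"): -1.22,
    ("GU", "GU"): 0.47,
    ("GU", "UG"): -0.50,
    ("UG", "GU"): 0.30,
}


def _close_symmetry(base: dict[tuple[str, str], float]) -> dict[tuple[str, str], float]:
    full: dict[tuple[str, str], float] = {}
    for (p1, p2), e in base.items():
        partner = (p2[::-1], p1[::-1])
        for key in ((p1, p2), partner):
            if key in full and abs(full[key] - e) > 1e-9:
                raise ValueError(f"inconsistent stack table at {key}")
            full[key] = e
    return full


STACK_ENERGIES = _close_symmetry(_STACK_REPRESENTATIVES)


@dataclass(frozen=True)
class EnergyModel:
    """Tunable energy model shared by the hairpin and duplex dynamic programs."""

    stack_energies: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(STACK_ENERGIES)
    )
    # affine loop costs: cost = init + slope * (unpaired length beyond minimum)
    hairpin_init: float = 5.4
    hairpin_slope: float = 0.25
    bulge_init: float = 3.8
    bulge_slope: float = 0.30
    internal_init: float = 2.0
    internal_slope: float = 0.40
    internal_asymmetry: float = 0.30
    # multiloop: offset + per-branch (incl. closing pair) + per-unpaired
    multiloop_offset: float = 3.4
    multiloop_branch: float = 0.40
    multiloop_unpaired: float = 0.10
    min_hairpin_unpaired: int = 3
    max_loop: int = 30  # per-side cap inside hairpin interior loops
    # intermolecular terms (duplex DP)
    duplex_init: float = 4.09
    duplex_max_loop_side: int = 15

    def stack(self, pair1: str, pair2: str) -> float | None:
        return self.stack_energies.get((pair1, pair2))

    def hairpin_loop(self, n_unpaired: int) -> float:
        assert n_unpaired >= self.min_hairpin_unpaired
        return self.hairpin_init + self.hairpin_slope * (
            n_unpaired - self.min_hairpin_unpaired
        )

    def internal_or_bulge(self, l1: int, l2: int) -> float:
        """Cost of an interior loop with l1/l2 unpaired bases on the two sides
        (l1 + l2 >= 1; a side of 0 makes it a bulge)."""
        if min(l1, l2) == 0:
            return self.bulge_init + self.bulge_slope * (max(l1, l2) - 1)
        return (
            self.internal_init
            + self.internal_slope * (l1 + l2 - 2)
            + self.internal_asymmetry * abs(l1 - l2)
        )


DEFAULT_MODEL = EnergyModel()
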