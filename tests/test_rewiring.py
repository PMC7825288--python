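import itertools

import pandas as pd
import pytest

from mirsnp_rewire.energy.duplex import DuplexHit
from mirsnp_rewire.rewiring import (
    CLASSES,
    classify_rewiring,
    consistency_filter,
    delta_mfe,
    rewire_all,
)


class TestDeltaMfe:
    def test_partial_gain_example(self):
        """Energies one allele apart reproduce the +1.8 kcal/mol shift that
        nominated a repressed target."""
        assert delta_mfe(-20.0, -21.8) == pytest.approx(1.8)

    def test_equal_energies_give_zero(self):
        assert delta_mfe(-17.0, -17.0) == 0.0

    def test_antisymmetric_under_allele_swap(self):
        assert delta_mfe(-20.0, -24.0) == -delta_mfe(-24.0, -20.0)

    def test_missing_energy_propagates_none(self):
        assert delta_mfe(None, -20.0) is None
        assert delta_mfe(-20.0, None) is None


class TestClassify:
    def test_gain_when_only_minor_has_site(self):
        assert classify_rewiring(False, True, 3.0) == "complete_gain"

    def test_loss_when_only_major_has_site(self):
        assert classify_rewiring(True, False, -2.0) == "complete_loss"

    def test_partial_classes_follow_delta_sign(self):
        assert classify_rewiring(True, True, 1.8) == "partial_gain"
        assert classify_rewiring(True, True, -1.8) == "partial_loss"

    def test_exhaustive_truth_table(self):
        """Every (site flags, delta sign) combination maps to exactly the
        documented class."""
        expected = {
            (False, False): "none",
            (False, True): "complete_gain",
            (True, False): "complete_loss",
        }
        for sm, sn, d in itertools.product([False, True], [False, True], [-1.0, 0.0, 1.0]):
            got = classify_rewiring(sm, sn, d)
            if (sm, sn) in expected:
                assert got == expected[(sm, sn)]
            else:
                assert got == {1.0: "partial_gain", -1.0: "partial_loss", 0.0: "none"}[d]
            assert got in CLASSES


class TestConsistency:
    def test_partial_gain_with_repression_is_target(self):
        consistent, is_target = consistency_filter("partial_gain", 1.8, -8.5, True)
        assert consistent and is_target

    def test_complete_loss_with_derepression_is_target(self):
        consistent, is_target = consistency_filter("complete_loss", -6.0, 0.9, True)
        assert consistent and is_target

    def test_partial_gain_with_wrong_sign_rejected(self):
        consistent, is_target = consistency_filter("partial_gain", 1.8, 8.5, True)
        assert not consistent and not is_target

    def test_consistent_but_insignificant_is_not_target(self):
        consistent, is_target = consistency_filter("complete_gain", None, -1.0, False)
        assert consistent and not is_target

    def test_zero_beta_is_inconsistent(self):
        assert consistency_filter("complete_gain", None, 0.0, True) == (False, False)

    def test_class_none_rejected(self):
        with pytest.raises(ValueError):
            consistency_filter("none", 0.0, 1.0, True)

    def test_allele_swap_metamorphic(self):
        """Relabelling major<->minor flips gain<->loss, negates both delta and
        beta, and preserves the verdicts."""
        cases = [
            ("complete_gain", None, -2.0), ("complete_loss", None, 1.5),
            ("partial_gain", 1.8, -8.5), ("partial_loss", -2.2, 3.0),
        ]
        flip = {
            "complete_gain": "complete_loss", "complete_loss": "complete_gain",
            "partial_gain": "partial_loss", "partial_loss": "partial_gain",
        }
        for cls, d, beta in cases:
            v1 = consistency_filter(cls, d, beta, True)
            v2 = consistency_filter(
                flip[cls], None if d is None else -d, -beta, True
            )
            assert v1 == v2


class TestRewireAll:
    def _hit(self, mfe, sig):
        return DuplexHit(
            mirna="m", target="t", mfe=mfe, target_window=(0, 10),
            pairing="", p_value=0.01 if sig else 0.5, significant=sig,
        )

    def _assoc(self, rows):
        return pd.DataFrame(
            rows, columns=["snp", "phenotype", "beta", "p", "significant"]
        )

    def test_planted_classes_recovered(self):
        hits = {
            ("rs1", "G_CG", "major"): None,
            ("rs1", "G_CG", "minor"): self._hit(-22.0, True),
            ("rs1", "G_CL", "major"): self._hit(-21.0, True),
            ("rs1", "G_CL", "minor"): self._hit(-14.0, False),
            ("rs1", "G_PG", "major"): self._hit(-20.0, True),
            ("rs1", "G_PG", "minor"): self._hit(-21.8, True),
            ("rs1", "G_PL", "major"): self._hit(-24.0, True),
            ("rs1", "G_PL", "minor"): self._hit(-18.0, True),
            ("rs1", "G_NONE", "major"): self._hit(-8.0, False),
            ("rs1", "G_NONE", "minor"): None,
        }
        assoc = self._assoc([
            ("rs1", "G_CG", -2.0, 1e-4, True),
            ("rs1", "G_CL", 1.5, 1e-3, True),
            ("rs1", "G_PG", -8.5, 1.17e-2, True),
            ("rs1", "G_PL", 3.0, 1e-3, True),
            ("rs1", "G_NONE", 0.4, 0.6, False),
        ])
        calls = rewire_all(hits, assoc).set_index("transcript")
        assert calls.loc["G_CG", "rewiring_class"] == "complete_gain"
        assert calls.loc["G_CL", "rewiring_class"] == "complete_loss"
        assert calls.loc["G_PG", "rewiring_class"] == "partial_gain"
        assert calls.loc["G_PL", "rewiring_class"] == "partial_loss"
        assert calls.loc["G_NONE", "rewiring_class"] == "none"
        assert calls["is_target"].sum() == 4
        assert not calls.loc["G_NONE", "is_target"]
        assert calls.loc["G_PG", "delta_mfe"] == pytest.approx(1.8)

    def test_each_pair_gets_exactly_one_class(self):
        hits = {
            ("rs1", "t1", "major"): self._hit(-20.0, True),
            ("rs1", "t1", "minor"): self._hit(-20.0, True),  # exact tie
        }
        assoc = self._assoc([("rs1", "t1", -1.0, 0.01, True)])
        calls = rewire_all(hits, assoc)
        assert len(calls) == 1
        assert calls["rewiring_class"].iloc[0] == "none"  # tie -> no rewiring

    def test_missing_allele_scan_raises(self):
        hits = {("rs1", "t1", "major"): self._hit(-20.0, True)}
        with pytest.raises(ValueError, match="missing allele"):
            rewire_all(hits, self._assoc([("rs1", "t1", -1.0, 0.01, True)]))

    def test_layers_evaluated_independently(self):
        hits = {
            ("rs1", "gene", "major"): self._hit(-20.0, True),
            ("rs1", "gene", "minor"): self._hit(-25.0, True),
        }
        assoc = self._assoc([("rs1", "gene", -3.0, 1e-3, True)])
        calls = rewire_all(hits, assoc, layers={"gene": "protein"})
        assert calls["expression_layer"].iloc[0] == "protein"
        assert calls["is_target"].iloc[0]
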