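"""Substitution-effect classification, reactivity prediction and MFI concordance."""

import numpy as np
import pytest

from allofoot.specificity import (
    EXAMPLE_EPITOPE_POSITIONS,
    EXAMPLE_EPITOPE_RESIDUES,
    EXAMPLE_HBONDED_POSITIONS,
    EXAMPLE_SUBSTITUTIONS,
    AllelePanel,
    ReactivityRules,
    classify_substitution,
    evaluate_concordance,
    epitope_variant_table,
    load_panel,
    normalize_allele_name,
    predict_reactivity,
)
from allofoot.synthetic import PanelSpec, make_allele_panel, write_panel


def _panel_from_epitope_table(extra=None):
    """Build a 100-residue panel where alleles differ only at curated
    epitope positions."""
    base = list("A" * 100)
    table = dict(EXAMPLE_EPITOPE_RESIDUES)
    if extra:
        table.update(extra)
    alleles = {}
    for name, residues in table.items():
        seq = base.copy()
        for pos, aa in residues.items():
            seq[pos - 1] = aa
        alleles[name] = "".join(seq)
    return AllelePanel(alleles, {}, first_position=1)


class TestPanelIO:
    def test_load_panel_roundtrip(self, tmp_path):
        panel, _ = make_allele_panel(PanelSpec(n_alleles=6, n_nonreactive=2,
                                               n_weakened_reactive=1, seed=3))
        fasta, mfi = tmp_path / "p.fasta", tmp_path / "p.csv"
        write_panel(panel, fasta, mfi)
        loaded = load_panel(fasta, mfi)
        assert loaded.alleles == panel.alleles
        assert loaded.mfi == pytest.approx({k: round(v, 1) for k, v in panel.mfi.items()})

    def test_hla_prefix_normalized(self, tmp_path):
        fasta = tmp_path / "p.fasta"
        fasta.write_text(">HLA-A*11:01\n" + "A" * 50 + "\n")
        mfi = tmp_path / "p.csv"
        mfi.write_text("allele,mfi\nA*11:01,15000\n")
        panel = load_panel(fasta, mfi)
        assert set(panel.alleles) == {"A*11:01"}
        assert panel.mfi["A*11:01"] == 15000
        assert normalize_allele_name(" HLA-B*73:01 ") == "B*73:01"

    def test_duplicate_allele_rejected(self, tmp_path):
        fasta = tmp_path / "p.fasta"
        fasta.write_text(">A*11:01\nAAAA\n>HLA-A*11:01\nAAAA\n")
        mfi = tmp_path / "p.csv"
        mfi.write_text("A*11:01,100\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_panel(fasta, mfi)

    def test_missing_mfi_warns_but_keeps_allele(self, tmp_path):
        fasta = tmp_path / "p.fasta"
        fasta.write_text(">A*11:01\nAAAA\n>A*02:01\nAAAA\n")
        mfi = tmp_path / "p.csv"
        mfi.write_text("allele,mfi\nA*11:01,100\n")
        with pytest.warns(UserWarning, match="without MFI"):
            panel = load_panel(fasta, mfi)
        assert "A*02:01" in panel.alleles
        assert "A*02:01" not in panel.mfi


class TestVariantTable:
    def test_a66_pair_differs_only_at_position_90(self):
        panel = _panel_from_epitope_table()
        table = epitope_variant_table(panel, "A*66:01", EXAMPLE_EPITOPE_POSITIONS)
        assert table["A*66:02"] == {90: ("D", "A")}
        assert table["A*66:01"] == {}
        assert table["A*11:01"] == {}

    def test_planted_differences_reported_exactly(self):
        panel = _panel_from_epitope_table(
            {"SYN*99:01": {14: "W", 17: "R", 19: "K", 39: "D", 90: "D"}})
        table = epitope_variant_table(panel, "A*11:01", EXAMPLE_EPITOPE_POSITIONS)
        assert table["SYN*99:01"] == {14: ("R", "W"), 19: ("E", "K")}

    def test_position_outside_sequence_rejected(self):
        panel = _panel_from_epitope_table()
        with pytest.raises(IndexError):
            epitope_variant_table(panel, "A*11:01", [90, 500])

    def test_unknown_reference_rejected(self):
        with pytest.raises(KeyError):
            epitope_variant_table(_panel_from_epitope_table(), "A*02:01", [90])


class TestSubstitutionEffects:
    @pytest.mark.parametrize("pos, ref, alt, effect, impact", [
        (90, "D", "A", "hbond_loss", "abrogating"),
        (14, "R", "W", "charge_to_hydrophobic", "abrogating"),
        (17, "R", "S", "hbond_loss", "abrogating"),
        (19, "E", "K", "charge_reversal", "weakening"),
        (39, "D", "Y", "charge_to_hydrophobic", "weakening"),
    ])
    def test_study_substitutions(self, pos, ref, alt, effect, impact):
        e = classify_substitution(pos, ref, alt, EXAMPLE_HBONDED_POSITIONS)
        assert (e.effect_class, e.predicted_impact) == (effect, impact)

    def test_curated_substitution_table_consistent(self):
        for pos, ref, alt in EXAMPLE_SUBSTITUTIONS:
            e = classify_substitution(pos, ref, alt, EXAMPLE_HBONDED_POSITIONS)
            assert e.effect_class != "none"

    def test_identity_is_none_tolerated(self):
        e = classify_substitution(55, "Q", "Q", EXAMPLE_HBONDED_POSITIONS)
        assert (e.effect_class, e.predicted_impact) == ("none", "tolerated")

    def test_substitution_off_rule_positions_tolerated(self):
        e = classify_substitution(55, "Q", "E", EXAMPLE_HBONDED_POSITIONS)
        assert e.predicted_impact == "tolerated"

    def test_nonstandard_amino_acid_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution(90, "D", "X", EXAMPLE_HBONDED_POSITIONS)

    def test_abrogating_only_at_critical_positions(self):
        rules = ReactivityRules()
        for pos in (19, 39, 55):
            for ref, alt in (("D", "A"), ("R", "S"), ("E", "K")):
                e = classify_substitution(pos, ref, alt, EXAMPLE_HBONDED_POSITIONS | {pos}, rules)
                assert e.predicted_impact != "abrogating" or pos in rules.critical_positions


class TestPrediction:
    def test_a66_allele_pair_split(self):
        panel = _panel_from_epitope_table()
        pred = predict_reactivity(panel, "A*11:01", EXAMPLE_EPITOPE_POSITIONS,
                                  EXAMPLE_HBONDED_POSITIONS)
        assert pred.predictions["A*66:01"] == "reactive"
        assert pred.predictions["A*66:02"] == "nonreactive"
        reasons = pred.reasons["A*66:02"]
        assert [e.position for e in reasons] == [90]
        assert reasons[0].predicted_impact == "abrogating"

    def test_identical_panel_all_reactive(self):
        panel, _ = make_allele_panel(PanelSpec(n_alleles=5, n_nonreactive=0,
                                               n_weakened_reactive=0, seed=1))
        pred = predict_reactivity(panel, "SYN*11:01", (14, 17, 19, 39, 90),
                                  EXAMPLE_HBONDED_POSITIONS)
        assert set(pred.predictions.values()) == {"reactive"}

    def test_prediction_is_pure_function_of_epitope_residues(self):
        # two alleles identical at the epitope but different elsewhere
        panel = _panel_from_epitope_table()
        seq = list(panel.alleles["A*66:02"])
        seq[62] = "W"  # off-epitope change
        panel.alleles["TWIN"] = "".join(seq)
        pred = predict_reactivity(panel, "A*11:01", EXAMPLE_EPITOPE_POSITIONS,
                                  EXAMPLE_HBONDED_POSITIONS)
        assert pred.predictions["TWIN"] == pred.predictions["A*66:02"]

    def test_adding_abrogating_substitution_never_rescues(self):
        base = {14: "R", 17: "R", 19: "K", 39: "D", 90: "A"}   # already nonreactive
        worse = {**base, 17: "S"}
        panel = _panel_from_epitope_table({"ONE": base, "TWO": worse})
        pred = predict_reactivity(panel, "A*11:01", EXAMPLE_EPITOPE_POSITIONS,
                                  EXAMPLE_HBONDED_POSITIONS)
        assert pred.predictions["ONE"] == "nonreactive"
        assert pred.predictions["TWO"] == "nonreactive"


class TestConcordance:
    def test_planted_panel_fully_concordant_across_thresholds(self):
        panel, labels = make_allele_panel(PanelSpec(seed=8))
        pred = predict_reactivity(panel, "SYN*11:01", (14, 17, 19, 39, 90),
                                  EXAMPLE_HBONDED_POSITIONS)
        assert pred.predictions == labels
        for threshold in (450.0, 500.0, 550.0):
            conc = evaluate_concordance(pred, panel, ReactivityRules(mfi_threshold=threshold))
            assert conc.fp == conc.fn == 0
            assert conc.accuracy == 1.0

    def test_planted_discordant_allele_is_listed(self):
        panel, labels = make_allele_panel(PanelSpec(seed=8))
        assert labels["SYN*12:01"] == "reactive"
        panel.mfi["SYN*12:01"] = 50.0  # force one reactive allele below threshold
        pred = predict_reactivity(panel, "SYN*11:01", (14, 17, 19, 39, 90),
                                  EXAMPLE_HBONDED_POSITIONS)
        conc = evaluate_concordance(pred, panel)
        assert conc.discordant == ["SYN*12:01"]
        assert conc.fp == 1 and conc.fn == 0

    def test_alleles_without_mfi_not_scored(self):
        panel, _ = make_allele_panel(PanelSpec(n_alleles=6, n_nonreactive=2,
                                               n_weakened_reactive=0, seed=2))
        del panel.mfi["SYN*02:01"]
        pred = predict_reactivity(panel, "SYN*11:01", (14, 17, 19, 39, 90),
                                  EXAMPLE_HBONDED_POSITIONS)
        conc = evaluate_concordance(pred, panel)
        assert conc.n == 5
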