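"""Structure-rationalized prediction of HLA allele reactivity.

An alloantibody whose epitope on the HLA alpha chain is known from a
crystal structure should react with exactly those alleles that preserve
the chemistry of the epitope positions. This module aligns panel alleles
to the reference allele at the epitope positions (class-I alpha chains are
length-conserved over this region, so alignment is positional), classifies
each substitution by its structural consequence (hydrogen-bond loss,
charge reversal, charged-to-hydrophobic swap, side-chain truncation,
conservative), predicts reactive/nonreactive per allele, and scores
concordance against single-antigen-bead mean fluorescence intensities
(MFI), with reactivity observed at MFI >= 500 by convention.

The default rule set encodes the anti-HLA-A*11:01 case: positions 90, 14
and 17 are critical (substitutions there abrogate binding), 19 and 39 are
weakening (binding reduced but not abolished).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from ._chem import (
    HYDROPHOBIC_AA,
    SIDECHAIN_HEAVY_ATOMS,
    STANDARD_AA1,
    charge_sign,
    has_sidechain_hbond_capacity,
)

EFFECT_CLASSES = ("hbond_loss", "charge_reversal", "charge_to_hydrophobic",
                  "side_chain_truncation", "conservative", "none")
IMPACTS = ("abrogating", "weakening", "tolerated")


def normalize_allele_name(name: str) -> str:
    """Canonical 'A*11:01'-style name (strips an 'HLA-' prefix, whitespace)."""
    name = name.strip()
    if name.upper().startswith("HLA-"):
        name = name[4:]
    return name


@dataclass
class AllelePanel:
    """Aligned alpha-chain sequences plus per-allele bead-assay MFI."""

    alleles: dict[str, str]                 # name -> mature-numbered sequence
    mfi: dict[str, float] = field(default_factory=dict)
    first_position: int = 1                 # mature number of sequence[0]

    def residue_at(self, allele: str, position: int) -> str:
        seq = self.alleles[allele]
        idx = position - self.first_position
        if not 0 <= idx < len(seq):
            raise IndexError(f"position {position} outside sequence of {allele}")
        return seq[idx]


def load_panel(fasta_path: str | Path, mfi_csv: str | Path,
               first_position: int = 1) -> AllelePanel:
    """Read allele sequences (FASTA) and MFI values (CSV: allele,mfi).

    Names are normalized on both sides; alleles lacking an MFI are kept
    with a warning, MFI rows lacking a sequence are reported and dropped.
    """
    alleles: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        name = normalize_allele_name(rec.id)
        if name in alleles:
            raise ValueError(f"duplicate allele {name!r} in {fasta_path}")
        alleles[name] = str(rec.seq).upper()
    if not alleles:
        raise ValueError(f"no sequences in {fasta_path}")

    mfi: dict[str, float] = {}
    with open(mfi_csv, newline="") as fh:
        reader = csv.reader(fh)
        rows = [r for r in reader if r and r[0].strip()]
    start = 1 if rows and rows[0] and not _is_number(rows[0][-1]) else 0
    for row in rows[start:]:
        name = normalize_allele_name(row[0])
        value = float(row[-1])
        if value < 0:
            raise ValueError(f"negative MFI for {name}")
        if name in mfi:
            raise ValueError(f"duplicate MFI entry for {name}")
        mfi[name] = value

    missing_mfi = sorted(set(alleles) - set(mfi))
    if missing_mfi:
        warnings.warn(f"alleles without MFI retained: {missing_mfi}")
    orphan_mfi = sorted(set(mfi) - set(alleles))
    if orphan_mfi:
        warnings.warn(f"MFI entries without sequence dropped: {orphan_mfi}")
        for name in orphan_mfi:
            del mfi[name]
    return AllelePanel(alleles, mfi, first_position)


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# substitution effects


@dataclass
class SubstitutionEffect:
    position: int
    ref_aa: str
    alt_aa: str
    effect_class: str
    predicted_impact: str
    rationale: str = ""


@dataclass
class ReactivityRules:
    """Positions on the alpha chain that drive the prediction.

    critical_positions: substitutions here abrogate binding;
    weakening_positions: substitutions here reduce but do not abolish it;
    mfi_threshold: observed-reactivity boundary for the bead assay.
    """

    critical_positions: frozenset[int] = frozenset({90, 14, 17})
    weakening_positions: frozenset[int] = frozenset({19, 39})
    mfi_threshold: float = 500.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "critical_positions", frozenset(self.critical_positions))
        object.__setattr__(self, "weakening_positions", frozenset(self.weakening_positions))
        if self.critical_positions & self.weakening_positions:
            raise ValueError("critical and weakening positions overlap")


def epitope_variant_table(
    panel: AllelePanel,
    reference: str,
    epitope_positions: Iterable[int],
) -> dict[str, dict[int, tuple[str, str]]]:
    """Per-allele map of epitope positions that differ from the reference."""
    if reference not in panel.alleles:
        raise KeyError(f"reference allele {reference!r} not in panel")
    positions = sorted(set(epitope_positions))
    table: dict[str, dict[int, tuple[str, str]]] = {}
    for allele in panel.alleles:
        diffs = {}
        for pos in positions:
            ref_aa = panel.residue_at(reference, pos)
            alt_aa = panel.residue_at(allele, pos)
            if ref_aa != alt_aa:
                diffs[pos] = (ref_aa, alt_aa)
        table[allele] = diffs
    return table


def classify_substitution(
    position: int,
    ref_aa: str,
    alt_aa: str,
    hbonded_positions: Iterable[int],
    rules: ReactivityRules | None = None,
) -> SubstitutionEffect:
    """Structural consequence of replacing ``ref_aa`` by ``alt_aa``.

    ``hbonded_positions`` are the alpha-chain positions whose reference
    residue takes part in an interface hydrogen bond (from the structure's
    interface report); a substitution there that removes side-chain
    donor/acceptor chemistry or shortens the side chain is a hydrogen-bond
    loss. Charge-sign flips, charged-to-hydrophobic swaps and large
    side-chain truncations are recognized next; anything else is
    conservative. The predicted impact is abrogating for hydrogen-bond loss
    or any charge change at a critical position, weakening for any change
    at a weakening position, tolerated otherwise.
    """
    rules = rules or ReactivityRules()
    for aa, label in ((ref_aa, "reference"), (alt_aa, "replacement")):
        if aa not in STANDARD_AA1:
            raise ValueError(f"non-standard {label} amino acid {aa!r} at position {position}")

    hb = position in set(hbonded_positions)
    if ref_aa == alt_aa:
        return SubstitutionEffect(position, ref_aa, alt_aa, "none", "tolerated", "identity")

    truncated = (SIDECHAIN_HEAVY_ATOMS[ref_aa] - SIDECHAIN_HEAVY_ATOMS[alt_aa]) >= 3
    lost_hb_chemistry = has_sidechain_hbond_capacity(ref_aa) and not has_sidechain_hbond_capacity(alt_aa)
    sref, salt = charge_sign(ref_aa), charge_sign(alt_aa)

    if hb and (lost_hb_chemistry or truncated):
        effect, why = "hbond_loss", "hydrogen-bonded residue loses donor/acceptor reach"
    elif sref != 0 and salt == -sref:
        effect, why = "charge_reversal", "side-chain charge sign flips"
    elif sref != 0 and alt_aa in HYDROPHOBIC_AA:
        effect, why = "charge_to_hydrophobic", "charged residue becomes hydrophobic"
    elif truncated:
        effect, why = "side_chain_truncation", "side chain loses >=3 heavy atoms"
    else:
        effect, why = "conservative", "chemistry broadly preserved"

    charge_change = sref != salt
    if position in rules.critical_positions and (effect == "hbond_loss" or charge_change):
        impact = "abrogating"
    elif position in rules.weakening_positions:
        impact = "weakening"
    elif position in rules.critical_positions and effect != "conservative":
        impact = "abrogating"
    else:
        impact = "tolerated"
    return SubstitutionEffect(position, ref_aa, alt_aa, effect, impact, why)


# ---------------------------------------------------------------------------
# prediction and concordance


@dataclass
class ReactivityPrediction:
    reference: str
    predictions: dict[str, str]                       # allele -> reactive|nonreactive
    reasons: dict[str, list[SubstitutionEffect]]

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps({
            "reference": self.reference,
            "alleles": {
                a: {
                    "predicted": self.predictions[a],
                    "reasons": [
                        {"position": e.position, "ref": e.ref_aa, "alt": e.alt_aa,
                         "effect": e.effect_class, "impact": e.predicted_impact}
                        for e in self.reasons[a]
                    ],
                }
                for a in self.predictions
            },
        }, indent=indent)


def predict_reactivity(
    panel: AllelePanel,
    reference: str,
    epitope_positions: Iterable[int],
    hbonded_positions: Iterable[int],
    rules: ReactivityRules | None = None,
) -> ReactivityPrediction:
    """Predict per-allele reactivity: nonreactive iff at least one epitope
    substitution is abrogating; alleles identical to the reference at all
    epitope positions are reactive."""
    rules = rules or ReactivityRules()
    table = epitope_variant_table(panel, reference, epitope_positions)
    hb = set(hbonded_positions)
    predictions, reasons = {}, {}
    for allele, diffs in table.items():
        effects = [classify_substitution(pos, ref, alt, hb, rules)
                   for pos, (ref, alt) in sorted(diffs.items())]
        nonreactive = any(e.predicted_impact == "abrogating" for e in effects)
        predictions[allele] = "nonreactive" if nonreactive else "reactive"
        reasons[allele] = effects
    return ReactivityPrediction(reference, predictions, reasons)


@dataclass
class ConcordanceResult:
    tp: int
    fp: int
    tn: int
    fn: int
    discordant: list[str]

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")


def evaluate_concordance(
    prediction: ReactivityPrediction,
    panel: AllelePanel,
    rules: ReactivityRules | None = None,
) -> ConcordanceResult:
    """Confusion counts of predicted vs observed (MFI >= threshold) classes.

    Alleles without an MFI value are not scored. 'Positive' is reactive.
    """
    rules = rules or ReactivityRules()
    tp = fp = tn = fn = 0
    discordant = []
    for allele, predicted in prediction.predictions.items():
        if allele not in panel.mfi:
            continue
        observed = "reactive" if panel.mfi[allele] >= rules.mfi_threshold else "nonreactive"
        if predicted == observed == "reactive":
            tp += 1
        elif predicted == observed == "nonreactive":
            tn += 1
        elif predicted == "reactive":
            fp += 1
            discordant.append(allele)
        else:
            fn += 1
            discordant.append(allele)
    return ConcordanceResult(tp, fp, tn, fn, sorted(discordant))


# ---------------------------------------------------------------------------
# curated example: epitope-position residues discussed in the source study
#
# Limited to substitutions the study describes explicitly; everything else
# about these alleles is deliberately absent. A*66:01 and A*66:02 differ only
# at positions 90 and 163, position 163 lying outside the epitope.

EXAMPLE_EPITOPE_POSITIONS = (14, 17, 19, 39, 90)

EXAMPLE_EPITOPE_RESIDUES: Mapping[str, Mapping[int, str]] = {
    "A*11:01": {14: "R", 17: "R", 19: "E", 39: "D", 90: "D"},
    "A*66:01": {14: "R", 17: "R", 19: "E", 39: "D", 90: "D"},
    "A*66:02": {14: "R", 17: "R", 19: "E", 39: "D", 90: "A"},
}

EXAMPLE_SUBSTITUTIONS = (
    (90, "D", "A"),   # eplet position: hydrogen bond to the light chain lost
    (14, "R", "W"),   # positive charge replaced by bulky hydrophobic
    (17, "R", "S"),   # four heavy-chain hydrogen bonds lost, shorter side chain
    (19, "E", "K"),   # charge reversal, no hydrogen bond involved: weakening
    (39, "D", "Y"),   # negative charge replaced by hydrophobic: weakening
)

EXAMPLE_HBONDED_POSITIONS = frozenset({90, 17})
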