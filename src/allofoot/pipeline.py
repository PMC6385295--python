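"""End-to-end orchestration: structure -> footprint -> reactivity -> co-engagement.

A single :class:`PipelineConfig` names the inputs (complex structure,
chain-role map, optional allele panel, optional receptor complexes) and
every tunable parameter; :func:`run_footprint_pipeline` executes the
stages that have inputs, skips the rest, and emits one JSON-serializable
report in which all parameters are echoed for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .interface import HbondCriteria, SasaParams, analyze_interface
from .specificity import (
    ReactivityRules,
    evaluate_concordance,
    load_panel,
    predict_reactivity,
)
from .structure import assign_roles, parse_structure
from .superpose import detect_clashes, superpose_by_shared_chain

log = logging.getLogger("allofoot")

REPORT_SCHEMA_VERSION = 1


@dataclass
class ReceptorInput:
    path: str
    name: str
    role_map: Mapping[str, str]
    fit_positions: tuple[int, int] = (1, 180)
    numbering_offset: Mapping[str, int] | int = 0


@dataclass
class PipelineConfig:
    structure_path: str
    role_map: Mapping[str, str] | str = "auto"
    structure_format: str | None = None
    numbering_offset: Mapping[str, int] | int = 0
    sasa: SasaParams = field(default_factory=SasaParams)
    hbond: HbondCriteria = field(default_factory=HbondCriteria)
    contact_cutoff: float = 4.0
    gap_tolerance: int = 3
    include_peptide: bool = False
    panel_fasta: str | None = None
    panel_mfi: str | None = None
    reference_allele: str | None = None
    rules: ReactivityRules = field(default_factory=ReactivityRules)
    receptors: Sequence[ReceptorInput] = ()
    clash_tolerance: float = 0.4
    output_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict[str, Any] = {}
        for simple in ("structure_path", "role_map", "structure_format", "numbering_offset",
                       "contact_cutoff", "gap_tolerance", "include_peptide", "panel_fasta",
                       "panel_mfi", "reference_allele", "clash_tolerance", "output_dir",
                       "seed", "log_level"):
            if simple in raw:
                kwargs[simple] = raw[simple]
        if "sasa" in raw:
            kwargs["sasa"] = SasaParams(**raw["sasa"])
        if "hbond" in raw:
            kwargs["hbond"] = HbondCriteria(**raw["hbond"])
        if "rules" in raw:
            r = dict(raw["rules"])
            kwargs["rules"] = ReactivityRules(
                critical_positions=frozenset(r.get("critical_positions", (90, 14, 17))),
                weakening_positions=frozenset(r.get("weakening_positions", (19, 39))),
                mfi_threshold=float(r.get("mfi_threshold", 500.0)),
            )
        if "receptors" in raw:
            kwargs["receptors"] = [
                ReceptorInput(path=e["path"], name=e.get("name", Path(e["path"]).stem),
                              role_map=e["role_map"],
                              fit_positions=tuple(e.get("fit_positions", (1, 180))),
                              numbering_offset=e.get("numbering_offset", 0))
                for e in raw["receptors"]
            ]
        return cls(**kwargs)

    def parameters_echo(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "sasa": {"probe_radius": self.sasa.probe_radius,
                     "n_sphere_points": self.sasa.n_sphere_points},
            "hbond": {"max_donor_acceptor_distance": self.hbond.max_donor_acceptor_distance,
                      "min_donor_angle": self.hbond.min_donor_angle},
            "contact_cutoff": self.contact_cutoff,
            "gap_tolerance": self.gap_tolerance,
            "include_peptide": self.include_peptide,
            "rules": {"critical_positions": sorted(self.rules.critical_positions),
                      "weakening_positions": sorted(self.rules.weakening_positions),
                      "mfi_threshold": self.rules.mfi_threshold},
            "clash_tolerance": self.clash_tolerance,
            "seed": self.seed,
        }


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def run_footprint_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages and return the consolidated report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    report: dict[str, Any] = {"parameters": config.parameters_echo(), "stages": {}}

    try:
        st = parse_structure(config.structure_path, config.structure_format,
                             numbering_offset=config.numbering_offset)
        st = assign_roles(st, config.role_map)
    except Exception as exc:
        raise StageError("structure", exc) from exc
    log.info("parsed %s: %d chains", st.identifier, len(st.chains))

    try:
        iface = analyze_interface(st, config.sasa, config.hbond,
                                  config.contact_cutoff, config.gap_tolerance,
                                  config.include_peptide)
    except Exception as exc:
        raise StageError("footprint", exc) from exc
    report["stages"]["footprint"] = json.loads(iface.to_json())
    log.info("footprint %.1f A^2 in %d alpha-chain segments",
             iface.total_footprint, len(iface.segments))

    if config.panel_fasta and config.panel_mfi and config.reference_allele:
        try:
            panel = load_panel(config.panel_fasta, config.panel_mfi)
            alpha = st.chain_for_role("hla_alpha")
            epitope_positions = sorted(p for c, p in iface.epitope_residues if c == alpha)
            hb_positions = iface.hbonded_positions(alpha)
            prediction = predict_reactivity(panel, config.reference_allele,
                                            epitope_positions, hb_positions, config.rules)
            concordance = evaluate_concordance(prediction, panel, config.rules)
        except Exception as exc:
            raise StageError("reactivity", exc) from exc
        report["stages"]["reactivity"] = {
            "prediction": json.loads(prediction.to_json()),
            "concordance": {"tp": concordance.tp, "fp": concordance.fp,
                            "tn": concordance.tn, "fn": concordance.fn,
                            "accuracy": concordance.accuracy,
                            "discordant": concordance.discordant},
            "epitope_positions": epitope_positions,
        }
    else:
        report["stages"]["reactivity"] = {"skipped": "no allele panel configured"}

    if config.receptors:
        fab_chains = [st.chain_for_role(r) for r in ("fab_heavy", "fab_light")
                      if r in st.role_map.values()]
        clash_reports = {}
        for rec in config.receptors:
            try:
                mob = parse_structure(rec.path, numbering_offset=rec.numbering_offset)
                mob = assign_roles(mob, rec.role_map)
                lo, hi = rec.fit_positions
                moved, tf = superpose_by_shared_chain(st, mob, "hla_alpha", range(lo, hi + 1))
                receptor_chains = [c for c, r in moved.role_map.items() if r == "receptor"]
                clashes = detect_clashes(st, fab_chains, moved, receptor_chains,
                                         config.clash_tolerance)
            except Exception as exc:
                raise StageError(f"coengage:{rec.name}", exc) from exc
            clash_reports[rec.name] = {
                "fit_rmsd": tf.rmsd, "n_fit_atoms": tf.n_fit_atoms,
                "n_clashes": clashes.n_clashes, "min_distance": clashes.min_distance,
            }
            log.info("%s: fit rmsd %.2f A, %d clashes", rec.name, tf.rmsd, clashes.n_clashes)
        report["stages"]["coengagement"] = clash_reports
    else:
        report["stages"]["coengagement"] = {"skipped": "no receptor structures configured"}

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
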