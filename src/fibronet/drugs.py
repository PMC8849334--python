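"""Drug-effect protocols: receptor blockers and peptide-boosting drugs as
Ymax modifiers under study-matched input conditions, reported as fold
changes of readout nodes against a reference condition.

Angiotensin-receptor blockers (ARB) subtract from the AT1R node's Ymax;
neprilysin inhibitors (NEPi), which raise natriuretic-peptide
bioavailability, add to the NP node's Ymax. Combination therapy applies
both. Doses between a protocol's printed minimum and maximum are spaced
geometrically, matching pharmacological dilution series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import (
    BASAL_DURATION_H,
    DEFAULT_BASAL_WEIGHT,
    STIMULUS_DURATION_H,
    CompiledModel,
    PerturbationSpec,
    SolverConfig,
    StageSpec,
    compile_model,
    run_protocol,
)
from .model import NetworkModel, ReactionDef, parse_rule

__all__ = [
    "DrugProtocol",
    "FOLD_CHANGE_FLOOR",
    "fold_change",
    "drug_dose_response",
    "multi_output_drug_effect",
    "regional_drug_effect",
    "add_reaction_variant",
]

FOLD_CHANGE_FLOOR = 1e-6


@dataclass(frozen=True)
class DrugProtocol:
    """Input weights and modifier ranges for one drug-comparison study.

    ``reference`` selects the fold-change denominator: ``control`` (all
    inputs at basal 0.1, no drug) or ``stimulated`` (the protocol's own
    input weights, no drug — the positive control).
    """

    label: str
    input_weights: Mapping[str, float] = field(default_factory=dict)
    at1r_node: str = "AT1R"
    np_node: str = "NP"
    at1r_range: tuple[float, float] | None = (0.01, 0.5)
    nep_range: tuple[float, float] | None = (0.05, 4.0)
    readouts: tuple[str, ...] = ("proCI",)
    reference: str = "control"

    def __post_init__(self) -> None:
        object.__setattr__(self, "input_weights", dict(self.input_weights))
        object.__setattr__(self, "readouts", tuple(self.readouts))
        if self.reference not in ("control", "stimulated"):
            raise ValueError(f"unknown reference {self.reference!r}")
        for rng in (self.at1r_range, self.nep_range):
            if rng is not None and not (0 < rng[0] <= rng[1]):
                raise ValueError(f"modifier range {rng} must satisfy 0 < min <= max")


def _steady(
    cm: CompiledModel,
    input_weights: Mapping[str, float],
    perturbations: Sequence[PerturbationSpec],
    config: SolverConfig | None,
) -> dict[str, float]:
    weights = {sid: DEFAULT_BASAL_WEIGHT for sid in cm.model.input_ids}
    weights.update(input_weights)
    stages = [
        StageSpec(input_weights=weights, duration=BASAL_DURATION_H),
        StageSpec(
            input_weights=weights,
            perturbations=tuple(perturbations),
            duration=STIMULUS_DURATION_H,
        ),
    ]
    return run_protocol(cm, stages, config=config).final_activities


def fold_change(treated: float, reference: float) -> tuple[float, bool]:
    """treated / reference with an epsilon floor; the flag marks floored results."""
    floored = reference < FOLD_CHANGE_FLOOR
    return treated / max(reference, FOLD_CHANGE_FLOOR), floored


def _reference_activities(
    cm: CompiledModel, protocol: DrugProtocol, config: SolverConfig | None
) -> dict[str, float]:
    weights = (
        {} if protocol.reference == "control" else dict(protocol.input_weights)
    )
    return _steady(cm, weights, (), config)


def drug_dose_response(
    model: NetworkModel | CompiledModel,
    protocol: DrugProtocol,
    n_doses: int = 8,
    config: SolverConfig | None = None,
) -> pd.DataFrame:
    """Readout fold changes vs dose for ARB alone, NEPi alone, and combination.

    Doses are geometric between each modifier range's min and max; the ARB
    and NEPi grids are paired index-wise for the combination arm. Returns a
    tidy frame (arm, dose_index, at1r_modifier, nep_modifier, readout,
    activity, fold_change, floored).
    """
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    if protocol.at1r_range is None or protocol.nep_range is None:
        raise ValueError("protocol must define both modifier ranges for dose response")
    arb_doses = np.geomspace(*protocol.at1r_range, n_doses)
    nep_doses = np.geomspace(*protocol.nep_range, n_doses)
    ref = _reference_activities(cm, protocol, config)

    rows = []
    arms = {
        "arb": [(a, None) for a in arb_doses],
        "nepi": [(None, b) for b in nep_doses],
        "combination": list(zip(arb_doses, nep_doses)),
    }
    for arm, dose_list in arms.items():
        for i, (a, b) in enumerate(dose_list):
            perts = []
            if a is not None:
                perts.append(PerturbationSpec(protocol.at1r_node, "subtract_ymax", float(a)))
            if b is not None:
                perts.append(PerturbationSpec(protocol.np_node, "add_ymax", float(b)))
            acts = _steady(cm, protocol.input_weights, perts, config)
            for readout in protocol.readouts:
                fc, floored = fold_change(acts[readout], ref[readout])
                rows.append(
                    {
                        "arm": arm,
                        "dose_index": i,
                        "at1r_modifier": a,
                        "nep_modifier": b,
                        "readout": readout,
                        "activity": acts[readout],
                        "fold_change": fc,
                        "floored": floored,
                    }
                )
    return pd.DataFrame(rows)


def multi_output_drug_effect(
    model: NetworkModel | CompiledModel,
    protocol: DrugProtocol,
    config: SolverConfig | None = None,
) -> pd.DataFrame:
    """Fold changes of each readout for ARB-only and ARB+NEPi at the
    protocol's maximum modifiers, against the protocol reference.

    Suited to fixed-dose comparisons of multi-output synergy (e.g. αSMA,
    proCI, periostin against a stimulated positive control).
    """
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    ref = _reference_activities(cm, protocol, config)
    a = protocol.at1r_range[1] if protocol.at1r_range else None
    b = protocol.nep_range[1] if protocol.nep_range else None
    arms: dict[str, list[PerturbationSpec]] = {"none": []}
    if a is not None:
        arms["arb"] = [PerturbationSpec(protocol.at1r_node, "subtract_ymax", a)]
    if b is not None:
        arms["nepi"] = [PerturbationSpec(protocol.np_node, "add_ymax", b)]
    if a is not None and b is not None:
        arms["combination"] = arms["arb"] + arms["nepi"]
    rows = []
    for arm, perts in arms.items():
        acts = _steady(cm, protocol.input_weights, perts, config)
        for readout in protocol.readouts:
            fc, floored = fold_change(acts[readout], ref[readout])
            rows.append(
                {
                    "arm": arm,
                    "readout": readout,
                    "activity": acts[readout],
                    "fold_change": fc,
                    "floored": floored,
                }
            )
    return pd.DataFrame(rows)


def regional_drug_effect(
    model: NetworkModel | CompiledModel,
    protocol: DrugProtocol,
    zone_tensions: Mapping[str, float] = {"remote": 0.1, "infarct": 0.6},
    tension_input: str = "Tension",
    config: SolverConfig | None = None,
) -> pd.DataFrame:
    """Per-zone fold changes (readout x zone x drug on/off) vs the
    non-infarcted control condition.

    Zone-specific tension weights model remote vs infarct mechanics; the
    protocol's (externally supplied) input weights model the post-injury
    cytokine milieu. The reference is the control condition: basal inputs
    with the lowest zone tension and no drug.
    """
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    if not zone_tensions:
        raise ValueError("zone_tensions must name at least one zone")
    control_tension = min(zone_tensions.values())
    ref = _steady(cm, {tension_input: control_tension}, (), config)
    a = protocol.at1r_range[1] if protocol.at1r_range else None
    drug_arms = {"off": []}
    if a is not None:
        drug_arms["on"] = [PerturbationSpec(protocol.at1r_node, "subtract_ymax", a)]
    rows = []
    for zone, tension in zone_tensions.items():
        weights = dict(protocol.input_weights)
        weights[tension_input] = tension
        for arm, perts in drug_arms.items():
            acts = _steady(cm, weights, perts, config)
            for readout in protocol.readouts:
                fc, floored = fold_change(acts[readout], ref[readout])
                rows.append(
                    {
                        "zone": zone,
                        "tension": tension,
                        "drug": arm,
                        "readout": readout,
                        "activity": acts[readout],
                        "fold_change": fc,
                        "floored": floored,
                    }
                )
    return pd.DataFrame(rows)


def add_reaction_variant(
    model: NetworkModel,
    rule_text: str,
    weight: float = 1.0,
    ec50: float = 0.5,
    n: float = 1.4,
) -> NetworkModel:
    """Return a copy of the model with one parsed reaction appended.

    Used to test candidate mechanisms (e.g. adding an inhibitory edge) on a
    variant network while leaving the original untouched.
    """
    reaction = parse_rule(rule_text, weight=weight, ec50=ec50, n=n)
    return model.with_reaction(reaction)
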