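"""Synthetic networks, validation tables, and independent brute-force
oracles.

These fixtures exist so every analysis stage is testable end-to-end without
a large curated model: small topologies with closed-form steady states, a
seeded random-network generator, a fixed-step explicit-Euler integrator
used only as a verification oracle, and a hand-authored mid-size
fibroblast-like demo network (synthetic — wiring chosen for plausibility
and coverage, not curated from literature) whose node names follow the
field's conventions so drug and screen protocols are expressible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .engine import (
    CompiledModel,
    StageSpec,
    compile_model,
    normalized_hill,
)
from .model import (
    ACTIVATOR,
    INHIBITOR,
    NetworkModel,
    ReactionDef,
    SpeciesDef,
    Term,
    parse_rule,
)
from .validation import (
    CLASSES,
    DEFAULT_THRESHOLD,
    ValidationRecord,
    classify_change,
    simulated_deltas,
)

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "make_demo_network",
    "euler_oracle",
    "make_validation_fixture",
]

TOPOLOGIES = ("chain", "star", "feedback_loop", "random_dag", "random_with_cycles")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a deterministic synthetic network."""

    topology: str
    n_nodes: int = 5
    n_inputs: int = 1
    inhibitor_fraction: float = 0.0
    and_gate_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if not (1 <= self.n_inputs <= self.n_nodes):
            raise ValueError("need n_nodes >= n_inputs >= 1")
        if not (0 <= self.inhibitor_fraction <= 1 and 0 <= self.and_gate_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")


def _species(ids_cats: list[tuple[str, str]], tau: float = 0.1) -> list[SpeciesDef]:
    return [SpeciesDef(id=i, category=c, tau=tau) for i, c in ids_cats]


def make_fixture(spec: FixtureSpec) -> NetworkModel:
    """Build a small network of the requested shape; same seed, same model.

    ``chain`` and ``star`` fixtures carry closed-form steady-state recipes in
    their metadata (activity of each node is a composition of normalized
    Hill evaluations of the input weight).
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_nodes, spec.n_inputs
    ids = [f"IN{i+1}" for i in range(k)] + [f"N{i+1}" for i in range(n - k)]
    cats = ["input"] * k + ["intermediate"] * (n - k)
    reactions = [ReactionDef(target=i) for i in ids[:k]]  # input drives

    if spec.topology == "chain":
        if spec.and_gate_fraction > 0:
            raise ValueError("chain topology cannot host AND gates")
        backbone = [ids[0]] + ids[k:]  # extra inputs stay isolated
        for up, down in zip(backbone[:-1], backbone[1:]):
            reactions.append(ReactionDef(target=down, terms=(Term(up),)))
        meta = {"closed_form": "chain"}
    elif spec.topology == "star":
        if spec.and_gate_fraction > 0 and k < 2:
            raise ValueError("star with AND gates needs >= 2 inputs")
        hub, leaves = ids[k], ids[k + 1 :]
        for inp in ids[:k]:
            reactions.append(ReactionDef(target=hub, terms=(Term(inp),)))
        for leaf in leaves:
            reactions.append(ReactionDef(target=leaf, terms=(Term(hub),)))
        meta = {"closed_form": "star", "hub": hub}
    elif spec.topology == "feedback_loop":
        loop = ids[k:]
        if len(loop) < 2:
            raise ValueError("feedback loop needs >= 2 non-input nodes")
        reactions.append(ReactionDef(target=loop[0], terms=(Term(ids[0]),)))
        for up, down in zip(loop, loop[1:] + [loop[0]]):
            sign = INHIBITOR if rng.random() < spec.inhibitor_fraction else ACTIVATOR
            reactions.append(
                ReactionDef(target=down, terms=(Term(up, sign),), weight=0.8)
            )
        meta = {}
    else:  # random_dag / random_with_cycles
        non_inputs = ids[k:]
        for i, node in enumerate(non_inputs):
            upstream = ids[: k + i]
            n_src = 2 if (len(upstream) >= 2 and rng.random() < spec.and_gate_fraction) else 1
            srcs = rng.choice(upstream, size=n_src, replace=False)
            terms = tuple(
                Term(s, INHIBITOR if rng.random() < spec.inhibitor_fraction else ACTIVATOR)
                for s in srcs
            )
            reactions.append(ReactionDef(target=node, terms=terms))
        if spec.topology == "random_with_cycles" and len(non_inputs) >= 2:
            n_back = max(1, len(non_inputs) // 4)
            for _ in range(n_back):
                j = int(rng.integers(1, len(non_inputs)))
                i = int(rng.integers(0, j))
                sign = (
                    INHIBITOR
                    if rng.random() < spec.inhibitor_fraction
                    else ACTIVATOR
                )
                reactions.append(
                    ReactionDef(
                        target=non_inputs[i],
                        terms=(Term(non_inputs[j], sign),),
                        weight=0.8,
                    )
                )
        meta = {}
    meta.update(
        {
            "fixture": spec.topology,
            "seed": spec.seed,
            "synthetic": True,
        }
    )
    return NetworkModel(
        species=_species(list(zip(ids, cats))), reactions=reactions, metadata=meta
    )


def chain_steady_state(model: NetworkModel, input_weight: float) -> dict[str, float]:
    """Closed-form fixed point of a chain fixture at one input weight.

    The input node settles at ``Ymax * w``; each downstream node at
    ``Ymax * w_r * f(upstream)`` for its single activating reaction.
    """
    if model.metadata.get("closed_form") != "chain":
        raise ValueError("model is not a chain fixture")
    out: dict[str, float] = {}
    for s in model.species:
        rxns = model.reactions_targeting(s.id)
        if s.category == "input":
            w = input_weight if s.id == "IN1" else rxns[0].weight
            out[s.id] = s.y_max * w
        elif rxns:
            (r,) = rxns
            (t,) = r.terms
            f = float(normalized_hill(out[t.source], r.ec50, r.n))
            drive = min(max(r.weight * f, 0.0), 1.0)
            out[s.id] = s.y_max * drive
        else:
            out[s.id] = 0.0
    return out


# ---------------------------------------------------------------------------
# Explicit-Euler oracle
# ---------------------------------------------------------------------------

def euler_oracle(
    model: NetworkModel | CompiledModel,
    stages: Sequence[StageSpec],
    dt: float = 1e-3,
    clamp_drives: bool = True,
) -> dict[str, float]:
    """Fixed-step explicit-Euler integration of the same right-hand side.

    A deliberately simple-minded independent check on the adaptive solver;
    ``dt`` must satisfy dt <= min(tau)/10 for stability. Raises on
    non-finite state.
    """
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    tau_min = float(np.min(cm.tau))
    if dt > tau_min / 10:
        raise ValueError(f"dt={dt} too large for min tau {tau_min} (need dt <= tau/10)")
    y = cm.y0.copy()
    weights: dict[str, float] = {}
    for stage in stages:
        weights.update(stage.input_weights)
        from .engine import _effective_ymax, _resolve_input_drive  # shared arrays

        y_max_eff = _effective_ymax(cm, stage.perturbations)
        input_drive = _resolve_input_drive(cm, weights)
        n_steps = int(round(stage.duration / dt))
        for step in range(n_steps):
            y = y + dt * cm.rhs(y, y_max_eff, input_drive, clamp_drives)
            if step % 1000 == 0 and not np.all(np.isfinite(y)):
                raise RuntimeError(f"euler oracle diverged at step {step}")
        if not np.all(np.isfinite(y)):
            raise RuntimeError("euler oracle produced non-finite state")
    return dict(zip(cm.species_ids, y.tolist()))


# ---------------------------------------------------------------------------
# Synthetic validation tables
# ---------------------------------------------------------------------------

def make_validation_fixture(
    model: NetworkModel,
    n_records: int,
    n_match: int | None = None,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
    tension_input: str = "Tension",
) -> tuple[list[ValidationRecord], int]:
    """Build a validation table with a known ground-truth accuracy.

    Exactly ``n_match`` of ``n_records`` records carry the class the model
    actually predicts under the validation protocol (default: all of them);
    the rest carry a deliberately wrong class. Returns (records, n_match).
    """
    if n_match is None:
        n_match = n_records
    if not (0 <= n_match <= n_records):
        raise ValueError("need 0 <= n_match <= n_records")
    rng = np.random.default_rng(seed)
    inputs = [i for i in model.input_ids]
    targets = [s.id for s in model.species if s.category != "input"]
    if not inputs or not targets:
        raise ValueError("model needs at least one input and one non-input node")
    deltas = simulated_deltas(model, inputs, tension_input=tension_input)
    pairs = [(i, t) for i in inputs for t in targets]
    if len(pairs) < n_records:
        raise ValueError(f"model supports at most {len(pairs)} distinct records")
    chosen = [pairs[i] for i in rng.choice(len(pairs), size=n_records, replace=False)]
    records = []
    for k, (stim, node) in enumerate(chosen):
        predicted = classify_change(deltas[stim][node], threshold)
        if k < n_match:
            observed = predicted
        else:
            others = [c for c in CLASSES if c != predicted]
            observed = others[int(rng.integers(len(others)))]
        records.append(
            ValidationRecord(
                stimulus=stim,
                measured_node=node,
                observed=observed,
                citation=f"synthetic:{seed}",
            )
        )
    return records, n_match


# ---------------------------------------------------------------------------
# Hand-authored fibroblast-like demo network (synthetic)
# ---------------------------------------------------------------------------

_DEMO_INPUTS = [
    "Tension", "TGFB", "AngII", "IL6", "IL1", "TNFa", "NE", "PDGF", "ET1", "NP",
]
_DEMO_RECEPTORS = [
    "AT1R", "TGFB1R", "IL6R", "IL1R", "TNFR", "BAR", "PDGFR", "ETAR", "NPRA", "BAMBI",
]
_DEMO_INTERMEDIATES = [
    "NOX", "ROS", "JNK", "ERK", "AP1", "NFKB", "smad3", "PI3K", "Akt", "mTOR",
    "STAT", "PKA", "CREB", "PKG", "Rho", "MRTF", "latentTGFB",
]
_DEMO_OUTPUTS = [
    "proCI", "proCIII", "fibronectin", "periostin", "osteopontin",
    "proMMP1", "proMMP2", "proMMP3", "proMMP8", "proMMP9", "proMMP12", "proMMP14",
    "TIMP1", "TIMP2", "PAI1", "aSMA", "CTGF",
]

# (rule, weight) — weight 1 unless noted; autocrine feedback edges carry 0.8.
_DEMO_RULES: list[tuple[str, float]] = [
    # receptor layer
    ("AngII => AT1R", 1.0),
    ("Tension => AT1R", 0.5),
    ("TGFB & !BAMBI => TGFB1R", 1.0),
    ("latentTGFB & !BAMBI => TGFB1R", 0.8),
    ("IL6 => IL6R", 1.0),
    ("IL1 => IL1R", 1.0),
    ("TNFa => TNFR", 1.0),
    ("NE => BAR", 1.0),
    ("PDGF => PDGFR", 1.0),
    ("ET1 => ETAR", 1.0),
    ("NP => NPRA", 1.0),
    ("IL1R => BAMBI", 1.0),
    ("TGFB1R => BAMBI", 0.5),
    # intracellular signaling
    ("AT1R => NOX", 1.0),
    ("TGFB1R => NOX", 0.5),
    ("NOX => ROS", 1.0),
    ("Tension => ROS", 0.4),
    ("ROS => JNK", 1.0),
    ("TNFR => JNK", 0.5),
    ("JNK => AP1", 1.0),
    ("ERK => AP1", 0.5),
    ("IL1R => NFKB", 1.0),
    ("TNFR => NFKB", 1.0),
    ("IL6R => STAT", 1.0),
    ("PDGFR => PI3K", 1.0),
    ("ETAR => PI3K", 0.5),
    ("IL6R => PI3K", 0.4),
    ("PI3K => Akt", 1.0),
    ("Akt => mTOR", 1.0),
    ("TGFB1R => smad3", 1.0),
    ("Tension & TGFB1R => smad3", 0.6),
    ("BAR => PKA", 1.0),
    ("PKA => CREB", 1.0),
    ("NPRA => PKG", 1.0),
    ("Tension => Rho", 1.0),
    ("Rho => MRTF", 1.0),
    ("PDGFR => ERK", 1.0),
    ("ETAR => ERK", 0.5),
    ("AP1 & !CREB => latentTGFB", 0.8),
    ("smad3 => latentTGFB", 0.4),
    # outputs
    ("smad3 & !CREB => proCI", 1.0),
    ("mTOR => proCI", 0.4),
    ("MRTF => proCI", 0.3),
    ("smad3 => proCIII", 1.0),
    ("MRTF => proCIII", 0.4),
    ("Akt => fibronectin", 0.6),
    ("smad3 => fibronectin", 0.6),
    ("smad3 => periostin", 1.0),
    ("MRTF => periostin", 0.5),
    ("NFKB => osteopontin", 1.0),
    ("AP1 => osteopontin", 0.5),
    ("AP1 => proMMP1", 1.0),
    ("NFKB => proMMP1", 0.5),
    ("AP1 => proMMP2", 1.0),
    ("NFKB => proMMP3", 1.0),
    ("STAT => proMMP3", 0.4),
    ("NFKB => proMMP8", 1.0),
    ("AP1 => proMMP9", 1.0),
    ("NFKB => proMMP9", 0.5),
    ("NFKB => proMMP12", 1.0),
    ("AP1 => proMMP14", 0.7),
    ("MRTF => proMMP14", 0.4),
    ("smad3 => TIMP1", 1.0),
    ("STAT => TIMP1", 0.5),
    ("smad3 => TIMP2", 1.0),
    ("smad3 => PAI1", 1.0),
    ("Akt => PAI1", 0.4),
    ("MRTF => aSMA", 1.0),
    ("smad3 => aSMA", 0.6),
    ("smad3 => CTGF", 1.0),
    ("ERK => CTGF", 0.4),
]


def make_demo_network() -> NetworkModel:
    """Mid-size synthetic fibroblast-like mechano-chemo network.

    Nine cytokine inputs plus a tension input feed receptor, kinase, and
    transcription-factor layers onto the standard matrix-turnover outputs
    (procollagens, matricellular proteins, proMMPs, protease inhibitors).
    Includes an autocrine latent-TGFB feedback loop (weight 0.8) and
    tension crosstalk through AT1R, ROS, Rho/MRTF, and smad3. The wiring is
    hand-authored for coverage and plausibility; it is not the curated
    literature model and carries no citations.
    """
    species: list[SpeciesDef] = []
    for sid in _DEMO_INPUTS:
        species.append(SpeciesDef(id=sid, category="input", tau=0.1))
    for sid in _DEMO_RECEPTORS:
        species.append(SpeciesDef(id=sid, category="intermediate", tau=1.0))
    for sid in _DEMO_INTERMEDIATES:
        tau = 10.0 if sid == "latentTGFB" else 0.1
        species.append(SpeciesDef(id=sid, category="intermediate", tau=tau))
    for sid in _DEMO_OUTPUTS:
        species.append(SpeciesDef(id=sid, category="output", tau=10.0))
    reactions = [ReactionDef(target=sid) for sid in _DEMO_INPUTS]
    for rule, weight in _DEMO_RULES:
        reactions.append(parse_rule(rule, weight=weight))
    return NetworkModel(
        species=species,
        reactions=reactions,
        metadata={"name": "demo-fibroblast-synthetic", "synthetic": True},
    )
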