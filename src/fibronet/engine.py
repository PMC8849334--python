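"""Logic-based ODE engine: normalized Hill activation, gate algebra, and
staged protocol integration.

Each node ``i`` relaxes toward a drive-determined level::

    dy_i/dt = (Ymax_i_eff * F_i(y) - y_i) / tau_i

where ``F_i`` OR-combines the drives of all reactions targeting ``i``. A
reaction's drive is its weight times the product over its AND-conjoined
terms of ``f(x)`` (activators) or ``1 - f(x)`` (inhibitors), with ``f`` the
normalized Hill function anchored at ``f(0) = 0``, ``f(EC50) = 0.5``,
``f(1) = 1``. OR uses the probabilistic-sum ``a + b - a*b``.

Activities are normalized to ``[0, Ymax]``; under overexpression
(``Ymax > 1``) upstream activities may exceed 1 and ``f`` saturates at its
ceiling ``B``, so reaction drives are clamped into ``[0, 1]`` before the OR
fold (the fold's algebraic domain). The clamp is exposed as a solver switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import reduce
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import ACTIVATOR, INHIBITOR, NetworkModel, ReactionDef

__all__ = [
    "PerturbationSpec",
    "StageSpec",
    "SolverConfig",
    "SimulationResult",
    "SolverError",
    "normalized_hill",
    "hill_ceiling",
    "reaction_activation",
    "or_fold",
    "node_drive",
    "CompiledModel",
    "compile_model",
    "run_protocol",
    "steady_state",
    "steady_state_delta",
    "DEFAULT_BASAL_WEIGHT",
    "BASAL_DURATION_H",
    "STIMULUS_DURATION_H",
]

DEFAULT_BASAL_WEIGHT = 0.1
BASAL_DURATION_H = 80.0
STIMULUS_DURATION_H = 240.0


class SolverError(RuntimeError):
    """Integration failed or produced non-finite state."""


@dataclass(frozen=True)
class PerturbationSpec:
    """A Ymax modifier applied for the duration of its stage.

    ``set_ymax`` models knockdown (0.1) / overexpression (5); ``add_ymax``
    and ``subtract_ymax`` model graded drug effects (e.g. receptor blockers
    subtract from the receptor's Ymax).
    """

    node: str
    mode: str  # set_ymax | add_ymax | subtract_ymax
    value: float

    def __post_init__(self) -> None:
        if self.mode not in ("set_ymax", "add_ymax", "subtract_ymax"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")


@dataclass(frozen=True)
class StageSpec:
    """One protocol stage: input weights + perturbations held for ``duration`` hours.

    Inputs not named here inherit the previous stage's weight (or the global
    basal default 0.1 in the first stage).
    """

    input_weights: Mapping[str, float] = field(default_factory=dict)
    perturbations: tuple[PerturbationSpec, ...] = ()
    duration: float = STIMULUS_DURATION_H

    def __post_init__(self) -> None:
        object.__setattr__(self, "perturbations", tuple(self.perturbations))
        object.__setattr__(self, "input_weights", dict(self.input_weights))
        if self.duration <= 0:
            raise ValueError("stage duration must be > 0")


@dataclass(frozen=True)
class SolverConfig:
    method: str = "LSODA"
    rtol: float = 1e-6
    atol: float = 1e-8
    steady_tol: float = 1e-5
    clamp_drives: bool = True
    n_trajectory_points: int = 0  # 0: final state only


@dataclass
class SimulationResult:
    final_activities: dict[str, float]
    converged: bool
    trajectory_t: np.ndarray | None = None
    trajectory_y: np.ndarray | None = None  # (n_species, n_times)
    species_ids: list[str] | None = None

    def __getitem__(self, sid: str) -> float:
        return self.final_activities[sid]


# ---------------------------------------------------------------------------
# Normalized Hill function and gate algebra (scalar reference API)
# ---------------------------------------------------------------------------

def _hill_params(ec50: float, n: float) -> tuple[float, float]:
    denom = 2.0 * ec50**n - 1.0
    if abs(denom) < 1e-9:
        raise ValueError(
            f"singular normalized-Hill parameters: 2*ec50^n = 1 (ec50={ec50}, n={n})"
        )
    b = (ec50**n - 1.0) / denom
    return b, b - 1.0  # (B, K^n)


def hill_ceiling(ec50: float, n: float) -> float:
    """Saturating value B of the normalized Hill curve as x -> infinity."""
    return _hill_params(ec50, n)[0]


def normalized_hill(x, ec50: float = 0.5, n: float = 1.4):
    """Normalized Hill activation ``f(x) = B x^n / (K^n + x^n)``.

    ``B`` and ``K^n`` are fixed by the anchors f(0)=0, f(EC50)=0.5, f(1)=1;
    monotone non-decreasing for x >= 0 and saturating at B for x > 1.
    """
    b, k_n = _hill_params(ec50, n)
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    xn = x**n
    return b * xn / (k_n + xn)


def reaction_activation(
    reaction: ReactionDef, activities: Mapping[str, float]
) -> float:
    """Drive of one reaction: ``w`` for input reactions, else
    ``w * prod(g(source))`` with g = f for activators and 1 - f for inhibitors."""
    if reaction.is_input_reaction:
        return reaction.weight
    drive = reaction.weight
    for t in reaction.terms:
        if t.source not in activities:
            raise KeyError(f"missing source activity for {t.source!r}")
        f = float(normalized_hill(activities[t.source], reaction.ec50, reaction.n))
        drive *= (1.0 - f) if t.sign == INHIBITOR else f
    return drive


def or_fold(drives: Iterable[float]) -> float:
    """Probabilistic-sum OR: a + b - a*b, folded over all drives.

    Equivalent to ``1 - prod(1 - d)``; associative and commutative, with 1 as
    the absorbing element.
    """
    return reduce(lambda a, b: a + b - a * b, drives, 0.0)


def node_drive(
    target: str,
    reactions: Sequence[ReactionDef],
    activities: Mapping[str, float],
    clamp: bool = True,
) -> float:
    """Total OR-combined drive on ``target`` from the reactions that feed it."""
    drives = []
    for r in reactions:
        if r.target != target:
            continue
        d = reaction_activation(r, activities)
        drives.append(min(max(d, 0.0), 1.0) if clamp else d)
    return or_fold(drives)


# ---------------------------------------------------------------------------
# Compiled (vectorized) form used by the integrator
# ---------------------------------------------------------------------------

@dataclass
class CompiledModel:
    """Flat-array view of a model for fast right-hand-side evaluation."""

    model: NetworkModel
    species_ids: list[str]
    index: dict[str, int]
    y_max: np.ndarray
    tau: np.ndarray
    y0: np.ndarray
    # reactions
    rxn_target: np.ndarray  # (n_rxn,) species index
    rxn_weight: np.ndarray
    rxn_is_input: np.ndarray  # bool
    input_target_of_rxn: dict[int, str]  # rxn index -> input species id
    # terms (flattened across reactions)
    term_rxn: np.ndarray  # (n_term,) reaction index
    term_src: np.ndarray  # (n_term,) species index
    term_inhib: np.ndarray  # bool
    term_b: np.ndarray
    term_kn: np.ndarray
    term_n: np.ndarray

    def rhs(
        self,
        y: np.ndarray,
        y_max_eff: np.ndarray,
        input_drive: np.ndarray,
        clamp_drives: bool = True,
    ) -> np.ndarray:
        """dy/dt for the current state; ``input_drive`` carries per-reaction
        constant drives (NaN for non-input reactions)."""
        x = np.maximum(y[self.term_src], 0.0)
        xn = x**self.term_n
        f = self.term_b * xn / (self.term_kn + xn)
        g = np.where(self.term_inhib, 1.0 - f, f)
        prod = np.ones(len(self.rxn_target))
        np.multiply.at(prod, self.term_rxn, g)
        drive = self.rxn_weight * prod
        drive = np.where(self.rxn_is_input, input_drive, drive)
        if clamp_drives:
            drive = np.clip(drive, 0.0, 1.0)
        one_minus = np.ones(len(self.species_ids))
        np.multiply.at(one_minus, self.rxn_target, 1.0 - drive)
        total = 1.0 - one_minus
        return (y_max_eff * total - y) / self.tau


def compile_model(model: NetworkModel) -> CompiledModel:
    idx = model.index
    n_rxn = len(model.reactions)
    rxn_target = np.empty(n_rxn, dtype=np.intp)
    rxn_weight = np.empty(n_rxn)
    rxn_is_input = np.zeros(n_rxn, dtype=bool)
    input_target_of_rxn: dict[int, str] = {}
    term_rxn, term_src, term_inhib, term_b, term_kn, term_n = [], [], [], [], [], []
    for j, r in enumerate(model.reactions):
        rxn_target[j] = idx[r.target]
        rxn_weight[j] = r.weight
        if r.is_input_reaction:
            rxn_is_input[j] = True
            input_target_of_rxn[j] = r.target
            continue
        b, kn = _hill_params(r.ec50, r.n)
        for t in r.terms:
            term_rxn.append(j)
            term_src.append(idx[t.source])
            term_inhib.append(t.sign == INHIBITOR)
            term_b.append(b)
            term_kn.append(kn)
            term_n.append(r.n)
    return CompiledModel(
        model=model,
        species_ids=model.species_ids,
        index=idx,
        y_max=np.array([s.y_max for s in model.species], dtype=float),
        tau=np.array([s.tau for s in model.species], dtype=float),
        y0=np.array([s.y0 for s in model.species], dtype=float),
        rxn_target=rxn_target,
        rxn_weight=rxn_weight,
        rxn_is_input=rxn_is_input,
        input_target_of_rxn=input_target_of_rxn,
        term_rxn=np.asarray(term_rxn, dtype=np.intp),
        term_src=np.asarray(term_src, dtype=np.intp),
        term_inhib=np.asarray(term_inhib, dtype=bool),
        term_b=np.asarray(term_b, dtype=float),
        term_kn=np.asarray(term_kn, dtype=float),
        term_n=np.asarray(term_n, dtype=float),
    )


def _effective_ymax(
    cm: CompiledModel, perturbations: Sequence[PerturbationSpec]
) -> np.ndarray:
    y_max_eff = cm.y_max.copy()
    for p in perturbations:
        if p.node not in cm.index:
            raise KeyError(f"perturbation names unknown node {p.node!r}")
        i = cm.index[p.node]
        if p.mode == "set_ymax":
            y_max_eff[i] = p.value
        elif p.mode == "add_ymax":
            y_max_eff[i] += p.value
        else:
            y_max_eff[i] -= p.value
        if y_max_eff[i] <= 0:
            raise ValueError(
                f"perturbation drives effective Ymax of {p.node!r} to "
                f"{y_max_eff[i]:.4g} <= 0"
            )
    return y_max_eff


def _resolve_input_drive(
    cm: CompiledModel, weights: Mapping[str, float]
) -> np.ndarray:
    drive = np.full(len(cm.rxn_target), np.nan)
    for j, sid in cm.input_target_of_rxn.items():
        drive[j] = weights.get(sid, DEFAULT_BASAL_WEIGHT)
    return drive


def run_protocol(
    model: NetworkModel | CompiledModel,
    stages: Sequence[StageSpec],
    config: SolverConfig | None = None,
    y_init: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate the model through ordered stages; return final activities.

    The initial state is the species' ``y0`` for stage 1 and the carried
    state thereafter. Convergence is judged at the end time by
    ``max |dy/dt| < steady_tol``.
    """
    if not stages:
        raise ValueError("protocol must contain at least one stage")
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    config = config or SolverConfig()
    y = cm.y0.copy() if y_init is None else np.asarray(y_init, dtype=float).copy()

    weights: dict[str, float] = {}
    traj_t: list[np.ndarray] = []
    traj_y: list[np.ndarray] = []
    t_offset = 0.0
    y_max_eff = cm.y_max
    input_drive = _resolve_input_drive(cm, weights)
    for stage in stages:
        weights.update(stage.input_weights)
        unknown = set(stage.input_weights) - set(cm.index)
        if unknown:
            raise KeyError(f"stage input weights name unknown species {sorted(unknown)}")
        y_max_eff = _effective_ymax(cm, stage.perturbations)
        input_drive = _resolve_input_drive(cm, weights)

        def f(t, yy):
            return cm.rhs(yy, y_max_eff, input_drive, config.clamp_drives)

        t_eval = (
            np.linspace(0.0, stage.duration, config.n_trajectory_points)
            if config.n_trajectory_points
            else None
        )
        sol = solve_ivp(
            f,
            (0.0, stage.duration),
            y,
            method=config.method,
            rtol=config.rtol,
            atol=config.atol,
            t_eval=t_eval,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise SolverError(f"integration failed in stage: {sol.message}")
        y = sol.y[:, -1]
        # kill solver-noise negatives; activities are physical in [0, ymax]
        y = np.maximum(y, 0.0)
        if t_eval is not None:
            traj_t.append(sol.t + t_offset)
            traj_y.append(sol.y)
        t_offset += stage.duration

    dydt = cm.rhs(y, y_max_eff, input_drive, config.clamp_drives)
    converged = bool(np.max(np.abs(dydt)) < config.steady_tol)
    return SimulationResult(
        final_activities=dict(zip(cm.species_ids, y.tolist())),
        converged=converged,
        trajectory_t=np.concatenate(traj_t) if traj_t else None,
        trajectory_y=np.concatenate(traj_y, axis=1) if traj_y else None,
        species_ids=cm.species_ids,
    )


def steady_state(
    model: NetworkModel | CompiledModel,
    input_weights: Mapping[str, float] | None = None,
    perturbations: Sequence[PerturbationSpec] = (),
    duration: float = BASAL_DURATION_H + STIMULUS_DURATION_H,
    config: SolverConfig | None = None,
    y_init: np.ndarray | None = None,
) -> SimulationResult:
    """Convenience: one stage at fixed conditions, long enough to settle."""
    stage = StageSpec(
        input_weights=dict(input_weights or {}),
        perturbations=tuple(perturbations),
        duration=duration,
    )
    return run_protocol(model, [stage], config=config, y_init=y_init)


def steady_state_delta(
    model: NetworkModel | CompiledModel,
    baseline_stage: StageSpec,
    test_stage: StageSpec,
    config: SolverConfig | None = None,
) -> dict[str, float]:
    """ΔActivity per species: final(test after baseline) − final(baseline).

    The test stage starts from the baseline end state, mirroring the
    basal-then-stimulus protocol convention.
    """
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    base = run_protocol(cm, [baseline_stage], config=config)
    y_base = np.array([base.final_activities[s] for s in cm.species_ids])
    test = run_protocol(
        cm, [baseline_stage, test_stage], config=config
    )
    return {
        s: test.final_activities[s] - base.final_activities[s]
        for s in cm.species_ids
    }
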