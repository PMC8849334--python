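"""Mechano-adaptive drug-target screen: enumerate single and double Ymax
perturbations, score each by its matrix-content change (MCC) per tension
context, and rank candidates that lower matrix content at low tension while
raising it at high tension.

MCC sums output-node activity changes with protease terms subtracted::

    MCC = sum(ΔActivity_matrix) - sum(ΔActivity_MMP) + sum(ΔActivity_inhibitor)

so a positive MCC means net matrix accumulation. The default output groups
are the matrix proteins (proCI, proCIII, fibronectin, periostin,
osteopontin), the proMMPs (1, 2, 3, 8, 9, 12, 14), and the protease
inhibitors (TIMP1, TIMP2, PAI1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .engine import (
    BASAL_DURATION_H,
    DEFAULT_BASAL_WEIGHT,
    STIMULUS_DURATION_H,
    CompiledModel,
    PerturbationSpec,
    SolverConfig,
    SolverError,
    StageSpec,
    compile_model,
    run_protocol,
)
from .model import NetworkModel

__all__ = [
    "ScreenPerturbation",
    "OutputGroups",
    "DEFAULT_OUTPUT_GROUPS",
    "KNOCKDOWN_YMAX",
    "OVEREXPRESSION_YMAX",
    "enumerate_perturbations",
    "matrix_content_change",
    "run_screen",
    "adaptive_rank",
]

KNOCKDOWN_YMAX = 0.1
OVEREXPRESSION_YMAX = 5.0
KD = "kd"
OE = "oe"


@dataclass(frozen=True)
class ScreenPerturbation:
    """One or two nodes, each knocked down (Ymax=0.1) or overexpressed (Ymax=5)."""

    nodes: tuple[str, ...]
    modes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "modes", tuple(self.modes))
        if len(self.nodes) != len(self.modes):
            raise ValueError("nodes and modes must pair up")
        if len(self.nodes) > 2:
            raise ValueError("only single and double perturbations are supported")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("perturbation nodes must be distinct")
        if any(m not in (KD, OE) for m in self.modes):
            raise ValueError(f"modes must be '{KD}' or '{OE}'")

    @property
    def label(self) -> str:
        return "+".join(f"{m}:{n}" for n, m in zip(self.nodes, self.modes)) or "none"

    def to_perturbation_specs(
        self,
        kd_ymax: float = KNOCKDOWN_YMAX,
        oe_ymax: float = OVEREXPRESSION_YMAX,
    ) -> tuple[PerturbationSpec, ...]:
        return tuple(
            PerturbationSpec(n, "set_ymax", kd_ymax if m == KD else oe_ymax)
            for n, m in zip(self.nodes, self.modes)
        )


@dataclass(frozen=True)
class OutputGroups:
    matrix: tuple[str, ...]
    mmp: tuple[str, ...]
    inhibitor: tuple[str, ...]

    @property
    def all_nodes(self) -> tuple[str, ...]:
        return self.matrix + self.mmp + self.inhibitor


DEFAULT_OUTPUT_GROUPS = OutputGroups(
    matrix=("proCI", "proCIII", "fibronectin", "periostin", "osteopontin"),
    mmp=("proMMP1", "proMMP2", "proMMP3", "proMMP8", "proMMP9", "proMMP12", "proMMP14"),
    inhibitor=("TIMP1", "TIMP2", "PAI1"),
)


def enumerate_perturbations(
    node_ids: Sequence[str],
    include_single: bool = True,
    include_double: bool = True,
) -> list[ScreenPerturbation]:
    """All single (2N) and double (4·C(N,2)) knockdown/overexpression specs.

    Doubles cover KD-KD, OE-OE, and both KD/OE assignments per unordered
    pair; ordering is deterministic in the input node order.
    """
    node_ids = list(node_ids)
    if len(set(node_ids)) != len(node_ids):
        raise ValueError("duplicate node ids in input list")
    out: list[ScreenPerturbation] = []
    if include_single:
        for n in node_ids:
            out.append(ScreenPerturbation((n,), (KD,)))
            out.append(ScreenPerturbation((n,), (OE,)))
    if include_double:
        if len(node_ids) < 2:
            raise ValueError("need >= 2 nodes for double perturbations")
        for a, b in itertools.combinations(node_ids, 2):
            for modes in ((KD, KD), (OE, OE), (KD, OE), (OE, KD)):
                out.append(ScreenPerturbation((a, b), modes))
    return out


def matrix_content_change(
    delta: Mapping[str, float], groups: OutputGroups = DEFAULT_OUTPUT_GROUPS
) -> float:
    """MCC = Σ matrix-group Δ − Σ MMP-group Δ + Σ inhibitor-group Δ."""
    missing = [n for n in groups.all_nodes if n not in delta]
    if missing:
        raise KeyError(f"ΔActivity missing output nodes: {missing}")
    return (
        sum(delta[n] for n in groups.matrix)
        - sum(delta[n] for n in groups.mmp)
        + sum(delta[n] for n in groups.inhibitor)
    )


def run_screen(
    model: NetworkModel | CompiledModel,
    perturbations: Sequence[ScreenPerturbation],
    input_weights: Mapping[str, float] | None = None,
    tensions: Sequence[float] = (0.1, 0.6),
    groups: OutputGroups = DEFAULT_OUTPUT_GROUPS,
    tension_input: str = "Tension",
    kd_ymax: float = KNOCKDOWN_YMAX,
    oe_ymax: float = OVEREXPRESSION_YMAX,
    basal_duration: float = BASAL_DURATION_H,
    perturb_duration: float = STIMULUS_DURATION_H,
    config: SolverConfig | None = None,
    cache_path: str | Path | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Simulate each perturbation at each tension; return MCC records.

    The baseline steady state is computed once per tension and reused. With
    ``cache_path`` set, rows are appended to a TSV as they complete and
    previously cached (perturbation, tension) rows are not recomputed, so a
    long screen is resumable. Per-perturbation solver failures are recorded
    (``error`` column) and the screen continues.
    """
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    out_nodes = list(groups.all_nodes)
    missing = [n for n in out_nodes if n not in cm.index]
    if missing:
        raise KeyError(f"model lacks screen output nodes: {missing}")

    cache_path = Path(cache_path) if cache_path else None
    cached: set[tuple[str, float]] = set()
    cached_rows: list[dict] = []
    if cache_path and cache_path.exists():
        prev = pd.read_csv(cache_path, sep="\t")
        cached_rows = prev.to_dict("records")
        cached = {(r["perturbation"], float(r["tension"])) for r in cached_rows}

    weights = {sid: DEFAULT_BASAL_WEIGHT for sid in cm.model.input_ids}
    weights.update(input_weights or {})

    rows: list[dict] = list(cached_rows)
    for tension in tensions:
        w = dict(weights)
        if tension_input in cm.index:
            w[tension_input] = float(tension)
        basal = run_protocol(
            cm, [StageSpec(input_weights=w, duration=basal_duration)], config=config
        )
        y_basal = np.array([basal.final_activities[s] for s in cm.species_ids])
        settled = run_protocol(
            cm,
            [StageSpec(input_weights=w, duration=perturb_duration)],
            config=config,
            y_init=y_basal,
        )
        base_out = {n: settled.final_activities[n] for n in out_nodes}

        for i, pert in enumerate(perturbations):
            key = (pert.label, float(tension))
            if key in cached:
                continue
            row: dict = {"perturbation": pert.label, "tension": float(tension)}
            try:
                res = run_protocol(
                    cm,
                    [
                        StageSpec(
                            input_weights=w,
                            perturbations=pert.to_perturbation_specs(kd_ymax, oe_ymax),
                            duration=perturb_duration,
                        )
                    ],
                    config=config,
                    y_init=y_basal,
                )
                delta = {
                    n: res.final_activities[n] - base_out[n] for n in out_nodes
                }
                row.update({f"delta_{n}": delta[n] for n in out_nodes})
                row["mcc"] = matrix_content_change(delta, groups)
                row["error"] = ""
            except (SolverError, ValueError, KeyError) as exc:
                row.update({f"delta_{n}": np.nan for n in out_nodes})
                row["mcc"] = np.nan
                row["error"] = str(exc)
            rows.append(row)
            if cache_path:
                pd.DataFrame([row]).to_csv(
                    cache_path,
                    sep="\t",
                    index=False,
                    mode="a",
                    header=not cache_path.exists(),
                )
            if progress and (i + 1) % 500 == 0:
                print(f"tension {tension}: {i + 1}/{len(perturbations)} perturbations")
    return pd.DataFrame(rows)


def adaptive_rank(
    records: pd.DataFrame,
    low_tension: float = 0.1,
    high_tension: float = 0.6,
    convention: str = "quoted",
) -> pd.DataFrame:
    """Filter-and-rank mechano-adaptive scoring over paired-tension records.

    Perturbations with ``mcc < 0`` at low tension and ``mcc > 0`` at high
    tension are retained. Retained low-tension MCCs are ranked ascending
    (most negative first) and high-tension MCCs descending (most positive
    first), with 1-based competition ranks and ties sharing the minimum
    rank. Score conventions:

    - ``quoted``: N_retained − 2·(rank_low + rank_high)
    - ``zero_based``: the same with 0-based ranks (adds 4 to every score)
    - ``clamped``: ``quoted`` clamped below at 0

    The best-adapted perturbation gets the highest score under all three.
    """
    if convention not in ("quoted", "zero_based", "clamped"):
        raise ValueError(f"unknown score convention {convention!r}")
    piv = records.pivot_table(index="perturbation", columns="tension", values="mcc")
    for t in (low_tension, high_tension):
        if t not in piv.columns:
            raise KeyError(f"records lack tension level {t}")
    df = pd.DataFrame(
        {"mcc_low": piv[low_tension], "mcc_high": piv[high_tension]}
    ).dropna()
    retained = df[(df["mcc_low"] < 0) & (df["mcc_high"] > 0)].copy()
    if retained.empty:
        return retained.assign(rank_low=[], rank_high=[], adaptive_score=[])
    n = len(retained)
    retained["rank_low"] = rankdata(retained["mcc_low"], method="min").astype(int)
    retained["rank_high"] = rankdata(-retained["mcc_high"], method="min").astype(int)
    rank_sum = retained["rank_low"] + retained["rank_high"]
    if convention == "zero_based":
        score = n - 2 * (rank_sum - 2)
    else:
        score = n - 2 * rank_sum
        if convention == "clamped":
            score = score.clip(lower=0)
    retained["adaptive_score"] = score
    return retained.sort_values(
        ["adaptive_score", "mcc_low"], ascending=[False, True]
    )
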