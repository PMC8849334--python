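"""Systematic single-node knockdown screens and influence / sensitivity
rankings across tension contexts.

For each tension level, basal conditions (all other inputs 0.1) run for
80 h; each node is then knocked down (Ymax = 0.1) for 240 h from the shared
basal state. ΔActivity is the difference between the knocked-down and the
unperturbed steady state. A node's *knockdown influence* sums |Δ| over all
other nodes when it is knocked down; its *knockdown sensitivity* sums |Δ|
of its own activity over knockdowns of all other nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
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
    SolverError,
    StageSpec,
    compile_model,
    run_protocol,
)
from .model import NetworkModel

__all__ = [
    "KnockdownMatrix",
    "knockdown_screen",
    "influence_sensitivity",
    "top_k",
    "cross_tension_ranking",
    "KNOCKDOWN_YMAX",
    "DEFAULT_SCREEN_TENSIONS",
]

KNOCKDOWN_YMAX = 0.1
DEFAULT_SCREEN_TENSIONS = (0.25, 0.5, 0.75)


@dataclass
class KnockdownMatrix:
    """Δ[i][j]: change of node j's activity under knockdown of node i."""

    tension_weight: float
    delta: pd.DataFrame  # index: knocked-down node, columns: measured node
    baseline: pd.Series  # unperturbed steady-state activities
    failures: dict[str, str]  # knockdown node -> error message


def knockdown_screen(
    model: NetworkModel | CompiledModel,
    tension_weight: float,
    nodes: Sequence[str] | None = None,
    kd_ymax: float = KNOCKDOWN_YMAX,
    tension_input: str = "Tension",
    basal_weight: float = DEFAULT_BASAL_WEIGHT,
    basal_duration: float = BASAL_DURATION_H,
    kd_duration: float = STIMULUS_DURATION_H,
    config: SolverConfig | None = None,
) -> KnockdownMatrix:
    """Knock down each node independently from a shared basal state.

    ``nodes`` restricts which nodes are knocked down (default: all model
    nodes). Solver failures are recorded per knockdown and the screen
    continues; failed rows are NaN.
    """
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    nodes = list(nodes) if nodes is not None else list(cm.species_ids)
    weights = {sid: basal_weight for sid in cm.model.input_ids}
    if tension_input in cm.index:
        weights[tension_input] = tension_weight

    basal = run_protocol(
        cm, [StageSpec(input_weights=weights, duration=basal_duration)], config=config
    )
    y_basal = np.array([basal.final_activities[s] for s in cm.species_ids])
    settled = run_protocol(
        cm,
        [StageSpec(input_weights=weights, duration=kd_duration)],
        config=config,
        y_init=y_basal,
    )
    baseline = pd.Series(settled.final_activities, name="baseline")

    rows = {}
    failures: dict[str, str] = {}
    for node in nodes:
        try:
            res = run_protocol(
                cm,
                [
                    StageSpec(
                        input_weights=weights,
                        perturbations=(PerturbationSpec(node, "set_ymax", kd_ymax),),
                        duration=kd_duration,
                    )
                ],
                config=config,
                y_init=y_basal,
            )
            rows[node] = pd.Series(res.final_activities) - baseline
        except (SolverError, ValueError, KeyError) as exc:
            failures[node] = str(exc)
            rows[node] = pd.Series(np.nan, index=baseline.index)
    delta = pd.DataFrame(rows).T.loc[nodes, list(cm.species_ids)]
    return KnockdownMatrix(
        tension_weight=tension_weight,
        delta=delta,
        baseline=baseline,
        failures=failures,
    )


def influence_sensitivity(
    matrix: KnockdownMatrix, exclude_self: bool = True
) -> pd.DataFrame:
    """Influence / sensitivity scores with dense ranks (rank 1 = top score).

    By default the self term Δ[i][i] — a node's own suppression — is
    excluded from both sums; the switch admits the include-self variant.
    """
    d = matrix.delta.abs()
    if exclude_self:
        d = d.copy()
        for node in d.index:
            if node in d.columns:
                d.loc[node, node] = 0.0
    influence = d.sum(axis=1)
    sensitivity = d.sum(axis=0)
    df = pd.DataFrame(
        {
            "influence": influence,
            "sensitivity": sensitivity.reindex(influence.index),
        }
    )
    df["influence_rank"] = df["influence"].rank(method="dense", ascending=False).astype(int)
    df["sensitivity_rank"] = (
        df["sensitivity"].rank(method="dense", ascending=False).astype(int)
    )
    return df


def top_k(scores: pd.DataFrame, metric: str, k: int = 10) -> list[str]:
    """Top-k node ids by a score column; ties broken alphabetically for display."""
    ordered = scores.assign(_id=scores.index.astype(str)).sort_values(
        [metric, "_id"], ascending=[False, True]
    )
    return list(ordered.head(k).index)


def cross_tension_ranking(
    scores_by_tension: Mapping[float, pd.DataFrame],
    metric: str = "influence",
    k: int = 10,
) -> pd.DataFrame:
    """Union of top-k nodes per tension with the tension of first entry.

    Returns one row per node in the union: the lowest tension at which it
    ranked top-k, plus its score and rank trajectory across tensions.
    """
    if len(scores_by_tension) < 2:
        raise ValueError("need scores at >= 2 tension levels")
    tensions = sorted(scores_by_tension)
    union: dict[str, float] = {}
    for t in tensions:
        for node in top_k(scores_by_tension[t], metric, k):
            union.setdefault(node, t)
    rows = []
    for node, first_t in union.items():
        row = {"node": node, "metric": metric, "first_top_k_tension": first_t}
        for t in tensions:
            df = scores_by_tension[t]
            row[f"score_at_{t}"] = float(df.loc[node, metric])
            row[f"rank_at_{t}"] = int(df.loc[node, f"{metric}_rank"])
        rows.append(row)
    return pd.DataFrame(rows).set_index("node")
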