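"""Qualitative validation: score simulated responses against curated
observations of increase / decrease / no-change in protein activity.

The protocol mirrors the standard in-vitro setting: basal conditions (all
inputs at 0.1, tension at 0.4 as the culture-plastic surrogate) for 80 h,
then one stimulus raised to 0.8 for 240 h. The simulated change in each
measured node is binned at a ±threshold (default 0.05 on the normalized
activity scale) and compared with the observed direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import (
    BASAL_DURATION_H,
    DEFAULT_BASAL_WEIGHT,
    STIMULUS_DURATION_H,
    CompiledModel,
    SolverConfig,
    StageSpec,
    compile_model,
    steady_state_delta,
)
from .model import NetworkModel

__all__ = [
    "ValidationRecord",
    "ValidationReport",
    "classify_change",
    "load_validation_records",
    "save_validation_records",
    "run_validation",
    "threshold_sweep",
    "INCREASE",
    "DECREASE",
    "NO_CHANGE",
    "DEFAULT_TENSION_WEIGHT",
    "DEFAULT_STIMULUS_WEIGHT",
    "DEFAULT_THRESHOLD",
]

INCREASE = "increase"
DECREASE = "decrease"
NO_CHANGE = "no_change"
CLASSES = (INCREASE, DECREASE, NO_CHANGE)

DEFAULT_TENSION_WEIGHT = 0.4
DEFAULT_STIMULUS_WEIGHT = 0.8
DEFAULT_THRESHOLD = 0.05


@dataclass(frozen=True)
class ValidationRecord:
    stimulus: str
    measured_node: str
    observed: str
    citation: str = ""

    def __post_init__(self) -> None:
        if self.observed not in CLASSES:
            raise ValueError(
                f"observed must be one of {CLASSES}, got {self.observed!r}"
            )


@dataclass
class ValidationReport:
    """Per-record predictions plus class-wise accuracy bookkeeping."""

    records: pd.DataFrame  # stimulus, measured_node, observed, predicted, delta, match, category
    threshold: float

    def accuracy(self, category: str | None = None) -> tuple[int, int, float]:
        """(matches, total, fraction) over all records or one node category."""
        df = self.records
        if category is not None:
            df = df[df["category"] == category]
        total = len(df)
        matches = int(df["match"].sum())
        return matches, total, (matches / total if total else float("nan"))

    @property
    def confusion(self) -> pd.DataFrame:
        return pd.crosstab(
            self.records["observed"], self.records["predicted"], dropna=False
        ).reindex(index=CLASSES, columns=CLASSES, fill_value=0)

    def summary(self) -> str:
        lines = [f"validation at threshold {self.threshold:g}"]
        for cat in ("output", "intermediate"):
            m, t, f = self.accuracy(cat)
            if t:
                lines.append(f"  {cat:13s}: {m}/{t} = {100 * f:.1f}%")
        m, t, f = self.accuracy()
        lines.append(f"  {'overall':13s}: {m}/{t} = {100 * f:.1f}%")
        return "\n".join(lines)


def classify_change(delta: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Bin a ΔActivity into increase / decrease / no_change.

    The comparison is inclusive: |delta| equal to the threshold counts as a
    change; the threshold is absolute on the normalized 0–1 activity scale.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if delta >= threshold:
        return INCREASE
    if delta <= -threshold:
        return DECREASE
    return NO_CHANGE


def load_validation_records(path: str | Path) -> list[ValidationRecord]:
    """Read a validation table TSV (columns: stimulus, node, observed, citation)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    node_col = "node" if "node" in df.columns else "measured_node"
    return [
        ValidationRecord(
            stimulus=str(r["stimulus"]),
            measured_node=str(r[node_col]),
            observed=str(r["observed"]),
            citation=str(r.get("citation", "")) if "citation" in df.columns else "",
        )
        for _, r in df.iterrows()
    ]


def save_validation_records(
    records: Sequence[ValidationRecord], path: str | Path
) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "stimulus": [r.stimulus for r in records],
            "node": [r.measured_node for r in records],
            "observed": [r.observed for r in records],
            "citation": [r.citation for r in records],
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def simulated_deltas(
    model: NetworkModel | CompiledModel,
    stimuli: Iterable[str],
    tension_input: str = "Tension",
    tension_weight: float = DEFAULT_TENSION_WEIGHT,
    stimulus_weight: float = DEFAULT_STIMULUS_WEIGHT,
    basal_weight: float = DEFAULT_BASAL_WEIGHT,
    config: SolverConfig | None = None,
) -> dict[str, dict[str, float]]:
    """ΔActivity per node for each stimulus under the validation protocol.

    One baseline + one stimulated simulation per distinct stimulus; tension
    stays at its surrogate weight unless tension itself is the stimulus.
    """
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    has_tension = tension_input in cm.index
    base_weights = {sid: basal_weight for sid in cm.model.input_ids}
    if has_tension:
        base_weights[tension_input] = tension_weight
    out: dict[str, dict[str, float]] = {}
    for stim in dict.fromkeys(stimuli):
        if stim not in cm.index:
            raise KeyError(f"validation record references unknown node {stim!r}")
        stim_weights = dict(base_weights)
        stim_weights[stim] = stimulus_weight
        out[stim] = steady_state_delta(
            cm,
            StageSpec(input_weights=base_weights, duration=BASAL_DURATION_H),
            StageSpec(input_weights=stim_weights, duration=STIMULUS_DURATION_H),
            config=config,
        )
    return out


def _report_from_deltas(
    model: NetworkModel,
    records: Sequence[ValidationRecord],
    deltas: Mapping[str, Mapping[str, float]],
    threshold: float,
) -> ValidationReport:
    cat = {s.id: s.category for s in model.species}
    rows = []
    for r in records:
        if r.measured_node not in cat:
            raise KeyError(f"validation record references unknown node {r.measured_node!r}")
        d = deltas[r.stimulus][r.measured_node]
        pred = classify_change(d, threshold)
        rows.append(
            {
                "stimulus": r.stimulus,
                "measured_node": r.measured_node,
                "observed": r.observed,
                "predicted": pred,
                "delta": d,
                "match": pred == r.observed,
                "category": cat[r.measured_node],
                "citation": r.citation,
            }
        )
    return ValidationReport(records=pd.DataFrame(rows), threshold=threshold)


def run_validation(
    model: NetworkModel,
    records: Sequence[ValidationRecord],
    tension_input: str = "Tension",
    tension_weight: float = DEFAULT_TENSION_WEIGHT,
    stimulus_weight: float = DEFAULT_STIMULUS_WEIGHT,
    threshold: float = DEFAULT_THRESHOLD,
    config: SolverConfig | None = None,
) -> ValidationReport:
    """Score the model against a curated table of qualitative observations."""
    deltas = simulated_deltas(
        model,
        (r.stimulus for r in records),
        tension_input=tension_input,
        tension_weight=tension_weight,
        stimulus_weight=stimulus_weight,
        config=config,
    )
    return _report_from_deltas(model, records, deltas, threshold)


def threshold_sweep(
    model: NetworkModel,
    records: Sequence[ValidationRecord],
    thresholds: Sequence[float] = tuple(np.round(np.arange(0.01, 0.101, 0.01), 3)),
    tension_input: str = "Tension",
    tension_weight: float = DEFAULT_TENSION_WEIGHT,
    stimulus_weight: float = DEFAULT_STIMULUS_WEIGHT,
    config: SolverConfig | None = None,
) -> pd.DataFrame:
    """Accuracy per classification threshold (simulations run once, rebinned).

    Returns a tidy frame (threshold, category, matches, total, accuracy,
    deviation_from_median) where the deviation is in accuracy percentage
    points within each category.
    """
    thresholds = list(thresholds)
    if any(t <= 0 for t in thresholds) or sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be strictly positive and sorted")
    deltas = simulated_deltas(
        model,
        (r.stimulus for r in records),
        tension_input=tension_input,
        tension_weight=tension_weight,
        stimulus_weight=stimulus_weight,
        config=config,
    )
    rows = []
    for t in thresholds:
        rep = _report_from_deltas(model, records, deltas, t)
        for cat in ("output", "intermediate", None):
            m, tot, f = rep.accuracy(cat)
            if tot:
                rows.append(
                    {
                        "threshold": t,
                        "category": cat or "all",
                        "matches": m,
                        "total": tot,
                        "accuracy": f,
                    }
                )
    df = pd.DataFrame(rows)
    df["deviation_from_median"] = df.groupby("category")["accuracy"].transform(
        lambda a: 100 * (a - a.median())
    )
    return df
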