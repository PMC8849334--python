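"""Mechano-chemo interaction analysis: tension-modulated dose-response
curves, normalized AUC, the amplified / dampened / reversed taxonomy, and
distribution statistics (two-sample KS with Benjamini-Hochberg correction).

For a fixed tension level, a biochemical input is swept over a dose grid
(0 to 1 in 0.01 steps by default); every dose is simulated independently
from a common basal state. Each node's curve is baseline-subtracted at dose
0 and summarized by its trapezoidal area (AUC, sign-preserving so
inhibitory responses carry negative area). The change in AUC between basal
tension (0.1) and an elevated level classifies the interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from statsmodels.stats.multitest import multipletests

from .engine import (
    BASAL_DURATION_H,
    DEFAULT_BASAL_WEIGHT,
    STIMULUS_DURATION_H,
    CompiledModel,
    SolverConfig,
    StageSpec,
    compile_model,
    run_protocol,
)
from .model import NetworkModel

__all__ = [
    "DoseResponseCurve",
    "dose_sweep",
    "auc",
    "classify_interaction",
    "interaction_table",
    "interaction_summary",
    "ks_bh",
    "AMPLIFIED",
    "DAMPENED",
    "REVERSED",
    "UNCHANGED",
    "DEFAULT_DOSES",
    "DEFAULT_AUC_THRESHOLD",
    "BASAL_TENSION",
]

AMPLIFIED = "amplified"
DAMPENED = "dampened"
REVERSED = "reversed"
UNCHANGED = "unchanged"

DEFAULT_DOSES = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 4)
DEFAULT_AUC_THRESHOLD = 0.05
BASAL_TENSION = 0.1
DEFAULT_KS_PAIRS = ((0.2, 0.5), (0.2, 0.9), (0.5, 0.9))


@dataclass
class DoseResponseCurve:
    """Steady-state activities over a dose grid at one tension level."""

    input_id: str
    tension_weight: float
    doses: np.ndarray
    activities: pd.DataFrame  # index: dose, columns: species

    @property
    def normalized(self) -> pd.DataFrame:
        """Curve minus its dose-0 row; exactly 0 at dose 0 by construction."""
        return self.activities - self.activities.iloc[0]

    def auc(self) -> pd.Series:
        """Signed trapezoidal area of the normalized curve per node."""
        return auc(self.normalized.to_numpy(), self.doses, self.activities.columns)


def dose_sweep(
    model: NetworkModel | CompiledModel,
    input_id: str,
    tension_weight: float,
    doses: np.ndarray = DEFAULT_DOSES,
    tension_input: str = "Tension",
    basal_weight: float = DEFAULT_BASAL_WEIGHT,
    basal_duration: float = BASAL_DURATION_H,
    stimulus_duration: float = STIMULUS_DURATION_H,
    config: SolverConfig | None = None,
) -> DoseResponseCurve:
    """Simulate steady states across the dose grid at one tension level.

    All other inputs sit at the basal weight; tension is held at its level
    through both the shared 80 h basal stage and each 240 h dose stage. Each
    dose restarts from the common basal end state.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.ndim != 1 or len(doses) < 2 or np.any(np.diff(doses) <= 0):
        raise ValueError("dose grid must be strictly increasing with >= 2 points")
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    if input_id not in cm.index:
        raise KeyError(f"unknown input {input_id!r}")
    base_weights = {sid: basal_weight for sid in cm.model.input_ids}
    if tension_input in cm.index:
        base_weights[tension_input] = tension_weight
    basal = run_protocol(
        cm,
        [StageSpec(input_weights=base_weights, duration=basal_duration)],
        config=config,
    )
    y_basal = np.array([basal.final_activities[s] for s in cm.species_ids])

    rows = []
    for dose in doses:
        w = dict(base_weights)
        w[input_id] = float(dose)
        res = run_protocol(
            cm,
            [StageSpec(input_weights=w, duration=stimulus_duration)],
            config=config,
            y_init=y_basal,
        )
        rows.append([res.final_activities[s] for s in cm.species_ids])
    activities = pd.DataFrame(rows, index=pd.Index(doses, name="dose"),
                              columns=cm.species_ids)
    return DoseResponseCurve(
        input_id=input_id,
        tension_weight=tension_weight,
        doses=doses,
        activities=activities,
    )


def auc(values: np.ndarray, doses: np.ndarray, columns=None):
    """Trapezoidal integral of (possibly multi-column) curves over the dose axis."""
    values = np.asarray(values, dtype=float)
    doses = np.asarray(doses, dtype=float)
    if values.shape[0] != len(doses):
        raise ValueError(
            f"curve length {values.shape[0]} does not match grid length {len(doses)}"
        )
    area = np.trapezoid(values, doses, axis=0)
    if columns is not None:
        return pd.Series(area, index=columns)
    return area if values.ndim > 1 else float(area)


def classify_interaction(
    auc_basal: float,
    auc_elevated: float,
    threshold: float = DEFAULT_AUC_THRESHOLD,
    mode: str = "magnitude",
) -> str:
    """Categorize how tension reshapes a node's total dose response.

    Reversal takes precedence: opposite AUC signs with |ΔAUC| at or above
    the threshold. Otherwise, in ``magnitude`` mode a response whose
    magnitude grew is amplified and one that shrank is dampened (so an
    inhibitory response that deepens counts as amplified); ``raw_delta``
    mode uses the sign of ΔAUC directly. Below threshold: unchanged.
    """
    if mode not in ("magnitude", "raw_delta"):
        raise ValueError(f"unknown classification mode {mode!r}")
    delta = auc_elevated - auc_basal
    if auc_basal * auc_elevated < 0 and abs(delta) >= threshold:
        return REVERSED
    if abs(delta) < threshold:
        return UNCHANGED
    if mode == "raw_delta":
        return AMPLIFIED if delta > 0 else DAMPENED
    return AMPLIFIED if abs(auc_elevated) > abs(auc_basal) else DAMPENED


def interaction_table(
    curves: Mapping[float, DoseResponseCurve],
    basal_tension: float = BASAL_TENSION,
    threshold: float = DEFAULT_AUC_THRESHOLD,
    mode: str = "magnitude",
) -> pd.DataFrame:
    """AUC / ΔAUC / category records for one input across tension levels.

    ``curves`` maps tension weight -> curve (must include the basal level).
    """
    if basal_tension not in curves:
        raise KeyError(f"basal tension {basal_tension} missing from curves")
    auc_basal = curves[basal_tension].auc()
    rows = []
    for tension, curve in sorted(curves.items()):
        a = curve.auc()
        for node in a.index:
            rows.append(
                {
                    "input": curve.input_id,
                    "node": node,
                    "tension": tension,
                    "auc": a[node],
                    "delta_auc": a[node] - auc_basal[node],
                    "category": classify_interaction(
                        auc_basal[node], a[node], threshold, mode
                    ),
                }
            )
    return pd.DataFrame(rows)


def run_tension_sweeps(
    model: NetworkModel | CompiledModel,
    inputs: Sequence[str],
    tension_levels: Sequence[float] = tuple(np.round(np.arange(0.1, 0.91, 0.1), 2)),
    doses: np.ndarray = DEFAULT_DOSES,
    tension_input: str = "Tension",
    config: SolverConfig | None = None,
) -> dict[str, dict[float, DoseResponseCurve]]:
    """Full sweep: input x tension -> dose-response curve."""
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    return {
        inp: {
            t: dose_sweep(
                cm, inp, t, doses=doses, tension_input=tension_input, config=config
            )
            for t in tension_levels
        }
        for inp in inputs
    }


def interaction_summary(
    sweeps: Mapping[str, Mapping[float, DoseResponseCurve]],
    basal_tension: float = BASAL_TENSION,
    threshold: float = DEFAULT_AUC_THRESHOLD,
    mode: str = "magnitude",
    denominator: str = "all_nodes",
    exclude_nodes: Sequence[str] = (),
) -> pd.DataFrame:
    """Per (input, tension): fraction of node AUCs in each category vs basal.

    ``denominator`` is ``all_nodes`` (every model node) or ``non_input``
    (input nodes excluded); numerators and denominators are reported so
    either convention is checkable downstream.
    """
    rows = []
    for inp, curves in sweeps.items():
        table = interaction_table(curves, basal_tension, threshold, mode)
        if denominator == "non_input":
            input_ids = set(sweeps.keys())
            table = table[~table["node"].isin(input_ids)]
        elif denominator != "all_nodes":
            raise ValueError(f"unknown denominator convention {denominator!r}")
        if exclude_nodes:
            table = table[~table["node"].isin(set(exclude_nodes))]
        for tension, sub in table.groupby("tension"):
            n = len(sub)
            counts = sub["category"].value_counts()
            sizable = int(n - counts.get(UNCHANGED, 0))
            rows.append(
                {
                    "input": inp,
                    "tension": tension,
                    "n_nodes": n,
                    "n_amplified": int(counts.get(AMPLIFIED, 0)),
                    "n_dampened": int(counts.get(DAMPENED, 0)),
                    "n_reversed": int(counts.get(REVERSED, 0)),
                    "n_sizable": sizable,
                    "frac_amplified": counts.get(AMPLIFIED, 0) / n,
                    "frac_dampened": counts.get(DAMPENED, 0) / n,
                    "frac_reversed": counts.get(REVERSED, 0) / n,
                    "frac_sizable": sizable / n,
                }
            )
    return pd.DataFrame(rows)


def category_switches(
    sweeps: Mapping[str, Mapping[float, DoseResponseCurve]],
    basal_tension: float = BASAL_TENSION,
    threshold: float = DEFAULT_AUC_THRESHOLD,
    mode: str = "magnitude",
) -> pd.DataFrame:
    """Count nodes switching category between adjacent tension levels, per input."""
    rows = []
    for inp, curves in sweeps.items():
        table = interaction_table(curves, basal_tension, threshold, mode)
        piv = table.pivot(index="node", columns="tension", values="category")
        tensions = sorted(piv.columns)
        for lo, hi in zip(tensions[:-1], tensions[1:]):
            changed = piv[lo] != piv[hi]
            amp_to_damp = (piv[lo] == AMPLIFIED) & (piv[hi] == DAMPENED)
            rows.append(
                {
                    "input": inp,
                    "tension_from": lo,
                    "tension_to": hi,
                    "n_switching": int(changed.sum()),
                    "n_amplified_to_dampened": int(amp_to_damp.sum()),
                }
            )
    return pd.DataFrame(rows)


def delta_auc_vectors(
    sweeps: Mapping[str, Mapping[float, DoseResponseCurve]],
    basal_tension: float = BASAL_TENSION,
) -> dict[str, dict[float, np.ndarray]]:
    """Per input and tension, the ΔAUC vector over all nodes (vs basal tension)."""
    out: dict[str, dict[float, np.ndarray]] = {}
    for inp, curves in sweeps.items():
        base = curves[basal_tension].auc()
        out[inp] = {
            t: (c.auc() - base).to_numpy() for t, c in curves.items()
        }
    return out


def ks_bh(
    delta_sets: Mapping[str, Mapping[float, np.ndarray]],
    pairs: Sequence[tuple[float, float]] = DEFAULT_KS_PAIRS,
) -> pd.DataFrame:
    """Two-sample KS tests between ΔAUC distributions, BH-adjusted jointly.

    For each input and each tension pair, the asymptotic two-sided KS
    statistic compares the node-wise ΔAUC distributions; all tests are
    corrected together with Benjamini-Hochberg.
    """
    rows = []
    for inp, by_tension in delta_sets.items():
        for lo, hi in pairs:
            a, b = np.asarray(by_tension[lo]), np.asarray(by_tension[hi])
            if len(a) == 0 or len(b) == 0:
                raise ValueError(f"empty ΔAUC vector for input {inp!r}")
            res = ks_2samp(a, b, method="asymp")
            rows.append(
                {
                    "input": inp,
                    "tension_a": lo,
                    "tension_b": hi,
                    "ks_statistic": float(res.statistic),
                    "p_value": float(res.pvalue),
                }
            )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
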