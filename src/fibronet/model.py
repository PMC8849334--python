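"""Network model definitions, rule parsing, tabular I/O, and graph topology.

A signaling network is described by two tables: a *species* table (one row
per node, carrying the maximal activity ``y_max``, the relaxation time
constant ``tau`` in hours, a coarse category, and the initial activity
``y0``) and a *reactions* table (one row per reaction, each a conjunction of
signed sources driving a single target). Boolean OR between regulators is
expressed only by listing several reactions with the same target; AND is the
``&`` conjunction inside one rule; NOT is the ``!`` prefix on a source.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "SpeciesDef",
    "Term",
    "ReactionDef",
    "NetworkModel",
    "RuleSyntaxError",
    "ModelValidationError",
    "parse_rule",
    "serialize_rule",
    "load_model",
    "save_model",
    "export_graph",
    "model_graph",
    "topology_metrics",
]

ACTIVATOR = "activator"
INHIBITOR = "inhibitor"

DEFAULT_EC50 = 0.5
DEFAULT_N = 1.4
DEFAULT_WEIGHT = 1.0
DEFAULT_TAU = 1.0
DEFAULT_YMAX = 1.0

CATEGORIES = ("input", "intermediate", "output")


class RuleSyntaxError(ValueError):
    """Raised when a reaction rule string does not match the grammar."""


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


@dataclass(frozen=True)
class SpeciesDef:
    """A network node.

    Parameters follow the normalized-activity convention: ``y_max`` is the
    maximal fractional activity (1 by default; knockdown lowers it,
    overexpression raises it), ``tau`` is the relaxation time constant in
    hours (0.1 / 1 / 10 for signaling, receptor, and transcription-level
    species respectively), and ``y0`` the initial activity.
    """

    id: str
    display_name: str = ""
    y_max: float = DEFAULT_YMAX
    tau: float = DEFAULT_TAU
    category: str = "intermediate"
    y0: float = 0.0

    def __post_init__(self) -> None:
        if not self.id or not str(self.id).strip():
            raise ModelValidationError("species id must be non-empty")
        if self.y_max <= 0:
            raise ModelValidationError(f"species {self.id}: y_max must be > 0")
        if self.tau <= 0:
            raise ModelValidationError(f"species {self.id}: tau must be > 0")
        if not (0.0 <= self.y0 <= self.y_max):
            raise ModelValidationError(
                f"species {self.id}: y0 must lie in [0, y_max]"
            )
        if self.category not in CATEGORIES:
            raise ModelValidationError(
                f"species {self.id}: category {self.category!r} not one of {CATEGORIES}"
            )


@dataclass(frozen=True)
class Term:
    """One signed source inside a reaction (AND-conjoined with its siblings)."""

    source: str
    sign: str = ACTIVATOR

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATOR, INHIBITOR):
            raise ModelValidationError(f"invalid term sign {self.sign!r}")


@dataclass(frozen=True)
class ReactionDef:
    """A single reaction: ``w * AND(terms) => target``.

    An empty term list marks an *input reaction*: a constant drive equal to
    its weight (the stimulus level itself), applied to an input node.
    """

    target: str
    terms: tuple[Term, ...] = ()
    weight: float = DEFAULT_WEIGHT
    ec50: float = DEFAULT_EC50
    n: float = DEFAULT_N

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        if not (0.0 <= self.weight <= 1.0):
            raise ModelValidationError(
                f"reaction -> {self.target}: weight must be in [0, 1]"
            )
        if not (0.0 < self.ec50 < 1.0):
            raise ModelValidationError(
                f"reaction -> {self.target}: ec50 must be in (0, 1)"
            )
        if self.n <= 0:
            raise ModelValidationError(f"reaction -> {self.target}: n must be > 0")
        if abs(2.0 * self.ec50**self.n - 1.0) < 1e-9:
            raise ModelValidationError(
                f"reaction -> {self.target}: 2*ec50^n = 1 is singular for the "
                "normalized Hill parameterization"
            )

    @property
    def is_input_reaction(self) -> bool:
        return len(self.terms) == 0

    @property
    def rule(self) -> str:
        return serialize_rule(self)


_TOKEN_RE = re.compile(r"\s*(=>|&|!|[A-Za-z_][A-Za-z0-9_.\-]*|\S)")


def _tokenize(rule_text: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(rule_text):
        m = _TOKEN_RE.match(rule_text, pos)
        if m is None:
            break
        tok = m.group(1)
        if len(tok) == 1 and not re.match(r"[A-Za-z_&!]|=", tok):
            raise RuleSyntaxError(
                f"unknown character {tok!r} at position {m.start(1)} in rule {rule_text!r}"
            )
        tokens.append(tok)
        pos = m.end()
    return tokens


def parse_rule(
    rule_text: str,
    weight: float = DEFAULT_WEIGHT,
    ec50: float = DEFAULT_EC50,
    n: float = DEFAULT_N,
) -> ReactionDef:
    """Parse ``[!]ID ('&' [!]ID)* '=>' ID`` (or ``'=>' ID`` for an input drive).

    ``!`` marks an inhibitory source. OR never appears inside a rule; it is
    expressed by multiple rules sharing a target.
    """
    tokens = _tokenize(rule_text)
    if not tokens:
        raise RuleSyntaxError(f"empty rule: {rule_text!r}")
    if "=>" not in tokens:
        raise RuleSyntaxError(f"missing '=>' in rule {rule_text!r}")
    arrow = tokens.index("=>")
    lhs, rhs = tokens[:arrow], tokens[arrow + 1 :]
    if len(rhs) != 1 or rhs[0] in ("&", "!", "=>"):
        raise RuleSyntaxError(
            f"rule {rule_text!r} must name exactly one target after '=>'"
        )
    target = rhs[0]

    terms: list[Term] = []
    i = 0
    expect_term = True
    while i < len(lhs):
        if not expect_term:
            if lhs[i] != "&":
                raise RuleSyntaxError(
                    f"expected '&' at token {i + 1} in rule {rule_text!r}"
                )
            i += 1
            expect_term = True
            continue
        sign = ACTIVATOR
        if lhs[i] == "!":
            sign = INHIBITOR
            i += 1
        if i >= len(lhs) or lhs[i] in ("&", "!"):
            raise RuleSyntaxError(
                f"expected species id at token {i + 1} in rule {rule_text!r}"
            )
        terms.append(Term(lhs[i], sign))
        i += 1
        expect_term = False
    if expect_term and lhs:
        raise RuleSyntaxError(
            f"dangling '&' at token {len(lhs)} in rule {rule_text!r}"
        )
    return ReactionDef(target=target, terms=tuple(terms), weight=weight, ec50=ec50, n=n)


def serialize_rule(reaction: ReactionDef) -> str:
    """Inverse of :func:`parse_rule` (modulo whitespace)."""
    lhs = " & ".join(
        ("!" if t.sign == INHIBITOR else "") + t.source for t in reaction.terms
    )
    return f"{lhs} => {reaction.target}" if lhs else f"=> {reaction.target}"


@dataclass
class NetworkModel:
    """Validated species + reactions; the executable network."""

    species: list[SpeciesDef]
    reactions: list[ReactionDef]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- indexing helpers -------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    @property
    def input_ids(self) -> list[str]:
        return [s.id for s in self.species if s.category == "input"]

    @property
    def output_ids(self) -> list[str]:
        return [s.id for s in self.species if s.category == "output"]

    def species_by_id(self, sid: str) -> SpeciesDef:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def reactions_targeting(self, sid: str) -> list[ReactionDef]:
        return [r for r in self.reactions if r.target == sid]

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            species=list(self.species),
            reactions=list(self.reactions),
            metadata=dict(self.metadata),
        )

    def with_reaction(self, reaction: ReactionDef) -> "NetworkModel":
        """Return a copy with one reaction appended (original untouched).

        A duplicate rule is allowed — the engine OR-combines it — but warned
        about, since it is usually an authoring mistake.
        """
        if any(serialize_rule(r) == serialize_rule(reaction) for r in self.reactions):
            warnings.warn(
                f"duplicate rule {serialize_rule(reaction)!r}; drives will be OR-combined",
                stacklevel=2,
            )
        return NetworkModel(
            species=list(self.species),
            reactions=list(self.reactions) + [reaction],
            metadata=dict(self.metadata),
        )

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        ids = [s.id for s in self.species]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ModelValidationError(f"duplicate species ids: {sorted(dupes)}")
        known = set(ids)
        targeted = set()
        for r in self.reactions:
            if r.target not in known:
                raise ModelValidationError(
                    f"rule {serialize_rule(r)!r} targets unknown species {r.target!r}"
                )
            for t in r.terms:
                if t.source not in known:
                    raise ModelValidationError(
                        f"rule {serialize_rule(r)!r} references unknown species "
                        f"{t.source!r}"
                    )
            targeted.add(r.target)
        orphans = [
            s.id
            for s in self.species
            if s.category != "input" and s.id not in targeted
        ]
        if orphans:
            warnings.warn(
                f"orphan non-input species with no incoming reaction: {orphans}",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# Tabular I/O. Canonical on-disk format: two TSV files, <base>.species.tsv and
# <base>.reactions.tsv. XLSX workbooks with sheets "species" and "reactions"
# are also read (the layout Netflux-style model workbooks use).
# ---------------------------------------------------------------------------

_SPECIES_COLS = {"id", "name", "ymax", "tau", "category", "y0"}
_REACTION_COLS = {"rule", "weight", "n", "ec50"}


def _norm_cols(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def _species_from_frame(df: pd.DataFrame) -> list[SpeciesDef]:
    df = _norm_cols(df)
    if "id" not in df.columns:
        raise ModelValidationError("species table lacks an 'id' column")
    out: list[SpeciesDef] = []
    for _, row in df.iterrows():
        def cell(col, default):
            if col not in df.columns:
                return default
            v = row[col]
            return default if pd.isna(v) or v == "" else v

        try:
            out.append(
                SpeciesDef(
                    id=str(row["id"]).strip(),
                    display_name=str(cell("name", "")),
                    y_max=float(cell("ymax", DEFAULT_YMAX)),
                    tau=float(cell("tau", DEFAULT_TAU)),
                    category=str(cell("category", "intermediate")).strip().lower(),
                    y0=float(cell("y0", 0.0)),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ModelValidationError(
                f"species row {row['id']!r}: non-numeric parameter ({exc})"
            ) from exc
    return out


def _reactions_from_frame(
    df: pd.DataFrame,
    default_ec50: float = DEFAULT_EC50,
    default_n: float = DEFAULT_N,
) -> list[ReactionDef]:
    df = _norm_cols(df)
    if "rule" not in df.columns:
        raise ModelValidationError("reactions table lacks a 'rule' column")
    out: list[ReactionDef] = []
    for _, row in df.iterrows():
        def cell(col, default):
            if col not in df.columns:
                return default
            v = row[col]
            return default if pd.isna(v) or v == "" else v

        try:
            weight = float(cell("weight", DEFAULT_WEIGHT))
            n = float(cell("n", default_n))
            ec50 = float(cell("ec50", default_ec50))
        except (TypeError, ValueError) as exc:
            raise ModelValidationError(
                f"reaction row {row['rule']!r}: non-numeric parameter ({exc})"
            ) from exc
        # tolerate Excel's leading-apostrophe text escape on rules like "=> X"
        out.append(
            parse_rule(str(row["rule"]).lstrip("'"), weight=weight, ec50=ec50, n=n)
        )
    return out


def _resolve_paths(path: str | Path) -> tuple[Path, Path] | Path:
    """Map a user-supplied path to (species_tsv, reactions_tsv) or an xlsx."""
    p = Path(path)
    if p.suffix.lower() in (".xlsx", ".xlsm"):
        return p
    name = p.name
    if name.endswith(".species.tsv") or name.endswith(".species.csv"):
        base = p.with_name(name.rsplit(".species.", 1)[0])
        ext = name.rsplit(".", 1)[1]
        return (p, base.parent / f"{base.name}.reactions.{ext}")
    if name.endswith(".reactions.tsv") or name.endswith(".reactions.csv"):
        base = p.with_name(name.rsplit(".reactions.", 1)[0])
        ext = name.rsplit(".", 1)[1]
        return (base.parent / f"{base.name}.species.{ext}", p)
    # base prefix: try tsv then csv
    for ext in ("tsv", "csv"):
        sp = p.parent / f"{p.name}.species.{ext}"
        rx = p.parent / f"{p.name}.reactions.{ext}"
        if sp.exists() and rx.exists():
            return (sp, rx)
    raise FileNotFoundError(
        f"no model found at {path!r}: expected <base>.species.tsv + "
        "<base>.reactions.tsv (or .csv) or an .xlsx workbook"
    )


def load_model(
    path: str | Path,
    default_ec50: float = DEFAULT_EC50,
    default_n: float = DEFAULT_N,
) -> NetworkModel:
    """Load a model from TSV/CSV table pairs or an xlsx workbook.

    Extra annotation columns (references, notes) are ignored; missing
    parameter cells take the documented defaults.
    """
    resolved = _resolve_paths(path)
    if isinstance(resolved, Path):  # xlsx workbook
        species_df = pd.read_excel(resolved, sheet_name="species")
        reactions_df = pd.read_excel(resolved, sheet_name="reactions")
        source = str(resolved)
    else:
        sp, rx = resolved
        sep = "\t" if sp.suffix == ".tsv" else ","
        species_df = pd.read_csv(sp, sep=sep)
        reactions_df = pd.read_csv(rx, sep=sep)
        source = str(sp)
    model = NetworkModel(
        species=_species_from_frame(species_df),
        reactions=_reactions_from_frame(reactions_df, default_ec50, default_n),
        metadata={"source": source},
    )
    return model


def save_model(model: NetworkModel, base: str | Path, fmt: str = "tsv") -> tuple[Path, Path]:
    """Write <base>.species.<fmt> and <base>.reactions.<fmt>; returns the paths."""
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unsupported format {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    sp = base.parent / f"{base.name}.species.{fmt}"
    rx = base.parent / f"{base.name}.reactions.{fmt}"
    pd.DataFrame(
        {
            "id": [s.id for s in model.species],
            "name": [s.display_name for s in model.species],
            "Ymax": [s.y_max for s in model.species],
            "tau": [s.tau for s in model.species],
            "category": [s.category for s in model.species],
            "y0": [s.y0 for s in model.species],
        }
    ).to_csv(sp, sep=sep, index=False)
    pd.DataFrame(
        {
            "rule": [serialize_rule(r) for r in model.reactions],
            "weight": [r.weight for r in model.reactions],
            "n": [r.n for r in model.reactions],
            "EC50": [r.ec50 for r in model.reactions],
        }
    ).to_csv(rx, sep=sep, index=False)
    return sp, rx


# ---------------------------------------------------------------------------
# Graph views and topology metrics
# ---------------------------------------------------------------------------

def model_graph(model: NetworkModel) -> nx.MultiDiGraph:
    """Directed multigraph with one edge per (source, target, sign) term.

    Input reactions have no source node and draw no edge. All species appear
    as nodes even when isolated.
    """
    g = nx.MultiDiGraph()
    g.add_nodes_from(model.species_ids)
    for r in model.reactions:
        for t in r.terms:
            g.add_edge(t.source, r.target, sign=t.sign)
    return g


def export_graph(model: NetworkModel, path: str | Path, fmt: str = "sif") -> Path:
    """Export the interaction graph as SIF (``activates``/``inhibits``) or GraphML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    g = model_graph(model)
    if fmt == "sif":
        lines = []
        for u, v, data in g.edges(data=True):
            rel = "activates" if data["sign"] == ACTIVATOR else "inhibits"
            lines.append(f"{u}\t{rel}\t{v}")
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unsupported graph format {fmt!r}")
    return path


def topology_metrics(model: NetworkModel) -> pd.DataFrame:
    """Per-node harmonic closeness, eccentricity, and mean shortest path length.

    Directed distances are measured *from* each node. Unreachable pairs are
    handled with the harmonic convention (they contribute 0 to closeness);
    eccentricity and mean path length are taken over the reachable set only,
    with the reachability fraction reported alongside. An isolated node has
    closeness 0 and eccentricity/mean path 0 over an empty reachable set.
    """
    g = nx.DiGraph(model_graph(model))  # collapse parallel edges
    nodes = list(g.nodes)
    if not nodes:
        raise ModelValidationError("empty graph")
    n = len(nodes)
    rows = []
    for u in nodes:
        dist = nx.single_source_shortest_path_length(g, u)
        dist.pop(u, None)
        reach = len(dist)
        closeness = sum(1.0 / d for d in dist.values()) / (n - 1) if n > 1 else 0.0
        rows.append(
            {
                "node": u,
                "closeness_centrality": closeness,
                "eccentricity": max(dist.values()) if reach else 0,
                "mean_shortest_path_length": (
                    sum(dist.values()) / reach if reach else 0.0
                ),
                "reachability_fraction": reach / (n - 1) if n > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("node")
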