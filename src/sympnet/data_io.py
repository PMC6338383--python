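"""Reading, validating and writing cohort tables, networks and result tables.

A cohort is a delimited text file with one row per participant: an id column,
a group column (ADHD vs control, case-insensitive), eighteen binary symptom
columns, and optional outcome columns suffixed ``_baseline`` / ``_followup``.
File column names may be arbitrary; a schema map fixes the correspondence to
the canonical symptom order.  Subtype is always derived from the profile,
never read from the file.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import configural
from .symptoms import DOMAINS, HI_SLICE, IA_SLICE, SYMPTOMS

logger = logging.getLogger(__name__)

OUTCOME_SUFFIXES = ("_baseline", "_followup")


class SchemaError(ValueError):
    """A required column is missing or the schema map is malformed."""


class CohortIntegrityError(ValueError):
    """Row-level contract violation: duplicate ids, non-binary symptoms."""


@dataclass
class CohortTable:
    """Validated participant table.

    ``data`` holds, in order: ``id``, ``group``, the 18 canonical symptom
    columns, the derived ``subtype``, then any outcome columns.
    """

    data: pd.DataFrame
    rule: configural.DiagnosticRule = field(default_factory=configural.DiagnosticRule)

    def __post_init__(self) -> None:
        self.data = validate_cohort(self.data, self.rule)

    @property
    def profiles(self) -> np.ndarray:
        """Participants x 18 binary matrix in canonical symptom order."""
        return self.data[list(SYMPTOMS)].to_numpy(dtype=np.int64)

    @property
    def outcome_columns(self) -> list[str]:
        return [
            c for c in self.data.columns
            if any(c.endswith(s) for s in OUTCOME_SUFFIXES)
        ]

    @property
    def n(self) -> int:
        return len(self.data)

    def group_rows(self, group: str) -> pd.DataFrame:
        if group == "combined":
            return self.data
        return self.data[self.data["group"] == group]

    def group_profiles(self, group: str) -> np.ndarray:
        if group == "combined":
            return self.profiles
        return self.profiles[(self.data["group"] == group).to_numpy()]


def validate_cohort(df: pd.DataFrame, rule: configural.DiagnosticRule) -> pd.DataFrame:
    """Normalize and validate a raw cohort frame; returns a fresh frame.

    Errors abort (duplicate ids, non-binary symptom values, unknown group
    labels); a control participant meeting the symptom threshold in either
    domain only warns, mirroring a screening-then-exclusion workflow where
    such rows are flagged for review rather than silently dropped.
    """
    df = df.copy()
    required = ["id", "group", *SYMPTOMS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    df["id"] = df["id"].astype(str)
    dupes = df["id"][df["id"].duplicated()].unique()
    if len(dupes):
        raise CohortIntegrityError(f"duplicate participant id(s): {', '.join(dupes)}")

    group = df["group"].astype(str).str.strip().str.lower()
    known = {"adhd": "ADHD", "control": "control", "controls": "control"}
    bad = sorted(set(group) - set(known))
    if bad:
        raise CohortIntegrityError(f"unknown group label(s): {', '.join(bad)}")
    df["group"] = group.map(known)

    for col in SYMPTOMS:
        vals = df[col]
        if vals.isna().any():
            row = df.loc[vals.isna(), "id"].iloc[0]
            raise CohortIntegrityError(f"missing symptom value in column {col!r} (id {row!r})")
        numeric = pd.to_numeric(vals, errors="coerce")
        ok = numeric.isin([0, 1])
        if not ok.all():
            row = df.loc[~ok, "id"].iloc[0]
            bad_val = vals[~ok].iloc[0]
            raise CohortIntegrityError(
                f"non-binary symptom value {bad_val!r} in column {col!r} (id {row!r})"
            )
        df[col] = numeric.astype(np.int64)

    profiles = df[list(SYMPTOMS)].to_numpy()
    ia = profiles[:, IA_SLICE].sum(axis=1)
    hi = profiles[:, HI_SLICE].sum(axis=1)
    df["subtype"] = [
        configural.classify_counts(int(a), int(h), rule) for a, h in zip(ia, hi)
    ]

    flagged = df[(df["group"] == "control") & (df["subtype"] != "none")]
    if len(flagged):
        ids = ", ".join(flagged["id"].head(5))
        msg = (
            f"{len(flagged)} control participant(s) meet the symptom threshold "
            f"in at least one domain (e.g. {ids}); study protocols typically "
            "exclude such rows"
        )
        warnings.warn(msg, UserWarning, stacklevel=2)
        logger.warning(msg)

    outcome_cols = [c for c in df.columns if any(c.endswith(s) for s in OUTCOME_SUFFIXES)]
    ordered = ["id", "group", *SYMPTOMS, "subtype", *outcome_cols]
    return df[ordered].reset_index(drop=True)


def read_cohort(
    path: str | Path,
    schema: dict[str, str] | None = None,
    rule: configural.DiagnosticRule | None = None,
) -> CohortTable:
    """Read a cohort CSV, mapping file columns to canonical names via ``schema``.

    ``schema`` maps canonical names (``id``, ``group``, the 18 symptom
    contractions) to file column names; omitted keys default to the canonical
    name itself.  Outcome columns (``*_baseline`` / ``*_followup``) are
    carried through unchanged; missing outcome values stay missing.
    """
    path = Path(path)
    raw = pd.read_csv(path)
    schema = schema or {}
    rename = {}
    for canon in ("id", "group", *SYMPTOMS):
        src = schema.get(canon, canon)
        if src not in raw.columns:
            raise SchemaError(
                f"column {src!r} (for {canon!r}) not found in {path.name}"
            )
        rename[src] = canon
    df = raw.rename(columns=rename)
    return CohortTable(df, rule=rule or configural.DiagnosticRule())


def write_cohort(cohort: CohortTable, path: str | Path) -> Path:
    """Write a cohort back to CSV (canonical column order, subtype included)."""
    path = Path(path)
    cohort.data.to_csv(path, index=False)
    return path


def write_table(rows: pd.DataFrame, path: str | Path) -> Path:
    """Write any result table as CSV with a deterministic column order.

    Floats are written with 12 significant decimals so a round-trip through
    text preserves values to the tolerance downstream comparisons use.
    """
    path = Path(path)
    rows.to_csv(path, index=False, float_format="%.12g")
    return path


def write_network(network, path: str | Path, format: str = "edgelist") -> Path:
    """Persist a symptom network as an edge-list CSV or GraphML file.

    The edge list has one row per unordered pair with nonzero weight:
    ``node_a, node_b, weight, raw_p, adjusted_p, survives_threshold``.
    GraphML carries the same edge attributes plus node domain tags.
    """
    path = Path(path)
    if format == "edgelist":
        write_table(network.edge_table(), path)
    elif format == "graphml":
        nx.write_graphml(_to_attr_graph(network), path)
    else:
        raise ValueError(f"unknown network format {format!r}")
    return path


def read_network(path: str | Path, nodes: list[str] | None = None):
    """Rebuild a SymptomNetwork from an edge-list CSV written by write_network."""
    from .network import SymptomNetwork

    path = Path(path)
    edges = pd.read_csv(path)
    if nodes is None:
        nodes = list(SYMPTOMS)
    index = {name: i for i, name in enumerate(nodes)}
    k = len(nodes)
    weights = np.zeros((k, k))
    raw_p = np.ones((k, k))
    adjusted_p = np.full((k, k), np.nan)
    for _, row in edges.iterrows():
        i, j = index[row["node_a"]], index[row["node_b"]]
        weights[i, j] = weights[j, i] = row["weight"]
        if not pd.isna(row.get("raw_p", np.nan)):
            raw_p[i, j] = raw_p[j, i] = row["raw_p"]
        if not pd.isna(row.get("adjusted_p", np.nan)):
            adjusted_p[i, j] = adjusted_p[j, i] = row["adjusted_p"]
    np.fill_diagonal(raw_p, 0.0)
    return SymptomNetwork(
        nodes=tuple(nodes),
        weights=weights,
        raw_p=raw_p,
        adjusted_p=adjusted_p if not np.isnan(adjusted_p).all() else None,
    )


def _to_attr_graph(network) -> nx.Graph:
    g = nx.Graph()
    for name in network.nodes:
        g.add_node(name, domain=DOMAINS.get(name, ""))
    for row in network.edge_table().itertuples(index=False):
        g.add_edge(
            row.node_a,
            row.node_b,
            weight=float(row.weight),
            raw_p=float(row.raw_p) if not pd.isna(row.raw_p) else 1.0,
            adjusted_p=float(row.adjusted_p) if not pd.isna(row.adjusted_p) else 1.0,
            survives_threshold=bool(row.survives_threshold),
        )
    return g
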