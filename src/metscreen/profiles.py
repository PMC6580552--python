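"""Expression matrices, IC50 tables and cell-line annotations.

Formats:
  expression  — TSV matrix, first column gene/probe id, one column per cell
                line (GCT exports accepted by skipping their 2 header lines);
  probe map   — 2-column TSV ``probe<TAB>gene``;
  IC50        — long CSV with header ``drug,cell_line,ic50_um``;
  annotations — CSV with header ``cell_line,cancer_type``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class ExpressionProfile:
    """Per-cell-line vector of non-negative expression values."""

    cell_line_id: str
    values: dict[str, float]
    cancer_type: str = "unknown"


@dataclass
class DrugResponseTable:
    """IC50 (µM) per (drug, cell line); drug order = first appearance."""

    entries: dict[tuple[str, str], float] = field(default_factory=dict)
    drugs: list[str] = field(default_factory=list)

    def add(self, drug: str, cell_line: str, ic50_um: float) -> None:
        key = (drug, cell_line)
        if key in self.entries:
            raise ValueError(f"duplicate IC50 entry for {key}")
        if not np.isfinite(ic50_um) or ic50_um <= 0:
            raise ValueError(f"IC50 for {key} must be a positive finite number, got {ic50_um}")
        self.entries[key] = float(ic50_um)
        if drug not in self.drugs:
            self.drugs.append(drug)

    def cell_lines(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, cl in self.entries:
            seen.setdefault(cl)
        return list(seen)

    def vector(self, drug: str, cell_lines: Sequence[str]) -> pd.Series:
        """Response over the given cell lines; NaN where unmeasured."""
        return pd.Series(
            [self.entries.get((drug, cl), np.nan) for cl in cell_lines], index=list(cell_lines), name=drug
        )


def read_expression_matrix(
    path: str | Path,
    aggregation: str = "mean",
    probe_map: str | Path | Mapping[str, str] | None = None,
    gct: bool = False,
) -> list[ExpressionProfile]:
    """One profile per column; multiple probes per gene collapsed by ``aggregation``."""
    with open(path) as fh:
        for _ in range(2 if gct else 0):
            fh.readline()
        header = [c.strip() for c in fh.readline().rstrip("\n").split("\t")[1:]]
    dups = sorted({c for c in header if header.count(c) > 1})
    if dups:
        raise ValueError(f"duplicate cell-line columns: {dups}")
    df = pd.read_csv(path, sep="\t", skiprows=2 if gct else 0, index_col=0, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    df.index = [str(i).strip() for i in df.index]

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | (numeric < 0) | ~np.isfinite(numeric)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"invalid expression value {df.iat[r, c]!r} at row {df.index[r]!r}, column {df.columns[c]!r}"
        )

    if probe_map is not None:
        if not isinstance(probe_map, Mapping):
            pm = pd.read_csv(probe_map, sep="\t", header=None, dtype=str)
            probe_map = dict(zip(pm[0].str.strip(), pm[1].str.strip()))
        numeric.index = [probe_map.get(p, p) for p in numeric.index]
    if aggregation not in {"mean", "median", "max"}:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    collapsed = numeric.groupby(level=0).agg(aggregation)

    return [
        ExpressionProfile(col, collapsed[col].to_dict()) for col in collapsed.columns
    ]


def read_ic50_table(path: str | Path) -> DrugResponseTable:
    df = pd.read_csv(path, dtype={"drug": str, "cell_line": str})
    expected = ["drug", "cell_line", "ic50_um"]
    if list(df.columns[:3]) != expected:
        raise ValueError(f"IC50 file must have header {','.join(expected)}, got {list(df.columns)}")
    table = DrugResponseTable()
    for row in df.itertuples(index=False):
        table.add(str(row.drug).strip(), str(row.cell_line).strip(), float(row.ic50_um))
    return table


def write_ic50_table(table: DrugResponseTable, path: str | Path) -> None:
    rows = [(d, cl, v) for (d, cl), v in table.entries.items()]
    pd.DataFrame(rows, columns=["drug", "cell_line", "ic50_um"]).to_csv(path, index=False)


def read_annotations(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["cell_line", "cancer_type"]:
        raise ValueError(f"annotation file must have header cell_line,cancer_type, got {list(df.columns)}")
    return {str(r.cell_line).strip(): str(r.cancer_type).strip() for r in df.itertuples(index=False)}


@dataclass
class Cohort:
    """Profiles, responses and labels aligned on one cell-line index."""

    cell_lines: list[str]
    cancer_types: dict[str, str]
    profiles: list[ExpressionProfile]
    responses: pd.DataFrame  # drugs x cell lines, NaN = unmeasured
    drugs: list[str]
    unmatched: dict[str, list[str]] = field(default_factory=dict)

    def cells_of_type(self, label: str) -> list[str]:
        if label == "all":
            return list(self.cell_lines)
        return [c for c in self.cell_lines if self.cancer_types.get(c) == label]


def join_cohort(
    profiles: Sequence[ExpressionProfile],
    responses: DrugResponseTable,
    annotations: Mapping[str, str] | None = None,
) -> Cohort:
    """Align by exact (whitespace-trimmed) cell-line id; unmeasured IC50s stay masked."""
    annotations = annotations or {}
    cells = [p.cell_line_id.strip() for p in profiles]
    if len(set(cells)) != len(cells):
        raise ValueError("duplicate cell-line ids among profiles")
    response_cells = set(responses.cell_lines())
    if response_cells and not response_cells & set(cells):
        raise ValueError("no overlap between profile and response cell-line ids")

    matrix = pd.DataFrame(
        {d: responses.vector(d, cells) for d in responses.drugs}
    ).T.reindex(responses.drugs)
    matrix.columns = cells

    labels = {}
    unlabeled = []
    for c in cells:
        if c in annotations:
            labels[c] = annotations[c]
        else:
            labels[c] = "unknown"
            unlabeled.append(c)
    for p, c in zip(profiles, cells):
        p.cancer_type = labels[c]

    unmatched = {
        "responses_without_profile": sorted(response_cells - set(cells)),
        "profiles_without_annotation": unlabeled if annotations else [],
    }
    return Cohort(cells, labels, list(profiles), matrix, list(responses.drugs), unmatched)
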