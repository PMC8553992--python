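"""Reading and validating the canonical long-format density table.

The pipeline's input is plain delimited text with one row per
(subject, condition, region) and columns::

    subject_id, condition, region, density

Density is the c-Fos cell density in cells/mm^3. The same layout serves
synthetic and real data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .coactivity import DensityTable
from .regions import RegionSet

REQUIRED_COLUMNS = ("subject_id", "condition", "region", "density")


@dataclass(frozen=True)
class SchemaFinding:
    row: int | None  # 1-based data row, None for file-level findings
    column: str | None
    message: str


def validate_input(path) -> list[SchemaFinding]:
    """Schema findings for a long-format file; empty list means valid."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    findings: list[SchemaFinding] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    for col in missing:
        findings.append(SchemaFinding(None, col, f"missing required column {col!r}"))
    if missing:
        return findings

    density = pd.to_numeric(df["density"], errors="coerce")
    for idx in df.index[density.isna()]:
        findings.append(
            SchemaFinding(
                int(idx) + 1, "density",
                f"non-numeric density {df.at[idx, 'density']!r}",
            )
        )
    for col in ("subject_id", "condition", "region"):
        for idx in df.index[df[col].str.strip() == ""]:
            findings.append(SchemaFinding(int(idx) + 1, col, f"empty {col}"))

    dup = df.duplicated(subset=["subject_id", "condition", "region"], keep=False)
    seen = set()
    for idx in df.index[dup]:
        triple = (
            df.at[idx, "subject_id"], df.at[idx, "condition"], df.at[idx, "region"]
        )
        if triple in seen:
            continue
        seen.add(triple)
        findings.append(
            SchemaFinding(
                int(idx) + 1, None,
                f"duplicate (subject_id, condition, region) = {triple}",
            )
        )
    return findings


def read_long(path) -> dict[str, DensityTable]:
    """Load a validated long-format file into per-condition density tables.

    Region order follows first appearance in the file and is shared by all
    conditions; a region absent for some subject yields a missing value
    handled downstream by pairwise-complete correlation.
    """
    path = Path(path)
    findings = validate_input(path)
    if findings:
        msgs = "; ".join(
            f"row {f.row}: {f.message}" if f.row else f.message for f in findings[:10]
        )
        raise ValueError(f"invalid input file {path}: {msgs}")
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)

    region_order = list(dict.fromkeys(df["region"]))
    region_set = RegionSet(region_order)
    tables: dict[str, DensityTable] = {}
    for cond, sub in df.groupby("condition", sort=False):
        wide = sub.pivot(index="subject_id", columns="region", values="density")
        wide = wide.reindex(columns=region_order)
        wide = wide.loc[sorted(wide.index)]
        tables[str(cond)] = DensityTable(
            condition=str(cond), region_set=region_set, data=wide
        )
    return tables
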