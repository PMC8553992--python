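"""Interregional coactivity: per-condition Pearson correlation matrices.

Functional connectivity here is the Pearson correlation of c-Fos densities
between region pairs, taken across the subjects of one condition.
Correlations are pairwise-complete; a pair observed in fewer than
``min_pairs`` subjects is flagged missing (NaN) and carries no edge
downstream. No p-values are attached anywhere: edges are defined purely by
the correlation threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import RegionSet


@dataclass(frozen=True)
class DensityTable:
    """Subjects x regions table of c-Fos densities (cells/mm^3) for one condition."""

    condition: str
    region_set: RegionSet
    data: pd.DataFrame  # index: subject ids, columns: region labels
    n_clipped: int = 0

    def __post_init__(self):
        if tuple(self.data.columns) != self.region_set.names:
            raise ValueError("table columns must match the region set, in order")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def to_long(self) -> pd.DataFrame:
        long = self.data.reset_index(names="subject_id").melt(
            id_vars="subject_id", var_name="region", value_name="density"
        )
        long.insert(1, "condition", self.condition)
        return long


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric interregional Pearson matrix with per-pair subject counts.

    Missing pairs (fewer than the minimum number of complete subject pairs)
    are NaN; NaN is the sentinel for "no valid correlation" throughout.
    """

    condition_name: str
    regions: RegionSet
    R: pd.DataFrame
    n_used: pd.DataFrame

    def __post_init__(self):
        a = self.R.to_numpy()
        if not np.allclose(np.diag(a), 1.0):
            raise ValueError("correlation diagonal must be exactly 1")
        if not np.array_equal(np.isnan(a), np.isnan(a.T)) or not np.allclose(
            np.nan_to_num(a), np.nan_to_num(a.T)
        ):
            raise ValueError("correlation matrix must be symmetric")
        off = a[~np.eye(len(a), dtype=bool)]
        off = off[~np.isnan(off)]
        if ((off < -1) | (off > 1)).any():
            raise ValueError("correlations must lie in [-1, 1]")


def correlation_matrix(table: DensityTable, min_pairs: int = 5) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations across subjects.

    Regions with zero variance across subjects have undefined correlations
    and are dropped with a warning. Pairs with fewer than ``min_pairs``
    complete subjects are set to NaN.
    """
    df = table.data.astype(float)

    variances = df.var(ddof=1, numeric_only=True)
    degenerate = [r for r in df.columns if not variances[r] > 0]
    if degenerate:
        warnings.warn(
            f"dropping zero-variance region(s) {degenerate} in condition "
            f"{table.condition!r}: correlations undefined"
        )
        df = df.drop(columns=degenerate)
    if df.shape[1] < 2:
        raise ValueError("fewer than 2 regions with variance; no correlations to compute")

    R = df.corr(method="pearson", min_periods=min_pairs)
    obs = df.notna().astype(int)
    n_used = pd.DataFrame(
        obs.T.to_numpy() @ obs.to_numpy(), index=df.columns, columns=df.columns
    )
    np.fill_diagonal(R.values, 1.0)
    # clamp rounding spill just outside [-1, 1]
    R = R.clip(-1.0, 1.0)

    missing = int(R.isna().to_numpy()[np.triu_indices(len(R), k=1)].sum())
    if missing:
        warnings.warn(
            f"{missing} region pair(s) in condition {table.condition!r} have "
            f"fewer than {min_pairs} complete subjects; flagged missing"
        )
    return CorrelationMatrix(
        condition_name=table.condition,
        regions=RegionSet(df.columns),
        R=R,
        n_used=n_used,
    )


def heatmap_export(cm: CorrelationMatrix, path) -> tuple[Path, Path]:
    """Write the matrix as delimited text and as a raster heat map.

    ``path`` is a stem: ``<stem>.tsv`` gets the full-precision matrix with
    region labels as header row and column, ``<stem>.png`` the image. The
    color scale is symmetric about zero so anticorrelation and correlation
    render with equal visual weight.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stem = Path(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    text_path = stem.with_suffix(".tsv")
    img_path = stem.with_suffix(".png")

    cm.R.to_csv(text_path, sep="\t", index_label="region")

    k = len(cm.R)
    fig, ax = plt.subplots(figsize=(max(4, 0.45 * k + 2),) * 2)
    im = ax.imshow(cm.R.to_numpy(), vmin=-1.0, vmax=1.0, cmap="RdBu_r")
    ax.set_xticks(range(k), labels=cm.R.columns, rotation=90)
    ax.set_yticks(range(k), labels=cm.R.index)
    ax.set_title(cm.condition_name)
    fig.colorbar(im, ax=ax, label="Pearson R")
    fig.tight_layout()
    fig.savefig(img_path, dpi=150)
    plt.close(fig)
    return text_path, img_path
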