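"""Pooled kinetic datasets: the observed (assay, x, y, sd) points.

The CSV dialect has the header ``assay_id,x_mM,y,sd``; a blank ``sd``
marks a missing standard deviation.  Weights used by the least-squares
objective are the per-point sd where available, otherwise the per-assay
``max |y|`` (so unweighted assays contribute relative errors).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .protocols import ASSAY_IDS

COLUMNS = ("assay_id", "x_mM", "y", "sd")


class DatasetError(ValueError):
    pass


@dataclass
class KineticDataset:
    """Validated table of pooled kinetic observations."""

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.reset_index(drop=True).copy()
        missing = set(COLUMNS) - set(df.columns)
        if missing:
            raise DatasetError(f"dataset lacks columns {sorted(missing)}")
        if len(df) == 0:
            raise DatasetError("no data rows")
        bad = ~df["assay_id"].isin(ASSAY_IDS)
        if bad.any():
            row = df.index[bad][0]
            raise DatasetError(
                f"row {row + 2}: unknown assay_id {df.loc[row, 'assay_id']!r}")
        for col in ("x_mM", "y", "sd"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        if df["x_mM"].isna().any() or df["y"].isna().any():
            row = df.index[df["x_mM"].isna() | df["y"].isna()][0]
            raise DatasetError(f"row {row + 2}: malformed x_mM/y value")
        nonpos = df["sd"].notna() & (df["sd"] <= 0)
        if nonpos.any():
            row = df.index[nonpos][0]
            raise DatasetError(
                f"row {row + 2}: sd must be positive, got {df.loc[row, 'sd']}")
        self.df = df

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def assays(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.df["assay_id"]))

    def weights(self) -> np.ndarray:
        """Per-point weights: sd, or the assay's max |y| where sd is missing."""
        w = self.df["sd"].to_numpy(dtype=float).copy()
        absmax = self.df.groupby("assay_id")["y"].transform(
            lambda s: np.abs(s).max())
        fallback = np.where(absmax > 0, absmax, 1.0)
        w = np.where(np.isnan(w), fallback, w)
        return w

    def to_csv(self, path: str | Path | None = None) -> str | None:
        out = self.df[list(COLUMNS)].to_csv(path, index=False)
        return out

    @classmethod
    def from_points(cls, points) -> "KineticDataset":
        """Build from an iterable of (assay_id, x_mM, y, sd) tuples."""
        return cls(pd.DataFrame(points, columns=COLUMNS))


def read_dataset(source: str | Path | io.TextIOBase) -> KineticDataset:
    """Read the dataset CSV dialect; malformed rows carry their line number."""
    try:
        df = pd.read_csv(source, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise DatasetError("no data rows") from None
    return KineticDataset(df)


def write_dataset(path: str | Path, dataset: KineticDataset) -> None:
    dataset.to_csv(path)
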