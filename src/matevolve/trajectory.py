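"""Per-generation trajectory records and their (de)serialization."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical column order of a trajectory table.
COLUMNS = [
    "generation", "engine", "replicate",
    "a_bar", "b_bar", "m_bar", "z_bar", "z_bar_star", "sigma_z2",
    "theta", "epsilon", "cue", "mean_fitness",
]

_FLOAT_COLS = [c for c in COLUMNS if c not in ("generation", "engine", "replicate")]


@dataclass
class Trajectory:
    """A tidy per-generation record of trait means, moments and environment.

    Thin wrapper around a :class:`pandas.DataFrame` with the canonical column
    set; replicate runs concatenate into a single long-format frame.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"trajectory frame missing columns: {missing}")
        self.frame = self.frame[COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __getitem__(self, col):
        return self.frame[col]

    @classmethod
    def from_arrays(cls, *, engine: str, replicate: int = 0, **arrays) -> "Trajectory":
        n = len(arrays["generation"])
        data = {"engine": np.repeat(engine, n),
                "replicate": np.repeat(replicate, n)}
        for col in COLUMNS:
            if col in ("engine", "replicate"):
                continue
            data[col] = np.asarray(arrays.get(col, np.full(n, np.nan)))
        return cls(pd.DataFrame(data))

    @classmethod
    def concat(cls, trajectories) -> "Trajectory":
        return cls(pd.concat([t.frame for t in trajectories], ignore_index=True))

    def final(self) -> pd.Series:
        """Last recorded generation (of the first replicate if several)."""
        rep0 = self.frame[self.frame["replicate"] == self.frame["replicate"].iloc[0]]
        return rep0.iloc[-1]

    def replicate_mean(self) -> "Trajectory":
        """Across-replicate mean per generation (engine label preserved)."""
        g = self.frame.groupby("generation", as_index=False)[_FLOAT_COLS].mean()
        g["engine"] = self.frame["engine"].iloc[0]
        g["replicate"] = -1
        return Trajectory(g)

    def aggregate(self) -> pd.DataFrame:
        """Per-generation mean and SD across replicates, wide format."""
        g = self.frame.groupby("generation")[_FLOAT_COLS]
        out = g.mean().add_suffix("_mean").join(g.std(ddof=0).add_suffix("_sd"))
        return out.reset_index()


def write_trajectory(trajectory: Trajectory, path, format: str = "tsv") -> Path:
    """Write a trajectory as a delimited table, lossless for float64.

    Floats are printed with 17 significant digits so that a read-back
    reproduces the written values bit for bit.
    """
    path = Path(path)
    sep = {"tsv": "\t", "csv": ","}.get(format)
    if sep is None:
        raise ValueError(f"unknown format {format!r}; use 'tsv' or 'csv'")
    path.parent.mkdir(parents=True, exist_ok=True)
    trajectory.frame.to_csv(path, sep=sep, index=False, float_format="%.17g")
    return path


def read_trajectory(path, format: str | None = None) -> Trajectory:
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix == ".csv" else "tsv"
    sep = {"tsv": "\t", "csv": ","}[format]
    return Trajectory(pd.read_csv(path, sep=sep,
                                  float_precision="round_trip"))


def write_aggregate(trajectory: Trajectory, path, format: str = "tsv") -> Path:
    """Write the across-replicate per-generation mean/SD table."""
    path = Path(path)
    sep = {"tsv": "\t", "csv": ","}[format]
    path.parent.mkdir(parents=True, exist_ok=True)
    trajectory.aggregate().to_csv(path, sep=sep, index=False, float_format="%.17g")
    return path
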