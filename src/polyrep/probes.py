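"""Probe-level log2 ratio profiles from tiling arrays.

A :class:`ProbeProfile` holds, per chromosome, strictly increasing probe
positions with the raw log2(experimental/diploid-control) ratio and — once the
caller has run — the locally weighted smoothed value and the mode-centered
value.  Internally a single pandas DataFrame sorted by (chrom, pos).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["ProbeProfile"]


class ProbeProfile:
    """Per-chromosome sorted probe positions with log2 ratio columns.

    Columns: ``chrom``, ``pos``, ``log2_raw`` always; ``log2_smooth`` and
    ``log2_centered`` after smoothing/centering.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"chrom", "pos", "log2_raw"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"probe table missing columns: {sorted(missing)}")
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if len(pos) > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"duplicate probe positions on chromosome {chrom!r}")
        self.df = df

    @classmethod
    def from_arrays(
        cls, data: Mapping[str, tuple[np.ndarray, np.ndarray]]
    ) -> "ProbeProfile":
        """Build from ``{chrom: (positions, log2_raw)}``."""
        frames = [
            pd.DataFrame({"chrom": chrom, "pos": np.asarray(p, dtype=np.int64),
                          "log2_raw": np.asarray(v, dtype=float)})
            for chrom, (p, v) in data.items()
        ]
        return cls(pd.concat(frames, ignore_index=True))

    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique())

    def chrom_data(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def positions(self, chrom: str) -> np.ndarray:
        return self.chrom_data(chrom)["pos"].to_numpy()

    def values(self, chrom: str, col: str = "log2_raw") -> np.ndarray:
        return self.chrom_data(chrom)[col].to_numpy()

    @property
    def n_probes(self) -> int:
        return len(self.df)

    def has(self, col: str) -> bool:
        return col in self.df.columns

    def with_column(self, col: str, values: np.ndarray) -> "ProbeProfile":
        df = self.df.copy()
        df[col] = values
        out = ProbeProfile.__new__(ProbeProfile)
        out.df = df
        return out

    def window(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """Probes with start <= pos < end on one chromosome."""
        sub = self.chrom_data(chrom)
        pos = sub["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [start, end])
        return sub.iloc[lo:hi]

    def value_column(self) -> str:
        """Preferred working column: centered if present, else raw."""
        return "log2_centered" if self.has("log2_centered") else "log2_raw"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeProfile):
            return NotImplemented
        return self.df.equals(other.df)

    def __repr__(self) -> str:
        return f"ProbeProfile({self.n_probes} probes on {len(self.chroms())} chromosomes)"
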