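"""Genetic maps: linear interpolation between (bp, cM) knots.

A map is a per-chromosome monotone table of physical/genetic coordinate
pairs. Positions between knots are interpolated linearly in both
directions, which makes ``cm_to_bp`` the exact inverse of ``bp_to_cm``
up to floating-point rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneticMap"]


@dataclass
class GeneticMap:
    """Piecewise-linear bp <-> cM map, one knot table per chromosome.

    ``knots[chrom]`` is a float array of shape (k, 2) with columns
    (position_bp, position_cM), strictly increasing in both columns.
    """

    knots: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, arr in self.knots.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise ValueError(f"map for {chrom!r} needs >=2 (bp, cM) knots")
            # bp strictly increasing; cM non-decreasing (flat = recombination desert)
            if not (np.all(np.diff(arr[:, 0]) > 0) and np.all(np.diff(arr[:, 1]) >= 0)):
                raise ValueError(f"map for {chrom!r} must be increasing")
            self.knots[chrom] = arr

    @classmethod
    def constant_rate(
        cls, chrom_lengths_bp: dict[str, int], cm_per_mb: float = 3.0
    ) -> "GeneticMap":
        """Uniform-recombination map: ``cm_per_mb`` centimorgan per megabase."""
        if cm_per_mb <= 0:
            raise ValueError("cm_per_mb must be positive")
        knots = {
            chrom: np.array([[0.0, 0.0], [length, length * cm_per_mb / 1e6]])
            for chrom, length in chrom_lengths_bp.items()
        }
        return cls(knots)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.knots)

    def _table(self, chrom: str) -> np.ndarray:
        try:
            return self.knots[chrom]
        except KeyError:
            raise KeyError(f"no genetic map for chromosome {chrom!r}") from None

    def bp_to_cm(self, chrom: str, pos_bp) -> np.ndarray | float:
        t = self._table(chrom)
        return np.interp(pos_bp, t[:, 0], t[:, 1])

    def cm_to_bp(self, chrom: str, pos_cm) -> np.ndarray | float:
        t = self._table(chrom)
        return np.interp(pos_cm, t[:, 1], t[:, 0])

    def length_cm(self, chrom: str) -> float:
        t = self._table(chrom)
        return float(t[-1, 1] - t[0, 1])

    def length_bp(self, chrom: str) -> int:
        t = self._table(chrom)
        return int(t[-1, 0])

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (chrom, int(bp), cm)
            for chrom, t in self.knots.items()
            for bp, cm in t
        ]
        return pd.DataFrame(rows, columns=["chrom", "pos_bp", "pos_cm"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "GeneticMap":
        """Read a map file.

        Accepts either the native 3-column TSV (chrom, pos_bp, pos_cm, with
        header) or a 4-column PLINK ``.map`` (chrom, id, cM, bp, no header).
        """
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
        if df.shape[1] == 4:  # PLINK .map
            out = pd.DataFrame(
                {
                    "chrom": df[0],
                    "pos_bp": pd.to_numeric(df[3]),
                    "pos_cm": pd.to_numeric(df[2]),
                }
            )
        elif df.shape[1] == 3:
            if df.iloc[0, 1] == "pos_bp":  # header row
                df = df.iloc[1:]
            out = pd.DataFrame(
                {
                    "chrom": df[0],
                    "pos_bp": pd.to_numeric(df[1]),
                    "pos_cm": pd.to_numeric(df[2]),
                }
            )
        else:
            raise ValueError(f"unrecognized map format in {path}")
        knots = {
            str(chrom): g[["pos_bp", "pos_cm"]].to_numpy(dtype=float)
            for chrom, g in out.groupby("chrom", sort=False)
        }
        return cls(knots)
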