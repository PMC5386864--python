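"""Genetic map container and the default synthetic marker map.

A genetic map is a table of markers with a chromosome number and a genetic
position in centimorgans (cM).  Positions must be non-decreasing within each
chromosome; marker names must be unique.  The default map mimics the marker
panel used for joint-linkage mapping in maize NIL libraries: 728 markers
spread over 10 chromosomes totalling roughly 1500 cM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneticMap", "default_map"]


@dataclass(frozen=True)
class GeneticMap:
    """Marker positions on numbered chromosomes.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``marker`` (str), ``chrom`` (int, 1-based) and ``pos_cm``
        (float, non-negative).  Rows are kept in the given order.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker", "chrom", "pos_cm"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"genetic map missing columns: {sorted(missing)}")
        if len(t) == 0:
            raise ValueError("genetic map has no markers")
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker identifier: {dup!r}")
        if (t["pos_cm"] < 0).any():
            raise ValueError("marker positions must be non-negative")
        for chrom, grp in t.groupby("chrom", sort=False):
            if not grp["pos_cm"].is_monotonic_increasing:
                raise ValueError(
                    f"positions on chromosome {chrom} are not non-decreasing"
                )

    @property
    def markers(self) -> np.ndarray:
        return self.table["marker"].to_numpy()

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self.table["chrom"].unique().tolist())

    def positions(self, chrom: int) -> np.ndarray:
        """cM positions of the markers on one chromosome, in map order."""
        return self.table.loc[self.table["chrom"] == chrom, "pos_cm"].to_numpy(
            dtype=float
        )

    def chrom_length(self, chrom: int) -> float:
        """Chromosome length in cM (position of the last marker)."""
        pos = self.positions(chrom)
        if pos.size == 0:
            raise KeyError(f"no markers on chromosome {chrom}")
        return float(pos[-1])

    @property
    def total_length(self) -> float:
        return float(sum(self.chrom_length(c) for c in self.chromosomes))

    def marker_index(self, marker: str) -> int:
        idx = np.flatnonzero(self.markers == marker)
        if idx.size == 0:
            raise KeyError(f"marker {marker!r} not in map")
        return int(idx[0])

    def marker_info(self, marker: str) -> tuple[int, float]:
        """(chromosome, cM position) of a marker."""
        row = self.table.iloc[self.marker_index(marker)]
        return int(row["chrom"]), float(row["pos_cm"])


# chromosome lengths (cM) of the default 10-chromosome map; total 1510 cM,
# within the 1400-1800 cM range typical of maize consensus maps
_DEFAULT_CHROM_LENGTHS = (200.0, 180.0, 170.0, 160.0, 150.0, 140.0, 140.0, 130.0, 120.0, 120.0)
_DEFAULT_N_MARKERS = 728


def default_map(
    n_markers: int = _DEFAULT_N_MARKERS,
    chrom_lengths: tuple[float, ...] = _DEFAULT_CHROM_LENGTHS,
) -> GeneticMap:
    """Evenly spaced synthetic marker map.

    Markers are allotted to chromosomes proportionally to length and placed
    uniformly from 0 to the chromosome end.  Names are ``m<chrom>_<index>``.
    """
    lengths = np.asarray(chrom_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("chromosome lengths must be positive")
    n_chrom = lengths.size
    # proportional allotment, at least 2 markers per chromosome
    raw = n_markers * lengths / lengths.sum()
    counts = np.maximum(np.floor(raw).astype(int), 2)
    # distribute the remainder by largest fractional part
    while counts.sum() < n_markers:
        counts[np.argmax(raw - counts)] += 1
    while counts.sum() > n_markers:
        counts[np.argmin(raw - counts)] -= 1
    rows = []
    for c in range(n_chrom):
        pos = np.linspace(0.0, lengths[c], counts[c])
        for i, p in enumerate(pos):
            rows.append((f"m{c + 1}_{i + 1}", c + 1, float(p)))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "pos_cm"]))
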