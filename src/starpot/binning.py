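"""Distance binning for atomic pair statistics.

The default scheme has 18 bins up to a 20 Å cutoff: a wide first bin 0-3 Å
(covering covalent and very short contacts, which are sparse) followed by
seventeen 1 Å bins.  Bins are half-open intervals [lo, hi); the cutoff is
exclusive.  Distances are Euclidean in Å and are never rounded before
binning, so boundary membership is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InputError


@dataclass(frozen=True)
class DistanceBinning:
    """Ordered bin edges in Å; bin k is [edges[k], edges[k+1])."""

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.edges) < 2:
            raise InputError("binning needs at least two edges")
        diffs = np.diff(self.edges)
        if not np.all(diffs > 0):
            raise InputError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def cutoff(self) -> float:
        return self.edges[-1]

    @property
    def widths(self) -> tuple[float, ...]:
        return tuple(float(w) for w in np.diff(self.edges))

    def serialize_edges(self) -> str:
        """Comma-separated edge list, as embedded in potential file headers."""
        return ",".join(f"{e:g}" for e in self.edges)

    @classmethod
    def from_serialized(cls, text: str) -> "DistanceBinning":
        return cls(edges=tuple(float(tok) for tok in text.split(",")))


def default_binning() -> DistanceBinning:
    """18-bin scheme: [0,3) then 1 Å bins up to the 20 Å cutoff."""
    return DistanceBinning(edges=(0.0,) + tuple(float(x) for x in range(3, 21)))


def bin_of(d: float, binning: Optional[DistanceBinning] = None) -> Optional[int]:
    """Bin index containing distance ``d`` (Å), or ``None`` beyond the cutoff.

    Raises :class:`InputError` for negative distances.
    """
    if binning is None:
        binning = default_binning()
    if d < 0:
        raise InputError(f"negative distance: {d}")
    if d >= binning.cutoff:
        return None
    # searchsorted(right) gives first edge > d; subtract 1 for the bin start.
    k = int(np.searchsorted(binning.edges, d, side="right")) - 1
    return k if k >= 0 else None


def bins_of(d: np.ndarray, binning: DistanceBinning) -> np.ndarray:
    """Vectorized :func:`bin_of` for distances already known to be < cutoff."""
    return np.searchsorted(binning.edges, d, side="right") - 1
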