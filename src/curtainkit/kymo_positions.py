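"""Binding-position analysis on the DNA substrate.

Spot positions measured in camera pixels are mapped to base pairs using
the chromium barrier (DNA start) and anchor (DNA end) as calibration
marks, binned into a fixed number of equal-width bins (40 by default),
and compared between bins overlapping annotated binding sites (CBS) and
all other bins to yield a fold enrichment.  AT-content tracks support
splitting positions into AT-rich (>= 50% A/T) and GC-rich regions.

Coordinates are 0-based, half-open (BED convention); positions are bp
from the barrier-proximal end.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Feature",
    "DNASubstrate",
    "PositionSet",
    "BinHistogram",
    "EnrichmentResult",
    "map_pixels_to_bp",
    "at_content_track",
    "classify_at_region",
    "bin_positions",
    "enrichment",
    "wash_survival_fraction",
]


@dataclass(frozen=True)
class Feature:
    start: int
    end: int            # half-open
    strand: str = "+"
    kind: str = "CBS"   # "CBS" or "promoter"


@dataclass
class DNASubstrate:
    """DNA substrate: sequence (optional), feature annotations and the bin
    layout used for enrichment histograms."""

    length: int
    sequence: str | None = None
    features: Sequence[Feature] = field(default_factory=tuple)
    n_bins: int = 40
    name: str = "substrate"

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"sequence length {len(self.sequence)} != declared length {self.length}"
                )
        for f in self.features:
            if not (0 <= f.start < f.end <= self.length):
                raise ValueError(
                    f"feature {f} outside [0, {self.length})"
                )

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, float(self.length), self.n_bins + 1)

    @property
    def bin_width(self) -> float:
        return self.length / self.n_bins

    def cbs_features(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "CBS"]

    def cbs_bin_mask(self) -> np.ndarray:
        """Bins overlapping any CBS feature by >= 1 bp."""
        edges = self.bin_edges
        mask = np.zeros(self.n_bins, dtype=bool)
        for f in self.cbs_features():
            lo = int(np.searchsorted(edges, f.start, side="right")) - 1
            hi = int(np.searchsorted(edges, f.end - 1e-9, side="right")) - 1
            mask[max(lo, 0) : min(hi, self.n_bins - 1) + 1] = True
        return mask

    def at_track(self, window: int = 500) -> np.ndarray:
        if self.sequence is None:
            raise ValueError(f"substrate {self.name!r} has no sequence")
        return at_content_track(self.sequence, window)


@dataclass
class PositionSet:
    positions: np.ndarray           # bp
    molecule_ids: np.ndarray | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.molecule_ids is None:
            self.molecule_ids = np.arange(self.positions.size)
        else:
            self.molecule_ids = np.asarray(self.molecule_ids)
            if self.molecule_ids.shape != self.positions.shape:
                raise ValueError("molecule_ids must parallel positions")


@dataclass
class BinHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    cbs_bins: np.ndarray            # boolean mask


@dataclass
class EnrichmentResult:
    fold: float
    cbs_mean: float
    other_mean: float
    n_cbs_bins: int
    n_other_bins: int
    undefined: bool = False


def map_pixels_to_bp(
    pixel: float,
    barrier_px: float,
    anchor_px: float,
    length: float,
    tolerance_px: float = 2.0,
) -> float:
    """Linear pixel-to-bp calibration: barrier -> 0, anchor -> ``length``.

    Pixels outside the tethered span by more than ``tolerance_px`` are
    rejected; within the tolerance the result is clipped into
    ``[0, length]``.
    """
    if barrier_px == anchor_px:
        raise ValueError("barrier_px and anchor_px must differ")
    lo, hi = sorted((barrier_px, anchor_px))
    if pixel < lo - tolerance_px or pixel > hi + tolerance_px:
        raise ValueError(
            f"pixel {pixel} outside tethered span [{lo}, {hi}] "
            f"by more than {tolerance_px} px"
        )
    frac = (pixel - barrier_px) / (anchor_px - barrier_px)
    return float(np.clip(frac * length, 0.0, length))


_AT_SET = frozenset("AT")
_ACGT = frozenset("ACGT")


def at_content_track(sequence: str, window: int = 500) -> np.ndarray:
    """Centered sliding-window A/T fraction per position.

    Edge positions use truncated windows.  Non-ACGT symbols count as
    non-AT and raise a warning.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if not (1 <= window <= n):
        raise ValueError(f"window must lie in [1, {n}], got {window}")
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    is_at = (arr == ord("A")) | (arr == ord("T"))
    bad = ~(
        is_at | (arr == ord("G")) | (arr == ord("C"))
    )
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} non-ACGT symbols counted as non-AT", UserWarning
        )
    half_lo = (window - 1) // 2
    half_hi = window - 1 - half_lo
    csum = np.concatenate([[0], np.cumsum(is_at)])
    idx = np.arange(n)
    lo = np.clip(idx - half_lo, 0, n)
    hi = np.clip(idx + half_hi + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def classify_at_region(value: float) -> str:
    """AT-rich iff the A/T fraction is >= 0.5 (boundary included)."""
    if not (0 <= value <= 1):
        raise ValueError(f"AT fraction must lie in [0, 1], got {value}")
    return "AT-rich" if value >= 0.5 else "GC-rich"


def bin_positions(positions: PositionSet, substrate: DNASubstrate) -> BinHistogram:
    """Histogram positions into the substrate's equal-width bins."""
    pos = positions.positions
    bad = np.flatnonzero((pos < 0) | (pos > substrate.length))
    if bad.size:
        raise ValueError(
            f"positions at indices {bad[:5].tolist()} outside "
            f"[0, {substrate.length}]"
        )
    edges = substrate.bin_edges
    idx = np.clip(
        np.searchsorted(edges, pos, side="right") - 1, 0, substrate.n_bins - 1
    )
    counts = np.bincount(idx, minlength=substrate.n_bins)
    return BinHistogram(
        bin_edges=edges, counts=counts, cbs_bins=substrate.cbs_bin_mask()
    )


def enrichment(hist: BinHistogram) -> EnrichmentResult:
    """Fold enrichment: mean count per CBS bin over mean count per
    non-CBS bin."""
    mask = hist.cbs_bins
    if not mask.any() or mask.all():
        raise ValueError("need at least one CBS bin and one non-CBS bin")
    cbs_mean = float(hist.counts[mask].mean())
    other_mean = float(hist.counts[~mask].mean())
    if other_mean == 0.0:
        warnings.warn("no molecules outside CBS bins; enrichment undefined", UserWarning)
        return EnrichmentResult(
            fold=math.inf,
            cbs_mean=cbs_mean,
            other_mean=0.0,
            n_cbs_bins=int(mask.sum()),
            n_other_bins=int((~mask).sum()),
            undefined=True,
        )
    return EnrichmentResult(
        fold=cbs_mean / other_mean,
        cbs_mean=cbs_mean,
        other_mean=other_mean,
        n_cbs_bins=int(mask.sum()),
        n_other_bins=int((~mask).sum()),
    )


def wash_survival_fraction(ids_before: Iterable, ids_after: Iterable) -> float:
    """Fraction of molecules present before a wash that persist after it."""
    before = set(ids_before)
    if not before:
        raise ValueError("empty before-wash molecule set")
    after = set(ids_after) & before
    return len(after) / len(before)
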