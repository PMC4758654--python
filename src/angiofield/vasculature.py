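"""Capillary-segment bookkeeping and the network functionality statistic S.

The vasculature is tracked as a list of segments: the pre-existing parent
vessel (length = the quarter-domain width) plus one sprout per tip-cell
activation, whose length is the cell's accumulated arc length.  The
functionality statistic

    S = l_max / sum_i l_i,   l_max = max_i l_i

is a crude inverse measure of network density used to scale the nutrient
production at capillaries: a single vessel gives S = 1, and every added
sprout lowers S, encoding the experimentally observed leakiness of dense
tumor-induced networks.

`skeleton_lengths_oracle` measures branch lengths directly from the capillary
phase field (threshold, skeletonize, split at branch points) and serves as an
independent cross-check of the tracked lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .grid_numerics import Grid

__all__ = ["Segment", "VascularNetwork", "compute_S", "grow_sprout",
           "skeleton_lengths_oracle"]


@dataclass
class Segment:
    id: int
    kind: str            # "parent" | "sprout"
    length: float
    open: bool = True    # an open sprout is still being led by its TEC

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("segment length must be strictly positive")


@dataclass
class VascularNetwork:
    """The capillary segments of the quarter domain."""

    segments: list[Segment] = field(default_factory=list)

    @classmethod
    def with_parent(cls, length: float) -> "VascularNetwork":
        return cls([Segment(id=0, kind="parent", length=length, open=False)])

    @property
    def n(self) -> int:
        return len(self.segments)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.segments])

    @property
    def l_max(self) -> float:
        return float(self.lengths.max())

    @property
    def S(self) -> float:
        return compute_S(self)

    def open_sprout(self, initial_length: float) -> int:
        """Register a new sprout; returns its segment id."""
        sid = max((s.id for s in self.segments), default=-1) + 1
        self.segments.append(Segment(id=sid, kind="sprout",
                                     length=max(initial_length, 1e-6)))
        return sid

    def close_sprout(self, sprout_id: int) -> None:
        self._find(sprout_id).open = False

    def _find(self, segment_id: int) -> Segment:
        for s in self.segments:
            if s.id == segment_id:
                return s
        raise KeyError(f"no segment with id {segment_id}")


def compute_S(network: VascularNetwork) -> float:
    """S = l_max / sum(l_i); 1 for a single vessel, in (0, 1] always."""
    if network.n == 0:
        raise ValueError("empty network")
    lengths = network.lengths
    return float(lengths.max() / lengths.sum())


def grow_sprout(network: VascularNetwork, sprout_id: int,
                d_length: float) -> VascularNetwork:
    """Extend an open sprout by the arc length its TEC just migrated."""
    if d_length < 0:
        raise ValueError("d_length must be nonnegative")
    seg = network._find(sprout_id)
    if not seg.open:
        raise ValueError(f"sprout {sprout_id} is closed")
    seg.length += d_length
    return network


# ---------------------------------------------------------------------------
# Skeleton-based independent length measurement
# ---------------------------------------------------------------------------

_NEIGHBOR_KERNEL = np.ones((3, 3), dtype=int)


def skeleton_lengths_oracle(c_field: np.ndarray, grid: Grid,
                            min_pixels: int = 3) -> list[float]:
    """Branch lengths of the capillary network measured from the c field.

    Thresholds c > 0, skeletonizes the mask, removes branch points (skeleton
    pixels with more than two neighbors), and returns the length of each
    remaining branch in nondimensional units (sum of inter-pixel step
    lengths, so diagonal steps count sqrt(2) spacings).
    """
    mask = np.asarray(c_field) > 0.0
    if not mask.any():
        raise ValueError("no capillary region (c > 0) in the field")
    if mask.all():
        raise ValueError("capillary mask covers the whole domain: no 1D structure")
    skel = skeletonize(mask)
    if not skel.any():
        raise ValueError("degenerate skeleton")
    neighbors = ndimage.convolve(skel.astype(int), _NEIGHBOR_KERNEL,
                                 mode="constant") - 1
    branches = skel & (neighbors <= 2)
    labels, n_labels = ndimage.label(branches, structure=_NEIGHBOR_KERNEL)
    step = 0.5 * (grid.dx + grid.dy)
    lengths = []
    for lab in range(1, n_labels + 1):
        ys, xs = np.nonzero(labels == lab)
        if len(xs) < min_pixels:
            continue
        lengths.append(_path_length(xs, ys) * step)
    if not lengths:
        raise ValueError("no branch longer than the minimum pixel count")
    return lengths


def _path_length(xs: np.ndarray, ys: np.ndarray) -> float:
    """Sum of 8-neighbor step lengths along one skeleton branch, in pixels."""
    pts = np.column_stack((xs, ys))
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    adjacent = (d2 > 0) & (d2 <= 2)
    steps = np.sqrt(d2[adjacent]).sum() / 2.0  # each pair counted twice
    # a simple path of n pixels has n-1 edges; junction-free branches are
    # simple up to occasional diagonal shortcuts, which slightly overcount
    return float(steps)
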