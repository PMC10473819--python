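"""Patch extraction and overlap aggregation for dynamic image series.

A dynamic series ``I`` of shape ``(M, N, T)`` is decomposed into spatiotemporal
patches of shape ``(K, K, T)`` by a sliding window with spatial stride ``w``
(patches always span the full time axis).  A pluggable segmenter maps each
patch to a per-pixel probability block; the patch-combination operator maps
the per-patch outputs back onto the image grid by combining, at every pixel,
the values assigned by all patches that cover it:

* the *mean* of the overlapping probabilities, binarized at 0.5 (inclusive),
  gives the segmentation mask;
* the *population standard deviation* of the overlapping probabilities gives
  the dynamic quality-control (dQC) map — a space-time map of inter-patch
  disagreement that is high exactly where the segmenter is unstable under
  spatial context changes.

Segmentation and dQC map are computed on separate grids: a coarse stride
(default 16) suffices for the mask, while the dQC map uses a dense stride
(default 2) so that each pixel is seen in many contexts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Sequence, Tuple

import numpy as np

__all__ = [
    "GeometryError",
    "SegmenterContractError",
    "ImageSeries",
    "MaskSeries",
    "PatchGrid",
    "OverlapIndex",
    "Segmenter",
    "plan_patch_grid",
    "build_overlap_index",
    "extract_patches",
    "aggregate",
    "segment_series",
    "compute_dqc_map",
]

#: A segmenter maps one ``(K, K, T)`` patch plus its ``(row, col)`` origin to a
#: ``(K, K, T)`` probability block with values in ``[0, 1]``.  It must be
#: deterministic given its own configured seed/state: the dQC pass may invoke
#: it more than once per patch.
Segmenter = Callable[[np.ndarray, Tuple[int, int]], np.ndarray]


class GeometryError(ValueError):
    """Patch geometry (K, stride) incompatible with the image extents."""


class SegmenterContractError(ValueError):
    """A segmenter returned something outside its contract."""


@dataclass(eq=False)
class ImageSeries:
    """A real-valued dynamic image, shape ``(M, N, T)``.

    Parameters
    ----------
    data
        Intensities, arbitrary units.  Must be finite.
    spacing
        Optional physical size per axis ``(mm, mm, s)``.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"image series must have 3 axes (row, col, time), got {self.data.ndim}"
            )
        if min(self.data.shape) < 1:
            raise ValueError("all axes must have extent >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image series contains non-finite values")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass(eq=False)
class MaskSeries:
    """A binary mask series, shape ``(M, N, T)``, values in {0, 1}.

    ``role`` tags the mask's provenance: ``prediction``, ``ground-truth`` or
    ``corrected``.
    """

    data: np.ndarray
    role: str = "prediction"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(
                f"mask series must have 3 axes (row, col, time), got {arr.ndim}"
            )
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be in {0, 1}")
        self.data = arr.astype(np.uint8)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def frame(self, t: int) -> np.ndarray:
        return self.data[:, :, t]


@dataclass(frozen=True)
class PatchGrid:
    """The patch extraction plan: size ``K``, stride ``w`` and patch origins.

    ``origins`` are 0-based ``(row, col)`` top-left anchors, unique and sorted
    row-major; the union of the ``K x K`` footprints covers the full ``M x N``
    extent.
    """

    K: int
    w: int
    M: int
    N: int
    origins: Tuple[Tuple[int, int], ...]

    @property
    def n_patches(self) -> int:
        return len(self.origins)


def _axis_origins(extent: int, K: int, w: int) -> List[int]:
    # Regular lattice 0, w, 2w, ... capped at extent-K, with the flush anchor
    # extent-K appended when the lattice does not land on it exactly.
    last = extent - K
    anchors = list(range(0, last + 1, w))
    if anchors[-1] != last:
        anchors.append(last)
    return anchors


def plan_patch_grid(M: int, N: int, K: int, w: int) -> PatchGrid:
    """Plan a sliding-window patch grid with stride ``w`` over ``M x N``.

    Row origins are ``{0, w, 2w, ...}`` capped at ``M - K``, with ``M - K``
    appended when ``(M - K) % w != 0`` so the bottom/right edges are always
    covered; similarly for columns.  Full coverage is guaranteed for any
    ``1 <= w <= K <= min(M, N)``.
    """
    if K < 1 or K > min(M, N):
        raise GeometryError(f"patch size K={K} must satisfy 1 <= K <= min(M, N)={min(M, N)}")
    if w < 1:
        raise GeometryError(f"stride w={w} must be >= 1")
    if w > K:
        raise GeometryError(f"stride w={w} must not exceed patch size K={K} (coverage gaps)")
    rows = _axis_origins(M, K, w)
    cols = _axis_origins(N, K, w)
    origins = tuple((r, c) for r in rows for c in cols)
    return PatchGrid(K=K, w=w, M=M, N=N, origins=origins)


@dataclass(eq=False)
class OverlapIndex:
    """Per-pixel patch coverage of a :class:`PatchGrid`.

    ``count[m, n]`` is the number of patches covering pixel ``(m, n)``
    (>= 1 everywhere by grid construction).  Full membership lists are
    available through :meth:`patches_covering` / :attr:`membership`; the
    aggregation routines never materialize them.
    """

    grid: PatchGrid
    count: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        cnt = np.zeros((self.grid.M, self.grid.N), dtype=np.int64)
        K = self.grid.K
        for r, c in self.grid.origins:
            cnt[r : r + K, c : c + K] += 1
        self.count = cnt

    def patches_covering(self, m: int, n: int) -> List[int]:
        """Indices (into ``grid.origins``) of the patches covering ``(m, n)``."""
        K = self.grid.K
        return [
            i
            for i, (r, c) in enumerate(self.grid.origins)
            if r <= m < r + K and c <= n < c + K
        ]

    @property
    def membership(self) -> List[List[List[int]]]:
        """Nested ``[M][N]`` lists of covering patch indices (O(P*K^2); small grids only)."""
        return [
            [self.patches_covering(m, n) for n in range(self.grid.N)]
            for m in range(self.grid.M)
        ]


def build_overlap_index(grid: PatchGrid) -> OverlapIndex:
    """Build the per-pixel coverage index for ``grid``."""
    return OverlapIndex(grid=grid)


def extract_patches(series: ImageSeries, grid: PatchGrid) -> np.ndarray:
    """Extract the ordered patch blocks, shape ``(P, K, K, T)``.

    Patch ``i`` equals the series restricted to footprint ``i`` over all
    frames; patches are full-depth in time.
    """
    M, N, _ = series.shape
    if (M, N) != (grid.M, grid.N):
        raise GeometryError(
            f"grid planned for {grid.M}x{grid.N} but series is {M}x{N}"
        )
    K = grid.K
    return np.stack([series.data[r : r + K, c : c + K, :] for r, c in grid.origins])


def _check_probabilities(block: np.ndarray, K: int, T: int, origin: Tuple[int, int]) -> np.ndarray:
    block = np.asarray(block, dtype=np.float64)
    if block.shape != (K, K, T):
        raise SegmenterContractError(
            f"segmenter returned shape {block.shape} for patch at {origin}, expected {(K, K, T)}"
        )
    if not np.all(np.isfinite(block)) or block.min() < 0.0 or block.max() > 1.0:
        raise SegmenterContractError(
            f"segmenter output at {origin} outside [0, 1]"
        )
    return block


def aggregate(stack: np.ndarray, index: OverlapIndex, mode: str) -> np.ndarray:
    """Combine a per-patch probability stack onto the image grid.

    Parameters
    ----------
    stack
        Array ``(P, K, K, T)`` aligned to ``index.grid.origins``, values in
        ``[0, 1]``.
    index
        Overlap index of the grid that produced the stack.
    mode
        ``"mean"`` or ``"std"``.  ``std`` is the population standard deviation
        (divisor = coverage count), so single-coverage pixels get exactly 0.

    Returns
    -------
    ndarray of shape ``(M, N, T)``.
    """
    if mode not in ("mean", "std"):
        raise ValueError(f"mode must be 'mean' or 'std', got {mode!r}")
    grid = index.grid
    K = grid.K
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 4 or stack.shape[0] != grid.n_patches or stack.shape[1:3] != (K, K):
        raise ValueError(
            f"stack shape {stack.shape} not aligned to grid ({grid.n_patches} patches of {K}x{K})"
        )
    T = stack.shape[3]
    cnt = index.count[:, :, None].astype(np.float64)

    acc = np.zeros((grid.M, grid.N, T), dtype=np.float64)
    for i, (r, c) in enumerate(grid.origins):
        acc[r : r + K, c : c + K, :] += stack[i]
    mean = acc / cnt
    if mode == "mean":
        return mean

    # Two-pass: squared deviations from the aggregated mean keep the result
    # exact to ~eps even when the per-pixel variance is tiny.
    sq = np.zeros_like(acc)
    for i, (r, c) in enumerate(grid.origins):
        d = stack[i] - mean[r : r + K, c : c + K, :]
        sq[r : r + K, c : c + K, :] += d * d
    return np.sqrt(sq / cnt)


def _stream_mean(
    data: np.ndarray, seg: Segmenter, grid: PatchGrid, cnt: np.ndarray
) -> np.ndarray:
    K = grid.K
    T = data.shape[2]
    acc = np.zeros((grid.M, grid.N, T), dtype=np.float64)
    for r, c in grid.origins:
        block = seg(data[r : r + K, c : c + K, :], (r, c))
        acc[r : r + K, c : c + K, :] += _check_probabilities(block, K, T, (r, c))
    return acc / cnt[:, :, None]


def segment_series(series: ImageSeries, seg: Segmenter, K: int, w_S: int) -> MaskSeries:
    """Segment a dynamic series: mean patch-combination binarized at 0.5.

    At each space-time location the probabilities of all covering patches are
    averaged; the mask is 1 where the mean is **>= 0.5** (inclusive
    threshold), 0 otherwise.
    """
    M, N, _ = series.shape
    grid = plan_patch_grid(M, N, K, w_S)
    index = build_overlap_index(grid)
    mean = _stream_mean(series.data, seg, grid, index.count)
    return MaskSeries((mean >= 0.5).astype(np.uint8), role="prediction")


def compute_dqc_map(
    series: ImageSeries,
    seg: Segmenter,
    K: int,
    w_M: int,
    w_S: int | None = None,
) -> np.ndarray:
    """Compute the dQC map: per-pixel inter-patch disagreement.

    ``map[m, n, t]`` is the population standard deviation of the probabilities
    assigned to ``(m, n, t)`` by every patch of the stride-``w_M`` grid that
    covers it.  This is a denser, independent inference pass from the
    segmentation grid; pass ``w_S`` to get a warning when ``w_M > w_S``
    (the dQC grid is meant to be at least as dense as the segmentation grid).

    The segmenter is invoked twice per patch (mean pass, then deviation pass)
    so the full probability stack never has to be held in memory; the
    Segmenter contract requires determinism, which makes this exact.

    Returns
    -------
    ndarray ``(M, N, T)`` with values in ``[0, 0.5]``; exactly 0 at pixels
    covered by a single patch, ~0 (to machine precision) wherever all covering
    patches agree.
    """
    if w_S is not None and w_M > w_S:
        warnings.warn(
            f"dQC stride w_M={w_M} is coarser than segmentation stride w_S={w_S}; "
            "the disagreement map will be undersampled",
            stacklevel=2,
        )
    M, N, T = series.shape
    grid = plan_patch_grid(M, N, K, w_M)
    index = build_overlap_index(grid)
    cnt = index.count[:, :, None].astype(np.float64)
    data = series.data

    mean = _stream_mean(data, seg, grid, index.count)
    sq = np.zeros((M, N, T), dtype=np.float64)
    for r, c in grid.origins:
        block = seg(data[r : r + K, c : c + K, :], (r, c))
        block = _check_probabilities(block, K, T, (r, c))
        d = block - mean[r : r + K, c : c + K, :]
        sq[r : r + K, c : c + K, :] += d * d
    return np.sqrt(sq / cnt)
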