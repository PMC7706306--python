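"""Relative leaf-wilting quantification from time-lapse plant images.

The score for a frame pair (t-w, t) is built in four stages: a dense optical
flow field between the two frames; an excess-green (ExG) plant mask taken from
the later frame; a two-bin histogram of oriented optical flow (HOOF) that
accumulates each masked vector's Euclidean magnitude into an upward or a
downward bin by the sign of its vertical component; and the scalar

    delta_wilt = (up_sum - down_sum) / masked_pixel_count,

in pixels per masked pixel.  Image row indices increase downward, so downward
leaf motion has v > 0: negative delta_wilt means net wilting, positive means
recovery.

The flow estimator is pluggable.  ``deepflow`` delegates to OpenCV's DeepFlow
when cv2 is importable and raises a capability error otherwise;
``dense_reference`` uses scikit-image's iterative Lucas-Kanade dense flow; and
``block_match`` is a built-in exhaustive integer-shift patch matcher whose
determinism (zero-shift preferred on cost ties) makes it the test backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ImageSequence",
    "FlowField",
    "FlowSequence",
    "HoofBins",
    "FlowBackendUnavailable",
    "exg_index",
    "plant_mask",
    "estimate_flow",
    "hoof_bins",
    "delta_wilt",
    "quantify_wilt_series",
    "quantify_wilt_from_flows",
]

WORKING_SIZE = 144  # frames are analysed at 144 x 144


class FlowBackendUnavailable(RuntimeError):
    """Requested optical-flow backend cannot run in this installation."""


@dataclass
class ImageSequence:
    """Timestamped, equally sized RGB frames for one plant.

    ``frames`` has shape (T, H, W, 3), dtype uint8; ``timestamps`` is a
    strictly increasing minute-resolution DatetimeIndex.  ``true_plant_masks``
    is filled by the synthetic renderer (ground-truth painted-pixel sets) and
    is None for real imagery.
    """

    frames: np.ndarray
    timestamps: pd.DatetimeIndex
    plant_id: str = "plant"
    true_plant_masks: np.ndarray | None = None
    gaps: list = field(default_factory=list)  # missing minutes, recorded explicitly

    def __post_init__(self):
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (T, H, W, 3)")
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if len(self.timestamps) != len(set(self.timestamps)):
            raise ValueError("timestamps must be unique")
        if not self.timestamps.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")

    def __len__(self):
        return len(self.frames)


@dataclass
class FlowField:
    """Per-pixel displacement planes: u rightward, v downward (row-index) pixels."""

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must have identical shapes")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("flow values must be finite")


@dataclass
class FlowSequence:
    """Precomputed (t-w, t) flow fields with plant masks, bypassing estimation."""

    timestamps: pd.DatetimeIndex
    flows: list
    masks: list
    window_w: int = 5


@dataclass
class HoofBins:
    """Two-bin magnitude-weighted histogram of oriented optical flow."""

    up_sum: float
    down_sum: float
    masked_pixel_count: int


def exg_index(rgb):
    """Excess-green index 2g - r - b on chromatic (brightness-normalised) coordinates.

    Accepts a single (R, G, B) triple or an (..., 3) array with values 0-255.
    An all-zero pixel returns 0 by convention.  Range is [-1, 2].
    """
    arr = np.asarray(rgb, dtype=float)
    scalar = arr.ndim == 1
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    total = r + g + b
    with np.errstate(divide="ignore", invalid="ignore"):
        exg = np.where(total > 0, (2.0 * g - r - b) / np.where(total > 0, total, 1.0), 0.0)
    return float(exg) if scalar else exg


def plant_mask(frame: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Boolean plant mask: pixels with ExG strictly above ``threshold``."""
    return exg_index(frame) > threshold


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 3:
        return frame.astype(float).mean(axis=2)
    return frame.astype(float)


def _shift_image(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer shift with edge replication (content moves by (dy, dx))."""
    h, w = img.shape
    padded = np.pad(img, ((abs(dy),) * 2, (abs(dx),) * 2), mode="edge")
    return padded[abs(dy) - dy : abs(dy) - dy + h, abs(dx) - dx : abs(dx) - dx + w]


def _box_sum(arr: np.ndarray, block: int) -> np.ndarray:
    """Windowed sum with zero padding; exact for integer-valued float input."""
    h = block // 2
    padded = np.pad(arr, h)
    ii = np.pad(padded, ((1, 0), (1, 0))).cumsum(axis=0).cumsum(axis=1)
    n = arr.shape[0] + 2 * h
    m = arr.shape[1] + 2 * h
    return (
        ii[block : n + 1, block : m + 1]
        - ii[: n + 1 - block, block : m + 1]
        - ii[block : n + 1, : m + 1 - block]
        + ii[: n + 1 - block, : m + 1 - block]
    )


def _block_match(frame_a, frame_b, radius: int = 4, block: int = 9) -> FlowField:
    """Exhaustive integer-shift matcher over ``block`` x ``block`` patches.

    For each pixel the shift (dy, dx), |dy|,|dx| <= radius, minimising the
    local sum of squared intensity differences is chosen.  Costs are exact
    integer arithmetic (channel sums, integral-image box sums), and candidates
    are scanned in order of increasing |dy|+|dx| with strict-improvement
    updates, so cost ties resolve to the smallest shift and identical frames
    yield an exactly zero field.
    """
    a = frame_a.astype(np.float64).sum(axis=2) if frame_a.ndim == 3 else frame_a.astype(np.float64)
    b = frame_b.astype(np.float64).sum(axis=2) if frame_b.ndim == 3 else frame_b.astype(np.float64)
    shifts = sorted(
        ((dy, dx) for dy in range(-radius, radius + 1) for dx in range(-radius, radius + 1)),
        key=lambda s: (abs(s[0]) + abs(s[1]), abs(s[0]), abs(s[1]), s[0] < 0, s[1] < 0),
    )
    best_cost = np.full(a.shape, np.inf)
    best_dy = np.zeros(a.shape, dtype=np.int32)
    best_dx = np.zeros(a.shape, dtype=np.int32)
    for dy, dx in shifts:
        # a(p) should land on b(p + d): compare a with b pulled back by d
        candidate = _shift_image(b, -dy, -dx)
        cost = _box_sum((a - candidate) ** 2, block)
        better = cost < best_cost
        best_cost[better] = cost[better]
        best_dy[better] = dy
        best_dx[better] = dx
    return FlowField(u=best_dx.astype(float), v=best_dy.astype(float))


def _dense_reference(frame_a, frame_b) -> FlowField:
    from skimage.registration import optical_flow_ilk

    # optical_flow_ilk(reference, moving) returns the displacement of
    # reference content toward moving, matching this package's convention.
    v, u = optical_flow_ilk(_to_gray(frame_a), _to_gray(frame_b))
    return FlowField(u=u, v=v)


def _deepflow(frame_a, frame_b) -> FlowField:
    try:
        import cv2  # noqa: F401

        create = cv2.optflow.createOptFlow_DeepFlow
    except (ImportError, AttributeError) as err:
        raise FlowBackendUnavailable(
            "deepflow backend requires opencv-contrib-python (cv2.optflow); "
            "use method='dense_reference' or 'block_match'"
        ) from err
    gray_a = _to_gray(frame_a).astype(np.uint8)
    gray_b = _to_gray(frame_b).astype(np.uint8)
    flow = create().calc(gray_a, gray_b, None)
    return FlowField(u=flow[..., 0].astype(float), v=flow[..., 1].astype(float))


_BACKENDS = {
    "deepflow": _deepflow,
    "dense_reference": _dense_reference,
    "block_match": _block_match,
}


def estimate_flow(frame_a, frame_b, method: str = "block_match", **kwargs) -> FlowField:
    """Dense displacement field mapping ``frame_a`` (earlier) toward ``frame_b``."""
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must have identical dimensions")
    if method not in _BACKENDS:
        raise ValueError(f"unknown flow method {method!r}; choose from {sorted(_BACKENDS)}")
    return _BACKENDS[method](frame_a, frame_b, **kwargs)


def hoof_bins(flow: FlowField, mask: np.ndarray) -> HoofBins:
    """Aggregate masked flow vectors into up/down magnitude-weighted bins.

    A vector contributes its Euclidean magnitude to the downward bin when
    v > 0 (down-screen), to the upward bin when v < 0, and to neither when
    v == 0 (purely horizontal motion is uninformative for wilting).
    """
    if flow.u.shape != mask.shape:
        raise ValueError("flow and mask dimensions must match")
    count = int(mask.sum())
    if count == 0:
        raise ValueError("empty plant mask: no plant area")
    mag = np.hypot(flow.u, flow.v)
    v = flow.v
    up = float(mag[mask & (v < 0)].sum())
    down = float(mag[mask & (v > 0)].sum())
    return HoofBins(up_sum=up, down_sum=down, masked_pixel_count=count)


def delta_wilt(bins: HoofBins) -> float:
    """delta_wilt = (up_sum - down_sum) / masked_pixel_count (pixels per masked pixel)."""
    if bins.masked_pixel_count <= 0:
        raise ValueError("masked_pixel_count must be positive")
    return (bins.up_sum - bins.down_sum) / bins.masked_pixel_count


def _resize_frame(frame: np.ndarray, size: int = WORKING_SIZE) -> np.ndarray:
    if frame.shape[0] == size and frame.shape[1] == size:
        return frame
    from skimage.transform import resize

    out = resize(frame, (size, size, 3), anti_aliasing=True, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def quantify_wilt_series(
    images: ImageSequence,
    w: int = 5,
    stride: int = 1,
    method: str = "block_match",
    exg_threshold: float = 0.0,
    **flow_kwargs,
) -> pd.DataFrame:
    """Compute the delta_wilt series over a moving w-minute window.

    For each timestamp t (every ``stride`` minutes) with both frames t and
    t - w present, the (t-w, t) pair is scored using the ExG mask of the later
    frame.  Timestamps with a missing partner are skipped and recorded in the
    result's ``attrs['gaps']``.

    Returns a DataFrame indexed by timestamp with columns ``delta_wilt, up,
    down, masked_pixels``; ``attrs`` carry ``w``, ``method`` and ``gaps``.
    """
    if w < 1 or stride < 1:
        raise ValueError("w and stride must be >= 1 minute")
    if len(images) < 2:
        raise ValueError("need at least two frames")
    frames = np.stack([_resize_frame(f) for f in images.frames])
    index = {ts: i for i, ts in enumerate(images.timestamps)}
    lag = pd.Timedelta(minutes=w)
    rows, gaps = [], []
    for pos, ts in enumerate(images.timestamps):
        if pos % stride:
            continue
        earlier = ts - lag
        if earlier not in index:
            gaps.append(ts)
            continue
        later_frame = frames[index[ts]]
        flow = estimate_flow(frames[index[earlier]], later_frame, method=method, **flow_kwargs)
        mask = plant_mask(later_frame, threshold=exg_threshold)
        bins = hoof_bins(flow, mask)
        rows.append((ts, delta_wilt(bins), bins.up_sum, bins.down_sum, bins.masked_pixel_count))
    out = pd.DataFrame(
        rows, columns=["timestamp", "delta_wilt", "up", "down", "masked_pixels"]
    ).set_index("timestamp")
    out.attrs.update(w=w, method=method, gaps=gaps, plant_id=images.plant_id)
    return out


def quantify_wilt_from_flows(flow_seq: FlowSequence) -> pd.DataFrame:
    """delta_wilt series from precomputed (t-w, t) flow fields (fast path)."""
    rows = []
    for ts, flow, mask in zip(flow_seq.timestamps, flow_seq.flows, flow_seq.masks):
        bins = hoof_bins(flow, mask)
        rows.append((ts, delta_wilt(bins), bins.up_sum, bins.down_sum, bins.masked_pixel_count))
    out = pd.DataFrame(
        rows, columns=["timestamp", "delta_wilt", "up", "down", "masked_pixels"]
    ).set_index("timestamp")
    out.attrs.update(w=flow_seq.window_w, method="precomputed", gaps=[])
    return out
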