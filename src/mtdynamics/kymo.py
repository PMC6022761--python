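"""Movie-to-kymograph-to-trace pipeline.

Seeds are detected by intensity thresholding on the (fiducial, immobile)
seed channel; frames are drift-corrected by phase correlation; each frame is
rotated so the microtubule axis is horizontal, cropped to a band around the
axis, and max-projected to one row; rows stacked in time order form the
kymograph.  Length per frame is then the distance from the chosen seed end
to the farthest contiguous above-threshold pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.registration import phase_cross_correlation
from skimage.transform import rotate as _sk_rotate

from .trace import LengthTrace

__all__ = [
    "Kymograph",
    "Seed",
    "RegistrationResult",
    "detect_seeds",
    "register_frames",
    "build_kymograph",
    "track_length",
]


@dataclass
class Kymograph:
    """2-D intensity matrix, one row per time point along the axis.

    Axial pixel 0 sits at one end of the seed; positions increase toward the
    tracked (plus) end.  ``seed_span_px`` is the [start, end) pixel span of
    the stabilized seed along the axis.
    """

    intensity: np.ndarray
    pixel_size_nm: float
    frame_interval_s: float
    seed_span_px: tuple[int, int] = (0, 0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2-D (time x position) matrix")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        if self.pixel_size_nm <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibration must be positive")
        s, e = self.seed_span_px
        if not (0 <= s <= e <= self.intensity.shape[1]):
            raise ValueError("seed_span_px must lie within the matrix")

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class Seed:
    """One detected seed: centroid (row, col), axis angle, endpoints."""

    centroid: tuple[float, float]
    angle_deg: float
    endpoints: tuple[tuple[float, float], tuple[float, float]]
    length_px: float


def detect_seeds(
    seed_image: np.ndarray,
    threshold: float | None = None,
    min_length_px: float = 5.0,
) -> list[Seed]:
    """Detect seeds by thresholding a single-channel image.

    One record per connected above-threshold component whose major-axis
    extent exceeds ``min_length_px``.  The axis angle (degrees from the
    column axis, positive toward increasing row index, in (-90, 90]) comes
    from the component's principal direction.  An empty or uniform image
    yields an empty list.
    """
    img = np.asarray(seed_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("seed_image must be 2-D")
    if img.max() == img.min():
        return []
    thr = threshold_otsu(img) if threshold is None else threshold
    mask = img > thr
    if not mask.any():
        return []
    lab = label(mask)
    out: list[Seed] = []
    for region in regionprops(lab):
        coords = region.coords.astype(float)  # (n, 2) as (row, col)
        centroid = coords.mean(axis=0)
        centered = coords - centroid
        # principal direction via SVD of the pixel cloud
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]  # (drow, dcol)
        if axis[1] < 0:
            axis = -axis
        angle = math.degrees(math.atan2(axis[0], axis[1]))
        proj = centered @ axis
        length = float(proj.max() - proj.min())
        if length < min_length_px:
            continue
        p0 = tuple(centroid + proj.min() * axis)
        p1 = tuple(centroid + proj.max() * axis)
        out.append(
            Seed(
                centroid=(float(centroid[0]), float(centroid[1])),
                angle_deg=angle,
                endpoints=(p0, p1),
                length_px=length,
            )
        )
    out.sort(key=lambda s: -s.length_px)
    return out


@dataclass
class RegistrationResult:
    frames: np.ndarray
    shifts: np.ndarray  # (T, 2) (drow, dcol) shift of each frame vs the first
    featureless: np.ndarray  # per-frame warning flag


def register_frames(
    frames: np.ndarray,
    upsample_factor: int = 20,
    apply_to: np.ndarray | None = None,
) -> RegistrationResult:
    """Remove XY drift by phase-correlating every frame to the first.

    Registration is estimated on ``frames`` (normally the seed channel,
    whose content is immobile) and applied to ``apply_to`` when given
    (normally the dynamic channel), else to ``frames`` itself.  Featureless
    frames get zero shift and a warning flag.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (T, H, W) stack with at least 2 frames")
    target = frames if apply_to is None else np.asarray(apply_to, dtype=float)
    if target.shape != frames.shape:
        raise ValueError("apply_to must match frames in shape")
    ref = frames[0]
    T = frames.shape[0]
    shifts = np.zeros((T, 2))
    featureless = np.zeros(T, dtype=bool)
    out = np.empty_like(target)
    out[0] = target[0]
    ref_flat = ref.std() == 0
    for i in range(1, T):
        if ref_flat or frames[i].std() == 0:
            featureless[i] = True
            out[i] = target[i]
            continue
        correction, _, _ = phase_cross_correlation(
            ref, frames[i], upsample_factor=upsample_factor
        )
        shifts[i] = -correction  # displacement of the frame vs the reference
        out[i] = ndimage.shift(target[i], correction, order=1, mode="nearest")
    return RegistrationResult(frames=out, shifts=shifts, featureless=featureless)


def build_kymograph(
    movie: np.ndarray,
    seed: Seed,
    pixel_size_nm: float,
    frame_interval_s: float,
    crop_halfwidth_px: int = 4,
    width_px: int | None = None,
) -> Kymograph:
    """Rotate, crop, and max-project each frame into one kymograph row.

    Every frame is rotated about the seed centroid so the axis is horizontal
    (bilinear interpolation), cropped to ``crop_halfwidth_px`` rows above and
    below the axis, and max-projected across rows.  Axial pixel 0 is the
    seed's minus end (the endpoint with the smaller axial coordinate).
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be (T, H, W)")
    if crop_halfwidth_px < 1:
        raise ValueError("crop_halfwidth_px must be >= 1")
    T, H, W = movie.shape
    cy, cx = seed.centroid
    if not (crop_halfwidth_px <= cy <= H - 1 - crop_halfwidth_px):
        raise ValueError(
            f"axis too close to the image border for a +/-{crop_halfwidth_px} px crop"
        )

    # axial coordinate of the seed endpoints after rotation about the centroid
    def _axial(p):
        dr, dc = p[0] - cy, p[1] - cx
        th = math.radians(seed.angle_deg)
        return cx + dc * math.cos(th) + dr * math.sin(th)

    ax0 = min(_axial(seed.endpoints[0]), _axial(seed.endpoints[1]))
    ax1 = max(_axial(seed.endpoints[0]), _axial(seed.endpoints[1]))
    origin = int(round(ax0))

    rows = []
    row_lo = int(round(cy)) - crop_halfwidth_px
    row_hi = int(round(cy)) + crop_halfwidth_px + 1
    for t in range(T):
        if abs(seed.angle_deg) > 1e-9:
            frame = _sk_rotate(
                movie[t],
                angle=seed.angle_deg,
                center=(cx, cy),
                order=1,
                preserve_range=True,
                mode="edge",
            )
        else:
            frame = movie[t]
        band = frame[row_lo:row_hi, :]
        rows.append(band.max(axis=0))
    mat = np.asarray(rows)[:, origin:]
    if width_px is not None:
        mat = mat[:, :width_px]
    seed_span = (0, max(int(round(ax1)) - origin, 1))
    return Kymograph(
        intensity=np.maximum(mat, 0.0),
        pixel_size_nm=pixel_size_nm,
        frame_interval_s=frame_interval_s,
        seed_span_px=seed_span,
        meta={"crop_halfwidth_px": crop_halfwidth_px, "seed_angle_deg": seed.angle_deg},
    )


def _farthest_contiguous(above: np.ndarray, start: int, step: int, max_gap: int) -> int:
    """Index of the farthest above-threshold pixel reachable from ``start``
    walking in direction ``step`` without crossing a gap longer than
    ``max_gap`` consecutive below-threshold pixels.  Returns -1 if the first
    pixel is already part of a terminating gap."""
    last = -1
    gap = 0
    i = start
    n = above.size
    while 0 <= i < n:
        if above[i]:
            last = i
            gap = 0
        else:
            gap += 1
            if gap > max_gap:
                break
        i += step
    return last


def track_length(
    kymo: Kymograph,
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
    k_sd: float = 3.0,
    direction: str = "auto",
    max_gap_px: int = 1,
) -> LengthTrace:
    """Per-frame microtubule length by intensity thresholding.

    Length is the distance (pixels x pixel size) from the chosen seed end to
    the farthest contiguous above-threshold pixel; a gap of more than
    ``max_gap_px`` consecutive below-threshold pixels terminates the
    microtubule (guards against speckle).  ``threshold_method`` is one of
    ``otsu`` (global Otsu, default), ``fixed`` (``threshold_value``), or
    ``background`` (robust background mean + ``k_sd`` x SD).  ``direction``
    selects the tracked plus end: ``right``/``left`` of the seed span, or
    ``auto`` = the end with the larger net length change over the movie.
    Frames entirely below threshold get length 0 with a flag.
    """
    img = kymo.intensity
    if threshold_method == "otsu":
        thr = threshold_otsu(img)
    elif threshold_method == "fixed":
        if threshold_value is None:
            raise ValueError("threshold_value required for method 'fixed'")
        thr = threshold_value
    elif threshold_method == "background":
        # robust background: quartile below the midpoint + MAD-based SD
        lo = img[img <= np.percentile(img, 25)]
        bg = float(np.median(lo))
        sd = 1.4826 * float(np.median(np.abs(lo - bg))) or float(lo.std()) or 1.0
        thr = bg + k_sd * sd
    else:
        raise ValueError("threshold_method must be otsu|fixed|background")

    above = img > thr
    s0, s1 = kymo.seed_span_px
    n_px = img.shape[1]

    def _measure(side: str) -> tuple[np.ndarray, np.ndarray]:
        lengths = np.zeros(kymo.n_frames)
        flags = np.zeros(kymo.n_frames, dtype=bool)
        for t in range(kymo.n_frames):
            # length runs from the seed boundary (pixel edge) to the center
            # of the farthest pixel plus half a pixel
            if side == "right":
                start = min(s1, n_px - 1)
                far = _farthest_contiguous(above[t], start, +1, max_gap_px)
                px_count = far - s1 + 0.5 if far >= s1 else 0.0
            else:
                start = max(s0 - 1, 0)
                far = _farthest_contiguous(above[t], start, -1, max_gap_px)
                px_count = s0 - far - 0.5 if (0 <= far < s0) else 0.0
            if px_count <= 0:
                flags[t] = True
                lengths[t] = 0.0
            else:
                lengths[t] = px_count * kymo.pixel_size_nm / 1000.0
        return lengths, flags

    if direction == "auto":
        right, rf = _measure("right")
        left, lf = _measure("left")
        if abs(right[-1] - right[0]) >= abs(left[-1] - left[0]):
            lengths, flags, chosen = right, rf, "right"
        else:
            lengths, flags, chosen = left, lf, "left"
    elif direction in ("right", "left"):
        lengths, flags = _measure(direction)
        chosen = direction
    else:
        raise ValueError("direction must be auto|right|left")

    return LengthTrace(
        times_s=kymo.times_s,
        lengths_um=lengths,
        frame_interval_s=kymo.frame_interval_s,
        flags=flags,
        meta={
            "threshold": float(thr),
            "threshold_method": threshold_method,
            "direction": chosen,
            "max_gap_px": max_gap_px,
        },
    )
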