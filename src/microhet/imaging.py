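"""Colony detection, segmentation, tracking and quantification.

The pipeline mirrors the scanner-array colony assay: convert the RGB
time-lapse to grayscale, project the per-pixel temporal standard
deviation (growing colonies leave a high-variance footprint, static agar
does not), Otsu-threshold within the plate to correct for illumination
differences between plates, split touching colonies by a watershed
seeded at the h-maxima of the std projection, link per-frame labels
across time by gated nearest-centroid assignment, and filter artifact
tracks.  Each surviving track carries per-frame area and mean RGB plus
the colony's plate coordinates and distance to the plate center.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from skimage import measure, morphology, segmentation
from skimage.filters import gaussian, threshold_otsu
from skimage.transform import hough_circle, hough_circle_peaks
from skimage.feature import canny

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "ColonyTrack",
    "QCConfig",
    "DegenerateThresholdError",
    "plate_mask",
    "detect_plate",
    "project_temporal_std",
    "threshold_plate",
    "segment_colonies",
    "track_colonies",
    "filter_artifacts",
    "extract_phenotype_inputs",
    "extract_colony_tracks",
    "tracks_to_frame",
]


class DegenerateThresholdError(ValueError):
    """Otsu threshold undefined: constant intensity inside the plate."""


@dataclass
class ImageStack:
    """An ordered RGB plate time-lapse with plate geometry.

    frames: (T, H, W, 3) float array; frame_times in minutes, strictly
    increasing; plate_center (row, col) and plate_radius in pixels.
    """

    frames: np.ndarray
    frame_times: np.ndarray
    plate_center: tuple[float, float]
    plate_radius: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (T, H, W, 3)")
        if self.frame_times.size != self.frames.shape[0]:
            raise ValueError("one frame time per frame required")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        h, w = self.frames.shape[1:3]
        r, c = self.plate_center
        if not (0 <= r - self.plate_radius and r + self.plate_radius < h
                and 0 <= c - self.plate_radius and c + self.plate_radius < w):
            raise ValueError("plate circle must lie inside the raster")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_h(self) -> np.ndarray:
        return self.frame_times / 60.0

    def grayscale(self) -> np.ndarray:
        """Mean of the RGB channels per frame."""
        return self.frames.mean(axis=-1)

    def mask(self) -> np.ndarray:
        return plate_mask(self.frames.shape[1:3], self.plate_center, self.plate_radius)

    @classmethod
    def from_frames(cls, frames, frame_interval_min: float,
                    plate_center=None, plate_radius=None) -> "ImageStack":
        frames = np.asarray(frames, dtype=float)
        times = np.arange(frames.shape[0]) * frame_interval_min
        if plate_center is None or plate_radius is None:
            plate_center, plate_radius = detect_plate(frames[0].mean(axis=-1))
        return cls(frames, times, tuple(plate_center), float(plate_radius))


def plate_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def detect_plate(gray: np.ndarray, radius_fraction=(0.30, 0.49)):
    """Locate the plate by a Hough circle transform on the first frame.

    Falls back to the largest inscribed circle when no strong circle is
    found (e.g. synthetic frames with a weak rim edge).
    """
    h, w = gray.shape
    edges = canny(gray, sigma=2.0)
    radii = np.arange(int(radius_fraction[0] * min(h, w)),
                      int(radius_fraction[1] * min(h, w)), 4)
    fallback = ((h - 1) / 2.0, (w - 1) / 2.0), 0.98 * min(h, w) / 2.0
    if radii.size == 0 or not edges.any():
        return fallback
    accum = hough_circle(edges, radii)
    accums, cx, cy, rad = hough_circle_peaks(accum, radii, total_num_peaks=1)
    if len(accums) == 0 or accums[0] < 0.2:
        return fallback
    return (float(cy[0]), float(cx[0])), float(rad[0])


def project_temporal_std(stack: ImageStack) -> np.ndarray:
    """Per-pixel population SD across frames of the grayscale stack."""
    if stack.n_frames < 2:
        raise ValueError("temporal std needs at least 2 frames")
    return stack.grayscale().std(axis=0)


def threshold_plate(raster: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Otsu threshold computed from in-plate pixels only.

    Returns the binary foreground (pixels above threshold, inside the
    mask); a constant raster inside the mask is a degenerate case.
    """
    vals = raster[mask]
    if vals.size == 0 or np.ptp(vals) == 0:
        raise DegenerateThresholdError("constant raster inside plate mask")
    thr = threshold_otsu(vals)
    return (raster > thr) & mask


def segment_colonies(std_raster: np.ndarray, binary_mask: np.ndarray,
                     h: float | None = None, smooth_sigma: float = 1.0) -> np.ndarray:
    """Watershed split of the foreground, seeded at std-projection maxima.

    Markers are the h-maxima of the (lightly smoothed) std raster within
    the foreground; regions without a marker fall back to seeds from the
    distance-transform maxima.  Returns a labeled raster (0 background).
    """
    if not binary_mask.any():
        return np.zeros_like(binary_mask, dtype=np.int32)
    smooth = gaussian(std_raster, sigma=smooth_sigma, preserve_range=True)
    if h is None:
        inside = smooth[binary_mask]
        h = max(0.05 * float(np.ptp(inside)), 1e-6)
    peaks = morphology.h_maxima(np.where(binary_mask, smooth, 0.0), h)
    markers = measure.label(peaks & binary_mask)
    # flat foreground regions with no std maximum: seed from distance map
    from scipy import ndimage as ndi
    comp = measure.label(binary_mask)
    missing = np.setdiff1d(np.unique(comp[comp > 0]),
                           np.unique(comp[markers > 0]))
    if missing.size:
        dist = ndi.distance_transform_edt(binary_mask)
        nmark = markers.max()
        for lab in missing:
            region = comp == lab
            peak = np.unravel_index(np.argmax(np.where(region, dist, -1)), dist.shape)
            nmark += 1
            markers[peak] = nmark
    labels = segmentation.watershed(-smooth, markers, mask=binary_mask)
    return labels.astype(np.int32)


@dataclass
class ColonyTrack:
    """One colony's time-indexed trace.

    centroid rows are (row, col) with NaN before detection; area is 0
    for missing/pre-detection frames; mean_rgb is NaN when absent.
    ``x``/``y`` are the plate coordinates (col, row) of the final
    centroid; ``distance_to_center`` is filled by the pipeline.
    """

    colony_id: int
    frame_times: np.ndarray        # minutes
    centroids: np.ndarray          # (T, 2)
    areas: np.ndarray              # (T,)
    mean_rgb: np.ndarray           # (T, 3)
    distance_to_center: float = np.nan
    interpolated: np.ndarray | None = None

    @property
    def final_centroid(self) -> np.ndarray:
        ok = ~np.isnan(self.centroids[:, 0])
        return self.centroids[np.where(ok)[0][-1]]

    @property
    def x(self) -> float:
        return float(self.final_centroid[1])

    @property
    def y(self) -> float:
        return float(self.final_centroid[0])

    @property
    def n_detected(self) -> int:
        return int(np.sum(self.areas > 0))


def _frame_regions(labels: np.ndarray, frame: np.ndarray | None):
    """(label, centroid, area, mean_rgb) per region of one labeled raster."""
    out = []
    for reg in measure.regionprops(labels):
        if frame is not None:
            coords = reg.coords
            rgb = frame[coords[:, 0], coords[:, 1]].mean(axis=0)
        else:
            rgb = np.full(3, np.nan)
        out.append((reg.label, np.array(reg.centroid), reg.area, rgb))
    return out


def track_colonies(labels_per_frame, frames=None, frame_times=None,
                   max_displacement: float | None = None) -> list[ColonyTrack]:
    """Link per-frame labels into colony tracks.

    Frame-to-frame association is a gated minimum-cost (Hungarian)
    nearest-centroid assignment; pairs farther apart than the gate are
    never linked, so identity swaps beyond the gate terminate tracks
    instead.  The default gate is 1.5x the median equivalent colony
    radius in the current frame (floor 5 px).  Colonies absent before
    detection carry zero area for those frames.
    """
    n_frames = len(labels_per_frame)
    if frame_times is None:
        frame_times = np.arange(n_frames, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    shape0 = labels_per_frame[0].shape
    for lab in labels_per_frame:
        if lab.shape != shape0:
            raise ValueError("labeled rasters must share one shape")

    tracks: list[dict] = []   # each: last_centroid, rows of per-frame data
    active: list[int] = []

    for f in range(n_frames):
        frame = frames[f] if frames is not None else None
        regions = _frame_regions(labels_per_frame[f], frame)
        if regions:
            radii = np.sqrt(np.array([r[2] for r in regions]) / np.pi)
            gate = max_displacement if max_displacement is not None else \
                max(1.5 * float(np.median(radii)), 5.0)
        else:
            gate = 0.0

        assigned_regions = set()
        if active and regions:
            cost = np.full((len(active), len(regions)), 1e9)
            for i, ti in enumerate(active):
                last = tracks[ti]["last_centroid"]
                for j, (_, cen, _, _) in enumerate(regions):
                    d = float(np.hypot(*(cen - last)))
                    if d <= gate:
                        cost[i, j] = d
            ri, rj = linear_sum_assignment(cost)
            for i, j in zip(ri, rj):
                if cost[i, j] >= 1e9:
                    continue
                ti = active[i]
                _, cen, area, rgb = regions[j]
                tracks[ti]["data"][f] = (cen, area, rgb)
                tracks[ti]["last_centroid"] = cen
                tracks[ti]["last_seen"] = f
                assigned_regions.add(j)

        for j, (_, cen, area, rgb) in enumerate(regions):
            if j in assigned_regions:
                continue
            tracks.append({"last_centroid": cen, "last_seen": f,
                           "data": {f: (cen, area, rgb)}})
        active = [i for i, tr in enumerate(tracks)]

    out = []
    for cid, tr in enumerate(tracks):
        centroids = np.full((n_frames, 2), np.nan)
        areas = np.zeros(n_frames)
        rgbs = np.full((n_frames, 3), np.nan)
        for f, (cen, area, rgb) in tr["data"].items():
            centroids[f] = cen
            areas[f] = area
            rgbs[f] = rgb
        out.append(ColonyTrack(colony_id=cid, frame_times=frame_times,
                               centroids=centroids, areas=areas, mean_rgb=rgbs))
    return out


@dataclass
class QCConfig:
    """Artifact-filter thresholds; ``None`` disables a rule."""

    min_frames: int | None = 5
    min_final_area: float | None = 4.0
    max_final_area: float | None = None
    edge_margin: float | None = 10.0
    max_rel_area_drop: float | None = 0.3


def filter_artifacts(tracks, qc: QCConfig,
                     plate_center=None, plate_radius=None) -> list[ColonyTrack]:
    """Drop tracks failing quality control.

    Rules: too few detected frames; final area outside bounds; final
    centroid within ``edge_margin`` of the plate rim (needs plate
    geometry); relative area decrease between consecutive detected
    frames exceeding ``max_rel_area_drop``.
    """
    kept = []
    for tr in tracks:
        if qc.min_frames is not None and tr.n_detected < qc.min_frames:
            continue
        final_area = tr.areas[tr.areas > 0][-1] if tr.n_detected else 0.0
        if qc.min_final_area is not None and final_area < qc.min_final_area:
            continue
        if qc.max_final_area is not None and final_area > qc.max_final_area:
            continue
        if (qc.edge_margin is not None and plate_center is not None
                and plate_radius is not None and tr.n_detected):
            r, c = tr.final_centroid
            d = np.hypot(r - plate_center[0], c - plate_center[1])
            if d > plate_radius - qc.edge_margin:
                continue
        if qc.max_rel_area_drop is not None:
            a = tr.areas[tr.areas > 0]
            if a.size >= 2 and np.any(np.diff(a) / a[:-1] < -qc.max_rel_area_drop):
                continue
        kept.append(tr)
    return kept


def extract_phenotype_inputs(track: ColonyTrack, stack: ImageStack,
                             interpolate_missing: bool = True) -> pd.DataFrame:
    """Per-colony time series for kinetic fitting.

    Columns: time_h, area_px2, mean_red, dist_center_px.  Frames where a
    detected colony was temporarily lost are linearly interpolated for
    area (flagged in the ``interpolated`` column); the leading
    pre-detection stretch keeps zero area.
    """
    r, c = track.final_centroid
    dist = float(np.hypot(r - stack.plate_center[0], c - stack.plate_center[1]))
    track.distance_to_center = dist
    t = stack.times_h
    area = track.areas.astype(float).copy()
    interp = np.zeros_like(area, dtype=bool)
    detected = np.where(area > 0)[0]
    if interpolate_missing and detected.size >= 2:
        first, last = detected[0], detected[-1]
        inner = np.arange(first, last + 1)
        missing = inner[area[inner] == 0]
        if missing.size:
            area[missing] = np.interp(t[missing], t[detected], area[detected])
            interp[missing] = True
    return pd.DataFrame({
        "time_h": t,
        "area_px2": area,
        "mean_red": track.mean_rgb[:, 0],
        "dist_center_px": dist,
        "interpolated": interp,
    })


def _per_frame_labels(stack: ImageStack, seg_labels: np.ndarray,
                      gray: np.ndarray, mask: np.ndarray) -> list[np.ndarray]:
    """Per-frame labeled rasters: frame foreground split along the
    global watershed boundaries, then independently relabeled.

    The watershed footprint comes from the temporal-std projection, which
    under-covers pixels colonized only near the end of the movie; labels
    are therefore expanded a few pixels so the per-frame Otsu foreground
    decides each colony's extent.
    """
    final = gray[-1]
    vals = final[mask]
    if np.ptp(vals) == 0:
        raise DegenerateThresholdError("constant final frame inside plate")
    thr = threshold_otsu(vals)
    parent = segmentation.expand_labels(seg_labels, distance=8)
    out = []
    for f in range(stack.n_frames):
        fg = (gray[f] > thr) & mask & (parent > 0)
        split = np.where(fg, parent, 0)
        out.append(measure.label(split > 0) if split.max() == 0 else
                   _relabel_components(split))
    return out


def _relabel_components(split: np.ndarray) -> np.ndarray:
    """Independent sequential labels for each (watershed label,
    connected component) piece."""
    out = np.zeros_like(split, dtype=np.int32)
    nxt = 0
    for lab in np.unique(split[split > 0]):
        comp = measure.label(split == lab)
        ncomp = comp.max()
        out[comp > 0] = comp[comp > 0] + nxt
        nxt += ncomp
    return out


def extract_colony_tracks(stack: ImageStack, qc: QCConfig | None = None,
                          h: float | None = None):
    """Full pipeline: std projection, Otsu, watershed, tracking, QC.

    Returns (tracks, per_colony_series): the retained ColonyTracks and a
    dict colony_id -> phenotype-input DataFrame.
    """
    mask = stack.mask()
    std = project_temporal_std(stack)
    fg = threshold_plate(std, mask)
    seg = segment_colonies(std, fg, h=h)
    gray = stack.grayscale()
    labels_per_frame = _per_frame_labels(stack, seg, gray, mask)
    tracks = track_colonies(labels_per_frame, frames=stack.frames,
                            frame_times=stack.frame_times)
    if qc is None:
        qc = QCConfig()
    tracks = filter_artifacts(tracks, qc, plate_center=stack.plate_center,
                              plate_radius=stack.plate_radius)
    series = {tr.colony_id: extract_phenotype_inputs(tr, stack) for tr in tracks}
    return tracks, series


def tracks_to_frame(tracks, stack: ImageStack | None = None) -> pd.DataFrame:
    """Long-form per-plate table: one row per (colony, frame)."""
    rows = []
    for tr in tracks:
        for f, t in enumerate(tr.frame_times):
            rows.append({
                "colony_id": tr.colony_id,
                "frame_time_min": t,
                "area_px2": tr.areas[f],
                "mean_R": tr.mean_rgb[f, 0],
                "mean_G": tr.mean_rgb[f, 1],
                "mean_B": tr.mean_rgb[f, 2],
                "x": tr.x, "y": tr.y,
                "dist_center_px": tr.distance_to_center,
            })
    return pd.DataFrame(rows)
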