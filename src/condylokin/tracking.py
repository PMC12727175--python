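"""Centroid tracking: image series -> smoothed trajectories -> motion phases.

The chain mirrors how condylar motion is measured from real-time MRI: a
stand-in intensity-threshold segmenter produces per-frame binary condyle
masks (the production systems use a learned segmenter; this package's scope
starts at the masks), centroids of the segmented components give per-side
2D tracks, local-polynomial smoothing suppresses frame-to-frame jitter, and
projecting onto an anatomical reference line (mid-sagittal in the axial
plane, Frankfurt horizontal in the sagittal planes) yields the scalar
displacement signal on which opening/closing phases are detected.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks, savgol_filter
from skimage import measure
from sklearn.cluster import KMeans

from .series import (
    CondyleTrack,
    DisplacementSignal,
    FrameSeries,
    MaskSeries,
    MotionPhase,
    PhasePair,
    ReferenceLine,
    TrackRejectedError,
)

MAX_GAP_FRAMES = 5
MIN_VALID_FRACTION = 0.8


def select_representative_frames(
    series: FrameSeries, k: int = 20, seed: int = 0
) -> np.ndarray:
    """Pick ``k`` representative frame indices by k-means over pixel vectors.

    Frames are intensity-normalized to [0, 1] over the series, flattened and
    clustered; the returned indices are those of the frames nearest
    (Euclidean) to each cluster centre, sorted.  Deterministic for a fixed
    seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > series.n_frames:
        raise ValueError(f"k={k} exceeds the number of frames ({series.n_frames})")
    x = series.frames.reshape(series.n_frames, -1).astype(float)
    lo, hi = x.min(), x.max()
    if hi > lo:
        x = (x - lo) / (hi - lo)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(x)
    chosen: list[int] = []
    for centre in km.cluster_centers_:
        d2 = np.sum((x - centre) ** 2, axis=1)
        order = np.argsort(d2, kind="stable")
        idx = next(int(i) for i in order if int(i) not in chosen)
        chosen.append(idx)
    return np.array(sorted(chosen), dtype=int)


def segment_condyles(
    series: FrameSeries, threshold: float = 0.5, min_area_px: int = 20
) -> MaskSeries:
    """Threshold segmentation keeping the largest condyle-sized components.

    Axial frames keep the two largest connected components, sagittal frames
    the largest one, each with area >= ``min_area_px``.  Frames missing a
    component are flagged invalid (all-background) rather than raising; a
    series with no valid frame at all is an error.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if min_area_px < 1:
        raise ValueError("min_area_px must be positive")
    n_keep = 2 if series.plane == "axial" else 1
    masks = np.zeros(series.frames.shape, dtype=bool)
    valid = np.zeros(series.n_frames, dtype=bool)
    for i, frame in enumerate(series.frames):
        labels = measure.label(frame >= threshold)
        props = [p for p in measure.regionprops(labels) if p.area >= min_area_px]
        props.sort(key=lambda p: p.area, reverse=True)
        if len(props) < n_keep:
            continue
        for p in props[:n_keep]:
            masks[i][labels == p.label] = True
        valid[i] = True
    if not valid.any():
        raise ValueError(
            f"segmentation failed on every frame of the {series.plane} series"
        )
    return MaskSeries(
        frames=masks,
        pixel_spacing_mm=series.pixel_spacing_mm,
        timestamps_ms=series.timestamps_ms,
        plane=series.plane,
        valid=valid,
    )


def _fill_gaps(positions: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate interior invalid runs of length <= MAX_GAP_FRAMES."""
    positions = positions.copy()
    valid = valid.copy()
    n = len(valid)
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        gap = j - i
        interior = i > 0 and j < n
        if interior and gap <= MAX_GAP_FRAMES:
            for axis in range(positions.shape[1]):
                positions[i:j, axis] = np.interp(
                    np.arange(i, j), [i - 1, j], [positions[i - 1, axis], positions[j, axis]]
                )
            valid[i:j] = True
        i = j
    return positions, valid


def extract_centroids(
    masks: MaskSeries, mid_sagittal: ReferenceLine | None = None
) -> list[CondyleTrack]:
    """Unweighted foreground centroids per frame, scaled to mm.

    Sagittal planes yield one track (the plane's side); axial planes yield
    two, with component-to-side assignment by the mid-sagittal line: the
    component on the image left (positive signed offset with the line's
    direction (0, 1)) is the subject's right condyle under radiological
    convention.  Invalid frames are linearly interpolated when the gap is at
    most 5 frames; tracks under 80% validity after gap filling are rejected.
    """
    sy, sx = masks.pixel_spacing_mm
    if masks.plane == "axial":
        if mid_sagittal is None:
            raise ValueError("axial centroid extraction requires the mid-sagittal line")
        sides = ["right", "left"]
    else:
        sides = [masks.plane.split("_", 1)[1]]

    n = masks.n_frames
    pos = {s: np.zeros((n, 2)) for s in sides}
    valid = {s: np.zeros(n, dtype=bool) for s in sides}
    for i in range(n):
        if not masks.valid[i] or not masks.frames[i].any():
            continue
        labels = measure.label(masks.frames[i])
        props = measure.regionprops(labels)
        centroids = np.array([[p.centroid[1] * sx, p.centroid[0] * sy] for p in props])
        if masks.plane == "axial":
            if len(props) != 2:
                continue
            offs = mid_sagittal.signed_offset(centroids)
            order = np.argsort(-offs)  # positive offset (image left) first
            pos["right"][i] = centroids[order[0]]
            pos["left"][i] = centroids[order[1]]
            valid["right"][i] = valid["left"][i] = True
        else:
            if len(props) != 1:
                continue
            pos[sides[0]][i] = centroids[0]
            valid[sides[0]][i] = True

    tracks = []
    for s in sides:
        p, v = _fill_gaps(pos[s], valid[s])
        if v.mean() < MIN_VALID_FRACTION:
            raise TrackRejectedError(
                f"track {masks.plane}/{s}: only {v.mean():.0%} of frames valid "
                f"after gap filling (needs >= {MIN_VALID_FRACTION:.0%})"
            )
        tracks.append(
            CondyleTrack(
                side=s,
                plane=masks.plane,
                timestamps_ms=masks.timestamps_ms,
                positions_mm=p,
                valid=v,
            )
        )
    return tracks


def smooth_track(
    track: CondyleTrack, window_frames: int = 11, poly_order: int = 2
) -> CondyleTrack:
    """Local polynomial (Savitzky-Golay) smoothing of each coordinate.

    Endpoints are handled by a polynomial fit on the truncated window.  The
    track is trimmed to its valid extent first; interior gaps must already
    be filled.
    """
    if window_frames % 2 == 0:
        raise ValueError("window_frames must be odd")
    if window_frames <= poly_order:
        raise ValueError("window_frames must exceed poly_order")
    track = track.trimmed()
    if window_frames > track.n_frames:
        raise ValueError(
            f"window_frames={window_frames} exceeds track length {track.n_frames}"
        )
    smoothed = savgol_filter(
        track.positions_mm, window_frames, poly_order, axis=0, mode="interp"
    )
    return CondyleTrack(
        side=track.side,
        plane=track.plane,
        timestamps_ms=track.timestamps_ms,
        positions_mm=smoothed,
        valid=track.valid.copy(),
    )


def odd_window_frames(
    frame_period_ms: float, window_ms: float, poly_order: int, n_frames: int
) -> int:
    """Convert a time-domain smoothing window to an odd frame count."""
    w = int(round(window_ms / frame_period_ms))
    w = max(w, poly_order + 1)
    if w % 2 == 0:
        w += 1
    w = min(w, n_frames if n_frames % 2 == 1 else n_frames - 1)
    return w


def project_displacement(
    track: CondyleTrack, line: ReferenceLine, origin_index: int = 0
) -> DisplacementSignal:
    """Displacement along the reference direction, relative to the origin frame.

    The sign is chosen so that the dominant excursion is positive (jaw
    opening increases displacement).
    """
    track = track.trimmed()
    if not 0 <= origin_index < track.n_frames:
        raise ValueError(f"origin_index {origin_index} outside track support")
    if not track.valid[origin_index]:
        raise ValueError(f"origin frame {origin_index} is invalid")
    proj = line.projection(track.positions_mm)
    d = proj - proj[origin_index]
    if abs(d.min()) > abs(d.max()):
        d = -d
    return DisplacementSignal(
        timestamps_ms=track.timestamps_ms,
        displacement_mm=d,
        side=track.side,
        plane=track.plane,
    )


def smooth_signal(
    signal: DisplacementSignal, window_frames: int = 11, poly_order: int = 2
) -> DisplacementSignal:
    """Savitzky-Golay smoothing of a scalar displacement signal."""
    if window_frames % 2 == 0:
        raise ValueError("window_frames must be odd")
    if window_frames <= poly_order:
        raise ValueError("window_frames must exceed poly_order")
    if window_frames > signal.n_samples:
        raise ValueError("window_frames exceeds signal length")
    d = savgol_filter(signal.displacement_mm, window_frames, poly_order, mode="interp")
    return DisplacementSignal(
        timestamps_ms=signal.timestamps_ms,
        displacement_mm=d,
        side=signal.side,
        plane=signal.plane,
    )


def compute_velocity(signal: DisplacementSignal) -> np.ndarray:
    """Velocity (mm/s) by central differences, one-sided at the ends."""
    if signal.n_samples < 3:
        raise ValueError("need at least 3 samples for a velocity estimate")
    t_s = signal.timestamps_ms / 1000.0
    if not np.all(np.diff(t_s) > 0):
        raise ValueError("timestamps must be strictly increasing")
    return np.gradient(signal.displacement_mm, t_s)


def _boundary_extremum(
    s: np.ndarray, lo: int, hi: int, want: int
) -> int:
    """Index of the max (want=+1) or min (want=-1) of s[lo:hi]."""
    seg = s[lo:hi]
    return lo + int(np.argmax(seg) if want > 0 else np.argmin(seg))


def detect_phases(
    signal: DisplacementSignal,
    min_amplitude_mm: float = 2.0,
    min_duration_ms: float = 500.0,
) -> list[MotionPhase]:
    """Opening/closing phases delimited by alternating displacement extrema.

    Internal extrema are found with a prominence filter of
    ``min_amplitude_mm`` and a minimum separation of ``min_duration_ms``;
    the series boundaries contribute an extremum when the excursion to the
    first/last internal extremum is large enough.  Rising segments are
    opening phases, falling segments closing.  Returns an empty list when no
    qualifying extrema exist.
    """
    if min_amplitude_mm <= 0 or min_duration_ms <= 0:
        raise ValueError("min_amplitude_mm and min_duration_ms must be positive")
    s = signal.displacement_mm
    t = signal.timestamps_ms
    if signal.n_samples < 3:
        return []
    dt = signal.frame_period_ms
    distance = max(1, int(round(min_duration_ms / dt)))
    peaks, _ = find_peaks(s, prominence=min_amplitude_mm, distance=distance)
    troughs, _ = find_peaks(-s, prominence=min_amplitude_mm, distance=distance)
    ext = sorted(
        [(int(i), +1) for i in peaks] + [(int(i), -1) for i in troughs]
    )

    if not ext:
        # Monotone-ish signal: use the global extrema if the swing qualifies.
        imin, imax = int(np.argmin(s)), int(np.argmax(s))
        if abs(s[imax] - s[imin]) >= min_amplitude_mm and imin != imax:
            ext = sorted([(imin, -1), (imax, +1)])
        else:
            return []
    else:
        first_i, first_k = ext[0]
        if first_i > 0:
            j = _boundary_extremum(s, 0, first_i, -first_k)
            if abs(s[first_i] - s[j]) >= min_amplitude_mm and j < first_i:
                ext.insert(0, (j, -first_k))
        last_i, last_k = ext[-1]
        if last_i < len(s) - 1:
            j = _boundary_extremum(s, last_i + 1, len(s), -last_k)
            if abs(s[j] - s[last_i]) >= min_amplitude_mm and j > last_i:
                ext.append((j, -last_k))

    # Enforce alternation: among same-kind neighbours keep the more extreme.
    alt: list[tuple[int, int]] = []
    for i, k in ext:
        if alt and alt[-1][1] == k:
            pi, _ = alt[-1]
            better = (k > 0 and s[i] > s[pi]) or (k < 0 and s[i] < s[pi])
            if better:
                alt[-1] = (i, k)
        else:
            alt.append((i, k))

    phases = []
    for (i0, k0), (i1, k1) in zip(alt, alt[1:]):
        kind = "opening" if k1 > k0 else "closing"
        duration = t[i1] - t[i0]
        if duration < min_duration_ms:
            continue
        if abs(s[i1] - s[i0]) < min_amplitude_mm:
            continue
        phases.append(
            MotionPhase(
                kind=kind,
                start_index=i0,
                end_index=i1,
                t_start_ms=float(t[i0]),
                t_end_ms=float(t[i1]),
            )
        )
    return phases


def pair_phases(
    right: list[MotionPhase], left: list[MotionPhase]
) -> list[PhasePair]:
    """Greedy kind-respecting matching of right/left phases by time overlap.

    Unmatched phases are simply not paired.  ``cycle_index`` counts pairs of
    each kind in temporal order.
    """
    pairs: list[PhasePair] = []
    for kind in ("opening", "closing"):
        r_list = [p for p in right if p.kind == kind]
        l_list = [p for p in left if p.kind == kind]
        used: set[int] = set()
        counter = 0
        for rp in r_list:
            best_j, best_overlap = None, 0.0
            for j, lp in enumerate(l_list):
                if j in used:
                    continue
                overlap = min(rp.t_end_ms, lp.t_end_ms) - max(
                    rp.t_start_ms, lp.t_start_ms
                )
                if overlap > best_overlap:
                    best_j, best_overlap = j, overlap
            if best_j is not None:
                used.add(best_j)
                pairs.append(
                    PhasePair(
                        kind=kind,
                        right_phase=rp,
                        left_phase=l_list[best_j],
                        cycle_index=counter,
                    )
                )
                counter += 1
    pairs.sort(key=lambda p: p.right_phase.t_start_ms)
    return pairs
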