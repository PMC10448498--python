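"""Double-spot localization and counting (classical backend).

The observable of prism-dispersed single-particle imaging is the double-spot
count per frame (DSC): the number of two-spot patterns whose separation
matches the dispersion of the target species.  The classical backend here is
a deterministic pipeline: robust background estimation (median filter),
difference-of-Gaussians blob detection with a MAD-based threshold, sub-pixel
centroid refinement, and greedy pairing of spots whose separation and
orientation match the expected dispersed pattern.  A trainable U-net backend
lives in :mod:`duospot.unet`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "DetectionParams",
    "SpotPair",
    "DetectionResult",
    "estimate_background",
    "find_spots",
    "pair_spots",
    "count_double_spots",
    "match_to_truth",
    "pairs_to_mask",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of the classical double-spot detector.

    The DoG band-pass (sigmas in px) should bracket the PSF width; the
    detection threshold is in multiples of the robust (MAD-based) SD of the
    DoG response.  Pairing accepts spot pairs whose separation is within
    ``separation_tol_px`` of ``expected_separation_px`` and whose orientation
    is within ``angle_tol_deg`` of the dispersion axis.
    """

    dog_sigma_small: float = 1.0
    dog_sigma_large: float = 2.5
    threshold_k: float = 5.0
    expected_separation_px: float = 6.5
    separation_tol_px: float = 3.0
    axis_angle_deg: float = 0.0
    angle_tol_deg: float = 10.0
    min_pair_intensity_ratio: float = 0.0
    median_window_px: int = 21
    edge_margin_px: int = 5

    def __post_init__(self) -> None:
        if self.dog_sigma_small >= self.dog_sigma_large:
            raise ValueError("dog_sigma_small must be < dog_sigma_large")
        if self.separation_tol_px <= 0 or self.angle_tol_deg <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class SpotPair:
    """One localized double spot: two sub-pixel spot positions, their
    intensities, measured separation, orientation and pairing score."""

    row1: float
    col1: float
    row2: float
    col2: float
    intensity1: float
    intensity2: float

    @property
    def separation_px(self) -> float:
        return math.hypot(self.row2 - self.row1, self.col2 - self.col1)

    @property
    def orientation_deg(self) -> float:
        return math.degrees(math.atan2(self.row2 - self.row1,
                                       self.col2 - self.col1)) % 180.0

    @property
    def score(self) -> float:
        return self.intensity1 + self.intensity2

    @property
    def midpoint(self) -> tuple[float, float]:
        return (self.row1 + self.row2) / 2.0, (self.col1 + self.col2) / 2.0


@dataclass
class DetectionResult:
    """Detections of one frame: paired double spots, unpaired singles and
    the binary pair mask (one connected component per pair)."""

    pairs: list[SpotPair]
    singles: np.ndarray  # (n, 3): row, col, intensity
    mask: np.ndarray | None = None

    @property
    def count(self) -> int:
        return len(self.pairs)


def estimate_background(frame: np.ndarray, window_px: int = 21,
                        decimation: int = 4) -> np.ndarray:
    """Smooth nonnegative background map via a median filter whose window is
    much larger than the PSF; sparse spots barely perturb the median.

    For speed the frame is first reduced by block-wise medians (factor
    ``decimation``), median-filtered at the equivalent window, and
    interpolated back to full resolution; set ``decimation=1`` for the plain
    median filter.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame must be 2-D")
    d = max(int(decimation), 1)
    h, w = img.shape
    if d > 1 and h % d == 0 and w % d == 0 and min(h, w) >= 8 * d:
        blocks = img.reshape(h // d, d, w // d, d)
        small = np.median(blocks, axis=(1, 3))
        size = max(3, int(round(window_px / d)) | 1)
        bg_small = ndimage.median_filter(small, size=size, mode="nearest")
        bg = ndimage.zoom(bg_small, d, order=1, mode="nearest",
                          grid_mode=True)[:h, :w]
    else:
        bg = ndimage.median_filter(img, size=window_px, mode="nearest")
    return np.clip(bg, 0.0, None)


def find_spots(frame_bgsub: np.ndarray, params: DetectionParams = DetectionParams()
               ) -> np.ndarray:
    """Detect spots in a background-subtracted frame.

    Difference-of-Gaussians response; local maxima above
    ``threshold_k`` robust SDs (1.4826 * MAD of the DoG response); sub-pixel
    refinement by intensity centroid in a 5x5 window.  Spots closer than
    ``edge_margin_px`` to the frame edge are discarded.

    Returns an (n, 3) array of (row, col, intensity), intensity being the
    background-subtracted sum over the 5x5 window.
    """
    img = np.asarray(frame_bgsub, dtype=float)
    dog = (ndimage.gaussian_filter(img, params.dog_sigma_small)
           - ndimage.gaussian_filter(img, params.dog_sigma_large))
    mad = np.median(np.abs(dog - np.median(dog)))
    robust_sd = 1.4826 * mad
    thresh = params.threshold_k * max(robust_sd, 1e-12)
    is_max = (dog == ndimage.maximum_filter(dog, size=3)) & (dog > thresh)
    rows, cols = np.nonzero(is_max)
    h, w = img.shape
    m = params.edge_margin_px
    keep = (rows >= m) & (rows < h - m) & (cols >= m) & (cols < w - m)
    rows, cols = rows[keep], cols[keep]
    out = np.empty((rows.size, 3), dtype=float)
    dr, dc = np.mgrid[-2:3, -2:3]
    for i, (r, c) in enumerate(zip(rows, cols)):
        win = np.clip(img[r - 2:r + 3, c - 2:c + 3], 0.0, None)
        total = win.sum()
        if total > 0:
            out[i, 0] = r + (dr * win).sum() / total
            out[i, 1] = c + (dc * win).sum() / total
        else:  # flat window: keep the integer maximum
            out[i, 0], out[i, 1] = r, c
        out[i, 2] = img[r - 2:r + 3, c - 2:c + 3].sum()
    return out


def _angle_diff(a: float, b: float) -> float:
    """Smallest difference between two axial (mod 180 deg) orientations."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def pair_spots(spots: np.ndarray, params: DetectionParams = DetectionParams()
               ) -> tuple[list[SpotPair], np.ndarray]:
    """Greedily pair spots into double spots.

    Candidate pairs must have separation within
    ``expected_separation_px +/- separation_tol_px``, orientation within
    ``angle_tol_deg`` of the dispersion axis, and (optionally) an intensity
    ratio weaker/stronger above ``min_pair_intensity_ratio``.  Conflicts are
    resolved per connected component of the candidate graph: components of up
    to 10 spots are matched exactly (maximum pair count, then maximum
    combined intensity), larger components greedily by descending combined
    intensity with (row, col) lexicographic tie-breaks.  Either way the
    result is deterministic and each spot belongs to at most one pair.

    Returns (pairs, singles) with singles the unpaired (row, col, intensity)
    rows.
    """
    spots = np.asarray(spots, dtype=float).reshape(-1, 3)
    n = len(spots)
    edges: list[tuple[int, int, float]] = []
    for i in range(n):
        for j in range(i + 1, n):
            dy = spots[j, 0] - spots[i, 0]
            dx = spots[j, 1] - spots[i, 1]
            sep = math.hypot(dy, dx)
            if abs(sep - params.expected_separation_px) > params.separation_tol_px:
                continue
            ang = math.degrees(math.atan2(dy, dx)) % 180.0
            if _angle_diff(ang, params.axis_angle_deg % 180.0) > params.angle_tol_deg:
                continue
            lo, hi = sorted((spots[i, 2], spots[j, 2]))
            if hi > 0 and lo / hi < params.min_pair_intensity_ratio:
                continue
            edges.append((i, j, spots[i, 2] + spots[j, 2]))

    # connected components of the candidate graph
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j, _ in edges:
        parent[find(i)] = find(j)
    comp_edges: dict[int, list[tuple[int, int, float]]] = {}
    for i, j, s in edges:
        comp_edges.setdefault(find(i), []).append((i, j, s))

    matched: list[tuple[int, int]] = []
    for root, ce in sorted(comp_edges.items()):
        nodes = sorted({k for i, j, _ in ce for k in (i, j)})
        if len(nodes) <= 10:
            matched.extend(_exact_matching(ce))
        else:
            order = sorted(ce, key=lambda e: (-e[2], spots[e[0], 0],
                                              spots[e[0], 1], e[0], e[1]))
            used_local: set[int] = set()
            for i, j, _ in order:
                if i in used_local or j in used_local:
                    continue
                used_local.update((i, j))
                matched.append((i, j))

    used: set[int] = set()
    pairs: list[SpotPair] = []
    for i, j in matched:
        used.update((i, j))
        # order the pair left-to-right along columns for reproducible output
        a, b = (i, j) if (spots[i, 1], spots[i, 0]) <= (spots[j, 1], spots[j, 0]) else (j, i)
        pairs.append(SpotPair(spots[a, 0], spots[a, 1], spots[b, 0], spots[b, 1],
                              spots[a, 2], spots[b, 2]))
    pairs.sort(key=lambda p: (p.col1, p.row1))
    singles = spots[[k for k in range(n) if k not in used]]
    return pairs, singles


def _exact_matching(edges: list[tuple[int, int, float]]) -> list[tuple[int, int]]:
    """Exhaustive maximum matching on a small candidate graph, maximizing
    (pair count, total combined intensity); deterministic tie-breaking via
    sorted edge order."""
    edges = sorted(edges)
    best: tuple[int, float, list[tuple[int, int]]] = (0, 0.0, [])

    def rec(idx: int, used: set[int], count: int, score: float,
            chosen: list[tuple[int, int]]) -> None:
        nonlocal best
        remaining = len(edges) - idx
        if count + remaining < best[0]:
            return
        if idx == len(edges):
            if (count, score) > (best[0], best[1]):
                best = (count, score, list(chosen))
            return
        i, j, s = edges[idx]
        if i not in used and j not in used:
            used.update((i, j))
            chosen.append((i, j))
            rec(idx + 1, used, count + 1, score + s, chosen)
            chosen.pop()
            used.difference_update((i, j))
        rec(idx + 1, used, count, score, chosen)

    rec(0, set(), 0, 0.0, [])
    return best[2]


def add_capsule(mask: np.ndarray, p1: tuple[float, float],
                p2: tuple[float, float], radius: float) -> None:
    """Mark all pixels within ``radius`` of the segment p1-p2 (a capsule:
    two spot disks joined along the pair axis, guaranteed 8-connected)."""
    h, w = mask.shape
    r1, c1 = p1
    r2, c2 = p2
    rr = int(math.ceil(radius)) + 1
    ys = np.arange(max(int(min(r1, r2)) - rr, 0),
                   min(int(max(r1, r2)) + rr + 1, h))
    xs = np.arange(max(int(min(c1, c2)) - rr, 0),
                   min(int(max(c1, c2)) + rr + 1, w))
    if ys.size == 0 or xs.size == 0:
        return
    py = ys[:, None] - r1
    px = xs[None, :] - c1
    vy, vx = r2 - r1, c2 - c1
    vv = vy * vy + vx * vx
    t = np.clip((py * vy + px * vx) / vv, 0.0, 1.0) if vv > 0 else 0.0
    dy = py - t * vy
    dx = px - t * vx
    mask[np.ix_(ys, xs)] |= dy**2 + dx**2 <= radius**2


def pairs_to_mask(pairs: list[SpotPair], shape: tuple[int, int],
                  radius: float = 3.0) -> np.ndarray:
    """Binary mask with a radius-``radius`` capsule over each pair (the two
    spot disks joined along the pair axis), so that connected components of
    the mask equal the pair count."""
    mask = np.zeros(shape, dtype=bool)
    for p in pairs:
        add_capsule(mask, (p.row1, p.col1), (p.row2, p.col2), radius)
    return mask


def detect_frame(frame: np.ndarray, params: DetectionParams = DetectionParams(),
                 with_mask: bool = False) -> DetectionResult:
    """Full classical pipeline on one frame: background subtraction, spot
    finding, pairing."""
    bg = estimate_background(frame, params.median_window_px)
    spots = find_spots(np.asarray(frame, dtype=float) - bg, params)
    pairs, singles = pair_spots(spots, params)
    mask = pairs_to_mask(pairs, frame.shape) if with_mask else None
    return DetectionResult(pairs=pairs, singles=singles, mask=mask)


def count_double_spots(frames: np.ndarray, params: DetectionParams = DetectionParams(),
                       with_masks: bool = False
                       ) -> tuple[np.ndarray, list[DetectionResult]]:
    """Per-frame double-spot counts for a stack.

    ``frames`` is a (n, H, W) array (or an object with a ``frames``
    attribute, e.g. a FrameStack).  Returns the per-frame count array and
    the per-frame :class:`DetectionResult` list.
    """
    frames = getattr(frames, "frames", frames)
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError("expected a (n, H, W) stack")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError("mixed frame shapes in stack")
    results = [detect_frame(f, params, with_mask=with_masks) for f in frames]
    counts = np.array([r.count for r in results], dtype=int)
    return counts, results


def match_to_truth(detected: np.ndarray, truth: np.ndarray, radius_px: float = 2.0
                   ) -> dict:
    """Greedy nearest-neighbour matching of detections to ground truth.

    ``detected`` and ``truth`` are (n, 2) arrays of (row, col) positions
    (e.g. pair midpoints).  A detection within ``radius_px`` of an unmatched
    truth position is a true positive.  With no detections, precision is
    reported as 1.0 by convention with ``precision_defined = False``.

    Returns a dict with precision, recall, counts, and statistics of the
    match distances.
    """
    det = np.asarray(detected, dtype=float).reshape(-1, 2)
    tru = np.asarray(truth, dtype=float).reshape(-1, 2)
    if len(det) and len(tru):
        d = np.linalg.norm(det[:, None, :] - tru[None, :, :], axis=2)
        order = np.argsort(d, axis=None)
        used_d: set[int] = set()
        used_t: set[int] = set()
        dists = []
        for flat in order:
            i, j = divmod(int(flat), len(tru))
            if d[i, j] > radius_px:
                break
            if i in used_d or j in used_t:
                continue
            used_d.add(i)
            used_t.add(j)
            dists.append(d[i, j])
        tp = len(dists)
    else:
        tp, dists = 0, []
    fp = len(det) - tp
    fn = len(tru) - tp
    precision_defined = len(det) > 0
    precision = tp / len(det) if precision_defined else 1.0
    recall = tp / len(tru) if len(tru) else 1.0
    return {
        "tp": tp, "fp": fp, "fn": fn,
        "precision": precision, "recall": recall,
        "precision_defined": precision_defined,
        "mean_match_dist_px": float(np.mean(dists)) if dists else float("nan"),
    }
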