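"""Spatial point-pattern statistics for nanocluster centroids.

The pair-correlation function g(r) — density of point pairs at separation r
relative to complete spatial randomness (CSR) — is estimated on a binned grid
out to 1 um with translation edge correction, and compared against pointwise
extrema of 49 CSR simulations conditioned on the observed point count.  Radii
where g exceeds the upper envelope are deemed significantly more clustered
than random.  Object-based juxtaposition (centre-to-centre distance below a
600 nm threshold) with a 90-degree rotation control completes the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PCFResult",
    "JuxtapositionResult",
    "pair_correlation",
    "pair_correlation_bruteforce",
    "csr_envelopes",
    "attach_envelopes",
    "juxtaposition",
]


@dataclass
class PCFResult:
    radii: np.ndarray            # bin centres, nm, strictly increasing
    g_values: np.ndarray
    envelope_low: np.ndarray | None = None
    envelope_high: np.ndarray | None = None
    n_points: int = 0
    window: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    bin_width: float = 0.0

    @property
    def peak_radius(self) -> float:
        return float(self.radii[int(np.argmax(self.g_values))])

    @property
    def peak_g(self) -> float:
        return float(np.max(self.g_values))

    @property
    def significant_radii(self) -> np.ndarray:
        """Radii where g exceeds the upper CSR envelope."""
        if self.envelope_high is None:
            raise ValueError("no envelopes attached")
        return self.radii[self.g_values > self.envelope_high]


@dataclass
class JuxtapositionResult:
    percent_juxtaposed: float
    percent_control: float
    threshold: float
    n_paired: int
    n_total: int
    n_paired_control: int = 0


# --------------------------------------------------------------------------
# pair-correlation estimator
# --------------------------------------------------------------------------

def _window_rect(window) -> tuple[float, float, float, float]:
    """Normalise a window spec to (x0, y0, x1, y1)."""
    w = tuple(float(v) for v in window)
    if len(w) == 2:
        return (0.0, 0.0, w[0], w[1])
    if len(w) == 4:
        return w
    raise ValueError("window must be (width, height) or (x0, y0, x1, y1)")


def _g_binned(points: np.ndarray, rect: tuple[float, float, float, float],
              edges: np.ndarray) -> np.ndarray:
    """Translation-corrected binned g(r) over the given annulus edges."""
    x0, y0, x1, y1 = rect
    a, b = x1 - x0, y1 - y0
    n = len(points)
    area = a * b
    # ordered-pair sum of translation weights per bin
    tree = cKDTree(points)
    pairs = tree.query_pairs(r=float(edges[-1]), output_type="ndarray")
    sums = np.zeros(len(edges) - 1, dtype=np.float64)
    if len(pairs):
        d = points[pairs[:, 0]] - points[pairs[:, 1]]
        dist = np.hypot(d[:, 0], d[:, 1])
        wt = 1.0 / ((a - np.abs(d[:, 0])) * (b - np.abs(d[:, 1])))
        which = np.searchsorted(edges, dist, side="right") - 1
        ok = (which >= 0) & (which < len(sums)) & (dist > edges[0]) & (dist <= edges[-1])
        np.add.at(sums, which[ok], 2.0 * wt[ok])  # both orderings of each pair
    lam2 = n * (n - 1) / area ** 2
    ann_area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = sums / (lam2 * ann_area)
    return np.nan_to_num(g, nan=0.0, posinf=0.0)


def pair_correlation(points: np.ndarray, window,
                     r_max: float = 1000.0, bin_width: float = 10.0) -> PCFResult:
    """Binned pair-correlation estimate of a 2D point pattern.

    g(r) per annulus ``(r, r + bin_width]`` is the translation-weighted
    ordered-pair count divided by the CSR expectation ``n(n-1)/|W|^2`` times
    the annulus area.  Requires at least 10 points, all inside the window.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(points) < 10:
        raise ValueError(f"need >= 10 points for a pair-correlation estimate, "
                         f"got {len(points)}")
    rect = _window_rect(window)
    x0, y0, x1, y1 = rect
    if (points[:, 0] < x0).any() or (points[:, 0] > x1).any() \
            or (points[:, 1] < y0).any() or (points[:, 1] > y1).any():
        raise ValueError("all points must lie inside the window")
    edges = np.arange(0.0, r_max + bin_width / 2.0, bin_width)
    g = _g_binned(points, rect, edges)
    radii = 0.5 * (edges[:-1] + edges[1:])
    return PCFResult(radii=radii, g_values=g, n_points=len(points),
                     window=rect, bin_width=float(bin_width))


def pair_correlation_bruteforce(points: np.ndarray, window,
                                r_max: float = 1000.0,
                                bin_width: float = 10.0) -> PCFResult:
    """O(n^2) loop oracle computing the identical estimator (for testing)."""
    points = np.asarray(points, dtype=np.float64)
    rect = _window_rect(window)
    x0, y0, x1, y1 = rect
    a, b = x1 - x0, y1 - y0
    edges = np.arange(0.0, r_max + bin_width / 2.0, bin_width)
    sums = np.zeros(len(edges) - 1)
    n = len(points)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dx = points[i, 0] - points[j, 0]
            dy = points[i, 1] - points[j, 1]
            dist = np.hypot(dx, dy)
            if dist <= edges[0] or dist > edges[-1]:
                continue
            k = int(np.searchsorted(edges, dist, side="right")) - 1
            sums[k] += 1.0 / ((a - abs(dx)) * (b - abs(dy)))
    lam2 = n * (n - 1) / (a * b) ** 2
    ann = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    g = sums / (lam2 * ann)
    return PCFResult(radii=0.5 * (edges[:-1] + edges[1:]), g_values=g,
                     n_points=n, window=rect, bin_width=float(bin_width))


def csr_envelopes(n_points: int, window, radii_or_edges: np.ndarray,
                  n_sims: int = 49, seed: int = 0,
                  bin_width: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise extrema of g(r) over CSR simulations.

    ``n_sims`` fields of exactly ``n_points`` uniform points (a binomial
    process, conditioning on the observed count) are simulated in the window;
    the per-radius minimum and maximum of their g estimates form the
    lower/upper envelopes.  A pattern's g exceeding the upper envelope at a
    radius is deemed significantly more clustered than random there.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rect = _window_rect(window)
    x0, y0, x1, y1 = rect
    radii = np.asarray(radii_or_edges, dtype=np.float64)
    if bin_width is None:
        bin_width = float(radii[1] - radii[0])
    edges = np.concatenate([[radii[0] - bin_width / 2.0],
                            radii + bin_width / 2.0])
    edges = np.clip(edges, 0.0, None)
    rng = np.random.default_rng(seed)
    lo = np.full(len(radii), np.inf)
    hi = np.full(len(radii), -np.inf)
    for _ in range(n_sims):
        pts = np.column_stack([rng.uniform(x0, x1, n_points),
                               rng.uniform(y0, y1, n_points)])
        g = _g_binned(pts, rect, edges)
        lo = np.minimum(lo, g)
        hi = np.maximum(hi, g)
    return lo, hi


def attach_envelopes(result: PCFResult, n_sims: int = 49, seed: int = 0) -> PCFResult:
    """Compute CSR envelopes matching a PCF result and attach them to it."""
    lo, hi = csr_envelopes(result.n_points, result.window, result.radii,
                           n_sims=n_sims, seed=seed, bin_width=result.bin_width)
    result.envelope_low = lo
    result.envelope_high = hi
    return result


# --------------------------------------------------------------------------
# juxtaposition with rotation control
# --------------------------------------------------------------------------

def _percent_within(centres_a: np.ndarray, centres_b: np.ndarray,
                    threshold: float) -> tuple[float, int]:
    tree = cKDTree(centres_b)
    d, _ = tree.query(centres_a, k=1)
    n = int((d <= threshold).sum())
    return 100.0 * n / len(centres_a), n


def juxtaposition(centres_a: np.ndarray, centres_b: np.ndarray,
                  threshold: float = 600.0, field=None) -> JuxtapositionResult:
    """Object-based colocalisation: fraction of A puncta with a B punctum
    within ``threshold`` nm (centre to centre), plus a rotation control.

    The control repeats the measurement after rotating channel B 90 degrees
    clockwise (image convention, y down) about the field centre, clipping
    rotated coordinates back into the window.
    """
    centres_a = np.atleast_2d(np.asarray(centres_a, dtype=np.float64))
    centres_b = np.atleast_2d(np.asarray(centres_b, dtype=np.float64))
    if len(centres_a) == 0 or len(centres_b) == 0:
        raise ValueError("both channels must contain at least one punctum")
    if field is None:
        allpts = np.vstack([centres_a, centres_b])
        rect = (0.0, 0.0, float(allpts[:, 0].max()), float(allpts[:, 1].max()))
    else:
        rect = _window_rect(field)
    x0, y0, x1, y1 = rect
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    pct, n_paired = _percent_within(centres_a, centres_b, threshold)
    # 90 deg clockwise with y pointing down: (x, y) -> (cx - (y - cy), cy + (x - cx))
    rot = np.column_stack([cx - (centres_b[:, 1] - cy),
                           cy + (centres_b[:, 0] - cx)])
    rot[:, 0] = np.clip(rot[:, 0], x0, x1)
    rot[:, 1] = np.clip(rot[:, 1], y0, y1)
    pct_ctrl, n_ctrl = _percent_within(centres_a, rot, threshold)
    return JuxtapositionResult(percent_juxtaposed=pct, percent_control=pct_ctrl,
                               threshold=float(threshold), n_paired=n_paired,
                               n_total=len(centres_a), n_paired_control=n_ctrl)
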