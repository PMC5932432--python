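"""Binarization of a vessel-detection response by classical thresholding.

The detection stage produces a gray-scale map with vessels as HIGH values.
Ten thresholding methods turn it into a binary vessel/background mask:

Global (operate on a 256-bin min-max histogram of the response; the selected
bin index ``t`` converts back to a response-value cutoff, foreground = above):

- ``otsu``            between-class variance maximization
- ``ridler_calvard``  iterative two-means (isodata) fixed point
- ``kapur``           maximum sum of within-class Shannon entropies
- ``pal``             maximum sum of within-class exponential entropies
- ``moments``         Tsai moment-preserving closed form
- ``concavity``       deepest local concavity of the histogram's convex hull
- ``rats``            gradient-weighted mean intensity (value-domain, no histogram)

Local (per-pixel thresholds from a sliding window):

- ``niblack``         m(p) + k * s(p)
- ``sauvola``         m(p) * (1 + k * (s(p)/R - 1))
- ``white_rohrer``    bias * response > m(p)

All global methods break ties among equally optimal ``t`` toward the
smallest ``t``, making each a pure function of the histogram.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Histogram",
    "LocalParams",
    "DegenerateHistogramError",
    "NoConcavityError",
    "make_histogram",
    "otsu",
    "ridler_calvard",
    "kapur",
    "pal_entropy",
    "moments",
    "concavity",
    "rats",
    "niblack",
    "sauvola",
    "white_rohrer",
    "segment",
    "METHODS",
]

N_BINS = 256


class DegenerateHistogramError(ValueError):
    """Histogram with fewer than two occupied bins: no threshold exists."""


class NoConcavityError(ValueError):
    """Convex histogram: the hull coincides with it and no concavity exists."""


@dataclass(frozen=True)
class Histogram:
    """256-bin intensity histogram of a response image with its binning map.

    ``vmin``/``vmax`` record the affine min-max map used for binning, so a
    bin-index threshold converts back to a response-value cutoff.
    """

    counts: np.ndarray
    vmin: float
    vmax: float

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def degenerate(self) -> bool:
        return np.count_nonzero(self.counts) < 2

    def bin_of(self, values: np.ndarray) -> np.ndarray:
        """Bin index of response values under the recorded map (round half up)."""
        if self.vmax == self.vmin:
            return np.zeros_like(np.asarray(values), dtype=np.int64)
        scaled = (np.asarray(values, dtype=np.float64) - self.vmin) / (self.vmax - self.vmin)
        return np.clip(np.floor(scaled * (N_BINS - 1) + 0.5), 0, N_BINS - 1).astype(np.int64)


@dataclass(frozen=True)
class LocalParams:
    """Window and weights of the local (adaptive) methods."""

    window: int = 15
    k: float = -0.2
    R: float = 0.5
    bias: float = 1.0

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")


def make_histogram(image: np.ndarray) -> Histogram:
    """Min-max rescale the response to [0, 255], round half up, and count."""
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    vmin, vmax = float(image.min()), float(image.max())
    hist = Histogram(counts=np.zeros(N_BINS, dtype=np.int64), vmin=vmin, vmax=vmax)
    bins = hist.bin_of(image.ravel())
    counts = np.bincount(bins, minlength=N_BINS).astype(np.int64)
    return Histogram(counts=counts, vmin=vmin, vmax=vmax)


def _check(hist: Histogram) -> np.ndarray:
    if hist.degenerate:
        raise DegenerateHistogramError("histogram has fewer than two occupied bins")
    return hist.counts.astype(np.float64)


def _class_stats(counts: np.ndarray):
    """Cumulative weight and mean of class 0 (bins <= t) and class 1, for every t."""
    levels = np.arange(N_BINS, dtype=np.float64)
    total = counts.sum()
    w0 = np.cumsum(counts)
    m0 = np.cumsum(counts * levels)
    w1 = total - w0
    m1 = m0[-1] - m0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(w0 > 0, m0 / w0, 0.0)
        mu1 = np.where(w1 > 0, m1 / w1, 0.0)
    return w0 / total, w1 / total, mu0, mu1


def otsu(hist: Histogram) -> int:
    """Threshold maximizing the between-class variance w0*w1*(mu0 - mu1)^2."""
    counts = _check(hist)
    w0, w1, mu0, mu1 = _class_stats(counts)
    objective = w0 * w1 * (mu0 - mu1) ** 2
    objective[(w0 == 0) | (w1 == 0)] = -np.inf
    return int(np.argmax(objective))  # argmax returns the first (smallest) maximizer


def ridler_calvard(hist: Histogram) -> int:
    """Isodata fixed point t <- round((mu0(t) + mu1(t)) / 2), from the histogram mean.

    The state is an integer bin index, so the iteration either reaches a fixed
    point or revisits a state; it stops at the first repeat and is therefore
    bounded by 256 iterations.
    """
    counts = _check(hist)
    _, _, mu0, mu1 = _class_stats(counts)
    levels = np.arange(N_BINS, dtype=np.float64)
    t = int(np.floor(counts @ levels / counts.sum() + 0.5))
    seen = set()
    while t not in seen:
        seen.add(t)
        t_new = int(np.floor((mu0[t] + mu1[t]) / 2.0 + 0.5))
        if t_new == t:
            break
        t = t_new
    return t


def _shannon_entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def kapur(hist: Histogram) -> int:
    """Threshold maximizing the sum of the two within-class Shannon entropies."""
    counts = _check(hist)
    p = counts / counts.sum()
    best_t, best_obj = None, -np.inf
    for t in range(N_BINS - 1):
        # direct slice sums (not a running cumsum) so thresholds separated
        # only by empty bins produce bit-identical objectives and the
        # smallest-t tie rule is exact
        w0, w1 = p[: t + 1].sum(), p[t + 1 :].sum()
        if w0 <= 0 or w1 <= 0:
            continue
        obj = _shannon_entropy(p[: t + 1] / w0) + _shannon_entropy(p[t + 1 :] / w1)
        if obj > best_obj:
            best_t, best_obj = t, obj
    if best_t is None:
        raise DegenerateHistogramError("no threshold separates two non-empty classes")
    return best_t


def pal_entropy(hist: Histogram) -> int:
    """Threshold maximizing the sum of within-class exponential entropies.

    The exponential entropy of a distribution p is sum_i p_i * e^(1 - p_i);
    unlike the Shannon form it is bounded, which changes the optimum on
    heavy-tailed histograms.
    """
    counts = _check(hist)
    p = counts / counts.sum()

    def _exp_entropy(q: np.ndarray) -> float:
        q = q[q > 0]
        return float((q * np.exp(1.0 - q)).sum())

    best_t, best_obj = None, -np.inf
    for t in range(N_BINS - 1):
        w0, w1 = p[: t + 1].sum(), p[t + 1 :].sum()  # see kapur: exact ties
        if w0 <= 0 or w1 <= 0:
            continue
        obj = _exp_entropy(p[: t + 1] / w0) + _exp_entropy(p[t + 1 :] / w1)
        if obj > best_obj:
            best_t, best_obj = t, obj
    if best_t is None:
        raise DegenerateHistogramError("no threshold separates two non-empty classes")
    return best_t


def moments(hist: Histogram) -> int:
    """Tsai's moment-preserving threshold (closed form).

    From the first three gray-level moments m1, m2, m3 the two representative
    levels z0 < z1 and the class-0 fraction p0 of the moment-preserving
    binary image are solved in closed form; ``t`` is the smallest bin whose
    cumulative fraction reaches p0.
    """
    counts = _check(hist)
    p = counts / counts.sum()
    levels = np.arange(N_BINS, dtype=np.float64)
    m1 = float(p @ levels)
    m2 = float(p @ levels**2)
    m3 = float(p @ levels**3)
    cd = m2 - m1 * m1
    if cd <= 0:
        raise DegenerateHistogramError("zero-variance histogram")
    c0 = (m1 * m3 - m2 * m2) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        warnings.warn(
            f"moment equations yield complex levels (disc={disc:.3g}); clamping to zero",
            RuntimeWarning,
            stacklevel=2,
        )
        disc = 0.0
    sq = np.sqrt(disc)
    z0 = 0.5 * (-c1 - sq)
    z1 = 0.5 * (-c1 + sq)
    p0 = 0.5 if z1 == z0 else (z1 - m1) / (z1 - z0)
    cum = np.cumsum(p)
    return int(np.searchsorted(cum, p0 - 1e-12, side="left"))


def _upper_hull(counts: np.ndarray) -> np.ndarray:
    """Piecewise-linear upper convex hull of the points (i, counts[i])."""
    pts = list(enumerate(counts))
    hull: list[tuple[int, float]] = []
    for x, y in pts:
        while len(hull) >= 2:
            (x1, y1), (x2, y2) = hull[-2], hull[-1]
            # drop middle point if it lies on or below the chord
            if (y2 - y1) * (x - x1) <= (y - y1) * (x2 - x1):
                hull.pop()
            else:
                break
        hull.append((x, y))
    out = np.empty(N_BINS)
    hx = np.array([h[0] for h in hull], dtype=np.float64)
    hy = np.array([h[1] for h in hull], dtype=np.float64)
    out[:] = np.interp(np.arange(N_BINS), hx, hy)
    return out


def concavity(hist: Histogram) -> int:
    """Deepest local concavity: argmax of hull(i) - counts[i] over local maxima."""
    counts = _check(hist)
    diff = _upper_hull(counts) - counts
    if np.all(diff <= 1e-9):
        raise NoConcavityError("histogram is convex; no concavity to threshold at")
    padded = np.concatenate([[-np.inf], diff, [-np.inf]])
    local_max = (diff >= padded[:-2]) & (diff >= padded[2:]) & (diff > 1e-9)
    candidates = np.flatnonzero(local_max)
    return int(candidates[np.argmax(diff[candidates])])


def rats(image: np.ndarray) -> float:
    """Gradient-weighted mean intensity (value-domain threshold).

    g = max(|dI/dx|, |dI/dy|) with central differences; the threshold is
    sum(g * I) / sum(g), i.e. the mean intensity under the edge mass.
    """
    image = np.asarray(image, dtype=np.float64)
    gy, gx = np.gradient(image)
    g = np.maximum(np.abs(gx), np.abs(gy))
    denom = g.sum()
    if denom == 0:
        raise DegenerateHistogramError("image has no gradient; RATS threshold undefined")
    return float((g * image).sum() / denom)


def _box_mean(image: np.ndarray, window: int) -> np.ndarray:
    """Sliding-window mean via an integral image (reflect padding).

    Unlike a running-sum filter this subtracts identical partial sums in flat
    regions, so the mean of an all-zero window is exactly zero — the strict
    '>' comparisons of the local methods depend on that.
    """
    pad = window // 2
    padded = np.pad(image, pad, mode="symmetric")
    c = np.zeros((padded.shape[0] + 1, padded.shape[1] + 1))
    np.cumsum(np.cumsum(padded, axis=0), axis=1, out=c[1:, 1:])
    w = window
    total = c[w:, w:] - c[:-w, w:] - c[w:, :-w] + c[:-w, :-w]
    return total / (w * w)


def _local_mean_std(image: np.ndarray, window: int):
    # anchor at the image minimum: windows that are flat at the anchor
    # (constant images, empty background) get exactly zero sums, so the
    # strict '>' decisions are not at the mercy of summation round-off;
    # mean and std are offset-covariant, so nothing else changes
    anchor = float(image.min())
    shifted = image - anchor
    mean_s = _box_mean(shifted, window)
    sq = _box_mean(shifted * shifted, window)
    var = np.maximum(sq - mean_s * mean_s, 0.0)
    return anchor + mean_s, np.sqrt(var)


def _check_local(image: np.ndarray, params: LocalParams) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if params.window > min(image.shape):
        raise ValueError(
            f"window {params.window} exceeds image extent {min(image.shape)}"
        )
    return image


def niblack(image: np.ndarray, params: LocalParams | None = None) -> np.ndarray:
    """Foreground where response > m(p) + k * s(p) over a sliding window."""
    params = params or LocalParams(k=-0.2)
    image = _check_local(image, params)
    mean, std = _local_mean_std(image, params.window)
    return image > mean + params.k * std


def sauvola(image: np.ndarray, params: LocalParams | None = None) -> np.ndarray:
    """Foreground where response > m(p) * (1 + k * (s(p)/R - 1)).

    Note: for k > 0 the threshold is LOWERED where the local spread is small
    (s < R) — the standard formula, kept even though it is sometimes
    described verbally with the opposite sense.
    """
    params = params or LocalParams(k=0.5)
    if params.R <= 0:
        raise ValueError("R must be > 0")
    image = _check_local(image, params)
    mean, std = _local_mean_std(image, params.window)
    return image > mean * (1.0 + params.k * (std / params.R - 1.0))


def white_rohrer(image: np.ndarray, params: LocalParams | None = None) -> np.ndarray:
    """Foreground where bias * response > m(p), the local expected intensity."""
    params = params or LocalParams(bias=1.0)
    if params.bias <= 0:
        raise ValueError("bias must be > 0")
    image = _check_local(image, params)
    mean, _ = _local_mean_std(image, params.window)
    return params.bias * image > mean


_GLOBAL_METHODS = {
    "otsu": otsu,
    "ridler_calvard": ridler_calvard,
    "kapur": kapur,
    "pal": pal_entropy,
    "moments": moments,
    "concavity": concavity,
}
_LOCAL_METHODS = {"niblack": niblack, "sauvola": sauvola, "white_rohrer": white_rohrer}
METHODS = tuple(_GLOBAL_METHODS) + ("rats",) + tuple(_LOCAL_METHODS)


def segment(
    image: np.ndarray, method: str = "otsu", params: LocalParams | None = None
) -> np.ndarray:
    """Binarize a detection response with the named method (vessel = above threshold).

    Global methods go through the 256-bin histogram; the returned mask is
    ``bin_of(response) > t``.  ``rats`` thresholds directly in value domain;
    local methods produce the mask directly.  Degenerate inputs (constant
    response, convex histogram with no concavity for ``concavity``) yield an
    all-background mask with a logged warning rather than an error.
    """
    image = np.asarray(image, dtype=np.float64)
    if method in _LOCAL_METHODS:
        return _LOCAL_METHODS[method](image, params)
    if method == "rats":
        try:
            return image > rats(image)
        except DegenerateHistogramError as exc:
            logger.warning("degenerate input for rats (%s); returning all-background", exc)
            return np.zeros(image.shape, dtype=bool)
    if method not in _GLOBAL_METHODS:
        raise ValueError(f"unknown thresholding method {method!r}; choose from {METHODS}")
    hist = make_histogram(image)
    try:
        t = _GLOBAL_METHODS[method](hist)
    except NoConcavityError as exc:
        logger.warning("%s; falling back to otsu", exc)
        t = otsu(hist)
    except DegenerateHistogramError as exc:
        logger.warning("degenerate input for %s (%s); returning all-background", method, exc)
        return np.zeros(image.shape, dtype=bool)
    return hist.bin_of(image) > t
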