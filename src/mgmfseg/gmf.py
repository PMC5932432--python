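"""Oriented Gaussian matched filters for vessel enhancement.

A Gaussian matched filter (GMF) approximates the cross-sectional intensity
profile of a contrast-filled vessel — a dark Gaussian valley on a brighter
background — with a template

    G(x, y) = -exp(-x**2 / (2 * sigma**2)),   |x| <= (T-1)/2,  |y| <= (L-1)/2,

constant along the local vessel axis ``y`` over a segment of length ``L`` and
truncated across the vessel at width ``T``.  The template is replicated at
``kappa`` evenly spaced orientations spanning 180 degrees and correlated with
the image; the per-pixel maximum over orientations is the detection response.
Because the template is zero-sum after normalization, flat background regions
respond with (numerically) zero and vessels of width comparable to ``sigma``
respond strongly.

A multiscale response evaluates the same bank at several ``sigma`` values so
that vessels of different calibers are each matched by some scale; fusing the
per-scale responses is the job of :mod:`mgmfseg.ann`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "GMFParams",
    "Kernel",
    "ResponseStack",
    "build_template",
    "rotate_template",
    "build_filter_bank",
    "gmf_response",
    "multiscale_response",
]


def _next_odd(n: int) -> int:
    n = int(n)
    return n if n % 2 == 1 else n + 1


@dataclass(frozen=True)
class GMFParams:
    """Parameters of one oriented Gaussian matched-filter bank.

    Parameters
    ----------
    sigma : float
        Spread of the Gaussian cross-section in pixels (> 0); proxy for the
        average vessel half-width.
    L : int
        Template length along the vessel axis in pixels (>= 1).  Even values
        are rounded up to the next odd integer so the template is centered.
    T : int
        Template width across the vessel axis in pixels (>= 1); the position
        where the Gaussian trails are cut.  Even values are rounded up.
    kappa : int
        Number of evenly spaced orientations covering 180 degrees (>= 1);
        orientation ``i`` has angle ``-90 + i * 180 / kappa`` degrees.
    """

    sigma: float
    L: int = 9
    T: int = 13
    kappa: int = 12

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError(f"sigma must be a positive finite number, got {self.sigma!r}")
        for name in ("L", "T", "kappa"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        object.__setattr__(self, "L", _next_odd(self.L))
        object.__setattr__(self, "T", _next_odd(self.T))
        object.__setattr__(self, "kappa", int(self.kappa))

    @property
    def side(self) -> int:
        """Side of the square kernel grid: smallest odd integer >= max(L, T)."""
        return _next_odd(max(self.L, self.T))

    @property
    def angles(self) -> np.ndarray:
        """Bank angles in degrees, ascending: -90 + i * 180/kappa."""
        return -90.0 + np.arange(self.kappa) * (180.0 / self.kappa)


@dataclass(frozen=True)
class Kernel:
    """A single oriented matched-filter template on a square odd-sided grid.

    ``weights`` are zero outside ``support``; over the support they sum to
    zero (mean-subtracted matched filter), so the response to any constant
    image vanishes.
    """

    weights: np.ndarray
    support: np.ndarray
    angle: float

    @property
    def side(self) -> int:
        return self.weights.shape[0]


def rotate_template(params: GMFParams, theta_deg: float) -> Kernel:
    """Build the matched-filter template at orientation ``theta_deg``.

    The kernel is produced by analytic resampling: each grid cell ``(u, v)``
    (``u`` = column offset, ``v`` = row offset from the center) is mapped back
    through the inverse rotation and the continuous template is evaluated at
    the back-rotated coordinate.  No image-space interpolation is involved.
    The support is the back-rotated L-by-T rectangle intersected with the
    grid; the mean over the support is subtracted so the kernel is zero-sum.
    """
    D = params.side
    half = (D - 1) // 2
    v, u = np.meshgrid(np.arange(-half, half + 1), np.arange(-half, half + 1), indexing="ij")
    theta = np.deg2rad(theta_deg)
    c, s = np.cos(theta), np.sin(theta)
    # (x, y) = R(-theta) @ (u, v)
    x = c * u + s * v
    y = -s * u + c * v
    half_T = (params.T - 1) / 2.0
    half_L = (params.L - 1) / 2.0
    eps = 1e-9  # tolerate rotation round-off at the support boundary
    support = (np.abs(x) <= half_T + eps) & (np.abs(y) <= half_L + eps)
    raw = np.where(support, -np.exp(-(x**2) / (2.0 * params.sigma**2)), 0.0)
    weights = np.where(support, raw - raw[support].mean(), 0.0)
    return Kernel(weights=weights, support=support, angle=float(theta_deg))


def build_template(params: GMFParams) -> Kernel:
    """Unrotated (angle 0) matched-filter template: a vertical-vessel detector."""
    return rotate_template(params, 0.0)


def build_filter_bank(params: GMFParams) -> list[Kernel]:
    """The ``kappa`` oriented templates at angles -90 + i*180/kappa, ascending."""
    return [rotate_template(params, a) for a in params.angles]


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ValueError(f"image must be a non-empty 2-D array, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    return image


def gmf_response(image: np.ndarray, params: GMFParams) -> np.ndarray:
    """Max-over-orientations matched-filter response of ``image``.

    The image is correlated (no kernel flip) with every kernel of the bank
    under symmetric-reflect border padding; each pixel keeps its maximum
    response over orientations.  Dark vessels on a bright background produce
    positive responses — the image is used with its native polarity.
    """
    image = _check_image(image)
    bank = build_filter_bank(params)
    pad = bank[0].side // 2
    padded = np.pad(image, pad, mode="symmetric")
    out = None
    for kernel in bank:
        # correlation == convolution with the doubly flipped kernel
        r = fftconvolve(padded, kernel.weights[::-1, ::-1], mode="valid")
        out = r if out is None else np.maximum(out, r)
    return out


@dataclass(frozen=True)
class ResponseStack:
    """Per-scale max-over-orientations responses of one image.

    ``responses`` has shape ``(n_scales, H, W)``; layer ``i`` is the response
    at ``sigmas[i]``.  All layers share the template shape parameters
    ``(L, T, kappa)``.  The per-pixel vector across layers is the feature
    vector consumed by the fusion network.
    """

    responses: np.ndarray
    sigmas: tuple[float, ...]
    L: int
    T: int
    kappa: int

    @property
    def n_scales(self) -> int:
        return self.responses.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.responses.shape[1:]

    def features(self) -> np.ndarray:
        """Pixels as rows: array of shape (H*W, n_scales)."""
        return self.responses.reshape(self.n_scales, -1).T


def multiscale_response(
    image: np.ndarray,
    sigmas,
    L: int = 13,
    T: int = 15,
    kappa: int = 12,
) -> ResponseStack:
    """One :func:`gmf_response` per scale, sharing (L, T, kappa).

    ``sigmas`` must be non-empty and strictly increasing; the stack is ordered
    as given.
    """
    sigmas = tuple(float(s) for s in np.atleast_1d(sigmas))
    if len(sigmas) == 0:
        raise ValueError("sigmas must be non-empty")
    if len(sigmas) > 1 and not all(a < b for a, b in zip(sigmas, sigmas[1:])):
        raise ValueError("sigmas must be strictly increasing")
    image = _check_image(image)
    layers = [gmf_response(image, GMFParams(sigma=s, L=L, T=T, kappa=kappa)) for s in sigmas]
    params = GMFParams(sigma=sigmas[0], L=L, T=T, kappa=kappa)
    return ResponseStack(
        responses=np.stack(layers), sigmas=sigmas, L=params.L, T=params.T, kappa=params.kappa
    )
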