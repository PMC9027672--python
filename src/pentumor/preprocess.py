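"""Gabor-filter preprocessing.

A Gabor filter is a sinusoidal carrier under a Gaussian envelope — a 2-D
bandpass filter localized in both space and frequency.  Applied as a small
bank over several orientations it enhances oriented texture and suppresses
broadband noise while preserving image geometry, which is why it is a
common first stage ahead of histogram-based segmentation.

The filtering step is plain spatial convolution with reflect padding, so a
single-kernel response is linear in the input; the combined bank response
is re-quantized to integer gray levels for downstream histogramming.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .phantoms import GrayImage


class GaborParamError(ValueError):
    """Raised for invalid Gabor kernel parameters."""


@dataclass(frozen=True)
class GaborParams:
    """Parameters of one real Gabor kernel.

    wavelength : pixels per sinusoid cycle (> 0)
    orientation : carrier direction, radians
    sigma : Gaussian envelope standard deviation, pixels; defaults to
        ``0.56 * wavelength`` (about one octave of bandwidth)
    aspect_ratio : envelope ellipticity (1 = isotropic)
    phase : carrier phase, radians (0 = even/cosine kernel)
    kernel_size : odd side length; defaults to an odd value covering ~6 sigma
    """

    wavelength: float = 8.0
    orientation: float = 0.0
    sigma: Optional[float] = None
    aspect_ratio: float = 1.0
    phase: float = 0.0
    kernel_size: Optional[int] = None

    def resolved_sigma(self) -> float:
        return 0.56 * self.wavelength if self.sigma is None else self.sigma

    def resolved_size(self) -> int:
        if self.kernel_size is not None:
            return self.kernel_size
        size = int(2 * math.ceil(3.0 * self.resolved_sigma()) + 1)
        return max(size, 3)

    def validate(self) -> None:
        if self.wavelength <= 0:
            raise GaborParamError(f"wavelength must be > 0, got {self.wavelength}")
        if self.resolved_sigma() <= 0:
            raise GaborParamError(f"sigma must be > 0, got {self.sigma}")
        if self.aspect_ratio <= 0:
            raise GaborParamError(f"aspect_ratio must be > 0, got {self.aspect_ratio}")
        size = self.resolved_size()
        if size < 3 or size % 2 == 0:
            raise GaborParamError(f"kernel_size must be odd and >= 3, got {size}")


def gabor_kernel(params: GaborParams) -> np.ndarray:
    """Real Gabor kernel: cosine carrier times Gaussian envelope.

    The center entry equals ``cos(phase)`` (the envelope is 1 at the
    origin).  With ``phase=0`` the kernel is even-symmetric about the
    carrier axis.
    """
    params.validate()
    size = params.resolved_size()
    sigma = params.resolved_sigma()
    half = size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    c, s = math.cos(params.orientation), math.sin(params.orientation)
    xr = x * c + y * s
    yr = -x * s + y * c
    envelope = np.exp(-(xr**2 + (params.aspect_ratio * yr) ** 2) / (2 * sigma**2))
    carrier = np.cos(2 * math.pi * xr / params.wavelength + params.phase)
    return envelope * carrier


def default_bank(
    wavelength: float = 8.0,
    orientations: Sequence[float] = (0.0, math.pi / 4, math.pi / 2, 3 * math.pi / 4),
) -> list[GaborParams]:
    """Standard 4-orientation texture-enhancement bank at one wavelength."""
    return [GaborParams(wavelength=wavelength, orientation=o) for o in orientations]


def gabor_response(image: GrayImage | np.ndarray, params: GaborParams) -> np.ndarray:
    """Raw (float, un-rescaled) response of one kernel.

    Spatial convolution with reflect padding: same shape as the input,
    linear in the input, and the response to a centered unit impulse is the
    kernel itself.
    """
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    kernel = gabor_kernel(params)
    return ndimage.convolve(pixels.astype(float), kernel, mode="reflect")


def gabor_filter(
    image: GrayImage,
    bank: Optional[Sequence[GaborParams]] = None,
    combine: str = "max",
) -> GrayImage:
    """Filter an image through a Gabor bank and re-quantize to gray levels.

    Parameters
    ----------
    image : GrayImage
    bank : sequence of GaborParams
        Defaults to :func:`default_bank`.
    combine : {"max", "mean"}
        "max" keeps, per pixel, the largest response magnitude across the
        bank; "mean" averages the raw responses.

    Returns
    -------
    GrayImage of the same shape, min-max rescaled to ``[0, levels - 1]``.
    A constant combined response maps to all zeros.
    """
    if bank is None:
        bank = default_bank()
    if len(bank) == 0:
        raise GaborParamError("filter bank must be non-empty")
    if combine not in ("max", "mean"):
        raise GaborParamError(f"combine must be 'max' or 'mean', got {combine!r}")
    responses = np.stack([gabor_response(image, p) for p in bank])
    if combine == "max":
        combined = np.abs(responses).max(axis=0)
    else:
        combined = responses.mean(axis=0)
    lo, hi = combined.min(), combined.max()
    if hi - lo < 1e-300:
        pixels = np.zeros_like(image.pixels)
    else:
        pixels = np.rint((combined - lo) / (hi - lo) * (image.levels - 1)).astype(
            np.int64
        )
    return GrayImage(pixels, levels=image.levels)
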