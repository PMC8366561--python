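"""Laplacian-of-Gaussian (LoG) band-pass filtration at millimetre spatial scales.

The filtration-histogram technique convolves a slice with a zero-mean LoG
kernel whose width is set by a spatial scale filter (SSF) value in mm:
SSF 2 highlights fine texture, SSF 3-5 medium, SSF 6 coarse, and SSF 0 is the
unfiltered control (exact identity).  The kernel is DC-free, so filtered
responses are insensitive to additive intensity offsets, and band-pass: an
object of diameter ~d mm responds most strongly at the SSF nearest d.

The mm-to-sigma mapping used by commercial implementations is not published;
here ``sigma_mm = sigma_ratio * ssf_mm`` with ``sigma_ratio = 0.5`` by
default, which places the peak blob response of an object of diameter d at
SSF ~ d.  Absolute filtered values depend on this choice; rank orderings
across lesions (what the downstream prognostic analysis uses) do not.

Sign convention: the kernel is the *negated* Laplacian of the Gaussian, so
bright blobs produce positive responses (and dark blobs negative ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .image import ImageSlice

__all__ = [
    "ALLOWED_SSF_MM",
    "FilterConfig",
    "TextureMap",
    "build_log_kernel",
    "filter_slice",
    "export_texture_map",
    "LoGFilterBank",
]

#: SSF values (mm) the filtration stage accepts; 0 means "unfiltered".
ALLOWED_SSF_MM = (0.0, 2.0, 3.0, 4.0, 5.0, 6.0)

#: Minimum per-axis sigma in pixels below which a discrete LoG kernel cannot
#: be resolved on the grid.
MIN_SIGMA_PX = 0.4


@dataclass(frozen=True)
class FilterConfig:
    """Configuration of one LoG filtration pass.

    Parameters
    ----------
    ssf_mm : float
        Spatial scale in mm; one of :data:`ALLOWED_SSF_MM` (0 = no filtering).
    sigma_ratio : float
        sigma_mm = sigma_ratio * ssf_mm.  Default 0.5.
    truncation : float
        Kernel half-width in multiples of sigma (>= 3).
    padding : {"reflect", "constant"}
        Edge handling of the convolution.
    """

    ssf_mm: float = 0.0
    sigma_ratio: float = 0.5
    truncation: float = 4.0
    padding: str = "reflect"

    def __post_init__(self) -> None:
        if float(self.ssf_mm) not in ALLOWED_SSF_MM:
            raise ValueError(
                f"ssf_mm must be one of {ALLOWED_SSF_MM}, got {self.ssf_mm}"
            )
        if self.truncation < 3:
            raise ValueError("truncation must be >= 3 sigma")
        if self.padding not in ("reflect", "constant"):
            raise ValueError("padding must be 'reflect' or 'constant'")
        if self.sigma_ratio <= 0:
            raise ValueError("sigma_ratio must be positive")


@dataclass
class TextureMap:
    """Filtered response map, same grid as its source slice."""

    pixels: np.ndarray
    ssf_mm: float
    modality: str


def build_log_kernel(
    ssf_mm: float,
    spacing_mm: tuple[float, float],
    sigma_ratio: float = 0.5,
    truncation: float = 4.0,
) -> np.ndarray:
    """Discrete zero-mean (negated) LoG kernel for a given SSF and spacing.

    Anisotropic spacing is handled by a per-axis sigma in pixel units,
    ``sigma_px[i] = sigma_ratio * ssf_mm / spacing_mm[i]``.  The analytic LoG
    is sampled on an integer grid truncated at ``truncation * sigma_px`` per
    axis, scale-normalized by ``sigma_mm**2`` (without this the response to a
    blob would decrease monotonically with scale and the filter bank would
    not be scale-selective: the normalized center response to a Gaussian blob
    of width sigma_b is proportional to sigma_b^2 sigma_f^2 /
    (sigma_b^2 + sigma_f^2)^2, peaking at sigma_f = sigma_b, i.e. at
    SSF = blob diameter under the default mapping), then shifted by its mean
    so the entries sum exactly to zero — a constant image therefore filters
    to exactly zero.

    Raises
    ------
    ValueError
        If ``ssf_mm <= 0`` or the implied sigma is under 0.4 pixel, i.e. the
        scale is unresolvable at the given spacing.
    """
    if ssf_mm <= 0:
        raise ValueError("ssf_mm must be positive for kernel construction")
    if any(s <= 0 for s in spacing_mm):
        raise ValueError("spacing must be positive")
    sigma_mm = sigma_ratio * float(ssf_mm)
    sigma_px = np.array([sigma_mm / spacing_mm[0], sigma_mm / spacing_mm[1]])
    if sigma_px.min() < MIN_SIGMA_PX:
        raise ValueError(
            f"sigma {sigma_px} px below {MIN_SIGMA_PX}; SSF {ssf_mm} mm is "
            f"unresolvable at spacing {spacing_mm} mm"
        )
    half = np.ceil(truncation * sigma_px).astype(int)
    y = np.arange(-half[0], half[0] + 1)[:, None]
    x = np.arange(-half[1], half[1] + 1)[None, :]
    sy2, sx2 = sigma_px[0] ** 2, sigma_px[1] ** 2
    g = np.exp(-(y**2 / (2 * sy2) + x**2 / (2 * sx2)))
    # Laplacian of the Gaussian, negated so bright blobs respond positively.
    log = -(y**2 / sy2**2 + x**2 / sx2**2 - 1 / sy2 - 1 / sx2) * g
    log *= sigma_mm**2 / g.sum()  # sigma^2 scale normalization (band-pass)
    return log - log.mean()


def filter_slice(slice_: ImageSlice, config: FilterConfig) -> TextureMap:
    """Apply one LoG filtration pass to a full slice.

    The ROI plays no role here: the whole slice is filtered (edge handling per
    ``config.padding``) and the downstream statistics stage restricts to ROI
    pixels.  ``ssf_mm == 0`` returns the input pixels unchanged.
    """
    if config.ssf_mm == 0:
        return TextureMap(
            pixels=slice_.pixels.copy(), ssf_mm=0.0, modality=slice_.modality
        )
    kernel = build_log_kernel(
        config.ssf_mm, slice_.spacing_mm, config.sigma_ratio, config.truncation
    )
    mode = {"reflect": "reflect", "constant": "constant"}[config.padding]
    out = ndimage.convolve(slice_.pixels, kernel, mode=mode, cval=0.0)
    # snap sub-machine-noise responses to exactly zero so a constant input
    # yields a genuinely degenerate map (MPP undefined, entropy 0) instead of
    # +/-1e-13 summation residue
    floor = 100 * np.finfo(np.float64).eps * max(1.0, np.abs(slice_.pixels).max())
    out[np.abs(out) < floor] = 0.0
    return TextureMap(pixels=out, ssf_mm=float(config.ssf_mm), modality=slice_.modality)


def export_texture_map(
    tmap: TextureMap, spacing_mm: tuple[float, float], path
) -> None:
    """Write a filtered response map as float32 NIfTI for visual review
    (see :func:`texhist.plotting.plot_texture_map` for the signed-response
    color convention)."""
    import nibabel as nib

    affine = np.diag([spacing_mm[0], spacing_mm[1], 1.0, 1.0])
    img = nib.Nifti1Image(tmap.pixels.astype(np.float32), affine)
    img.header.set_zooms(spacing_mm)
    nib.save(img, str(path))


class LoGFilterBank(TransformerMixin, BaseEstimator):
    """Transformer applying a bank of LoG filters to image slices.

    ``transform`` maps a list of :class:`~texhist.image.ImageSlice` to a list
    of per-slice dicts ``{ssf_mm: TextureMap}``.  Stateless; ``fit`` only
    validates parameters.
    """

    def __init__(
        self,
        ssf_mm: tuple[float, ...] = (0.0, 2.0, 3.0, 4.0, 5.0, 6.0),
        sigma_ratio: float = 0.5,
        truncation: float = 4.0,
        padding: str = "reflect",
    ) -> None:
        self.ssf_mm = ssf_mm
        self.sigma_ratio = sigma_ratio
        self.truncation = truncation
        self.padding = padding

    def _configs(self) -> list[FilterConfig]:
        return [
            FilterConfig(
                ssf_mm=s,
                sigma_ratio=self.sigma_ratio,
                truncation=self.truncation,
                padding=self.padding,
            )
            for s in self.ssf_mm
        ]

    def fit(self, X=None, y=None) -> "LoGFilterBank":
        self.configs_ = self._configs()
        return self

    def transform(self, X) -> list[dict[float, TextureMap]]:
        configs = getattr(self, "configs_", None) or self._configs()
        return [
            {c.ssf_mm: filter_slice(slice_, c) for c in configs} for slice_ in X
        ]
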