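"""Despeckling and per-ROI intensity normalization.

Ultrasound B-mode images carry multiplicative speckle noise. The pipeline
despeckles each frame with a 3x3 adaptive (local) Wiener filter and then
standardizes intensities *within the lesion ROI* to Z-scores, so that
downstream texture features compare relative contrast rather than absolute
echo amplitude. Per-ROI Z-scoring makes every feature exactly invariant to
global gain/offset differences between scanners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class DegenerateROIError(ValueError):
    """Raised when a ROI has zero intensity variance and cannot be Z-scored."""


@dataclass
class NormalizedROI:
    """Z-scored intensities of a masked lesion region.

    Attributes
    ----------
    zscores : 2-D float array, values valid only where ``mask`` is True.
    mask : 2-D boolean array, same shape as ``zscores``.
    source_case_id : identifier of the originating case.
    raw_mean, raw_sd : ROI mean and sample SD (n-1) of the despeckled image,
        kept for provenance.
    """

    zscores: np.ndarray
    mask: np.ndarray
    source_case_id: str = ""
    raw_mean: float = field(default=float("nan"))
    raw_sd: float = field(default=float("nan"))

    @property
    def pixels(self) -> np.ndarray:
        """1-D array of in-mask Z-scores."""
        return self.zscores[self.mask]

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def wiener_despeckle(image: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Adaptive local Wiener filter for speckle reduction.

    For every pixel, the local mean ``m`` and local variance ``v`` are taken
    over a ``kernel`` x ``kernel`` window (symmetric edge padding). The noise
    variance ``nu`` is estimated as the mean of all local variances, and the
    output is

        m + max(v - nu, 0) / max(v, nu) * (x - m)

    i.e. pixels in flat regions are pulled to the local mean while pixels in
    high-variance regions are left nearly untouched. The result is clipped to
    the representable range of the input dtype and returned as float64.

    Parameters
    ----------
    image : 2-D array of intensities.
    kernel : odd window size, >= 3.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got ndim={img.ndim}")
    if kernel < 3 or kernel % 2 == 0:
        raise ValueError(f"kernel must be odd and >= 3, got {kernel}")
    if min(img.shape) < kernel:
        raise ValueError(f"image shape {img.shape} smaller than kernel {kernel}")

    x = img.astype(np.float64)
    m = ndimage.uniform_filter(x, size=kernel, mode="reflect")
    m2 = ndimage.uniform_filter(x * x, size=kernel, mode="reflect")
    v = np.maximum(m2 - m * m, 0.0)
    nu = float(v.mean())

    denom = np.maximum(v, nu)
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(denom > 0, np.maximum(v - nu, 0.0) / np.where(denom > 0, denom, 1.0), 0.0)
    out = m + gain * (x - m)

    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        out = np.clip(out, info.min, info.max)
    return out


def zscore_roi(image: np.ndarray, mask: np.ndarray, case_id: str = "") -> NormalizedROI:
    """Standardize masked pixels to Z-scores using ROI mean and sample SD.

    Only pixels inside ``mask`` enter the mean/SD and all downstream feature
    computation; the returned array holds 0 outside the mask (never used).

    Raises
    ------
    DegenerateROIError
        If the masked pixels are constant (SD = 0).
    """
    img = np.asarray(image, dtype=np.float64)
    msk = np.asarray(mask).astype(bool)
    if img.shape != msk.shape:
        raise ValueError(f"image shape {img.shape} != mask shape {msk.shape}")
    vals = img[msk]
    if vals.size == 0:
        raise ValueError("mask selects no pixels")
    mean = float(vals.mean())
    if vals.size < 2:
        raise DegenerateROIError(f"ROI of case {case_id!r} has a single pixel")
    sd = float(vals.std(ddof=1))
    if sd == 0.0:
        raise DegenerateROIError(f"ROI of case {case_id!r} has zero intensity variance")
    z = np.zeros_like(img)
    z[msk] = (vals - mean) / sd
    return NormalizedROI(zscores=z, mask=msk, source_case_id=case_id, raw_mean=mean, raw_sd=sd)
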