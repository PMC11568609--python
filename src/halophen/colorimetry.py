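"""CIELab colorimetry for plant images.

Device RGB is decoded as sRGB and converted to CIELab under illuminant D65
(the standard 2° observer matrices, via scikit-image).  On top of the Lab
coordinates the module computes the derived colour metrics used for salinity
phenotyping:

* chroma  S* = sqrt(a*^2 + b*^2)
* hue angle Hue = atan2(b*, a*) in degrees, [0, 360) — green foliage sits
  near 120°, yellow near 90°
* colour difference ΔE = Euclidean distance in Lab space; ΔE1 is taken
  against a white standard (default L*=100, a*=0, b*=0) and ΔE2 against the
  mean colour of the no-salinity (NO-S) group

plus an affine colour-checker correction fitted on 24-patch charts.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "WHITE_STANDARD",
    "LabTriplet",
    "ColourFeatures",
    "ColorCorrection",
    "rgb_to_lab",
    "chroma",
    "hue_angle",
    "delta_e",
    "colour_summary",
    "fit_colour_correction",
]


@dataclasses.dataclass(frozen=True)
class LabTriplet:
    """A CIELab colour: L* in [0, 100], a* green–red, b* blue–yellow."""

    L: float
    a: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)


#: Perfect diffuse white under D65: the ΔE1 reference.
WHITE_STANDARD = LabTriplet(100.0, 0.0, 0.0)


@dataclasses.dataclass(frozen=True)
class ColourFeatures:
    """Per-plant colour summary: mean Lab plus derived metrics."""

    L: float
    a: float
    b: float
    S: float
    hue_deg: float
    delta_e1: float
    delta_e2: float | None

    def mean_lab(self) -> LabTriplet:
        return LabTriplet(self.L, self.a, self.b)


def _validate_rgb(rgb: np.ndarray) -> np.ndarray:
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("RGB input must have 3 channels in the last axis")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("RGB channel values must lie in [0, 255]")
    return arr


def rgb_to_lab(rgb):
    """Convert 8-bit sRGB to CIELab (D65).

    Parameters
    ----------
    rgb : length-3 sequence or (..., 3) array
        Channel values in [0, 255].

    Returns
    -------
    LabTriplet for a single triplet input, otherwise an (..., 3) float array
    of Lab values.
    """
    arr = _validate_rgb(rgb)
    single = arr.ndim == 1
    lab = _skcolor.rgb2lab(arr / 255.0)
    if single:
        return LabTriplet(float(lab[0]), float(lab[1]), float(lab[2]))
    return lab


def chroma(a_star, b_star):
    """Chroma S* = sqrt(a*^2 + b*^2)."""
    a = np.asarray(a_star, dtype=float)
    b = np.asarray(b_star, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("chroma requires finite a*, b*")
    out = np.hypot(a, b)
    return float(out) if out.ndim == 0 else out

def hue_angle(a_star, b_star):
    """Hue angle in degrees, [0, 360), by quadrant-aware arctangent.

    Raises ValueError at the achromatic origin (a*, b*) = (0, 0), where hue
    is undefined.
    """
    a = np.asarray(a_star, dtype=float)
    b = np.asarray(b_star, dtype=float)
    if np.any((a == 0) & (b == 0)):
        raise ValueError("hue is undefined at (a*, b*) = (0, 0)")
    out = np.degrees(np.arctan2(b, a)) % 360.0
    return float(out) if out.ndim == 0 else out


def _as_lab_array(t) -> np.ndarray:
    if isinstance(t, LabTriplet):
        return t.as_array()
    arr = np.asarray(t, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("Lab triplet must have 3 components")
    return arr


def delta_e(sample, reference) -> float:
    """Euclidean colour difference ΔE between two Lab triplets."""
    s = _as_lab_array(sample)
    r = _as_lab_array(reference)
    out = np.sqrt(np.sum((s - r) ** 2, axis=-1))
    return float(out) if out.ndim == 0 else out


def colour_summary(
    lab_image: np.ndarray,
    mask: np.ndarray,
    white_ref: LabTriplet = WHITE_STANDARD,
    baseline_ref: LabTriplet | None = None,
) -> ColourFeatures:
    """Summarize a Lab image over a plant mask.

    Means of L*, a*, b* are taken over the masked pixels; S*, Hue, ΔE1 and
    (when a no-salinity baseline is given) ΔE2 are computed from those means.
    """
    lab = np.asarray(lab_image, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if lab.shape[:-1] != m.shape:
        raise ValueError("mask geometry does not match the Lab image")
    if not m.any():
        raise ValueError("empty mask: no pixels to summarize")
    mean = lab[m].mean(axis=0)
    L, a, b = (float(v) for v in mean)
    return ColourFeatures(
        L=L,
        a=a,
        b=b,
        S=chroma(a, b),
        hue_deg=hue_angle(a, b),
        delta_e1=delta_e((L, a, b), white_ref),
        delta_e2=None if baseline_ref is None else delta_e((L, a, b), baseline_ref),
    )


def _srgb_decode(rgb01: np.ndarray) -> np.ndarray:
    a = 0.055
    return np.where(rgb01 <= 0.04045, rgb01 / 12.92, ((rgb01 + a) / (1 + a)) ** 2.4)


def _srgb_encode(lin: np.ndarray) -> np.ndarray:
    a = 0.055
    lin = np.clip(lin, 0.0, 1.0)
    return np.where(lin <= 0.0031308, lin * 12.92, (1 + a) * lin ** (1 / 2.4) - a)


class ColorCorrection:
    """Affine device-RGB → reference-RGB correction from a colour checker.

    The map (3×3 matrix + offset) is fitted by least squares in *linearized*
    sRGB, the simplest model that contains the identity and absorbs exposure
    offsets.  Fitted attributes: ``matrix_``, ``offset_``, ``residual_``
    (RMS patch error in linear RGB units).
    """

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "ColorCorrection":
        return self

    def fit(self, measured: Sequence, reference: Sequence) -> "ColorCorrection":
        X = _srgb_decode(_validate_rgb(measured) / 255.0)
        Y = _srgb_decode(_validate_rgb(reference) / 255.0)
        if X.ndim != 2 or X.shape != Y.shape:
            raise ValueError("measured and reference patch sets must match in shape")
        if X.shape[0] < 4:
            raise ValueError("at least 4 patches are required to fit an affine map")
        design = np.hstack([X, np.ones((X.shape[0], 1))])
        if np.linalg.matrix_rank(design) < 4:
            raise ValueError("degenerate patch set: patches are rank-deficient")
        coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
        self.matrix_ = coef[:3].T
        self.offset_ = coef[3]
        resid = design @ coef - Y
        self.residual_ = float(np.sqrt(np.mean(resid**2)))
        return self

    def transform(self, rgb):
        """Apply the correction to 8-bit RGB triplets or images."""
        arr = _validate_rgb(rgb)
        lin = _srgb_decode(arr / 255.0)
        corrected = lin @ self.matrix_.T + self.offset_
        return _srgb_encode(corrected) * 255.0


def fit_colour_correction(measured, reference) -> ColorCorrection:
    """Fit an affine colour-checker correction (thin wrapper)."""
    return ColorCorrection().fit(measured, reference)
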