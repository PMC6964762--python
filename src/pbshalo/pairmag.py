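"""Pair-magnification compositing.

Successive exposures of the same spot at increasing delivered dose each
resolve a different intensity band: the 1x shot holds the unsaturated
core, the 20x and 400x shots lift the faint halo out of the noise floor at
the price of a saturated centre.  Registering the exposures and letting
the highest trusted magnification serve each pixel yields one composite
relative-intensity image whose usable range reaches 0.01% of the peak.

Per-pixel rule: a pixel takes its value from the highest-magnification
exposure in which it is unsaturated and below ``threshold_fraction`` of
the saturation level, divided by that exposure's magnification.  Where two
adjacent levels are both trusted, the hand-over is cross-faded linearly in
intensity across a band below the trust threshold, so the composite is
continuous through level transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import InvalidParameterError, RegistrationError
from .synthetic import ExposureSet, grid_coords

logger = logging.getLogger("pbshalo")

DEFAULT_THRESHOLD_FRACTION = 0.8
# lower edge of the cross-fade band, as a fraction of the trust threshold
BLEND_BAND_LOWER = 0.5
MIN_OVERLAP_PIXELS = 64


@dataclass
class CompositeProfile:
    """Stitched high-dynamic-range spot profile, peak-normalized to 1."""

    values: np.ndarray
    valid_mask: np.ndarray
    source_level: np.ndarray
    rel_uncertainty: np.ndarray
    pixel_pitch: float
    labels: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def coords(self):
        return grid_coords(self.shape, self.pixel_pitch)


def _trusted_mask(image, device, threshold_fraction: float) -> np.ndarray:
    mask = ~image.saturated_mask & np.isfinite(image.values)
    if np.isfinite(device.saturation_level):
        mask &= image.values <= threshold_fraction * device.saturation_level
    return mask


def _ncc(a: np.ndarray, b: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray,
         di: int, dj: int) -> float:
    """Pearson correlation of a and b shifted by (di, dj) pixels, over
    mutually trusted pixels; nan when the overlap is too small."""
    n_i, n_j = a.shape
    ai0, ai1 = max(0, -di), n_i + min(0, -di)
    aj0, aj1 = max(0, -dj), n_j + min(0, -dj)
    if ai1 <= ai0 or aj1 <= aj0:
        return np.nan
    a_sub = a[ai0:ai1, aj0:aj1]
    b_sub = b[ai0 + di:ai1 + di, aj0 + dj:aj1 + dj]
    m = mask_a[ai0:ai1, aj0:aj1] & mask_b[ai0 + di:ai1 + di, aj0 + dj:aj1 + dj]
    if m.sum() < MIN_OVERLAP_PIXELS:
        return np.nan
    av, bv = a_sub[m], b_sub[m]
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = np.sqrt((av @ av) * (bv @ bv))
    if denom == 0:
        return np.nan
    return float((av @ bv) / denom)


def _parabolic_offset(cm: float, c0: float, cp: float) -> float:
    """Vertex offset of the parabola through three equispaced samples."""
    denom = cm - 2.0 * c0 + cp
    if denom >= 0 or not np.isfinite(denom):
        return 0.0
    return float(np.clip(0.5 * (cm - cp) / denom, -1.0, 1.0))


def register_exposures(exposures: ExposureSet, max_shift_mm: float = 3.0,
                       threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION):
    """Estimate each exposure's (dx, dy) mm offset relative to the first.

    The offset maximizing normalized cross-correlation over mutually
    trusted (unsaturated, sub-threshold) pixels is found by exhaustive
    integer search within ``max_shift_mm``, then refined to sub-pixel
    precision with a parabolic fit through the correlation peak.
    """
    pitch = exposures.pixel_pitch
    device = exposures.device
    max_px = max(1, int(round(max_shift_mm / pitch)))
    ref = exposures.exposures[0]
    mask_ref = _trusted_mask(ref, device, threshold_fraction)
    offsets = [(0.0, 0.0)]
    for image in exposures.exposures[1:]:
        mask = _trusted_mask(image, device, threshold_fraction)
        shifts = np.arange(-max_px, max_px + 1)
        scores = np.full((shifts.size, shifts.size), np.nan)
        for ii, di in enumerate(shifts):
            for jj, dj in enumerate(shifts):
                scores[ii, jj] = _ncc(ref.values, image.values, mask_ref, mask, di, dj)
        if not np.any(np.isfinite(scores)):
            raise RegistrationError(
                "no overlapping trusted region between exposures within the search window"
            )
        bi, bj = np.unravel_index(np.nanargmax(scores), scores.shape)
        di, dj = float(shifts[bi]), float(shifts[bj])
        if 0 < bi < shifts.size - 1 and np.all(np.isfinite(scores[bi - 1:bi + 2, bj])):
            di += _parabolic_offset(*scores[bi - 1:bi + 2, bj])
        if 0 < bj < shifts.size - 1 and np.all(np.isfinite(scores[bi, bj - 1:bj + 2])):
            dj += _parabolic_offset(*scores[bi, bj - 1:bj + 2])
        offsets.append((dj * pitch, di * pitch))  # (dx, dy): columns are x, rows y
    logger.info("registration offsets (mm): %s", offsets)
    return offsets


def _aligned(image, offset_mm, pitch):
    """Resample an exposure onto the reference grid (bilinear); returns the
    shifted values and a mask of pixels resampled from inside the frame."""
    di = offset_mm[1] / pitch
    dj = offset_mm[0] / pitch
    if abs(di) < 1e-9 and abs(dj) < 1e-9:
        return image.values, image.saturated_mask.astype(float), np.ones(image.shape, bool)
    values = ndimage.shift(image.values, (-di, -dj), order=1, mode="constant", cval=0.0)
    sat = ndimage.shift(image.saturated_mask.astype(float), (-di, -dj),
                        order=1, mode="constant", cval=1.0)
    inside = ndimage.shift(np.ones(image.shape), (-di, -dj),
                           order=1, mode="constant", cval=0.0) > 0.999
    return values, sat, inside


def compose(exposures: ExposureSet, offsets=None,
            threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION) -> CompositeProfile:
    """Stitch an exposure set into one high-dynamic-range composite.

    Pixels saturated (or above the trust threshold) in every exposure are
    flagged invalid rather than raising.  The per-pixel relative
    uncertainty is propagated from the device noise fraction assuming
    independent exposures.
    """
    if exposures is None or len(exposures.exposures) == 0:
        raise InvalidParameterError("empty exposure set")
    if not 0.0 < threshold_fraction < 1.0:
        raise InvalidParameterError("threshold_fraction must be in (0, 1)")
    if offsets is None:
        offsets = register_exposures(exposures, threshold_fraction=threshold_fraction)
    if len(offsets) != len(exposures.exposures):
        raise InvalidParameterError("one offset per exposure required")

    device = exposures.device
    pitch = exposures.pixel_pitch
    sat_level = device.saturation_level
    b_hi = threshold_fraction * sat_level
    b_lo = BLEND_BAND_LOWER * b_hi

    shape = exposures.exposures[0].shape
    out = np.zeros(shape)
    var = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    source_level = np.full(shape, -1, dtype=int)

    for level, (image, off, mag) in enumerate(
            zip(exposures.exposures, offsets, exposures.magnifications)):
        raw, sat_frac, inside = _aligned(image, off, pitch)
        trusted = inside & (sat_frac < 1e-6) & np.isfinite(raw)
        if np.isfinite(sat_level):
            trusted &= raw <= b_hi
        norm = raw / mag
        if np.isfinite(sat_level):
            # cross-fade: weight 0 at the trust threshold, 1 at the lower
            # band edge and below (this level fully serves fainter pixels)
            w = np.clip((b_hi - raw) / (b_hi - b_lo), 0.0, 1.0)
        else:
            w = np.ones(shape)
        w = np.where(trusted, w, 0.0)
        w = np.where(trusted & ~valid, 1.0, w)  # first trusted level takes over fully
        out = (1.0 - w) * out + w * norm
        var = (1.0 - w) ** 2 * var + w**2 * (device.noise_fraction * norm) ** 2
        source_level = np.where(w > 0, level, source_level)
        valid |= trusted

    if not np.any(valid):
        raise InvalidParameterError("no valid pixels in any exposure")
    peak = float(out[valid].max())
    if peak <= 0:
        raise InvalidParameterError("composite peak is non-positive")
    values = np.where(valid, out / peak, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_unc = np.where(out > 0, np.sqrt(var) / out, 0.0)
    labels = dict(exposures.exposures[0].labels)
    comp = CompositeProfile(values, valid, source_level, rel_unc, pitch, labels)
    logger.info("composite %s: %d/%d valid pixels, dynamic range %.3g",
                labels, int(valid.sum()), valid.size, dynamic_range(comp))
    return comp


def dynamic_range(composite: CompositeProfile) -> float:
    """Peak relative intensity divided by the smallest positive valid one."""
    vals = composite.values[composite.valid_mask]
    vals = vals[vals > 0]
    if vals.size == 0:
        raise InvalidParameterError("composite has no positive valid pixels")
    return float(vals.max() / vals.min())
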