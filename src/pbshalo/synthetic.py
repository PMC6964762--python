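"""Synthetic proton pencil-beam spot data.

A scanned proton spot measured in air is, to good approximation, a narrow
Gaussian core surrounded by a broad, low-intensity "halo" produced by
large-angle scattering in the beam line.  This module renders such spots
onto pixel grids and then degrades them the way real 2D dosimeters do:
radiochromic film clips above its useful dose range, and a
scintillator+CCD panel (Lynx-style) clips at its count ceiling and
over-responds on the side of the image facing the camera neck.  Exposure
series at increasing delivered dose (1x, 20x, 400x) are generated so the
pair-magnification compositing stage can be exercised end to end without
any measured data.

Coordinate convention: continuous mm coordinates, origin at the grid
centre, x along columns and y along rows, y increasing with row index;
pixel centres sit at half-pixel offsets, ``(i - n/2 + 0.5) * pitch``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DomainError, InvalidParameterError

logger = logging.getLogger("pbshalo")

# Full width of a Gaussian at a fraction f of its peak is
# 2*sigma*sqrt(2*ln(1/f)); these are the classic level constants.
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))        # 2.35482
FW10_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(10.0))       # 4.29193
FW1_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(100.0))       # 6.06970

# Device dynamic ranges and the headroom convention for the first (1x)
# shot: film is exposed to a 6 Gy peak against an 8 Gy useful ceiling;
# the scintillator panel to 800 of its 1000-count range.
FILM_SATURATION_GY = 8.0
FILM_FIRST_SHOT_PEAK_GY = 6.0
LYNX_SATURATION_COUNTS = 1000.0
LYNX_FIRST_SHOT_PEAK_COUNTS = 800.0
LYNX_ARTIFACT_MAX_FRACTION = 0.40
DEFAULT_PIXEL_PITCH_MM = 0.5
DEFAULT_NOISE_FRACTION = 0.001
DEFAULT_MAGNIFICATIONS = (1.0, 20.0, 400.0)

ENERGIES_MEV = (70, 80, 90, 100, 130, 150, 180, 210, 242)
POSITIONS = ("Z0", "Z300")

# Published radially-averaged width triplets (FWHM, FW10%, FW1%) in mm for
# the film and scintillator measurements at isocenter (Z0) and 30 cm
# upstream (Z300).  These drive the default spot models and serve as
# reference inputs for device-comparison tables.
FILM_WIDTHS_MM = {
    (70, "Z0"): (12.5, 24.1, 36.1),
    (80, "Z0"): (11.5, 22.0, 32.8),
    (90, "Z0"): (10.7, 20.2, 30.0),
    (100, "Z0"): (9.8, 18.8, 28.0),
    (130, "Z0"): (9.5, 17.4, 25.1),
    (150, "Z0"): (9.4, 16.9, 23.9),
    (180, "Z0"): (9.1, 15.9, 22.2),
    (210, "Z0"): (9.0, 15.2, 20.9),
    (242, "Z0"): (8.7, 14.5, 19.7),
    (70, "Z300"): (9.4, 17.3, 25.5),
    (80, "Z300"): (9.4, 16.3, 23.9),
    (90, "Z300"): (8.8, 15.3, 22.5),
    (100, "Z300"): (8.3, 14.7, 21.2),
    (130, "Z300"): (8.5, 14.0, 19.8),
    (150, "Z300"): (8.8, 14.3, 19.6),
    (180, "Z300"): (8.8, 14.0, 19.0),
    (210, "Z300"): (8.7, 13.8, 18.5),
    (242, "Z300"): (8.4, 13.4, 17.8),
}

LYNX_WIDTHS_MM = {
    (70, "Z0"): (12.6, 24.2, 37.6),
    (80, "Z0"): (11.8, 22.3, 33.6),
    (90, "Z0"): (11.2, 21.0, 31.7),
    (100, "Z0"): (10.7, 19.9, 30.0),
    (130, "Z0"): (9.9, 18.2, 26.9),
    (150, "Z0"): (9.5, 17.5, 25.8),
    (180, "Z0"): (9.2, 16.5, 24.0),
    (210, "Z0"): (8.7, 15.5, 22.4),
    (242, "Z0"): (8.7, 14.5, 20.8),
    (70, "Z300"): (9.2, 17.5, 26.2),
    (80, "Z300"): (8.9, 16.5, 24.7),
    (90, "Z300"): (8.5, 15.8, 23.2),
    (100, "Z300"): (8.4, 15.3, 22.3),
    (130, "Z300"): (8.1, 14.5, 20.7),
    (150, "Z300"): (7.9, 14.0, 20.0),
    (180, "Z300"): (8.3, 13.5, 19.3),
    (210, "Z300"): (7.9, 13.0, 18.3),
    (242, "Z300"): (8.2, 13.0, 17.3),
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpotModel:
    """Analytic spot profile: Gaussian core plus optional broader Gaussian halo.

    Relative intensity at distance ``r`` from ``center`` is

        (1 - w) * exp(-r^2 / (2 sigma_core^2)) + w * exp(-r^2 / (2 sigma_halo^2))

    with ``w = halo_weight``, so the peak is 1 by construction.
    """

    sigma_core: float
    halo_weight: float = 0.0
    sigma_halo: float | None = None
    center: tuple[float, float] = (0.0, 0.0)
    energy_label: str = ""
    position_label: str = "Z0"

    def __post_init__(self) -> None:
        if not self.sigma_core > 0:
            raise InvalidParameterError(f"sigma_core must be > 0, got {self.sigma_core}")
        if not 0.0 <= self.halo_weight < 1.0:
            raise InvalidParameterError(f"halo_weight must be in [0, 1), got {self.halo_weight}")
        if self.halo_weight > 0:
            if self.sigma_halo is None or not self.sigma_halo > self.sigma_core:
                raise InvalidParameterError(
                    "sigma_halo must exceed sigma_core when halo_weight > 0 "
                    f"(got sigma_halo={self.sigma_halo}, sigma_core={self.sigma_core})"
                )

    @property
    def outer_sigma(self) -> float:
        """Width scale of the broadest component (drives grid sizing)."""
        return self.sigma_halo if self.halo_weight > 0 else self.sigma_core

    def intensity(self, x, y):
        """Relative intensity at mm coordinates ``(x, y)`` (vectorized)."""
        r2 = (np.asarray(x, dtype=float) - self.center[0]) ** 2 \
            + (np.asarray(y, dtype=float) - self.center[1]) ** 2
        core = np.exp(-r2 / (2.0 * self.sigma_core**2))
        if self.halo_weight == 0:
            return core
        halo = np.exp(-r2 / (2.0 * self.sigma_halo**2))
        return (1.0 - self.halo_weight) * core + self.halo_weight * halo

    def radial_intensity(self, r):
        """Relative intensity at radius ``r`` mm from the spot centre."""
        r = np.asarray(r, dtype=float)
        return self.intensity(self.center[0] + r, self.center[1])

    @classmethod
    def from_widths(cls, fwhm: float, fw10: float, fw1: float, **labels) -> "SpotModel":
        """Build the spot model whose radial profile matches measured widths.

        Solves for ``(sigma_core, halo_weight, sigma_halo)`` so the
        closed-form profile crosses 50%, 10% and 1% of its peak at the
        given full widths.  Width triplets with sub-Gaussian ratios
        (``fw10/fwhm < sqrt(ln 10 / ln 2)``) cannot be produced by a
        core-plus-broader-halo mixture; for those the model degrades to a
        single Gaussian matching the FWHM exactly.
        """
        if not (fw1 >= fw10 >= fwhm > 0):
            raise InvalidParameterError(
                f"widths must satisfy fw1 >= fw10 >= fwhm > 0, got {(fwhm, fw10, fw1)}"
            )
        radii = np.array([fwhm, fw10, fw1]) / 2.0
        log_levels = np.log(np.array([0.5, 0.1, 0.01]))

        def residuals(p):
            sc, w, sh = p
            prof = (1 - w) * np.exp(-radii**2 / (2 * sc**2)) \
                + w * np.exp(-radii**2 / (2 * sh**2))
            return np.log(prof) - log_levels

        best = None
        for w0 in (0.05, 0.15, 0.3, 0.5, 0.7):
            for sh0 in (fw1 / FW1_PER_SIGMA, fw1 / 4.0, fw1 / 3.0):
                fit = least_squares(
                    residuals,
                    [0.95 * fwhm / FWHM_PER_SIGMA, w0, sh0],
                    bounds=([0.1, 1e-6, 0.2], [30.0, 0.9, 120.0]),
                )
                if best is None or fit.cost < best.cost:
                    best = fit
        sc, w, sh = best.x
        if best.cost < 1e-10 and sh > sc * (1 + 1e-6):
            return cls(sigma_core=float(sc), halo_weight=float(w),
                       sigma_halo=float(sh), **labels)
        # sub-Gaussian triplet: single Gaussian pinned to the FWHM
        return cls(sigma_core=fwhm / FWHM_PER_SIGMA, halo_weight=0.0, **labels)


def default_spot_model(energy_mev: int, position: str = "Z0") -> SpotModel:
    """Default spot model for a beam energy/position, fitted to the film
    width table (FWHM/FW10%/FW1% at that energy and position)."""
    key = (int(energy_mev), position)
    if key not in FILM_WIDTHS_MM:
        raise InvalidParameterError(
            f"no default widths for {key}; energies {ENERGIES_MEV}, positions {POSITIONS}"
        )
    fwhm, fw10, fw1 = FILM_WIDTHS_MM[key]
    return SpotModel.from_widths(
        fwhm, fw10, fw1, energy_label=f"{energy_mev}MeV", position_label=position
    )


@dataclass(frozen=True)
class DeviceModel:
    """Parametric 2D dosimeter: dynamic-range clipping, multiplicative
    noise, and (scintillator panels only) a directional over-response."""

    kind: str  # "film" | "lynx" | "ideal"
    saturation_level: float
    first_shot_peak: float
    noise_fraction: float = DEFAULT_NOISE_FRACTION
    artifact_max_fraction: float = 0.0
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_MM

    def __post_init__(self) -> None:
        if self.kind not in ("film", "lynx", "ideal"):
            raise InvalidParameterError(f"unknown device kind {self.kind!r}")
        if not self.saturation_level > 0:
            raise InvalidParameterError("saturation_level must be > 0")
        if not 0.0 <= self.artifact_max_fraction <= 1.0:
            raise InvalidParameterError("artifact_max_fraction must be in [0, 1]")
        if self.noise_fraction < 0:
            raise InvalidParameterError("noise_fraction must be >= 0")
        if not self.pixel_pitch > 0:
            raise InvalidParameterError("pixel_pitch must be > 0")


def film_device(noise_fraction: float = DEFAULT_NOISE_FRACTION,
                pixel_pitch: float = DEFAULT_PIXEL_PITCH_MM) -> DeviceModel:
    """Radiochromic film: useful range 0.01-8 Gy, 6 Gy first-shot peak."""
    return DeviceModel("film", FILM_SATURATION_GY, FILM_FIRST_SHOT_PEAK_GY,
                       noise_fraction, 0.0, pixel_pitch)


def lynx_device(noise_fraction: float = DEFAULT_NOISE_FRACTION,
                artifact_max_fraction: float = LYNX_ARTIFACT_MAX_FRACTION,
                pixel_pitch: float = DEFAULT_PIXEL_PITCH_MM) -> DeviceModel:
    """Scintillator+CCD panel: 0-1000 counts, +y over-response artifact."""
    return DeviceModel("lynx", LYNX_SATURATION_COUNTS, LYNX_FIRST_SHOT_PEAK_COUNTS,
                       noise_fraction, artifact_max_fraction, pixel_pitch)


def ideal_device(pixel_pitch: float = DEFAULT_PIXEL_PITCH_MM) -> DeviceModel:
    """Noiseless device with unbounded dynamic range (for oracles)."""
    return DeviceModel("ideal", math.inf, 1.0, 0.0, 0.0, pixel_pitch)


@dataclass
class SpotImage:
    """One 2D intensity grid with its physical geometry and provenance."""

    values: np.ndarray
    pixel_pitch: float
    origin: tuple[float, float] = (0.0, 0.0)
    saturated_mask: np.ndarray | None = None
    magnification: float = 1.0
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidParameterError("values must be a 2D grid")
        if not self.pixel_pitch > 0:
            raise InvalidParameterError("pixel_pitch must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("values must be finite")
        if self.saturated_mask is None:
            self.saturated_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.saturated_mask = np.asarray(self.saturated_mask, dtype=bool)
        if self.saturated_mask.shape != self.values.shape:
            raise InvalidParameterError("saturated_mask shape must equal values shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """1D x (columns) and y (rows) pixel-centre coordinates in mm."""
        return grid_coords(self.shape, self.pixel_pitch, self.origin)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        x, y = self.coords()
        return np.meshgrid(x, y)


def grid_coords(shape: tuple[int, int], pixel_pitch: float,
                origin: tuple[float, float] = (0.0, 0.0)):
    """Pixel-centre coordinates of a grid centred on ``origin``."""
    ny, nx = shape
    x = (np.arange(nx) - nx / 2.0 + 0.5) * pixel_pitch + origin[0]
    y = (np.arange(ny) - ny / 2.0 + 0.5) * pixel_pitch + origin[1]
    return x, y


@dataclass
class ExposureSet:
    """Ordered exposures of one spot at increasing delivered-dose factors."""

    exposures: list
    magnifications: tuple
    device: DeviceModel
    seed: int

    def __post_init__(self) -> None:
        mags = tuple(float(m) for m in self.magnifications)
        if len(mags) == 0 or len(mags) != len(self.exposures):
            raise InvalidParameterError("one magnification per exposure required")
        if mags[0] != 1.0:
            raise InvalidParameterError("first magnification must be 1")
        if any(b <= a for a, b in zip(mags, mags[1:])):
            raise InvalidParameterError(f"magnifications must be strictly increasing: {mags}")
        shapes = {e.shape for e in self.exposures}
        pitches = {e.pixel_pitch for e in self.exposures}
        if len(shapes) != 1 or len(pitches) != 1:
            raise InvalidParameterError("all exposures must share grid shape and pixel pitch")
        self.magnifications = mags

    @property
    def pixel_pitch(self) -> float:
        return self.exposures[0].pixel_pitch


# ---------------------------------------------------------------------------
# rendering operations
# ---------------------------------------------------------------------------

def make_truth_image(model: SpotModel, grid_half_width: float,
                     pixel_pitch: float = DEFAULT_PIXEL_PITCH_MM) -> SpotImage:
    """Render the noise-free spot model onto a pixel grid.

    The grid must extend at least five outer sigmas from the centre so the
    halo tail is contained; smaller requests are rejected rather than
    silently truncated.
    """
    if not pixel_pitch > 0:
        raise InvalidParameterError("pixel_pitch must be > 0")
    required = 5.0 * model.outer_sigma
    if grid_half_width < required:
        raise DomainError(
            f"grid_half_width {grid_half_width} mm too small; "
            f"need at least {required} mm (5 x outer sigma)"
        )
    n = 2 * int(math.ceil(grid_half_width / pixel_pitch))
    x, y = grid_coords((n, n), pixel_pitch)
    xx, yy = np.meshgrid(x, y)
    values = model.intensity(xx, yy)
    labels = {"energy": model.energy_label, "position": model.position_label,
              "device": "truth"}
    return SpotImage(values, pixel_pitch, magnification=1.0, labels=labels)


def apply_lynx_artifact(image: SpotImage, max_fraction: float) -> SpotImage:
    """Apply the scintillator-panel over-response to the +y half plane.

    Pixels with y > 0 are boosted by a factor ramping from 1 (at or above
    10% of the image peak) to ``1 + max_fraction`` (at or below 1% of the
    peak), linearly in log10 of the local relative intensity.  The ramp
    shape between the two anchors is a modelling choice; the direction,
    ceiling and low-dose onset are the device's documented behaviour.
    """
    if not 0.0 <= max_fraction <= 1.0:
        raise InvalidParameterError("max_fraction must be in [0, 1]")
    peak = float(image.values.max())
    if max_fraction == 0.0 or peak <= 0.0:
        return replace(image, values=image.values.copy(),
                       saturated_mask=image.saturated_mask.copy())
    rel = image.values / peak
    with np.errstate(divide="ignore"):
        t = np.clip(-1.0 - np.log10(np.where(rel > 0, rel, np.nan)), 0.0, 1.0)
    t = np.where(np.isnan(t), 1.0, t)  # zero-intensity pixels: full ramp, no-op
    factor = 1.0 + max_fraction * t
    _, y = image.coords()
    boosted = np.where(y[:, None] > 0, image.values * factor, image.values)
    return replace(image, values=boosted, saturated_mask=image.saturated_mask.copy())


def render_exposure(truth: SpotImage, magnification: float, device: DeviceModel,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None) -> SpotImage:
    """Expose the device to ``magnification`` times the base delivery.

    The truth grid is scaled so the 1x exposure peaks at the device's
    first-shot level, the directional artifact is applied (scintillator
    panels), multiplicative Gaussian noise is drawn from the seeded
    generator, and finally values above the saturation level are clamped
    and flagged.
    """
    if not magnification > 0:
        raise InvalidParameterError("magnification must be > 0")
    peak = float(truth.values.max())
    # ideal devices record the truth as-is; real ones expose the 1x shot
    # to their first-shot level (6 Gy film, 800 counts panel)
    scale = 1.0 if device.kind == "ideal" or peak <= 0 \
        else device.first_shot_peak / peak
    image = replace(
        truth,
        values=truth.values * (magnification * scale),
        saturated_mask=np.zeros(truth.shape, dtype=bool),
        magnification=magnification,
        labels={**truth.labels, "device": device.kind},
    )
    if device.kind == "lynx" and device.artifact_max_fraction > 0:
        image = apply_lynx_artifact(image, device.artifact_max_fraction)
    values = image.values
    if device.noise_fraction > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        values = values * (1.0 + device.noise_fraction * rng.standard_normal(values.shape))
        values = np.maximum(values, 0.0)
    saturated = values > device.saturation_level
    values = np.where(saturated, device.saturation_level, values)
    return replace(image, values=values, saturated_mask=saturated)


def make_exposure_set(model: SpotModel | None = None,
                      magnifications=DEFAULT_MAGNIFICATIONS,
                      device: DeviceModel | None = None,
                      seed: int = 0,
                      truth: SpotImage | None = None,
                      grid_half_width: float | None = None,
                      pixel_pitch: float | None = None) -> ExposureSet:
    """Generate a full magnification series for one spot.

    Either ``model`` or a pre-rendered ``truth`` image must be given.  Each
    exposure draws its noise from an independent child of the seed, so a
    fixed seed reproduces the set bit for bit.
    """
    mags = tuple(float(m) for m in magnifications)
    if len(mags) == 0 or mags[0] != 1.0 or any(b <= a for a, b in zip(mags, mags[1:])):
        raise InvalidParameterError(
            f"magnifications must be strictly increasing and start at 1: {mags}"
        )
    if device is None:
        device = film_device()
    if truth is None:
        if model is None:
            raise InvalidParameterError("either model or truth must be provided")
        pitch = pixel_pitch if pixel_pitch is not None else device.pixel_pitch
        half = grid_half_width if grid_half_width is not None else 5.0 * model.outer_sigma
        truth = make_truth_image(model, half, pitch)
    child_seeds = np.random.SeedSequence(seed).spawn(len(mags))
    exposures = []
    for mag, child in zip(mags, child_seeds):
        rng = np.random.default_rng(child)
        exposures.append(render_exposure(truth, mag, device, rng=rng))
    n_sat = [int(e.saturated_mask.sum()) for e in exposures]
    logger.info("exposure set seed=%s device=%s saturated pixels per level: %s",
                seed, device.kind, n_sat)
    return ExposureSet(exposures, mags, device, seed)
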