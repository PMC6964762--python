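"""Field size factors by spot superposition.

A uniformly scanned square field is the sum of identical spots on a
2.5 mm lattice; the central dose therefore inherits the spot's tails: the
broader the halo, the more of a small field's dose leaks outside it, and
the lower its output relative to the 10 cm normalization field.  This
module evaluates that lattice sum for analytic (single/double Gaussian)
kernels and for measured composite profiles, with an optional disc
average emulating an ion chamber's finite volume, and builds percent
error tables of one FSF curve against a reference.

For a single-Gaussian kernel the fine-spacing limit of the lattice sum is
closed form: FSF(L) = erf(L / (2 sqrt(2) sigma))^2 normalized at the
reference side, which serves as an independent oracle for the lattice
computation.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.special import erf

from .pairmag import CompositeProfile
from .exceptions import AlignmentError, InvalidParameterError
from .radial import find_center
from .synthetic import SpotModel

logger = logging.getLogger("pbshalo")

DEFAULT_SIDE_LENGTHS_MM = (20.0, 32.0, 40.0, 60.0, 100.0, 140.0, 200.0)
DEFAULT_SPOT_SPACING_MM = 2.5
DEFAULT_NORMALIZATION_SIDE_MM = 100.0
DEFAULT_AVERAGING_RADIUS_MM = 2.0


class SpotKernel:
    """Relative spot intensity evaluable at any (x, y) mm displacement.

    Wraps either an analytic spot model (closed form) or a composite grid
    (bilinear interpolation about the measured peak, zero outside the
    grid).  The kernel is normalized to 1 at its centre.
    """

    def __init__(self, evaluate_fn, support_radius: float, label: str = "kernel"):
        self._evaluate = evaluate_fn
        self.support_radius = float(support_radius)
        self.label = label

    @classmethod
    def from_model(cls, model: SpotModel) -> "SpotKernel":
        support = math.inf  # closed form: no grid edge, no truncation

        def evaluate(x, y):
            return model.intensity(np.asarray(x) + model.center[0],
                                   np.asarray(y) + model.center[1])

        kind = "double-gaussian" if model.halo_weight > 0 else "gaussian"
        return cls(evaluate, support, kind)

    @classmethod
    def from_composite(cls, composite: CompositeProfile) -> "SpotKernel":
        center = find_center(composite)
        x, y = composite.coords()
        values = np.where(composite.valid_mask, composite.values, 0.0)
        interp = RegularGridInterpolator((y, x), values, method="linear",
                                         bounds_error=False, fill_value=0.0)
        peak = float(interp((center[1], center[0])))
        if peak <= 0:
            raise InvalidParameterError("composite kernel has non-positive peak")
        support = min(x.max() - center[0], center[0] - x.min(),
                      y.max() - center[1], center[1] - y.min())

        def evaluate(xq, yq):
            xq = np.asarray(xq, dtype=float)
            yq = np.asarray(yq, dtype=float)
            pts = np.stack([yq + center[1], xq + center[0]], axis=-1)
            return interp(pts) / peak

        return cls(evaluate, support, composite.labels.get("device", "composite"))

    def __call__(self, x, y):
        return np.clip(self._evaluate(x, y), 0.0, None)


class ScanPlan:
    """Square-field scan description: side lengths, spot spacing and the
    normalization field."""

    def __init__(self, side_lengths=DEFAULT_SIDE_LENGTHS_MM,
                 spot_spacing: float = DEFAULT_SPOT_SPACING_MM,
                 normalization_side: float = DEFAULT_NORMALIZATION_SIDE_MM):
        self.side_lengths = tuple(float(s) for s in side_lengths)
        self.spot_spacing = float(spot_spacing)
        self.normalization_side = float(normalization_side)
        if not self.spot_spacing > 0:
            raise InvalidParameterError("spot_spacing must be > 0")
        if any(s <= 0 for s in self.side_lengths):
            raise InvalidParameterError("side lengths must be > 0")
        if self.normalization_side not in self.side_lengths:
            raise InvalidParameterError(
                f"normalization_side {self.normalization_side} not among side lengths"
            )


def spot_positions(side: float, spacing: float = DEFAULT_SPOT_SPACING_MM) -> np.ndarray:
    """Square spot lattice centred on the origin, shape (n_spots, 2) in mm.

    The lattice uses ``round(side / spacing)`` intervals per axis, so the
    delivered side is that count times the spacing; with an even interval
    count a spot sits exactly at the field centre.
    """
    if not (side > 0 and spacing > 0):
        raise InvalidParameterError("side and spacing must be > 0")
    n = int(math.floor(side / spacing + 0.5))
    coords = (np.arange(n + 1) - n / 2.0) * spacing
    xx, yy = np.meshgrid(coords, coords)
    return np.column_stack([xx.ravel(), yy.ravel()])


def delivered_side(side: float, spacing: float = DEFAULT_SPOT_SPACING_MM) -> float:
    """Side length actually spanned by the lattice for a nominal side."""
    return int(math.floor(side / spacing + 0.5)) * spacing


def effective_side(side: float, spacing: float = DEFAULT_SPOT_SPACING_MM) -> float:
    """Continuum-equivalent side of the delivered lattice.

    A lattice of n+1 spots spanning the delivered side is the midpoint
    quadrature of a uniform fluence one spacing wider (each spot carries a
    spacing-sized cell centred on it), so the closed-form oracle must be
    evaluated at ``delivered_side + spacing`` to match the lattice sum.
    """
    return delivered_side(side, spacing) + spacing


def _disc_samples(radius: float, n_per_radius: int = 6) -> np.ndarray:
    """Deterministic uniform Cartesian sampling of a disc (includes centre)."""
    step = radius / n_per_radius
    offs = np.arange(-n_per_radius, n_per_radius + 1) * step
    xx, yy = np.meshgrid(offs, offs)
    keep = xx**2 + yy**2 <= radius**2 + 1e-12
    return np.column_stack([xx[keep], yy[keep]])


def central_dose(kernel: SpotKernel, positions: np.ndarray,
                 averaging_radius: float | None = None,
                 eval_point: tuple[float, float] = (0.0, 0.0)) -> float:
    """Relative dose at the field centre from superposing one kernel per spot.

    With ``averaging_radius`` set, the point value is replaced by the mean
    over a uniformly sampled disc of that radius (an in-plane surrogate
    for an ion chamber's volume average).
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise InvalidParameterError("positions must be non-empty")
    if averaging_radius is None:
        samples = np.array([[0.0, 0.0]])
    else:
        if not averaging_radius > 0:
            raise InvalidParameterError("averaging_radius must be > 0")
        samples = _disc_samples(averaging_radius)
    samples = samples + np.asarray(eval_point, dtype=float)

    dist = np.linalg.norm(positions - np.asarray(eval_point), axis=1)
    if np.all(dist > kernel.support_radius):
        warnings.warn("field centre lies outside the kernel support for every spot; "
                      "central dose is zero", stacklevel=2)

    dx = samples[:, None, 0] - positions[None, :, 0]
    dy = samples[:, None, 1] - positions[None, :, 1]
    doses = kernel(dx, dy).sum(axis=1)
    return float(doses.mean())


def fsf_curve(kernel: SpotKernel, plan: ScanPlan | None = None,
              averaging_radius: float | None = None) -> pd.DataFrame:
    """Field size factor per side length, normalized to the reference field.

    Returns a table with columns ``side_mm``, ``delivered_side_mm`` and
    ``fsf``; the normalization side has FSF exactly 1.
    """
    if plan is None:
        plan = ScanPlan()
    doses = {}
    for side in set(plan.side_lengths) | {plan.normalization_side}:
        positions = spot_positions(side, plan.spot_spacing)
        doses[side] = central_dose(kernel, positions, averaging_radius)
    norm = doses[plan.normalization_side]
    if norm <= 0:
        raise InvalidParameterError("normalization-field central dose is non-positive")
    if delivered_side(max(plan.side_lengths), plan.spot_spacing) / 2.0 > kernel.support_radius:
        logger.warning("largest field extends beyond the kernel support radius "
                       "(%.1f mm); far-tail contributions are truncated",
                       kernel.support_radius)
    rows = [{"side_mm": s,
             "delivered_side_mm": delivered_side(s, plan.spot_spacing),
             "fsf": 1.0 if s == plan.normalization_side else doses[s] / norm}
            for s in plan.side_lengths]
    return pd.DataFrame(rows)


def gaussian_fsf_closed_form(sigma: float, side: float,
                             normalization_side: float = DEFAULT_NORMALIZATION_SIDE_MM) -> float:
    """Fine-spacing limit of the lattice FSF for a single-Gaussian kernel:
    erf(L / (2 sqrt(2) sigma))^2 ratio between field and reference."""
    if not sigma > 0:
        raise InvalidParameterError("sigma must be > 0")
    num = erf(side / (2.0 * math.sqrt(2.0) * sigma)) ** 2
    den = erf(normalization_side / (2.0 * math.sqrt(2.0) * sigma)) ** 2
    return float(num / den)


def percent_error_table(model: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Per-side percent error of one FSF table against a reference.

    Both tables need ``side_mm`` and ``fsf`` columns over the same sides;
    the result appends an arithmetic-mean row.
    """
    m = model.set_index("side_mm")["fsf"]
    r = reference.set_index("side_mm")["fsf"]
    if set(m.index) != set(r.index):
        raise AlignmentError(f"side sets differ: {sorted(m.index)} vs {sorted(r.index)}")
    r = r.reindex(m.index)
    err = (m - r) / r * 100.0
    table = pd.DataFrame({"fsf": m, "reference": r, "percent_error": err})
    mean = pd.DataFrame({"fsf": [math.nan], "reference": [math.nan],
                         "percent_error": [err.mean()]}, index=["Mean"])
    table.index.name = "side_mm"
    return pd.concat([table, mean])
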