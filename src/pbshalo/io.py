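"""File formats, run configuration and the end-to-end pipeline driver.

Spot images travel as 32-bit float TIFF (geometry in a JSON image
description, saturation mask in an 8-bit sidecar ``*_mask.tif``) or as a
plain CSV grid with ``pixel_pitch_mm`` / ``origin_x_mm`` / ``origin_y_mm``
header lines.  ``run_pipeline`` ties the stages together: simulate
exposure sets per (energy, position, device), composite them, extract
radially averaged widths, build device-comparison tables and FSF /
percent-error tables, and record a manifest with the seed and per-file
checksums so a bundle is regenerable from the configuration alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import pairmag
from . import fsf as fsf_mod
from . import radial as radial_mod
from . import synthetic
from .exceptions import FormatError, InvalidParameterError, PbsHaloError
from .synthetic import DeviceModel, SpotImage

logger = logging.getLogger("pbshalo")

CSV_HEADER_FIELDS = ("pixel_pitch_mm", "origin_x_mm", "origin_y_mm")
CSV_FLOAT_FORMAT = "%.9g"  # 9 significant digits: printed values round-trip


# ---------------------------------------------------------------------------
# image readers / writers
# ---------------------------------------------------------------------------

def _mask_path(path: Path) -> Path:
    return path.with_name(path.stem + "_mask" + path.suffix)


def write_image(image, path) -> Path:
    """Write a spot image (or composite) as float TIFF or CSV grid.

    The format is chosen from the suffix (.tif/.tiff or .csv).  A mask
    sidecar (saturated pixels for exposures, invalid pixels for
    composites) is written alongside as ``<stem>_mask<suffix>``.
    """
    path = Path(path)
    values = np.asarray(image.values, dtype=np.float32)
    origin = tuple(getattr(image, "origin", (0.0, 0.0)))
    mask = getattr(image, "saturated_mask", None)
    if mask is None:
        valid = getattr(image, "valid_mask", None)
        mask = ~valid if valid is not None else np.zeros(values.shape, dtype=bool)
    meta = {
        "pixel_pitch_mm": float(image.pixel_pitch),
        "origin_x_mm": float(origin[0]),
        "origin_y_mm": float(origin[1]),
        "magnification": float(getattr(image, "magnification", 1.0)),
        "labels": dict(getattr(image, "labels", {})),
    }
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, values, description=json.dumps(meta))
        tifffile.imwrite(_mask_path(path), mask.astype(np.uint8))
    elif path.suffix.lower() == ".csv":
        with open(path, "w") as fh:
            for key in ("pixel_pitch_mm", "origin_x_mm", "origin_y_mm", "magnification"):
                fh.write(f"# {key},{CSV_FLOAT_FORMAT % meta[key]}\n")
            np.savetxt(fh, values, fmt=CSV_FLOAT_FORMAT, delimiter=",")
        np.savetxt(_mask_path(path), mask.astype(np.uint8), fmt="%d", delimiter=",")
    else:
        raise FormatError(f"unsupported image format {path.suffix!r}")
    return path


def read_image(path) -> SpotImage:
    """Read a spot image written by :func:`write_image`; restores pixel
    pitch, origin, magnification, labels and the saturation mask."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tif:
            values = tif.asarray().astype(float)
            desc = tif.pages[0].tags.get("ImageDescription")
            if desc is None:
                raise FormatError("TIFF missing metadata description")
            try:
                meta = json.loads(desc.value)
            except (TypeError, json.JSONDecodeError) as exc:
                raise FormatError("TIFF metadata is not valid JSON") from exc
    elif path.suffix.lower() == ".csv":
        meta = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line.lstrip("# ").partition(",")
                    meta[key.strip()] = float(val)
                else:
                    rows.append([float(v) for v in line.split(",")])
        values = np.asarray(rows, dtype=float)
    else:
        raise FormatError(f"unsupported image format {path.suffix!r}")
    for key in CSV_HEADER_FIELDS:
        if key not in meta:
            raise FormatError(f"missing required metadata field {key!r} in {path.name}")
    mask = None
    mpath = _mask_path(path)
    if mpath.exists():
        if mpath.suffix.lower() == ".csv":
            mask = np.loadtxt(mpath, delimiter=",", dtype=int).astype(bool)
        else:
            mask = tifffile.imread(mpath).astype(bool)
    return SpotImage(
        values=values,
        pixel_pitch=float(meta["pixel_pitch_mm"]),
        origin=(float(meta["origin_x_mm"]), float(meta["origin_y_mm"])),
        saturated_mask=mask,
        magnification=float(meta.get("magnification", 1.0)),
        labels=dict(meta.get("labels", {})),
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to regenerate a pipeline bundle."""

    energies: tuple = (70,)
    positions: tuple = ("Z0",)
    devices: tuple = ("film", "lynx")
    magnifications: tuple = synthetic.DEFAULT_MAGNIFICATIONS
    device_params: dict = field(default_factory=dict)
    pixel_pitch: float = synthetic.DEFAULT_PIXEL_PITCH_MM
    side_lengths: tuple = fsf_mod.DEFAULT_SIDE_LENGTHS_MM
    spot_spacing: float = fsf_mod.DEFAULT_SPOT_SPACING_MM
    normalization_side: float = fsf_mod.DEFAULT_NORMALIZATION_SIDE_MM
    averaging_radius: float | None = None
    seed: int = 0
    output_dir: str = "pbshalo_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        for key in ("energies", "positions", "devices", "magnifications", "side_lengths"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = {}
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            out[name] = list(value) if isinstance(value, tuple) else value
        return out

    def device_model(self, kind: str) -> DeviceModel:
        params = dict(self.device_params.get(kind, {}))
        params.setdefault("pixel_pitch", self.pixel_pitch)
        if kind == "film":
            return synthetic.film_device(**params)
        if kind == "lynx":
            return synthetic.lynx_device(**params)
        if kind == "ideal":
            params.pop("noise_fraction", None)
            return synthetic.ideal_device(**params)
        raise InvalidParameterError(f"unknown device kind {kind!r}")


def _stage_seed(base_seed: int, *labels) -> int:
    """Deterministic per-stage seed below 2^31 derived from the run seed."""
    digest = hashlib.sha256(repr((base_seed,) + labels).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> compose -> analyze -> fsf -> report for a config.

    Returns a bundle dict with the width table, comparison tables, FSF
    tables and the manifest; all artifacts are also written under
    ``config.output_dir``.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    width_rows = []
    composites = {}
    files = []

    for energy in config.energies:
        for position in config.positions:
            stage = f"simulate {energy} MeV {position}"
            try:
                model = synthetic.default_spot_model(energy, position)
                truth = synthetic.make_truth_image(
                    model, 5.0 * model.outer_sigma, config.pixel_pitch)
            except PbsHaloError as exc:
                raise PbsHaloError(f"stage '{stage}' failed: {exc}") from exc
            for kind in config.devices:
                case = f"{energy}MeV_{position}_{kind}"
                case_dir = out_dir / case
                case_dir.mkdir(exist_ok=True)
                try:
                    device = config.device_model(kind)
                    exposures = synthetic.make_exposure_set(
                        magnifications=config.magnifications, device=device,
                        seed=_stage_seed(config.seed, energy, position, kind),
                        truth=truth)
                    offsets = pairmag.register_exposures(exposures)
                    comp = pairmag.compose(exposures, offsets)
                    interval = radial_mod.LYNX_MASK_DEG if kind == "lynx" \
                        else radial_mod.FULL_CIRCLE_DEG
                    center = radial_mod.find_center(comp)
                    profile = radial_mod.to_radial(comp, center, interval)
                    widths = radial_mod.summarize_widths(profile)
                except PbsHaloError as exc:
                    raise PbsHaloError(
                        f"stage 'analyze {case}' failed: {exc}") from exc
                composites[(energy, position, kind)] = comp
                width_rows.append({"energy": energy, "position": position,
                                   "device": kind, **widths})
                files.append(write_image(comp, case_dir / "composite.tif"))
                files.append(_mask_path(case_dir / "composite.tif"))
                prof_df = pd.DataFrame({
                    "radius_mm": profile.bin_radii,
                    "mean_intensity_rel": profile.mean_intensity,
                    "pixel_count": profile.pixel_counts,
                })
                prof_path = case_dir / "radial_profile.csv"
                prof_df.to_csv(prof_path, index=False, float_format=CSV_FLOAT_FORMAT)
                files.append(prof_path)
                logger.info("%s: dynamic range %.3g, widths %s",
                            case, pairmag.dynamic_range(comp), widths)

    widths_df = radial_mod.width_table(width_rows)
    widths_path = out_dir / "widths.csv"
    widths_df.to_csv(widths_path, index=False, float_format=CSV_FLOAT_FORMAT)
    files.append(widths_path)

    comparisons = {}
    if {"film", "lynx"} <= set(config.devices):
        for position in config.positions:
            sub = widths_df[widths_df["position"] == position]
            film = sub[sub["device"] == "film"]
            lynx = sub[sub["device"] == "lynx"]
            for metric in ("fwhm", "fw10", "fw1"):
                table = radial_mod.compare_devices(
                    film, lynx, metric, names=("film", "lynx"))
                comparisons[(position, metric)] = table
                cmp_path = out_dir / f"compare_{metric}_{position}.csv"
                table.to_csv(cmp_path, float_format=CSV_FLOAT_FORMAT)
                files.append(cmp_path)

    # FSF stage: halo kernel from the first composite of the first device,
    # single-Gaussian surrogate from the same measurement's FWHM.
    fsf_tables = {}
    first_key = (config.energies[0], config.positions[0], config.devices[0])
    if first_key in composites:
        plan = fsf_mod.ScanPlan(config.side_lengths, config.spot_spacing,
                                config.normalization_side)
        comp = composites[first_key]
        interval = radial_mod.LYNX_MASK_DEG if first_key[2] == "lynx" \
            else radial_mod.FULL_CIRCLE_DEG
        profile = radial_mod.to_radial(comp, None, interval)
        sigma = radial_mod.sigma_from_fwhm(radial_mod.width_at_fraction(profile, 0.5))
        halo_kernel = fsf_mod.SpotKernel.from_composite(comp)
        gauss_kernel = fsf_mod.SpotKernel.from_model(synthetic.SpotModel(sigma))
        halo_fsf = fsf_mod.fsf_curve(halo_kernel, plan, config.averaging_radius)
        gauss_fsf = fsf_mod.fsf_curve(gauss_kernel, plan, config.averaging_radius)
        errors = fsf_mod.percent_error_table(gauss_fsf, halo_fsf)
        fsf_tables = {"halo": halo_fsf, "gaussian": gauss_fsf,
                      "gaussian_vs_halo_percent_error": errors}
        for name, table in fsf_tables.items():
            fsf_path = out_dir / f"fsf_{name}.csv"
            table.to_csv(fsf_path, float_format=CSV_FLOAT_FORMAT,
                         index=name.endswith("percent_error"))
            files.append(fsf_path)

    manifest = {
        "package": "pbshalo",
        "version": __import__("pbshalo").__version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "checksums": {str(p.relative_to(out_dir)): _sha256(p) for p in files},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {"widths": widths_df, "comparisons": comparisons, "fsf": fsf_tables,
            "composites": composites, "manifest": manifest,
            "output_dir": out_dir}
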