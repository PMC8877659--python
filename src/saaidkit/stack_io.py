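"""Reading and writing two-channel depth stacks and caliper measurement tables.

A stack holds a pair of co-registered intensity volumes — second harmonic
generation (SHG, mostly fibrillar type I collagen) and two-photon
autofluorescence (AF, mostly elastin) — indexed by physical depth below the
skin surface. Two on-disk TIFF dialects are supported and must be declared
explicitly by the caller (no layout guessing):

``two_file``
    one single-channel multi-page TIFF per channel, pages ordered by depth;
``interleaved``
    a single multi-page TIFF with alternating SHG/AF pages, SHG first.

The depth axis is always carried explicitly: either from a JSON sidecar
written next to the TIFF, or from a declared (start, step) grid. Intensities
stay in native detector units; 8/16-bit integer and floating-point rasters
are accepted, negative or non-finite pixels are rejected.

Caliper wound measurements are plain CSV with columns
``animal, group, day, A_mm, B_mm`` (major and minor wound diameters in mm).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "TwoChannelStack",
    "RunConfig",
    "DEFAULT_PIXEL_SIZE_UM",
    "read_stack",
    "write_stack",
    "write_rgb_preview",
    "read_measurements",
    "validate_measurements",
    "write_measurements",
    "load_run_config",
]

#: Lateral pixel size of a 512-pixel raster spanning a 70 um field of view.
DEFAULT_PIXEL_SIZE_UM = 70.0 / 512.0

_LAYOUTS = ("two_file", "interleaved")


@dataclass
class TwoChannelStack:
    """Depth-indexed SHG/AF image pair with physical calibration.

    Parameters
    ----------
    shg, af
        3-D arrays ``(depth, rows, cols)`` of non-negative finite
        intensities in native detector units.
    depths_um
        Strictly increasing physical depths in micrometres, one per page;
        depth 0 is the top of the stratum corneum.
    pixel_size_um
        Lateral pixel size (metadata only; no index math depends on it).
    meta
        Free-form acquisition metadata (animal id, group label, day, ...).
    """

    shg: np.ndarray
    af: np.ndarray
    depths_um: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shg = np.asarray(self.shg, dtype=float)
        self.af = np.asarray(self.af, dtype=float)
        self.depths_um = np.asarray(self.depths_um, dtype=float)
        if self.shg.ndim != 3 or self.af.ndim != 3:
            raise ValueError("channel arrays must be 3-D (depth, rows, cols)")
        if self.shg.shape != self.af.shape:
            raise ValueError(
                f"channel shapes differ: SHG {self.shg.shape} vs AF {self.af.shape}"
            )
        if self.depths_um.ndim != 1 or len(self.depths_um) != self.shg.shape[0]:
            raise ValueError("depths_um length must equal the number of pages")
        if np.any(self.depths_um < 0) or np.any(np.diff(self.depths_um) <= 0):
            raise ValueError("depths_um must be non-negative and strictly increasing")
        for name, arr in (("SHG", self.shg), ("AF", self.af)):
            bad = ~np.isfinite(arr) | (arr < 0)
            if np.any(bad):
                page = int(np.argwhere(bad.any(axis=(1, 2)))[0, 0])
                raise ValueError(
                    f"{name} page {page} contains negative or non-finite pixels"
                )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_depths(self) -> int:
        return self.shg.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.shg.shape[1:]  # type: ignore[return-value]

    def scaled(self, shg_gain: float = 1.0, af_gain: float = 1.0) -> "TwoChannelStack":
        """Return a copy with per-channel gain factors applied."""
        if shg_gain <= 0 or af_gain <= 0:
            raise ValueError("gain factors must be positive")
        return TwoChannelStack(
            self.shg * shg_gain,
            self.af * af_gain,
            self.depths_um.copy(),
            self.pixel_size_um,
            dict(self.meta),
        )


@dataclass(frozen=True)
class RunConfig:
    """Run-level acquisition conventions shared across a dataset."""

    layout: str = "two_file"
    depth_start_um: float = 0.0
    depth_step_um: float = 4.0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.layout not in _LAYOUTS:
            raise ValueError(f"layout must be one of {_LAYOUTS}, got {self.layout!r}")
        if self.depth_step_um <= 0:
            raise ValueError("depth_step_um must be positive")


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration (layout, depth grid, pixel size, groups)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    groups = tuple(raw.pop("groups", ()))
    return RunConfig(groups=groups, **raw)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _check_pages(pages: np.ndarray, source: Path) -> np.ndarray:
    pages = np.asarray(pages, dtype=float)
    if pages.ndim == 2:
        pages = pages[None]
    for i, page in enumerate(pages):
        if not np.all(np.isfinite(page)) or np.any(page < 0):
            raise ValueError(
                f"{source}: page {i} contains negative or non-finite pixels"
            )
    return pages


def read_stack(
    path: str | Path | Sequence[str | Path],
    layout: str,
    *,
    depth_start_um: float = 0.0,
    depth_step_um: float = 4.0,
    pixel_size_um: float | None = None,
    meta: dict | None = None,
) -> TwoChannelStack:
    """Read a two-channel stack in a declared TIFF layout.

    For ``two_file`` pass a ``(shg_path, af_path)`` pair; for ``interleaved``
    a single path whose pages alternate SHG/AF with SHG first. Depths come
    from the JSON sidecar written by :func:`write_stack` when present,
    otherwise from the declared ``(depth_start_um, depth_step_um)`` grid.
    """
    if layout not in _LAYOUTS:
        raise ValueError(f"layout must be one of {_LAYOUTS}, got {layout!r}")

    if layout == "two_file":
        if isinstance(path, (str, Path)):
            raise ValueError("two_file layout needs a (shg_path, af_path) pair")
        shg_path, af_path = (Path(p) for p in path)
        for p in (shg_path, af_path):
            if not p.exists():
                raise FileNotFoundError(p)
        shg = _check_pages(tifffile.imread(shg_path), shg_path)
        af = _check_pages(tifffile.imread(af_path), af_path)
        if shg.shape != af.shape:
            raise ValueError(
                f"channel shapes differ: {shg_path} {shg.shape} vs {af_path} {af.shape}"
            )
        sidecar = _sidecar_path(shg_path)
    else:
        if not isinstance(path, (str, Path)):
            raise ValueError("interleaved layout takes a single path")
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(p)
        pages = _check_pages(tifffile.imread(p), p)
        if pages.shape[0] % 2:
            raise ValueError(
                f"{p}: interleaved layout needs an even page count, got {pages.shape[0]}"
            )
        shg, af = pages[0::2], pages[1::2]
        sidecar = _sidecar_path(p)

    side = {}
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
    n = shg.shape[0]
    if "depths_um" in side:
        depths = np.asarray(side["depths_um"], dtype=float)
    else:
        depths = depth_start_um + depth_step_um * np.arange(n)
    px = pixel_size_um if pixel_size_um is not None else side.get(
        "pixel_size_um", DEFAULT_PIXEL_SIZE_UM
    )
    full_meta = dict(side.get("meta", {}))
    if meta:
        full_meta.update(meta)
    return TwoChannelStack(shg, af, depths, px, full_meta)


def write_stack(
    stack: TwoChannelStack,
    path: str | Path | Sequence[str | Path],
    layout: str,
) -> None:
    """Write a stack in the requested layout plus a JSON depth/metadata sidecar."""
    if layout not in _LAYOUTS:
        raise ValueError(f"layout must be one of {_LAYOUTS}, got {layout!r}")
    sidecar_payload = json.dumps(
        {
            "depths_um": stack.depths_um.tolist(),
            "pixel_size_um": stack.pixel_size_um,
            "meta": stack.meta,
        },
        sort_keys=True,
    )
    if layout == "two_file":
        if isinstance(path, (str, Path)):
            raise ValueError("two_file layout needs a (shg_path, af_path) pair")
        shg_path, af_path = (Path(p) for p in path)
        tifffile.imwrite(shg_path, stack.shg, photometric="minisblack")
        tifffile.imwrite(af_path, stack.af, photometric="minisblack")
        _sidecar_path(shg_path).write_text(sidecar_payload)
    else:
        p = Path(path)
        pages = np.empty((2 * stack.n_depths, *stack.frame_shape), dtype=stack.shg.dtype)
        pages[0::2] = stack.shg
        pages[1::2] = stack.af
        tifffile.imwrite(p, pages, photometric="minisblack")
        _sidecar_path(p).write_text(sidecar_payload)


def write_rgb_preview(
    stack: TwoChannelStack, depth_index: int, path: str | Path
) -> None:
    """Write an 8-bit RGB PNG of one depth: SHG in red, AF in green, blue zero.

    Each channel is max-normalised independently (an all-zero channel stays
    zero); the output is deterministic for identical input stacks.
    """
    if not 0 <= depth_index < stack.n_depths:
        raise IndexError(
            f"depth_index {depth_index} out of range for {stack.n_depths} pages"
        )
    rgb = np.zeros((*stack.frame_shape, 3), dtype=np.uint8)
    for chan, img in enumerate((stack.shg[depth_index], stack.af[depth_index])):
        peak = img.max()
        if peak > 0:
            rgb[..., chan] = np.round(img / peak * 255).astype(np.uint8)
    iio.imwrite(Path(path), rgb, extension=".png")


_MEASUREMENT_COLUMNS = ["animal", "group", "day", "A_mm", "B_mm"]


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Validate (and normalise) a caliper measurement table.

    Enforces positive numeric diameters, integer non-negative days, the
    major/minor ordering ``A >= B`` (swapping with a warning when violated),
    and uniqueness of ``(animal, day)`` within each group.
    """
    missing = [c for c in _MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    df = df.loc[:, _MEASUREMENT_COLUMNS].copy()
    for col in ("day", "A_mm", "B_mm"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if np.any(df["day"] < 0) or np.any(df["day"] % 1 != 0):
        raise ValueError("day must be a non-negative integer")
    df["day"] = df["day"].astype(int)
    if np.any(df[["A_mm", "B_mm"]] <= 0) or not np.all(
        np.isfinite(df[["A_mm", "B_mm"]])
    ):
        raise ValueError("diameters must be positive and finite")
    swapped = df["B_mm"] > df["A_mm"]
    if swapped.any():
        rows = df.index[swapped].tolist()
        warnings.warn(
            f"B > A in rows {rows}; swapping to enforce major/minor ordering",
            stacklevel=2,
        )
        a = df.loc[swapped, "B_mm"].to_numpy()
        b = df.loc[swapped, "A_mm"].to_numpy()
        df.loc[swapped, "A_mm"] = a
        df.loc[swapped, "B_mm"] = b
    dupes = df.duplicated(subset=["group", "animal", "day"], keep=False)
    if dupes.any():
        first = df.loc[dupes, ["group", "animal", "day"]].iloc[0]
        raise ValueError(
            "duplicate measurement for animal "
            f"{first['animal']!r} day {first['day']} in group {first['group']!r}"
        )
    return df.reset_index(drop=True)


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read and validate a caliper CSV (animal, group, day, A_mm, B_mm)."""
    return validate_measurements(pd.read_csv(path))


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    validate_measurements(df).to_csv(path, index=False)
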