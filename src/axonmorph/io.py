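"""Label-volume and measurement-table I/O.

The interchange format for segmented volumes is a multi-page TIFF of
integer label images, one page per z-slice, indexed ``(z, y, x)`` with 0-based
indices and label 0 reserved for background.  Semantic classes (axon,
compact myelin, decompacted myelin, mitochondrion) are carried as disjoint
label-id ranges within the single stack; the myelin annulus belonging to
axon ``i`` is labelled ``i + 1000`` (compact) or ``i + 2000`` (decompacted),
so the axon-myelin association is explicit in the labels themselves.

All physical outputs are in micrometres (µm, µm² for areas) even though the
voxel spacing is specified in nanometres; the conversion happens exactly once,
at measurement time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger("axonmorph")

NM_PER_UM = 1000.0

#: semantic class -> inclusive (low, high) label-id range
DEFAULT_CHANNEL_MAP: dict[str, tuple[int, int]] = {
    "axon": (1, 999),
    "compact_myelin": (1001, 1999),
    "decompacted_myelin": (2001, 2999),
    "mitochondrion": (3001, 3999),
}

#: offset added to an axon id to obtain its paired myelin label
COMPACT_OFFSET = 1000
DECOMPACTED_OFFSET = 2000

#: canonical measurement units, fixed per metric
METRIC_UNITS: dict[str, str] = {
    "area": "um^2",
    "axon_diameter": "um",
    "myelin_thickness": "um",
    "fiber_diameter": "um",
    "g_ratio": "unitless",
    "decompaction_pct": "%",
    "arc_position": "um",
}


@dataclass(frozen=True)
class VoxelSpacing:
    """Anisotropic voxel spacing in nanometres.

    Defaults match the acquisition geometry of a 3View SBF-SEM stack:
    5 nm/pixel in-plane, 50 nm slice thickness.
    """

    dx: float = 5.0
    dy: float = 5.0
    dz: float = 50.0

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def dx_um(self) -> float:
        return self.dx / NM_PER_UM

    @property
    def dy_um(self) -> float:
        return self.dy / NM_PER_UM

    @property
    def dz_um(self) -> float:
        return self.dz / NM_PER_UM

    @property
    def pixel_area_um2(self) -> float:
        return self.dx_um * self.dy_um


@dataclass
class LabelVolume:
    """A 3D integer label grid with physical spacing and a channel map.

    ``stack`` is indexed ``(z, y, x)``; the physical coordinate of a voxel
    centre is ``(index + 0.5) * spacing`` on each axis.
    """

    stack: np.ndarray
    spacing: VoxelSpacing = field(default_factory=VoxelSpacing)
    channel_map: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_MAP)
    )

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack)
        if self.stack.ndim != 3:
            raise ValueError(f"stack must be 3D (z, y, x), got ndim={self.stack.ndim}")
        if not np.issubdtype(self.stack.dtype, np.integer):
            raise TypeError(f"stack must be integer-typed, got {self.stack.dtype}")
        self._validate_channel_map()

    def _validate_channel_map(self) -> None:
        ranges = sorted(self.channel_map.items(), key=lambda kv: kv[1][0])
        for (name_a, (lo_a, hi_a)), (name_b, (lo_b, hi_b)) in zip(ranges, ranges[1:]):
            if hi_a >= lo_b:
                raise ValueError(
                    f"channel ranges overlap: {name_a}={lo_a}-{hi_a}, "
                    f"{name_b}={lo_b}-{hi_b}"
                )

    # -- shape / extent -------------------------------------------------

    @property
    def n_slices(self) -> int:
        return self.stack.shape[0]

    def extent_um(self) -> tuple[float, float, float]:
        """Physical (z, y, x) extent of the volume in µm."""
        nz, ny, nx = self.stack.shape
        return (
            nz * self.spacing.dz_um,
            ny * self.spacing.dy_um,
            nx * self.spacing.dx_um,
        )

    # -- semantic classes ----------------------------------------------

    def class_of_label(self, label: int) -> str | None:
        """Semantic class of a label id, or None for background/unmapped."""
        if label == 0:
            return None
        for name, (lo, hi) in self.channel_map.items():
            if lo <= label <= hi:
                return name
        return None

    def class_mask(self, name: str, z: int | None = None) -> np.ndarray:
        lo, hi = self.channel_map[name]
        arr = self.stack if z is None else self.stack[z]
        return (arr >= lo) & (arr <= hi)

    def axon_ids(self) -> list[int]:
        """Sorted axon instance ids present anywhere in the volume."""
        lo, hi = self.channel_map["axon"]
        labels = np.unique(self.stack)
        return [int(v) for v in labels if lo <= v <= hi]

    def mito_ids(self) -> list[int]:
        lo, hi = self.channel_map["mitochondrion"]
        labels = np.unique(self.stack)
        return [int(v) for v in labels if lo <= v <= hi]

    def myelin_labels(self, axon_id: int) -> tuple[int, int]:
        """(compact, decompacted) myelin labels paired with an axon id."""
        return axon_id + COMPACT_OFFSET, axon_id + DECOMPACTED_OFFSET


def read_label_volume(
    path: str | Path,
    spacing: VoxelSpacing | None = None,
    channel_map: dict[str, tuple[int, int]] | None = None,
) -> LabelVolume:
    """Read a multi-page TIFF label stack into a :class:`LabelVolume`.

    Every page must be an integer image of identical shape.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        pages = [p.asarray() for p in tf.pages]
    if not pages:
        raise ValueError(f"{path}: empty TIFF")
    shape0 = pages[0].shape
    for i, page in enumerate(pages):
        if page.shape != shape0:
            raise ValueError(
                f"{path}: slice {i} has shape {page.shape}, expected {shape0}"
            )
        if not np.issubdtype(page.dtype, np.integer):
            raise TypeError(f"{path}: slice {i} is {page.dtype}, expected integer")
    stack = np.stack(pages, axis=0)
    vol = LabelVolume(
        stack=stack,
        spacing=spacing or VoxelSpacing(),
        channel_map=dict(channel_map) if channel_map else dict(DEFAULT_CHANNEL_MAP),
    )
    log.info("read %s: shape %s, %d axon ids", path, stack.shape, len(vol.axon_ids()))
    return vol


def write_label_volume(volume: LabelVolume, path: str | Path) -> Path:
    """Write a label volume as an uncompressed multi-page TIFF."""
    path = Path(path)
    stack = volume.stack
    if stack.min() >= 0 and stack.max() < 2**16:
        stack = stack.astype(np.uint16)
    else:
        stack = stack.astype(np.uint32)
    tifffile.imwrite(path, stack)
    return path


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------

TABLE_COLUMNS = ["axon_id", "z_index", "metric", "value", "units"]


class MeasurementTable:
    """Long-format per-slice measurement records.

    One row per ``(axon_id, z_index, metric)``; units are fixed per metric
    and validated on construction.  Round-trips losslessly through CSV.
    """

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=TABLE_COLUMNS)
        missing = set(TABLE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        self.df = df[TABLE_COLUMNS].reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        if self.df.empty:
            return
        dup = self.df.duplicated(subset=["axon_id", "z_index", "metric"])
        if dup.any():
            raise ValueError("duplicate (axon_id, z_index, metric) rows")
        per_metric = self.df.groupby("metric")["units"].nunique()
        bad = per_metric[per_metric > 1]
        if not bad.empty:
            raise ValueError(f"mixed units for metric(s): {list(bad.index)}")
        for metric, units in self.df.groupby("metric")["units"].first().items():
            if metric in METRIC_UNITS and units != METRIC_UNITS[metric]:
                raise ValueError(
                    f"metric {metric!r} must use units {METRIC_UNITS[metric]!r}, "
                    f"got {units!r}"
                )

    @classmethod
    def from_records(cls, records: list[dict]) -> "MeasurementTable":
        return cls(pd.DataFrame.from_records(records, columns=TABLE_COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        a = self.sorted().df
        b = other.sorted().df
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        return True

    def sorted(self) -> "MeasurementTable":
        df = self.df.sort_values(
            ["axon_id", "z_index", "metric"], kind="mergesort"
        ).reset_index(drop=True)
        return MeasurementTable(df)

    def pivot(self) -> pd.DataFrame:
        """Wide view: one row per (axon_id, z_index), one column per metric."""
        return self.df.pivot_table(
            index=["axon_id", "z_index"], columns="metric", values="value"
        ).reset_index()


def write_measurements(
    table: MeasurementTable, path: str | Path, allow_empty: bool = False
) -> Path:
    """Write a measurement table as CSV with a deterministic row order."""
    if len(table) == 0 and not allow_empty:
        raise ValueError("refusing to write empty table (pass allow_empty=True)")
    path = Path(path)
    table.sorted().df.to_csv(path, index=False)
    return path


def read_measurements(path: str | Path) -> MeasurementTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"axon_id": int, "z_index": int, "value": float})
    if df.empty:
        return MeasurementTable()
    return MeasurementTable(df)


# ---------------------------------------------------------------------------
# flat key-value config files
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` text config; '#' starts a comment."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def save_config(config: dict, path: str | Path) -> Path:
    path = Path(path)
    lines = [f"{k} = {v}" for k, v in config.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


def spacing_from_config(config: dict[str, str]) -> VoxelSpacing:
    return VoxelSpacing(
        dx=float(config.get("dx_nm", 5.0)),
        dy=float(config.get("dy_nm", 5.0)),
        dz=float(config.get("dz_nm", 50.0)),
    )
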