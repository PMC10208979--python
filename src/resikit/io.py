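"""Localization data model and table I/O.

The universal currency of the pipeline is the :class:`LocalizationTable`: one
row per single-molecule localization with lateral coordinates ``x``/``y`` (nm),
an optional axial coordinate ``z`` (nm), the acquisition ``frame`` index, the
lateral localization precision ``lp`` (nm) and an integer ``channel``
identifying the imaging round. All coordinates are held in nanometres
internally; pixel-unit sources (the de-facto Picasso HDF5 dialect stores
coordinates in camera pixels) are converted at the I/O boundary.

Two on-disk dialects are supported:

* HDF5: a single structured dataset named ``"locs"`` with fields ``frame``,
  ``x``, ``y`` (``z`` for 3D), ``lpx``, ``lpy`` and ``channel``, coordinates in
  pixels, plus a YAML metadata sidecar (``<file>.yaml``) carrying the
  acquisition metadata. This mirrors the Picasso layout so RESI output can be
  rendered by standard SMLM viewers.
* CSV: header ``frame,x,y[,z],lp,channel`` with coordinates already in nm.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError

#: canonical column order for in-memory tables
COLUMNS_2D = ["frame", "x", "y", "lp", "channel"]
COLUMNS_3D = ["frame", "x", "y", "z", "lp", "channel"]


@dataclass
class AcquisitionMeta:
    """Acquisition metadata carried alongside a localization table.

    Parameters
    ----------
    n_frames
        Total number of camera frames in the acquisition. Frames are 0-based,
        half-open ``[0, n_frames)``.
    pixel_size
        Camera pixel pitch in nm/pixel, used to convert pixel-unit sources.
    field_width, field_height
        Field-of-view extent in nm.
    is_3d
        Whether localizations carry an axial ``z`` coordinate.
    """

    n_frames: int
    pixel_size: float = 130.0
    field_width: float | None = None
    field_height: float | None = None
    is_3d: bool = False

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValidationError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.pixel_size <= 0:
            raise ValidationError(f"pixel_size must be > 0, got {self.pixel_size}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class LocalizationTable:
    """An ordered set of localizations from one imaging round (or several).

    ``locs`` is a :class:`pandas.DataFrame` with columns ``frame`` (int),
    ``x``, ``y`` (nm), optionally ``z`` (nm), ``lp`` (nm) and ``channel``
    (int). Row order is stable under round-trip I/O.
    """

    locs: pd.DataFrame
    meta: AcquisitionMeta = field(default_factory=lambda: AcquisitionMeta(n_frames=1))

    def __post_init__(self) -> None:
        cols = COLUMNS_3D if "z" in self.locs.columns else COLUMNS_2D
        missing = [c for c in cols if c not in self.locs.columns and c != "z"]
        if missing:
            raise FormatError(f"localization table missing column(s): {missing}")
        self.locs = self.locs[cols].reset_index(drop=True)
        self.meta.is_3d = "z" in self.locs.columns
        validate_table(self)

    @property
    def is_3d(self) -> bool:
        return "z" in self.locs.columns

    def __len__(self) -> int:
        return len(self.locs)

    def coords(self) -> np.ndarray:
        """Return an (N, 2) or (N, 3) coordinate array in nm."""
        cols = ["x", "y", "z"] if self.is_3d else ["x", "y"]
        return self.locs[cols].to_numpy(float)


def validate_table(table: LocalizationTable) -> None:
    """Check per-row invariants; raise :class:`ValidationError` naming rows."""
    locs = table.locs
    if len(locs) == 0:
        return
    bad_lp = np.flatnonzero(~(locs["lp"].to_numpy(float) > 0))
    if bad_lp.size:
        raise ValidationError(
            f"non-positive localization precision at row(s) {bad_lp[:5].tolist()}"
        )
    frames = locs["frame"].to_numpy()
    bad_fr = np.flatnonzero((frames < 0) | (frames >= table.meta.n_frames))
    if bad_fr.size:
        raise ValidationError(
            f"frame index outside [0, {table.meta.n_frames}) at row(s) "
            f"{bad_fr[:5].tolist()}"
        )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_HDF5_MANDATORY = ("frame", "x", "y", "lpx", "lpy")
_CSV_MANDATORY = ("frame", "x", "y", "lp")


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".hdf5", ".h5"):
        return "hdf5"
    if ext in (".csv", ".txt"):
        return "csv"
    raise FormatError(f"cannot infer table format from extension {ext!r}")


def _sidecar_path(path: str) -> str:
    return os.path.splitext(path)[0] + ".yaml"


def read_table(
    path: str,
    format: str | None = None,
    pixel_size: float | None = None,
) -> LocalizationTable:
    """Read a localization table from HDF5 (Picasso dialect) or CSV.

    Parameters
    ----------
    path
        Input file. For HDF5, a YAML sidecar ``<stem>.yaml`` is read when
        present and supplies the acquisition metadata.
    format
        ``"hdf5"`` or ``"csv"``; inferred from the extension if omitted.
    pixel_size
        nm per pixel, required when HDF5 coordinates are in pixels and no
        sidecar records the pitch. Overrides the sidecar value when given.

    Returns
    -------
    LocalizationTable
        Table in nm units with 0-based frames; ``lp`` is the mean of
        ``lpx``/``lpy`` when the source stores both.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        return _read_hdf5(path, pixel_size)
    if fmt == "csv":
        return _read_csv(path, pixel_size)
    raise FormatError(f"unknown format {fmt!r}")


def _read_meta_sidecar(path: str) -> dict | None:
    sc = _sidecar_path(path)
    if os.path.exists(sc):
        with open(sc) as fh:
            return yaml.safe_load(fh)
    return None


def _read_hdf5(path: str, pixel_size: float | None) -> LocalizationTable:
    with h5py.File(path, "r") as fh:
        if "locs" not in fh:
            raise FormatError("HDF5 file has no 'locs' dataset")
        rec = fh["locs"][()]
    names = rec.dtype.names or ()
    for col in _HDF5_MANDATORY:
        if col not in names:
            raise FormatError(f"HDF5 'locs' dataset missing mandatory field {col!r}")
    side = _read_meta_sidecar(path) or {}
    if pixel_size is None:
        pixel_size = side.get("pixel_size")
    p = float(pixel_size) if pixel_size is not None else 1.0

    df = pd.DataFrame(
        {
            "frame": rec["frame"].astype(np.int64),
            "x": rec["x"].astype(float) * p,
            "y": rec["y"].astype(float) * p,
            "lp": 0.5 * (rec["lpx"].astype(float) + rec["lpy"].astype(float)) * p,
            "channel": (
                rec["channel"].astype(np.int64)
                if "channel" in names
                else np.zeros(len(rec), dtype=np.int64)
            ),
        }
    )
    if "z" in names:
        # Picasso convention: z is stored in nm already
        df.insert(3, "z", rec["z"].astype(float))
    meta = AcquisitionMeta(
        n_frames=int(side.get("n_frames", int(df["frame"].max()) + 1 if len(df) else 1)),
        pixel_size=p if pixel_size is not None else 130.0,
        field_width=side.get("field_width"),
        field_height=side.get("field_height"),
        is_3d="z" in df.columns,
    )
    return LocalizationTable(df, meta)


def _read_csv(path: str, pixel_size: float | None) -> LocalizationTable:
    df = pd.read_csv(path)
    for col in _CSV_MANDATORY:
        if col not in df.columns:
            raise FormatError(f"CSV missing mandatory column {col!r}")
    if "channel" not in df.columns:
        df["channel"] = 0
    if "z" in df.columns and df["z"].isna().all():
        df = df.drop(columns="z")
    if pixel_size is not None:
        for col in ("x", "y", "lp"):
            df[col] = df[col] * pixel_size
    side = _read_meta_sidecar(path) or {}
    df["frame"] = df["frame"].astype(np.int64)
    df["channel"] = df["channel"].astype(np.int64)
    meta = AcquisitionMeta(
        n_frames=int(side.get("n_frames", int(df["frame"].max()) + 1 if len(df) else 1)),
        pixel_size=float(side.get("pixel_size", pixel_size or 130.0)),
        field_width=side.get("field_width"),
        field_height=side.get("field_height"),
        is_3d="z" in df.columns,
    )
    return LocalizationTable(df, meta)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_table(table: LocalizationTable, path: str, format: str | None = None) -> None:
    """Write a localization table (plus YAML metadata sidecar).

    HDF5 output stores coordinates and precisions in pixel units (Picasso
    dialect, pitch from ``table.meta.pixel_size``); CSV output stays in nm.
    ``read_table`` round-trips both losslessly at float64 width.
    """
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        _write_hdf5(table, path)
    elif fmt == "csv":
        _write_csv(table, path)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(table.meta.to_dict(), fh, sort_keys=False)


def _write_hdf5(table: LocalizationTable, path: str) -> None:
    p = table.meta.pixel_size
    locs = table.locs
    fields = [
        ("frame", np.int64),
        ("x", np.float64),
        ("y", np.float64),
    ]
    if table.is_3d:
        fields.append(("z", np.float64))
    fields += [("lpx", np.float64), ("lpy", np.float64), ("channel", np.int64)]
    rec = np.zeros(len(locs), dtype=np.dtype(fields))
    rec["frame"] = locs["frame"]
    rec["x"] = locs["x"] / p
    rec["y"] = locs["y"] / p
    if table.is_3d:
        rec["z"] = locs["z"]  # nm, Picasso convention
    rec["lpx"] = locs["lp"] / p
    rec["lpy"] = locs["lp"] / p
    rec["channel"] = locs["channel"]
    with h5py.File(path, "w") as fh:
        fh.create_dataset("locs", data=rec)


def _write_csv(table: LocalizationTable, path: str) -> None:
    table.locs.to_csv(path, index=False)
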