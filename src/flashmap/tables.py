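"""The central localization record: a table of super-resolved coordinates.

A :class:`LocalizationTable` wraps a pandas DataFrame with one row per
localization and nm coordinates, plus the metadata the pipeline needs
(pixel size, round frame-ranges, processing flags).  HDF5 (dataset ``locs``)
is the native on-disk form; a CSV export with identical columns is provided
for interoperability.  Coordinates are always stored in nm internally;
pixel-unit CSVs are converted on read using the pixel size in the header.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["LocalizationTable", "REQUIRED_COLUMNS", "read_localizations"]

#: Mandatory columns of any localization table.
REQUIRED_COLUMNS = ("frame", "round", "x", "y", "photons", "loc_precision")

#: Optional columns carried through when present.
OPTIONAL_COLUMNS = ("species", "site", "sigma_psf_fit", "background", "n_frames")

_INT_COLUMNS = {"frame", "round", "species", "site", "n_frames"}


@dataclass
class LocalizationTable:
    """Per-localization records (nm) with acquisition metadata.

    ``df`` columns: ``frame`` (0-based global frame), ``round``, ``x``, ``y``
    (nm), ``photons``, ``loc_precision`` (per-axis nm), plus optional
    ``species``/``site`` ground truth for synthetic data, ``sigma_psf_fit``
    and ``background`` from frame-mode fitting.  Records are kept sorted by
    (round, frame).
    """

    df: pd.DataFrame
    pixel_size: float = 108.0
    drift_corrected: bool = False
    aligned: bool = False
    counters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing column: {missing[0]}")
        df = self.df
        for col in df.columns:
            if col in _INT_COLUMNS:
                df[col] = df[col].astype(np.int64)
            else:
                df[col] = df[col].astype(np.float64)
        if len(df):
            if not np.all(np.isfinite(df["x"])) or not np.all(np.isfinite(df["y"])):
                raise ValueError("x, y must be finite")
            if np.any(df["photons"] <= 0):
                raise ValueError("photons must be > 0")
            if np.any(df["loc_precision"] <= 0):
                raise ValueError("loc_precision must be > 0")
        self.df = df.sort_values(["round", "frame"], kind="stable").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def rounds(self) -> np.ndarray:
        return np.unique(self.df["round"].to_numpy())

    @property
    def xy(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy()

    def species_table(self, species: int) -> "LocalizationTable":
        """Records of one ground-truth species (shares metadata)."""
        sub = self.df[self.df["species"] == species].reset_index(drop=True)
        return self.replace(df=sub)

    def replace(self, **kwargs) -> "LocalizationTable":
        state = dict(
            df=self.df.copy(),
            pixel_size=self.pixel_size,
            drift_corrected=self.drift_corrected,
            aligned=self.aligned,
            counters=dict(self.counters),
        )
        state.update(kwargs)
        return LocalizationTable(**state)

    # ------------------------------------------------------------------ I/O

    def to_hdf5(self, path: str | Path) -> None:
        """Write the table to HDF5 (dataset ``locs``, metadata as attrs)."""
        rec = self.df.to_records(index=False)
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("locs", data=rec)
            ds.attrs["pixel_size"] = self.pixel_size
            ds.attrs["drift_corrected"] = self.drift_corrected
            ds.attrs["aligned"] = self.aligned
            ds.attrs["units"] = "nm"
            ds.attrs["counters"] = json.dumps(self.counters)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "LocalizationTable":
        with h5py.File(path, "r") as f:
            ds = f["locs"]
            df = pd.DataFrame(ds[()])
            units = ds.attrs.get("units", "nm")
            if isinstance(units, bytes):
                units = units.decode()
            if units != "nm":
                raise ValueError(f"unknown units: {units!r}")
            return cls(
                df=df,
                pixel_size=float(ds.attrs.get("pixel_size", 108.0)),
                drift_corrected=bool(ds.attrs.get("drift_corrected", False)),
                aligned=bool(ds.attrs.get("aligned", False)),
                counters=json.loads(ds.attrs.get("counters", "{}")),
            )

    def to_csv(self, path: str | Path) -> None:
        """CSV export with identical columns; a ``#`` header records units."""
        with open(path, "w") as fh:
            fh.write(
                f"# units=nm pixel_size={self.pixel_size} "
                f"drift_corrected={int(self.drift_corrected)} "
                f"aligned={int(self.aligned)}\n"
            )
            self.df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LocalizationTable":
        """Read a CSV table; pixel-unit coordinates are converted to nm.

        The first line may be a ``#`` header with ``units=`` (``nm`` or
        ``px``) and ``pixel_size=`` entries.  Without a header, nm units are
        assumed.
        """
        meta: dict[str, str] = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh)
        units = meta.get("units", "nm")
        pixel_size = float(meta.get("pixel_size", 108.0))
        if units == "px":
            df["x"] = df["x"] * pixel_size
            df["y"] = df["y"] * pixel_size
            if "loc_precision" in df.columns:
                df["loc_precision"] = df["loc_precision"] * pixel_size
        elif units != "nm":
            raise ValueError(f"unknown units: {units!r}")
        return cls(
            df=df,
            pixel_size=pixel_size,
            drift_corrected=bool(int(meta.get("drift_corrected", "0"))),
            aligned=bool(int(meta.get("aligned", "0"))),
        )


def read_localizations(path: str | Path) -> LocalizationTable:
    """Read a localization table from HDF5 (dataset ``locs``) or CSV."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5", ".hdf"}:
        return LocalizationTable.from_hdf5(path)
    return LocalizationTable.from_csv(path)
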