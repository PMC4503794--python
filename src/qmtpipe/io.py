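"""NIfTI volume, protocol-table and provenance I/O.

All image volumes travel as NIfTI-1 with an isotropic-voxel diagonal affine;
protocol tables are TSV/CSV/JSON with one row per acquired volume; every
output directory gets a provenance JSON capturing the generating
configuration and seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .signal_models import AcquisitionSpec

__all__ = [
    "read_volume",
    "write_volume",
    "read_protocol",
    "write_protocol",
    "write_provenance",
]

logger = logging.getLogger(__name__)

_PROTOCOL_COLUMNS = ["volume_index", "kind", "flip_deg", "tr_ms", "trf_ms"]


def write_volume(volume: np.ndarray, path, voxel_size_mm: float = 1.0) -> None:
    """Write a 3-D or 4-D array as NIfTI-1 with an isotropic diagonal affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine)
    img.header.set_zooms(
        (voxel_size_mm,) * 3 + ((1.0,) if volume.ndim == 4 else ())
    )
    nib.save(img, str(path))


def read_volume(path):
    """Read a NIfTI volume; returns (data, voxel_size_mm).

    Raises FileNotFoundError for a missing path and nibabel's format error
    for a malformed file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    voxel = float(img.header.get_zooms()[0])
    return data, voxel


def write_protocol(protocol: Sequence[AcquisitionSpec], path) -> None:
    """Write an acquisition protocol as TSV (or CSV/JSON by extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        dict(
            volume_index=i, kind=s.kind, flip_deg=s.flip_angle,
            tr_ms=s.tr, trf_ms=s.trf if s.trf is not None else np.nan,
        )
        for i, s in enumerate(protocol)
    ]
    df = pd.DataFrame(rows, columns=_PROTOCOL_COLUMNS)
    if path.suffix == ".json":
        df.to_json(path, orient="records", indent=2)
    elif path.suffix == ".csv":
        df.to_csv(path, index=False)
    else:
        df.to_csv(path, sep="\t", index=False)


def read_protocol(path) -> list[AcquisitionSpec]:
    """Read and validate an acquisition protocol table (TSV/CSV/JSON).

    Rows are returned in ``volume_index`` order; validation errors name the
    offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such protocol table: {path}")
    if path.suffix == ".json":
        df = pd.read_json(path, precise_float=True)
    elif path.suffix == ".csv":
        df = pd.read_csv(path)
    else:
        df = pd.read_csv(path, sep="\t")
    missing = [c for c in _PROTOCOL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"protocol table missing columns: {missing}")
    df = df.sort_values("volume_index")
    protocol = []
    for _, row in df.iterrows():
        trf = row["trf_ms"]
        trf = None if pd.isna(trf) else float(trf)
        try:
            protocol.append(
                AcquisitionSpec(
                    kind=str(row["kind"]), flip_angle=float(row["flip_deg"]),
                    tr=float(row["tr_ms"]), trf=trf,
                )
            )
        except ValueError as err:
            raise ValueError(
                f"invalid protocol row {int(row['volume_index'])}: {err}"
            ) from err
    return protocol


def write_provenance(path, **payload) -> None:
    """Write a provenance JSON (config, seeds, package version)."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if hasattr(obj, "__dataclass_fields__"):
            return asdict(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump({"qmtpipe_version": __version__, **payload}, fh,
                  indent=2, default=default)
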