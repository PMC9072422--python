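"""Configuration, serialization and seeding.

Units are fixed at the I/O boundary: cortical coordinates in micrometres,
visual coordinates in degrees, canonical coordinates dimensionless, delays in
frames with the frame rate carried in metadata.  Cell tables are CSV with a
format-version comment line; array-valued data live in a ``.npz`` archive
with a JSON sidecar of scalar metadata.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError

FORMAT_VERSION = 1

#: Columns a classified cell table must provide, and those that must be
#: finite when present.
REQUIRED_CELL_COLUMNS = ("cell_id", "cell_class", "x1", "x2", "x3")
COORDINATE_COLUMNS = ("x1", "x2", "x3")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every tunable of the analysis, each appearing exactly once.

    Defaults reproduce the reference acquisition and analysis settings:
    an 18 x 8 sparse-noise grid at 10%/10%/80% tile probabilities, 1500
    presentations at 15.6 Hz, a 15-frame kernel window with significance at
    norm ratio 5 and 50% fit variance, KDE bandwidths of 30 um (native) and
    0.25 (canonical), 1000 label shuffles at alpha 0.001, and a k = 5
    neighbourhood for the non-negative model.
    """

    master_seed: int = 0
    out_dir: str = "run"
    # synthetic population
    n_on: int = 450
    n_off: int = 900
    n_simple: int = 150
    n_complex: int = 150
    bias_amplitude: float = 0.8
    bias_n_blobs: int = 6
    bias_length_scale: float = 20.0
    scatter_sigma_on: float = 40.0
    scatter_sigma_off: float = 25.0
    rf_sigma_deg: float = 6.0
    # stimulus / responses
    n_stimuli: int = 1500
    p_bright: float = 0.1
    p_dark: float = 0.1
    frame_rate: float = 15.6
    gain: float = 2.0
    baseline: float = 0.08
    delay_frames: int = 5
    # kernel estimation / classification
    max_delay: int = 15
    norm_threshold: float = 5.0
    ve_threshold: float = 0.5
    simple_threshold: float = 0.5
    # density estimation
    sigma_native_um: float = 30.0
    sigma_canonical: float = 0.25
    native_spacing_um: float = 10.0
    canonical_spacing: float = 0.05
    canonical_limit: float = 2.5
    n_shuffles: int = 1000
    alpha: float = 0.001
    # neighbourhood model
    knn_k: int = 5
    sweep_k_max: int = 8
    saturation_eps: float = 0.02

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def save(self, path) -> None:
        obj = dict(format_version=FORMAT_VERSION, **self.to_dict())
        Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        obj = yaml.safe_load(Path(path).read_text())
        if not isinstance(obj, dict):
            raise ValidationError(f"config {path} is not a mapping")
        version = obj.pop("format_version", None)
        if version != FORMAT_VERSION:
            raise ValidationError(f"unknown config format version {version!r}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**obj)


#: Pipeline stages in execution order; the master seed fans out one
#: independent stream per stage.
STAGES = ("simulate", "kernels", "domains", "cca", "canonical_maps", "rfmodel")


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Independent per-stage integer seeds derived from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(STAGES))
    return {name: int(np.random.default_rng(c).integers(2 ** 31))
            for name, c in zip(STAGES, children)}


# ---------------------------------------------------------------------------
# cell tables
# ---------------------------------------------------------------------------

def write_cells(cells: pd.DataFrame, path) -> None:
    """Write a cell table as CSV with a format-version comment line."""
    _validate_cells(cells)
    with open(path, "w") as fh:
        fh.write(f"# onoffmap cell table, format_version={FORMAT_VERSION}\n")
        cells.to_csv(fh, index=False)


def read_cells(path) -> pd.DataFrame:
    """Read and validate a cell table written by :func:`write_cells`."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"cell table {path} does not exist")
    first = path.open().readline()
    if "format_version" in first:
        version = first.strip().rsplit("=", 1)[-1]
        if version != str(FORMAT_VERSION):
            raise ValidationError(f"unknown cell-table format version {version}")
    cells = pd.read_csv(path, comment="#")
    _validate_cells(cells)
    return cells


def _validate_cells(cells: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValidationError(f"cell table is missing column(s) {missing}")
    for c in COORDINATE_COLUMNS:
        vals = cells[c].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            raise ValidationError(f"cell table column {c!r} contains NaN/inf")


# ---------------------------------------------------------------------------
# array archives
# ---------------------------------------------------------------------------

def write_arrays(path, arrays: dict[str, np.ndarray],
                 metadata: dict | None = None) -> None:
    """Named-array archive (.npz) plus a JSON sidecar of scalar metadata."""
    np.savez(path, __format_version__=np.array(FORMAT_VERSION), **arrays)
    side = Path(str(path)).with_suffix(".json")
    side.write_text(json.dumps(dict(format_version=FORMAT_VERSION,
                                    **(metadata or {})), indent=1))


def read_arrays(path, required: tuple[str, ...] = ()) -> tuple[dict, dict]:
    """Read an archive written by :func:`write_arrays`; returns
    (arrays, metadata).  Truncated or malformed archives fail loudly."""
    path = Path(str(path))
    if not path.exists():
        raise ValidationError(f"archive {path} does not exist")
    try:
        with np.load(path, allow_pickle=False) as z:
            arrays = {k: z[k] for k in z.files if k != "__format_version__"}
            if "__format_version__" not in z.files:
                raise ValidationError(f"{path} has no format version")
            version = int(z["__format_version__"])
    except (ValueError, OSError, KeyError, zipfile.BadZipFile, EOFError) as exc:
        raise ValidationError(f"archive {path} is corrupt: {exc}") from exc
    if version != FORMAT_VERSION:
        raise ValidationError(f"unknown archive format version {version}")
    missing = set(required) - set(arrays)
    if missing:
        raise ValidationError(f"archive {path} is missing array(s) {sorted(missing)}")
    for k, a in arrays.items():
        if a.dtype.kind in "fc" and not np.all(np.isfinite(a)):
            raise ValidationError(f"archive {path} array {k!r} contains NaN/inf")
    meta = {}
    side = path.with_suffix(".json")
    if side.exists():
        meta = json.loads(side.read_text())
    return arrays, meta


def file_digest(path) -> str:
    """SHA-256 digest of a file, for run manifests."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
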