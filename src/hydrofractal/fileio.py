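"""File formats: spectrum/point CSV schemas, PNG rasters, voxel grids,
and the JSON run report.

Formats are deliberately plain so every artifact can be inspected with a
text editor or standard image viewer:

* spectrum CSV: header ``frequency_hz,eps_real,eps_imag``; the loss
  column is the positive epsilon''; ``#`` starts a comment line.
* tau-beta points CSV: header
  ``label,tau_s,beta,tau_err,beta_err[,composition]``.
* binary images: PNG, background 0 / foreground 255.
* voxel grids: a small text header followed by a bit-packed occupancy
  stream (C order), plus an optional ``.xyz``-style text dump of occupied
  voxel centres for debugging.
* run reports: JSON.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .geometry_models import BinaryImage2D, VoxelGrid3D
from .relaxation_models import DielectricSpectrum, DomainError
from .tau_beta_fractal import TauBetaPoint

SPECTRUM_HEADER = ["frequency_hz", "eps_real", "eps_imag"]
POINTS_HEADER = ["label", "tau_s", "beta", "tau_err", "beta_err"]

__version__ = "0.1.0"


class SchemaError(DomainError):
    """A file does not conform to its documented schema."""


def _data_rows(path: Path):
    """Yield (line_number, row) skipping blank lines and '#' comments."""
    with open(path, newline="") as fh:
        for ln, row in enumerate(csv.reader(fh), start=1):
            if not row or (row[0].lstrip().startswith("#")):
                continue
            yield ln, [c.strip() for c in row]


def read_spectrum(path) -> DielectricSpectrum:
    """Read a spectrum CSV; malformed rows are reported with line numbers."""
    path = Path(path)
    rows = list(_data_rows(path))
    if not rows:
        raise SchemaError(f"{path}: empty file")
    ln0, header = rows[0]
    if [h.lower() for h in header[:3]] != SPECTRUM_HEADER:
        raise SchemaError(
            f"{path}:{ln0}: expected header {','.join(SPECTRUM_HEADER)}, got {','.join(header)}"
        )
    freqs, eps = [], []
    prev_f = 0.0
    for ln, row in rows[1:]:
        if len(row) < 3:
            raise SchemaError(f"{path}:{ln}: expected 3 columns, got {len(row)}")
        try:
            f, er, ei = (float(c) for c in row[:3])
        except ValueError as exc:
            raise SchemaError(f"{path}:{ln}: non-numeric cell ({exc})") from None
        if f <= prev_f:
            raise SchemaError(
                f"{path}:{ln}: frequencies must be strictly increasing "
                f"({f} after {prev_f})"
            )
        prev_f = f
        freqs.append(f)
        eps.append(er - 1j * abs(ei))
    return DielectricSpectrum(np.array(freqs), np.array(eps))


def write_spectrum(spectrum: DielectricSpectrum, path, comment: str | None = None) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        w = csv.writer(fh)
        w.writerow(SPECTRUM_HEADER)
        for f, e in zip(spectrum.frequencies, spectrum.eps_complex):
            w.writerow([repr(float(f)), repr(float(e.real)), repr(float(-e.imag))])


def read_points(path) -> list[TauBetaPoint]:
    """Read a tau-beta points CSV (optional trailing composition column)."""
    path = Path(path)
    rows = list(_data_rows(path))
    if not rows:
        raise SchemaError(f"{path}: empty file")
    ln0, header = rows[0]
    if [h.lower() for h in header[:5]] != POINTS_HEADER:
        raise SchemaError(
            f"{path}:{ln0}: expected header {','.join(POINTS_HEADER)}[,composition]"
        )
    has_comp = len(header) > 5 and header[5].lower() == "composition"
    points = []
    for ln, row in rows[1:]:
        if len(row) < 5:
            raise SchemaError(f"{path}:{ln}: expected >= 5 columns, got {len(row)}")
        try:
            tau, beta, te, be = (float(c) for c in row[1:5])
            comp = float(row[5]) if has_comp and len(row) > 5 and row[5] != "" else None
        except ValueError as exc:
            raise SchemaError(f"{path}:{ln}: non-numeric cell ({exc})") from None
        points.append(
            TauBetaPoint(tau=tau, beta=beta, tau_err=te, beta_err=be,
                         composition=comp, label=row[0])
        )
    return points


def write_points(points, path) -> None:
    path = Path(path)
    has_comp = any(p.composition is not None for p in points)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(POINTS_HEADER + (["composition"] if has_comp else []))
        for p in points:
            row = [p.label, repr(p.tau), repr(p.beta), repr(p.tau_err), repr(p.beta_err)]
            if has_comp:
                row.append("" if p.composition is None else repr(p.composition))
            w.writerow(row)


# ---------------------------------------------------------------------------
# Rasters


def write_image(image: BinaryImage2D, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), (image.occupancy.astype(np.uint8) * 255))


def read_image(path) -> BinaryImage2D:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:  # collapse identical channels
        arr = arr[..., 0]
    return BinaryImage2D(occupancy=arr >= 128)


_VOX_MAGIC = "hydrofractal-voxels v1"


def write_voxels(grid: VoxelGrid3D, path) -> None:
    """Header lines (text) + bit-packed occupancy (C order)."""
    path = Path(path)
    packed = np.packbits(grid.occupancy.astype(np.uint8).ravel())
    with open(path, "wb") as fh:
        header = (
            f"{_VOX_MAGIC}\n"
            f"shape {grid.shape[0]} {grid.shape[1]} {grid.shape[2]}\n"
            f"cell_size {grid.cell_size!r}\n"
            "data packbits\n"
        )
        fh.write(header.encode())
        fh.write(packed.tobytes())


def read_voxels(path) -> VoxelGrid3D:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.readline().decode().strip()
        if magic != _VOX_MAGIC:
            raise SchemaError(f"{path}: not a voxel file (bad magic {magic!r})")
        shape = tuple(int(x) for x in fh.readline().decode().split()[1:4])
        cell = float(fh.readline().decode().split()[1])
        mode = fh.readline().decode().split()[1]
        if mode != "packbits":
            raise SchemaError(f"{path}: unknown data mode {mode!r}")
        packed = np.frombuffer(fh.read(), dtype=np.uint8)
    n = int(np.prod(shape))
    occ = np.unpackbits(packed)[:n].reshape(shape).astype(bool)
    return VoxelGrid3D(occupancy=occ, cell_size=cell)


def write_voxels_xyz(grid: VoxelGrid3D, path, max_points: int | None = None) -> None:
    """Text dump of occupied voxel centres: ``x y z`` per line (model units)."""
    coords = np.argwhere(grid.occupancy)
    if max_points is not None:
        coords = coords[:max_points]
    centres = (coords + 0.5) * grid.cell_size
    np.savetxt(Path(path), centres, fmt="%.6g", header="x y z")


# ---------------------------------------------------------------------------
# Run report


@dataclass
class RunReport:
    """Reproducible record of one analysis run.

    Every numeric output is stored under the stage that produced it, with
    the seed and the configuration echo; serialisation round-trips
    losslessly (no timestamps by design, so identical runs give identical
    files).
    """

    tool_version: str = __version__
    seed: int | None = None
    config: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def add_stage(self, name: str, **outputs) -> None:
        self.stages[name] = _jsonable(outputs)

    def add_warning(self, message: str) -> None:
        self.warnings.append(str(message))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_report(report: RunReport, path) -> None:
    Path(path).write_text(report.to_json() + "\n")


def read_report(path) -> RunReport:
    return RunReport.from_json(Path(path).read_text())
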