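"""MRC2014 map/stack and RELION STAR particle-metadata I/O.

Volumes are stored as (z, y, x) slabs and image stacks as (n, y, x), matching
the on-disk MRC section order; no axis permutation is ever applied. Angles are
kept in degrees in metadata records (the STAR convention) and converted to
radians only inside the geometry code. Image indices are 0-based internally;
the 1-based ``index@file`` notation appears only at the STAR boundary.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
from gemmi import cif

from .optics import CTFParams
from .geometry import Pose

__all__ = [
    "FormatError",
    "StarSchemaError",
    "VoxelGrid",
    "ImageStack",
    "ParticleRecord",
    "ParticleStack",
    "OpticsGroup",
    "read_mrc",
    "write_mrc",
    "read_star",
    "write_star",
]


class FormatError(ValueError):
    """Malformed MRC/STAR container (bad header, truncated payload, ...)."""


class StarSchemaError(FormatError):
    """STAR file parsed, but a required column or table is missing."""


# ---------------------------------------------------------------------------
# domain containers


@dataclass
class VoxelGrid:
    """Cubic 3D density map with a physical voxel size in Angstrom."""

    data: np.ndarray  # (L, L, L) float32, (z, y, x)
    voxel_size: float  # Angstrom per voxel
    origin_at_center: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError(f"volume must be a cube, got shape {self.data.shape}")
        if self.data.shape[0] % 2 != 0:
            raise ValueError(f"volume edge must be even, got {self.data.shape[0]}")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def edge(self) -> int:
        return self.data.shape[0]


@dataclass
class ImageStack:
    """Raw particle images without metadata: (n, L, L) float32."""

    images: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.images.ndim != 3:
            raise ValueError(f"stack must be (n, L, L), got {self.images.shape}")
        if self.images.shape[1] != self.images.shape[2]:
            raise FormatError(f"non-square images: {self.images.shape[1:]}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def edge(self) -> int:
        return self.images.shape[1]


@dataclass
class ParticleRecord:
    """Per-particle metadata: pose, optics and half-set membership."""

    image_index: int
    pose: Pose
    ctf: Optional[CTFParams]  # None means a unit (no-op) CTF
    half_set: int
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.half_set not in (1, 2):
            raise ValueError(f"half_set must be 1 or 2, got {self.half_set}")


@dataclass
class ParticleStack:
    """N square particle images plus one metadata record per image."""

    images: np.ndarray  # (N, L, L) float32
    pixel_size: float
    records: List[ParticleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.images.ndim != 3 or self.images.shape[1] != self.images.shape[2]:
            raise ValueError(f"images must be (N, L, L), got {self.images.shape}")
        if len(self.records) != self.images.shape[0]:
            raise ValueError(
                f"{len(self.records)} records for {self.images.shape[0]} images"
            )
        idx = [r.image_index for r in self.records]
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate image_index in records")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def edge(self) -> int:
        return self.images.shape[1]

    def subset(self, indices: Sequence[int]) -> "ParticleStack":
        """New stack holding the given records (by position) and their images.

        ``image_index`` values are preserved so downstream STAR output keeps
        addressing the original MRCS.
        """
        indices = list(indices)
        recs = [replace(self.records[i]) for i in indices]
        imgs = self.images[indices]
        return ParticleStack(images=imgs, pixel_size=self.pixel_size, records=recs)


@dataclass
class OpticsGroup:
    """RELION optics-group table row (shared microscope parameters)."""

    group_id: int = 1
    voltage: float = 300.0  # kV
    cs: float = 2.7  # mm
    amplitude_contrast: float = 0.1
    pixel_size: float = 1.0  # Angstrom
    image_size: int = 0


# ---------------------------------------------------------------------------
# MRC2014

_HEADER_BYTES = 1024
_MODE_DTYPES = {
    0: np.dtype("int8"),
    1: np.dtype("<i2"),
    2: np.dtype("<f4"),
    6: np.dtype("<u2"),
    12: np.dtype("<f2"),
}


def _parse_header(raw: bytes) -> dict:
    ints = np.frombuffer(raw, dtype="<i4", count=56)
    floats = np.frombuffer(raw, dtype="<f4", count=56)
    return {
        "nx": int(ints[0]),
        "ny": int(ints[1]),
        "nz": int(ints[2]),
        "mode": int(ints[3]),
        "mx": int(ints[7]),
        "my": int(ints[8]),
        "mz": int(ints[9]),
        "cella": tuple(float(v) for v in floats[10:13]),
        "mapc": int(ints[16]),
        "mapr": int(ints[17]),
        "maps": int(ints[18]),
        "ispg": int(ints[22]),
        "nsymbt": int(ints[23]),
        "map_id": raw[208:212],
    }


def read_mrc(path: Union[str, Path]) -> Union[VoxelGrid, ImageStack]:
    """Read an MRC2014 map or MRCS image stack.

    A file is treated as a 2D stack when the header marks image-stack
    semantics (``ispg == 0`` with ``mz`` covering a single section) and as a
    3D map otherwise. Modes 0/1/6/12 are converted to float32.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_BYTES:
        raise FormatError(f"{path}: file shorter than the 1024-byte MRC header")
    hdr = _parse_header(raw[:_HEADER_BYTES])
    if hdr["map_id"] != b"MAP ":
        raise FormatError(f"{path}: missing 'MAP ' signature; not an MRC2014 file")
    if hdr["mode"] not in _MODE_DTYPES:
        raise FormatError(f"{path}: unsupported MRC mode {hdr['mode']}")
    nx, ny, nz = hdr["nx"], hdr["ny"], hdr["nz"]
    if min(nx, ny, nz) <= 0:
        raise FormatError(f"{path}: non-positive dimensions {(nx, ny, nz)}")
    if nx != ny:
        raise FormatError(f"{path}: non-square sections {(ny, nx)}")
    dtype = _MODE_DTYPES[hdr["mode"]]
    start = _HEADER_BYTES + hdr["nsymbt"]
    nbytes = nx * ny * nz * dtype.itemsize
    if len(raw) < start + nbytes:
        raise FormatError(
            f"{path}: truncated data block ({len(raw) - start} of {nbytes} bytes)"
        )
    data = np.frombuffer(raw, dtype=dtype, count=nx * ny * nz, offset=start)
    data = data.reshape(nz, ny, nx).astype(np.float32)
    mx = hdr["mx"] or nx
    px = hdr["cella"][0] / mx if hdr["cella"][0] > 0 else 1.0
    is_stack = hdr["ispg"] == 0 and (hdr["mz"] in (0, 1) or hdr["mz"] != nz)
    if nz == 1:
        is_stack = True
    if not is_stack and nz == ny == nx:
        return VoxelGrid(data=data, voxel_size=px)
    return ImageStack(images=data, pixel_size=px)


def write_mrc(obj: Union[VoxelGrid, ImageStack], path: Union[str, Path]) -> None:
    """Write a volume (MRC) or an image stack (MRCS), mode 2 float32."""
    if isinstance(obj, VoxelGrid):
        data, px, is_stack = obj.data, obj.voxel_size, False
    elif isinstance(obj, ImageStack):
        data, px, is_stack = obj.images, obj.pixel_size, True
    else:
        raise TypeError(f"cannot write {type(obj).__name__} as MRC")
    data = np.ascontiguousarray(data, dtype="<f4")
    nz, ny, nx = data.shape
    mz = 1 if is_stack else nz
    ints = np.zeros(256, dtype="<i4")
    floats = ints.view("<f4")
    ints[0:3] = (nx, ny, nz)
    ints[3] = 2
    ints[7:10] = (nx, ny, mz)
    floats[10:13] = (nx * px, ny * px, mz * px)
    floats[13:16] = 90.0
    ints[16:19] = (1, 2, 3)
    floats[19] = float(data.min())
    floats[20] = float(data.max())
    floats[21] = float(data.mean())
    ints[22] = 0 if is_stack else 1
    ints[27] = 20140  # nversion
    hdr = ints.tobytes()
    hdr = hdr[:208] + b"MAP " + bytes([0x44, 0x44, 0, 0]) + hdr[216:]
    rms = np.float32(data.std()).tobytes()
    hdr = hdr[:216] + rms + hdr[220:]
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(data.tobytes())


# ---------------------------------------------------------------------------
# RELION STAR

_ANGLE_COLS = ("_rlnAngleRot", "_rlnAngleTilt", "_rlnAnglePsi")
_DEFOCUS_COLS = ("_rlnDefocusU", "_rlnDefocusV")
_SCORE_COL = "_rlnParticleScore"


def _block(doc: cif.Document, *names: str):
    for name in names:
        b = doc.find_block(name)
        if b is not None:
            return b
    return None


def _column(block, tag: str) -> Optional[List[str]]:
    col = block.find_loop(tag)
    vals = list(col)
    return vals if vals else None


def read_star(path: Union[str, Path]):
    """Read a RELION 3.1 (or 3.0-style) particle STAR file.

    Returns ``(records, optics)`` where ``optics`` is a list of
    :class:`OpticsGroup`. With no optics table (RELION 3.0 dialect), optics
    parameters are taken from per-particle columns. Missing
    ``rlnRandomSubset`` triggers the documented fallback: half-sets assigned
    alternating 1,2,1,2,... by row order, with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"STAR file not found: {path}")
    doc = cif.read_file(str(path))

    optics_block = _block(doc, "optics")
    optics: dict[int, OpticsGroup] = {}
    if optics_block is not None:
        ids = _column(optics_block, "_rlnOpticsGroup")
        if ids is None:
            raise StarSchemaError(f"{path}: data_optics lacks _rlnOpticsGroup")
        n = len(ids)

        def ocol(tag, default):
            vals = _column(optics_block, tag)
            return [float(v) for v in vals] if vals else [default] * n

        volt = ocol("_rlnVoltage", 300.0)
        cs = ocol("_rlnSphericalAberration", 2.7)
        ac = ocol("_rlnAmplitudeContrast", 0.1)
        px = ocol("_rlnImagePixelSize", 1.0)
        size = ocol("_rlnImageSize", 0.0)
        for i, gid in enumerate(ids):
            g = int(gid)
            optics[g] = OpticsGroup(
                group_id=g,
                voltage=volt[i],
                cs=cs[i],
                amplitude_contrast=ac[i],
                pixel_size=px[i],
                image_size=int(size[i]),
            )

    pblock = _block(doc, "particles", "images", "")
    if pblock is None or _column(pblock, "_rlnAngleRot") is None:
        # RELION writes a bare data_ block in the 3.0 dialect
        pblock = next(
            (b for b in doc if _column(b, "_rlnAngleRot") is not None), None
        )
    if pblock is None:
        raise StarSchemaError(f"{path}: no particle loop with _rlnAngleRot found")

    def col(tag: str, required: bool = False, default: float = 0.0):
        vals = _column(pblock, tag)
        if vals is None:
            if required:
                raise StarSchemaError(f"{path}: missing required column {tag}")
            return None
        return vals

    rot = [float(v) for v in col("_rlnAngleRot", required=True)]
    n = len(rot)
    tilt = [float(v) for v in col("_rlnAngleTilt", required=True)]
    psi = [float(v) for v in col("_rlnAnglePsi", required=True)]
    du = [float(v) for v in col("_rlnDefocusU", required=True)]
    dv_raw = col("_rlnDefocusV")
    dv = [float(v) for v in dv_raw] if dv_raw else du
    da = col("_rlnDefocusAngle")
    da = [float(v) for v in da] if da else [0.0] * n
    ps = col("_rlnPhaseShift")
    ps = [float(v) for v in ps] if ps else [0.0] * n
    ox = col("_rlnOriginXAngst")
    ox = [float(v) for v in ox] if ox else [0.0] * n
    oy = col("_rlnOriginYAngst")
    oy = [float(v) for v in oy] if oy else [0.0] * n

    group_col = col("_rlnOpticsGroup")
    if optics and group_col is not None:
        for g in group_col:
            if int(g) not in optics:
                raise StarSchemaError(
                    f"{path}: optics group {int(g)} referenced but not defined"
                )

    # per-particle optics fallback (3.0 dialect)
    volt_col = col("_rlnVoltage")
    cs_col = col("_rlnSphericalAberration")
    ac_col = col("_rlnAmplitudeContrast")

    def optics_for(i: int) -> OpticsGroup:
        if optics:
            g = int(group_col[i]) if group_col is not None else next(iter(optics))
            return optics[g]
        return OpticsGroup(
            voltage=float(volt_col[i]) if volt_col else 300.0,
            cs=float(cs_col[i]) if cs_col else 2.7,
            amplitude_contrast=float(ac_col[i]) if ac_col else 0.1,
        )

    name_col = col("_rlnImageName")
    if name_col is not None:
        image_index = [int(v.split("@")[0]) - 1 for v in name_col]
    else:
        image_index = list(range(n))

    subset_col = col("_rlnRandomSubset")
    if subset_col is None:
        warnings.warn(
            f"{path}: no _rlnRandomSubset column; assigning half-sets "
            "alternating 1,2 by row order",
            stacklevel=2,
        )
        half = [1 if i % 2 == 0 else 2 for i in range(n)]
    else:
        half = [int(v) for v in subset_col]

    score_col = col(_SCORE_COL)
    scores = [float(v) for v in score_col] if score_col else [None] * n

    records = []
    for i in range(n):
        og = optics_for(i)
        records.append(
            ParticleRecord(
                image_index=image_index[i],
                pose=Pose(rot=rot[i], tilt=tilt[i], psi=psi[i],
                          shift_x=ox[i], shift_y=oy[i]),
                ctf=CTFParams(
                    voltage=og.voltage,
                    cs=og.cs,
                    amplitude_contrast=og.amplitude_contrast,
                    defocus_u=du[i],
                    defocus_v=dv[i],
                    astig_angle=da[i],
                    phase_shift=ps[i],
                ),
                half_set=half[i],
                score=scores[i],
            )
        )
    if not optics:
        optics[1] = OpticsGroup()
    return records, sorted(optics.values(), key=lambda g: g.group_id)


def write_star(
    records: Sequence[ParticleRecord],
    path: Union[str, Path],
    optics: Optional[Sequence[OpticsGroup]] = None,
    image_file: str = "particles.mrcs",
) -> None:
    """Write records as a RELION 3.1 STAR file (data_optics + data_particles)."""
    if not records:
        raise ValueError("cannot write an empty record list")
    if optics is None:
        c0 = records[0].ctf or CTFParams()
        optics = [
            OpticsGroup(
                voltage=c0.voltage,
                cs=c0.cs,
                amplitude_contrast=c0.amplitude_contrast,
            )
        ]
    doc = cif.Document()
    ob = doc.add_new_block("optics")
    oloop = ob.init_loop(
        "_rln",
        ["OpticsGroup", "Voltage", "SphericalAberration",
         "AmplitudeContrast", "ImagePixelSize", "ImageSize"],
    )
    for g in optics:
        oloop.add_row([
            str(g.group_id), f"{g.voltage:.6g}", f"{g.cs:.6g}",
            f"{g.amplitude_contrast:.6g}", f"{g.pixel_size:.6g}",
            str(g.image_size),
        ])

    pb = doc.add_new_block("particles")
    tags = ["ImageName", "AngleRot", "AngleTilt", "AnglePsi",
            "OriginXAngst", "OriginYAngst", "DefocusU", "DefocusV",
            "DefocusAngle", "PhaseShift", "OpticsGroup", "RandomSubset"]
    have_scores = any(r.score is not None for r in records)
    if have_scores:
        tags.append(_SCORE_COL.removeprefix("_rln"))
    ploop = pb.init_loop("_rln", tags)
    for r in records:
        c = r.ctf or CTFParams(defocus_u=0.0, defocus_v=0.0)
        row = [
            f"{r.image_index + 1:06d}@{image_file}",
            f"{r.pose.rot:.6f}", f"{r.pose.tilt:.6f}", f"{r.pose.psi:.6f}",
            f"{r.pose.shift_x:.6f}", f"{r.pose.shift_y:.6f}",
            f"{c.defocus_u:.6f}", f"{c.defocus_v:.6f}",
            f"{c.astig_angle:.6f}", f"{c.phase_shift:.6f}",
            "1", str(r.half_set),
        ]
        if have_scores:
            row.append("0.0" if r.score is None else f"{r.score:.8g}")
        ploop.add_row(row)
    doc.write_file(str(path))
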