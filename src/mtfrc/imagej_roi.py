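"""Minimal ImageJ .roi binary codec.

Reads and writes the subset of the ImageJ ROI format needed for outlining
features: polygon, rectangle, oval, and freehand ROIs, with the stack
position either in the header's position field or encoded in the file name
(the ROI manager's "slice-y-x" naming). Traced, composite, line, and point
ROIs are rejected. All integers are big-endian.
"""

from __future__ import annotations

import io
import struct
import zipfile
from pathlib import Path

import numpy as np

_MAGIC = b"Iout"
_VERSION = 228

# header type byte
POLYGON, RECT, OVAL, LINE, FREELINE, POLYLINE, NO_ROI, FREEHAND, TRACED, ANGLE, POINT = range(11)
_SUPPORTED = {POLYGON, RECT, OVAL, FREEHAND}
_NAMES = {
    LINE: "line", FREELINE: "freeline", POLYLINE: "polyline", NO_ROI: "none",
    TRACED: "traced", ANGLE: "angle", POINT: "point",
}


def decode_roi(data: bytes) -> tuple[np.ndarray, int | None]:
    """Decode one .roi blob into ((n, 2) vertex array, 0-based slice or None).

    Rectangles and ovals are converted to polygons (the oval as a 64-gon
    inscribed in its bounding box). The slice comes from the header position
    field or, if present, the Z position in the second header; 0 means the
    ROI is untagged (applies to every slice) and maps to None.
    """
    if len(data) < 64 or data[:4] != _MAGIC:
        raise ValueError("not an ImageJ ROI file")
    roi_type = data[6]
    top, left, bottom, right = struct.unpack(">4h", data[8:16])
    n_coords = struct.unpack(">h", data[16:18])[0]
    position = struct.unpack(">i", data[56:60])[0]
    hdr2 = struct.unpack(">i", data[60:64])[0]
    if 0 < hdr2 <= len(data) - 12:
        z_pos = struct.unpack(">i", data[hdr2 + 8 : hdr2 + 12])[0]
        if z_pos > 0:
            position = z_pos

    if roi_type not in _SUPPORTED:
        kind = _NAMES.get(roi_type, f"type {roi_type}")
        raise ValueError(f"unsupported ROI type: {kind}")

    if roi_type == RECT:
        verts = np.array(
            [(left, top), (right, top), (right, bottom), (left, bottom)], dtype=float
        )
    elif roi_type == OVAL:
        theta = np.linspace(0.0, 2.0 * np.pi, 64, endpoint=False)
        cx, cy = (left + right) / 2.0, (top + bottom) / 2.0
        rx, ry = (right - left) / 2.0, (bottom - top) / 2.0
        verts = np.column_stack([cx + rx * np.cos(theta), cy + ry * np.sin(theta)])
    else:  # polygon / freehand
        if n_coords < 3:
            raise ValueError(f"polygon ROI needs >= 3 vertices, got {n_coords}")
        end = 64 + 4 * n_coords
        if len(data) < end:
            raise ValueError("truncated ROI coordinate block")
        xs = np.frombuffer(data[64 : 64 + 2 * n_coords], dtype=">i2").astype(float) + left
        ys = np.frombuffer(data[64 + 2 * n_coords : end], dtype=">i2").astype(float) + top
        verts = np.column_stack([xs, ys])

    return verts, (position - 1) if position > 0 else None


def encode_roi(vertices, slice_1based: int = 0) -> bytes:
    """Encode a polygon as an ImageJ .roi blob; slice 0 marks an untagged ROI."""
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("need an (n >= 3, 2) vertex array")
    xs = np.round(verts[:, 0]).astype(int)
    ys = np.round(verts[:, 1]).astype(int)
    left, top = int(xs.min()), int(ys.min())
    right, bottom = int(xs.max()), int(ys.max())
    header = bytearray(64)
    header[:4] = _MAGIC
    struct.pack_into(">h", header, 4, _VERSION)
    header[6] = POLYGON
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, len(verts))
    struct.pack_into(">i", header, 56, int(slice_1based))
    body = (xs - left).astype(">i2").tobytes() + (ys - top).astype(">i2").tobytes()
    return bytes(header) + body


def _slice_from_name(name: str) -> int | None:
    """0-based slice from an ROI-manager file name like '0003-0120-0450.roi'."""
    stem = Path(name).stem
    parts = stem.split("-")
    if len(parts) >= 3 and all(p.isdigit() for p in parts):
        return int(parts[0]) - 1
    return None


def read_roi_file(path) -> tuple[np.ndarray, int | None]:
    """Read a single .roi file from disk."""
    return decode_roi(Path(path).read_bytes())


def read_roi_zip(path) -> list[tuple[np.ndarray, int | None]]:
    """Read every .roi entry of a zip, resolving slices from names or headers."""
    out = []
    with zipfile.ZipFile(path) as zf:
        for name in sorted(zf.namelist()):
            if not name.lower().endswith(".roi"):
                continue
            verts, z = decode_roi(zf.read(name))
            if z is None:
                z = _slice_from_name(name)
            out.append((verts, z))
    if not out:
        raise ValueError(f"{path}: zip contains no .roi entries")
    return out


def write_roi_zip(path, rois: list[tuple[np.ndarray, int | None]]) -> None:
    """Write (vertices, 0-based slice or None) pairs as an ImageJ ROI zip."""
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for i, (verts, z) in enumerate(rois):
            if z is None:
                name, pos = f"roi_{i:04d}.roi", 0
            else:
                name, pos = f"{z + 1:04d}-{i:04d}-0000.roi", z + 1
            zf.writestr(name, encode_roi(verts, pos))
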