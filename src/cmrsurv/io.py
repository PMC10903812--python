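"""File ingest and the portable array container.

PNG (long-axis LGE) is read through Pillow. Cine/LGE video ingest uses a
self-contained uncompressed RIFF/AVI reader-writer (8-bit palettized or
24-bit BI_RGB frames): lossless, codec-free, so encode/decode round trips
are bit-exact and tests never depend on an external codec.

The canonical on-disk form for a cohort is the *portable array container*:
a compressed ``.npz`` of homogenized tensors and masks plus a JSON sidecar
recording dimensions, slice/time ordering conventions and per-patient
native dims. PNG/AVI are ingest formats only.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .images import (
    HomogenizedBundle,
    ImageLAx,
    TargetDims,
    VideoLAx,
)


class FormatError(ValueError):
    """Raised for unreadable or undecodable input files."""


# ---------------------------------------------------------------------------
# PNG
# ---------------------------------------------------------------------------

def load_lax_image(path, plane_id: str) -> ImageLAx:
    """Read an 8-bit grayscale or RGB PNG into a [0, 1] long-axis image.

    RGB is collapsed to luminance as the unweighted mean of channels
    (sources are grayscale stored as RGB, so any convention coincides).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    try:
        with Image.open(path) as img:
            arr = np.asarray(img)
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise FormatError(f"cannot decode PNG {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    if arr.dtype == np.uint16:
        arr = arr.astype(np.float64) / 65535.0
    else:
        arr = arr.astype(np.float64) / 255.0
    return ImageLAx(pixels=arr, plane_id=plane_id)


# ---------------------------------------------------------------------------
# Uncompressed AVI (RIFF) — lossless 8-bit grayscale frames
# ---------------------------------------------------------------------------

def _chunk(fourcc: bytes, payload: bytes) -> bytes:
    pad = b"\x00" if len(payload) % 2 else b""
    return fourcc + struct.pack("<I", len(payload)) + payload + pad


def _list(fourcc: bytes, payload: bytes) -> bytes:
    return _chunk(b"LIST", fourcc + payload)


def write_avi(path, frames: np.ndarray, fps: int = 25) -> None:
    """Write (T, H, W) uint8 frames as an uncompressed 8-bit grayscale AVI.

    Frames are stored as bottom-up BI_RGB DIBs with a 256-entry grayscale
    palette; rows are padded to 4-byte boundaries per the DIB contract.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.dtype != np.uint8:
        raise FormatError("write_avi expects (T, H, W) uint8 frames")
    n_frames, height, width = frames.shape
    row_bytes = (width + 3) & ~3
    frame_bytes = row_bytes * height

    avih = struct.pack(
        "<14I",
        1_000_000 // fps,        # microseconds per frame
        frame_bytes * fps,       # max bytes/sec
        0,                       # padding granularity
        0x10,                    # AVIF_HASINDEX
        n_frames, 0, 1, frame_bytes,
        width, height, 0, 0, 0, 0,
    )
    strh = (
        b"vids" + b"DIB " + struct.pack("<10I", 0, 0, 0, 1, fps, 0, n_frames,
                                        frame_bytes, 0xFFFFFFFF, 0)
        + struct.pack("<4h", 0, 0, width, height)
    )
    palette = b"".join(struct.pack("<4B", v, v, v, 0) for v in range(256))
    strf = struct.pack("<IiiHHIIiiII", 40, width, height, 1, 8, 0,
                       frame_bytes, 0, 0, 256, 0) + palette

    movi_payload = b"movi"
    index_entries = []
    offset = 4  # relative to start of 'movi' fourcc
    for t in range(n_frames):
        dib = np.zeros((height, row_bytes), dtype=np.uint8)
        dib[:, :width] = frames[t][::-1]  # bottom-up row order
        data = _chunk(b"00db", dib.tobytes())
        index_entries.append((offset, frame_bytes))
        offset += len(data)
        movi_payload += data

    idx1 = b"".join(
        b"00db" + struct.pack("<3I", 0x10, off, size) for off, size in index_entries
    )
    hdrl = _list(b"hdrl", _chunk(b"avih", avih)
                 + _list(b"strl", _chunk(b"strh", strh) + _chunk(b"strf", strf)))
    riff_payload = b"AVI " + hdrl + _chunk(b"LIST", movi_payload) + _chunk(b"idx1", idx1)
    Path(path).write_bytes(b"RIFF" + struct.pack("<I", len(riff_payload)) + riff_payload)


def _iter_chunks(buf: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc = buf[pos:pos + 4]
        (size,) = struct.unpack_from("<I", buf, pos + 4)
        yield fourcc, pos + 8, size
        pos += 8 + size + (size % 2)


def read_avi(path) -> np.ndarray:
    """Decode an uncompressed AVI into (T, H, W) uint8 grayscale frames.

    Supports 8-bit palettized and 24-bit BI_RGB video streams; anything
    compressed raises :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such video file: {path}")
    buf = path.read_bytes()
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise FormatError(f"{path} is not a RIFF/AVI file")

    bmp = None
    palette = None
    frames_raw = []

    def walk(start, end):
        nonlocal bmp, palette
        for fourcc, data_off, size in _iter_chunks(buf, start, end):
            if fourcc == b"LIST":
                walk(data_off + 4, data_off + size)
            elif fourcc == b"strf":
                bmp = struct.unpack_from("<IiiHHIIiiII", buf, data_off)
                n_colors = bmp[9] or (256 if bmp[4] == 8 else 0)
                pal_off = data_off + 40
                if n_colors:
                    pal = np.frombuffer(buf[pal_off:pal_off + 4 * n_colors], dtype=np.uint8)
                    palette = pal.reshape(-1, 4)[:, :3][:, ::-1]  # BGR0 -> RGB
            elif fourcc in (b"00db", b"00dc"):
                frames_raw.append(buf[data_off:data_off + size])

    walk(12, len(buf))
    if bmp is None:
        raise FormatError(f"{path}: no stream format (strf) header found")
    if not frames_raw:
        raise FormatError(f"{path}: stream contains zero frames")
    width, height, bitcount, compression = bmp[1], abs(bmp[2]), bmp[4], bmp[5]
    bottom_up = bmp[2] > 0
    if compression != 0:
        raise FormatError(
            f"{path}: compressed AVI streams are not supported (biCompression={compression})"
        )

    out = np.empty((len(frames_raw), height, width), dtype=np.uint8)
    if bitcount == 8:
        row_bytes = (width + 3) & ~3
        lut = (palette.mean(axis=1).round().astype(np.uint8)
               if palette is not None else np.arange(256, dtype=np.uint8))
        for t, raw in enumerate(frames_raw):
            rows = np.frombuffer(raw[: row_bytes * height], dtype=np.uint8)
            img = lut[rows.reshape(height, row_bytes)[:, :width]]
            out[t] = img[::-1] if bottom_up else img
    elif bitcount == 24:
        row_bytes = (width * 3 + 3) & ~3
        for t, raw in enumerate(frames_raw):
            rows = np.frombuffer(raw[: row_bytes * height], dtype=np.uint8)
            bgr = rows.reshape(height, row_bytes)[:, : width * 3].reshape(height, width, 3)
            img = bgr.astype(np.float64).mean(axis=2).round().astype(np.uint8)
            out[t] = img[::-1] if bottom_up else img
    else:
        raise FormatError(f"{path}: unsupported bit depth {bitcount}")
    return out


def load_avi_video(path, plane_id: str = "4-chamber") -> VideoLAx:
    """Read an AVI into a [0, 1] long-axis cine video (H, W, T)."""
    frames = read_avi(path)  # (T, H, W)
    pixels = frames.astype(np.float64).transpose(1, 2, 0) / 255.0
    return VideoLAx(pixels=pixels, plane_id=plane_id)


# ---------------------------------------------------------------------------
# Portable array container
# ---------------------------------------------------------------------------

_CONTAINER_META = {
    "slice_order": "base->apex, then LAx planes 2ch/3ch/4ch",
    "time_origin": "first stored frame",
    "axis_order_cine": "(H, W, S+3, T)",
    "axis_order_lge": "(H, W, S+3)",
    "null_value": 0.0,
}


def save_cohort_container(path, homogenized, native_dims=None) -> None:
    """Write homogenized bundles as compressed arrays + a JSON sidecar."""
    path = Path(path)
    homogenized = list(homogenized)
    arrays = {}
    for hb in homogenized:
        arrays[f"{hb.patient_id}__cine"] = hb.cine_tensor
        arrays[f"{hb.patient_id}__lge"] = hb.lge_tensor
        arrays[f"{hb.patient_id}__mask_cine"] = hb.valid_mask_cine.astype(np.uint8)
        arrays[f"{hb.patient_id}__mask_lge"] = hb.valid_mask_lge.astype(np.uint8)
    np.savez_compressed(path, **arrays)
    t = homogenized[0].targets
    sidecar = {
        "targets": {"H": t.H, "W": t.W, "S": t.S, "T": t.T},
        "patients": [hb.patient_id for hb in homogenized],
        "native_dims": native_dims or {},
        "conventions": _CONTAINER_META,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_cohort_container(path):
    """Read a portable container back into :class:`HomogenizedBundle` objects."""
    path = Path(path)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    sidecar = json.loads(npz_path.with_suffix(".json").read_text())
    targets = TargetDims(**sidecar["targets"])
    out = []
    with np.load(npz_path) as data:
        for pid in sidecar["patients"]:
            out.append(HomogenizedBundle(
                patient_id=pid,
                cine_tensor=data[f"{pid}__cine"],
                lge_tensor=data[f"{pid}__lge"],
                valid_mask_cine=data[f"{pid}__mask_cine"].astype(np.float64),
                valid_mask_lge=data[f"{pid}__mask_lge"].astype(np.float64),
                targets=targets,
            ))
    return out, sidecar
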