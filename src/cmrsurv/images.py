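"""Containers and homogenization for heterogeneous cardiac-MR inputs.

Four input families are handled, distinguished by dimensionality:

* long-axis LGE images — 2D (height x width),
* long-axis cine videos — 2D + time,
* short-axis LGE hyperimages — 3D (height x width x slice),
* short-axis cine hypervideos — 3D + time.

Per-patient slice and frame counts vary (retrospective acquisitions), so
before a cohort can be batched every bundle is *homogenized*: arrays are
zero-padded ("null" frames/slices) up to cohort-wide maximum dimensions,
never resampled or cropped, and a binary validity mask records which
entries are real data. The three long-axis planes are appended as extra
slice positions after the short-axis stack so each modality collapses to
a single fixed-shape tensor.

Array conventions: intensities are floats in [0, 1]; axis order is
(H, W[, S][, T]) with slices ordered base -> apex and time starting at
the first stored frame.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

LAX_PLANES = ("2-chamber", "3-chamber", "4-chamber")


class DimensionError(ValueError):
    """Raised when array dimensions violate a container's contract."""


def _check_intensities(pixels: np.ndarray, ndim: int, name: str) -> np.ndarray:
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != ndim:
        raise DimensionError(f"{name} expects a {ndim}-d array, got shape {pixels.shape}")
    if any(s < 1 for s in pixels.shape):
        raise DimensionError(f"{name} has an empty axis: shape {pixels.shape}")
    if not np.isfinite(pixels).all():
        raise ValueError(f"{name} contains non-finite intensities")
    if pixels.min() < 0.0 or pixels.max() > 1.0:
        raise ValueError(
            f"{name} intensities must lie in [0, 1], got range "
            f"[{pixels.min():.4g}, {pixels.max():.4g}]"
        )
    return pixels


def _check_plane(plane_id: str) -> str:
    if plane_id not in LAX_PLANES:
        raise ValueError(f"plane_id must be one of {LAX_PLANES}, got {plane_id!r}")
    return plane_id


@dataclass(frozen=True)
class ImageLAx:
    """A single long-axis LGE image: (H, W) intensities in [0, 1]."""

    pixels: np.ndarray
    plane_id: str

    def __post_init__(self):
        object.__setattr__(self, "pixels", _check_intensities(self.pixels, 2, "ImageLAx"))
        _check_plane(self.plane_id)


@dataclass(frozen=True)
class VideoLAx:
    """A long-axis cine video: (H, W, T), one frame per cardiac phase."""

    pixels: np.ndarray
    plane_id: str

    def __post_init__(self):
        object.__setattr__(self, "pixels", _check_intensities(self.pixels, 3, "VideoLAx"))
        _check_plane(self.plane_id)

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[2]


@dataclass(frozen=True)
class HyperImageSAx:
    """A short-axis LGE stack: (H, W, S), slices ordered base -> apex."""

    pixels: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "pixels", _check_intensities(self.pixels, 3, "HyperImageSAx"))

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[2]


@dataclass(frozen=True)
class HyperVideoSAx:
    """A short-axis cine stack: (H, W, S, T)."""

    pixels: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "pixels", _check_intensities(self.pixels, 4, "HyperVideoSAx"))

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[2]

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[3]


@dataclass(frozen=True)
class PatientImagingBundle:
    """All four imaging families for one patient, native (pre-padding) dims."""

    patient_id: str
    cine_sax: HyperVideoSAx
    cine_lax: tuple
    lge_sax: HyperImageSAx
    lge_lax: tuple

    def __post_init__(self):
        object.__setattr__(self, "cine_lax", tuple(self.cine_lax))
        object.__setattr__(self, "lge_lax", tuple(self.lge_lax))
        if len(self.cine_lax) != 3 or len(self.lge_lax) != 3:
            raise DimensionError("a bundle requires exactly 3 long-axis planes per modality")

    def native_dims(self) -> dict:
        """Maximum native extent over this patient's arrays, per axis."""
        arrays = (
            [self.cine_sax.pixels, self.lge_sax.pixels]
            + [v.pixels for v in self.cine_lax]
            + [im.pixels for im in self.lge_lax]
        )
        h = max(a.shape[0] for a in arrays)
        w = max(a.shape[1] for a in arrays)
        s = max(self.cine_sax.n_slices, self.lge_sax.n_slices)
        t = max([self.cine_sax.n_frames] + [v.n_frames for v in self.cine_lax])
        return {"H": h, "W": w, "S": s, "T": t}


@dataclass(frozen=True)
class TargetDims:
    """Fixed cohort-wide dimensions every bundle is padded up to."""

    H: int
    W: int
    S: int
    T: int

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 1:
                raise DimensionError(f"target {f.name} must be >= 1")


@dataclass(frozen=True)
class HomogenizedBundle:
    """Fixed-shape tensors + validity masks for one patient.

    ``cine_tensor``: (H, W, S+3, T) — S short-axis slices then the three
    long-axis planes along the slice axis. ``lge_tensor``: (H, W, S+3).
    Masks are 1 where the entry came from source data, 0 where padded.
    """

    patient_id: str
    cine_tensor: np.ndarray
    lge_tensor: np.ndarray
    valid_mask_cine: np.ndarray
    valid_mask_lge: np.ndarray
    targets: TargetDims

    def __post_init__(self):
        if self.cine_tensor.shape != self.valid_mask_cine.shape:
            raise DimensionError("cine tensor and mask shapes differ")
        if self.lge_tensor.shape != self.valid_mask_lge.shape:
            raise DimensionError("lge tensor and mask shapes differ")
        t = self.targets
        if self.cine_tensor.shape != (t.H, t.W, t.S + 3, t.T):
            raise DimensionError(
                f"cine tensor shape {self.cine_tensor.shape} != "
                f"targets {(t.H, t.W, t.S + 3, t.T)}"
            )
        if self.lge_tensor.shape != (t.H, t.W, t.S + 3):
            raise DimensionError("lge tensor shape inconsistent with targets")


def assemble_sax_hypervideo(slice_videos) -> HyperVideoSAx:
    """Stack per-slice (H, W, T) cine videos, ordered base -> apex, into 4D.

    All slices must share H, W and T; heterogeneity across *patients* is
    handled later by :func:`homogenize_bundle`, not here.
    """
    arrays = [np.asarray(v, dtype=np.float64) for v in slice_videos]
    if not arrays:
        raise DimensionError("need at least one slice video")
    ref = arrays[0].shape
    for k, a in enumerate(arrays):
        if a.ndim != 3:
            raise DimensionError(f"slice {k} is not a (H, W, T) array: shape {a.shape}")
        if a.shape != ref:
            raise DimensionError(
                f"slice {k} has shape {a.shape}, expected {ref} (all slices "
                "of one study must share H, W, T)"
            )
    return HyperVideoSAx(np.stack(arrays, axis=2))


def _pad_to(arr: np.ndarray, shape) -> np.ndarray:
    """Zero-pad ``arr`` at the high end of each axis up to ``shape``."""
    if any(t < s for s, t in zip(arr.shape, shape)):
        raise DimensionError(
            f"cannot pad {arr.shape} to smaller target {tuple(shape)}: "
            "homogenization pads, never crops"
        )
    out = np.zeros(shape, dtype=arr.dtype)
    out[tuple(slice(0, s) for s in arr.shape)] = arr
    return out


def cohort_target_dims(bundles) -> TargetDims:
    """Per-axis maxima over a cohort's native dimensions."""
    dims = [b.native_dims() for b in bundles]
    return TargetDims(
        H=max(d["H"] for d in dims),
        W=max(d["W"] for d in dims),
        S=max(d["S"] for d in dims),
        T=max(d["T"] for d in dims),
    )


def homogenize_bundle(bundle: PatientImagingBundle, targets: TargetDims) -> HomogenizedBundle:
    """Pad one patient's arrays to fixed cohort dimensions with null entries.

    Real voxels are kept bit-exactly at origin-anchored positions; zeros
    are appended at the high end of every axis. No interpolation or
    resampling takes place. The long-axis planes occupy slice positions
    S..S+2 of the combined tensor (2-, 3-, 4-chamber order for cine;
    same for LGE).
    """
    t = targets
    cine = np.zeros((t.H, t.W, t.S + 3, t.T), dtype=np.float64)
    mcine = np.zeros_like(cine)
    sax = bundle.cine_sax.pixels
    cine[: sax.shape[0], : sax.shape[1], : sax.shape[2], : sax.shape[3]] = _pad_check(sax, (t.H, t.W, t.S, t.T))
    mcine[: sax.shape[0], : sax.shape[1], : sax.shape[2], : sax.shape[3]] = 1.0
    for k, video in enumerate(bundle.cine_lax):
        v = video.pixels
        _pad_check(v, (t.H, t.W, t.T))
        cine[: v.shape[0], : v.shape[1], t.S + k, : v.shape[2]] = v
        mcine[: v.shape[0], : v.shape[1], t.S + k, : v.shape[2]] = 1.0

    lge = np.zeros((t.H, t.W, t.S + 3), dtype=np.float64)
    mlge = np.zeros_like(lge)
    lsax = bundle.lge_sax.pixels
    _pad_check(lsax, (t.H, t.W, t.S))
    lge[: lsax.shape[0], : lsax.shape[1], : lsax.shape[2]] = lsax
    mlge[: lsax.shape[0], : lsax.shape[1], : lsax.shape[2]] = 1.0
    for k, image in enumerate(bundle.lge_lax):
        im = image.pixels
        _pad_check(im, (t.H, t.W))
        lge[: im.shape[0], : im.shape[1], t.S + k] = im
        mlge[: im.shape[0], : im.shape[1], t.S + k] = 1.0

    return HomogenizedBundle(
        patient_id=bundle.patient_id,
        cine_tensor=cine,
        lge_tensor=lge,
        valid_mask_cine=mcine,
        valid_mask_lge=mlge,
        targets=targets,
    )


def _pad_check(arr: np.ndarray, target_shape):
    if any(ts < s for s, ts in zip(arr.shape, target_shape)):
        raise DimensionError(
            f"native shape {arr.shape} exceeds targets {tuple(target_shape)}: "
            "homogenization pads, never crops"
        )
    return arr


def homogenize_cohort(bundles, targets: TargetDims | None = None):
    """Homogenize every bundle to shared targets (cohort maxima by default)."""
    bundles = list(bundles)
    if targets is None:
        targets = cohort_target_dims(bundles)
    return [homogenize_bundle(b, targets) for b in bundles], targets
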