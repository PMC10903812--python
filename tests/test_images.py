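"""Containers, homogenization and file ingest."""

import numpy as np
import pytest
from PIL import Image

from cmrsurv.images import (
    DimensionError,
    HyperImageSAx,
    HyperVideoSAx,
    ImageLAx,
    PatientImagingBundle,
    TargetDims,
    VideoLAx,
    assemble_sax_hypervideo,
    cohort_target_dims,
    homogenize_bundle,
    homogenize_cohort,
)
from cmrsurv.io import (
    FormatError,
    load_avi_video,
    load_cohort_container,
    load_lax_image,
    read_avi,
    save_cohort_container,
    write_avi,
)


def _bundle(rng, h=6, w=6, s=2, t=3, pid="P0"):
    return PatientImagingBundle(
        patient_id=pid,
        cine_sax=HyperVideoSAx(rng.uniform(0, 1, (h, w, s, t))),
        cine_lax=[VideoLAx(rng.uniform(0, 1, (h, w, t)), p)
                  for p in ("2-chamber", "3-chamber", "4-chamber")],
        lge_sax=HyperImageSAx(rng.uniform(0, 1, (h, w, s))),
        lge_lax=[ImageLAx(rng.uniform(0, 1, (h, w)), p)
                 for p in ("2-chamber", "3-chamber", "4-chamber")],
    )


class TestContainers:
    def test_intensity_range_enforced(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            ImageLAx(np.full((4, 4), 1.5), "2-chamber")

    def test_bundle_requires_three_lax_planes(self, rng):
        b = _bundle(rng)
        with pytest.raises(DimensionError):
            PatientImagingBundle(patient_id="X", cine_sax=b.cine_sax,
                                 cine_lax=b.cine_lax[:2], lge_sax=b.lge_sax,
                                 lge_lax=b.lge_lax)


class TestPngIngest:
    @pytest.mark.parametrize("value,expected", [(0, 0.0), (255, 1.0)])
    def test_constant_images_hit_normalization_bounds(self, tmp_path, value, expected):
        p = tmp_path / "c.png"
        Image.fromarray(np.full((8, 8), value, dtype=np.uint8), mode="L").save(p)
        img = load_lax_image(p, "2-chamber")
        assert np.all(img.pixels == expected)

    def test_checkerboard_matches_independent_encoding(self, tmp_path):
        """A 16x16 checkerboard written by a PNG encoder the loader does
        not share code with must decode pixel-by-pixel to value/255."""
        board = np.indices((16, 16)).sum(axis=0) % 2 * 200 + 30
        board = board.astype(np.uint8)
        p = tmp_path / "b.png"
        _write_png_gray(p, board)
        img = load_lax_image(p, "3-chamber")
        np.testing.assert_array_equal(img.pixels, board / 255.0)

    def test_rgb_collapses_to_channel_mean(self, tmp_path):
        rgb = np.zeros((4, 4, 3), dtype=np.uint8)
        rgb[..., 0], rgb[..., 1], rgb[..., 2] = 30, 60, 90
        p = tmp_path / "rgb.png"
        Image.fromarray(rgb, mode="RGB").save(p)
        img = load_lax_image(p, "4-chamber")
        assert np.allclose(img.pixels, 60 / 255.0)

    def test_unreadable_file_raises_named_format_error(self, tmp_path):
        p = tmp_path / "junk.png"
        p.write_bytes(b"not a png at all")
        with pytest.raises(FormatError, match="junk.png"):
            load_lax_image(p, "2-chamber")


class TestAviIngest:
    def test_single_constant_frame(self, tmp_path):
        p = tmp_path / "c.avi"
        write_avi(p, np.full((1, 8, 8), 128, dtype=np.uint8))
        video = load_avi_video(p, "2-chamber")
        assert video.pixels.shape == (8, 8, 1)
        assert np.all(video.pixels == 128 / 255.0)

    def test_frame_count_and_order_preserved(self, tmp_path):
        frames = np.stack([np.full((4, 4), 10 * t, dtype=np.uint8) for t in range(5)])
        p = tmp_path / "o.avi"
        write_avi(p, frames)
        video = load_avi_video(p, "3-chamber")
        assert video.n_frames == 5
        for t in range(5):
            assert np.all(video.pixels[:, :, t] == 10 * t / 255.0)

    def test_lossless_round_trip_bit_exact(self, tmp_path, rng):
        frames = rng.integers(0, 256, (7, 11, 13), dtype=np.uint8)
        p = tmp_path / "r.avi"
        write_avi(p, frames)
        np.testing.assert_array_equal(read_avi(p), frames)

    def test_corrupt_stream_raises(self, tmp_path):
        p = tmp_path / "bad.avi"
        p.write_bytes(b"RIFF\x04\x00\x00\x00AVI ")
        with pytest.raises(FormatError):
            read_avi(p)


class TestAssembly:
    def test_single_slice_is_identity(self, rng):
        v = rng.uniform(0, 1, (5, 5, 4))
        hv = assemble_sax_hypervideo([v])
        assert hv.n_slices == 1
        np.testing.assert_array_equal(hv.pixels[:, :, 0, :], v)

    def test_slice_axis_ordering(self):
        slices = [np.full((3, 3, 2), v) for v in (0.0, 0.5, 1.0)]
        hv = assemble_sax_hypervideo(slices)
        np.testing.assert_array_equal(hv.pixels[0, 0, :, 0], [0.0, 0.5, 1.0])

    def test_mixed_frame_counts_rejected(self):
        with pytest.raises(DimensionError, match="slice 1"):
            assemble_sax_hypervideo([np.zeros((3, 3, 10)), np.zeros((3, 3, 12))])


class TestHomogenization:
    def test_trailing_null_phases_and_mask(self, rng):
        b = _bundle(rng, t=3)
        hb = homogenize_bundle(b, TargetDims(H=6, W=6, S=2, T=8))
        assert hb.cine_tensor.shape == (6, 6, 5, 8)
        # every real voxel column carries 3 valid phases, padding is zero
        assert np.all(hb.valid_mask_cine[:, :, :, 3:] == 0)
        np.testing.assert_array_equal(hb.valid_mask_cine[:, :, 0, :].sum(axis=-1),
                                      np.full((6, 6), 3))
        assert np.all(hb.cine_tensor[:, :, :, 3:] == 0)

    def test_native_equal_targets_is_identity(self, rng):
        b = _bundle(rng, h=6, w=6, s=2, t=3)
        hb = homogenize_bundle(b, TargetDims(H=6, W=6, S=2, T=3))
        np.testing.assert_array_equal(hb.cine_tensor[:, :, :2, :], b.cine_sax.pixels)
        assert np.all(hb.valid_mask_cine == 1)
        assert np.all(hb.valid_mask_lge == 1)

    def test_cropping_rejected(self, rng):
        b = _bundle(rng, s=4)
        with pytest.raises(DimensionError, match="pads, never crops"):
            homogenize_bundle(b, TargetDims(H=6, W=6, S=3, T=3))

    def test_padding_conservation_and_no_interpolation(self, rng):
        """Masked-valid voxels reproduce the native voxels exactly: equal
        sums (conservation) and equal value multisets (no interpolation)."""
        for _ in range(5):
            h, w, s, t = rng.integers(3, 7, 4)
            b = _bundle(rng, h=h, w=w, s=s, t=t)
            hb = homogenize_bundle(b, TargetDims(H=h + 2, W=w + 1, S=s + 3, T=t + 2))
            native = np.concatenate(
                [b.cine_sax.pixels.ravel()] + [v.pixels.ravel() for v in b.cine_lax])
            kept = hb.cine_tensor[hb.valid_mask_cine == 1]
            assert np.isclose(kept.sum(), native.sum())
            np.testing.assert_array_equal(np.sort(kept), np.sort(native))
            assert np.all(hb.cine_tensor[hb.valid_mask_cine == 0] == 0)

    def test_idempotence_on_cohort_maxima(self, rng):
        bundles = [_bundle(rng, s=int(s), t=int(t), pid=f"P{i}")
                   for i, (s, t) in enumerate([(2, 3), (4, 5), (3, 4)])]
        homog, targets = homogenize_cohort(bundles)
        assert targets == cohort_target_dims(bundles)
        again = [homogenize_bundle(b, targets) for b in bundles]
        for a, b2 in zip(homog, again):
            np.testing.assert_array_equal(a.cine_tensor, b2.cine_tensor)
            np.testing.assert_array_equal(a.valid_mask_lge, b2.valid_mask_lge)


class TestContainerRoundTrip:
    def test_cohort_container_round_trip(self, tmp_path, small_cohort):
        _, (bundles, _, _, _) = small_cohort
        homog, targets = homogenize_cohort(bundles)
        path = tmp_path / "cohort.npz"
        save_cohort_container(path, homog)
        back, sidecar = load_cohort_container(path)
        assert sidecar["targets"] == {"H": targets.H, "W": targets.W,
                                      "S": targets.S, "T": targets.T}
        for a, b in zip(homog, back):
            assert a.patient_id == b.patient_id
            np.testing.assert_array_equal(a.cine_tensor, b.cine_tensor)
            np.testing.assert_array_equal(a.valid_mask_cine, b.valid_mask_cine)


def _write_png_gray(path, arr):
    """Minimal independent PNG encoder (8-bit grayscale, filter 0)."""
    import struct
    import zlib

    h, w = arr.shape
    raw = b"".join(b"\x00" + arr[r].tobytes() for r in range(h))

    def chunk(tag, data):
        body = tag + data
        return struct.pack(">I", len(data)) + body + struct.pack(">I", zlib.crc32(body))

    ihdr = struct.pack(">IIBBBBB", w, h, 8, 0, 0, 0, 0)
    png = (b"\x89PNG\r\n\x1a\n" + chunk(b"IHDR", ihdr)
           + chunk(b"IDAT", zlib.compress(raw)) + chunk(b"IEND", b""))
    path.write_bytes(png)
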