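"""Manifest parsing, image loading/normalization, and summary CSV I/O."""

import numpy as np
import pytest

from canopyspec.errors import (
    ChannelError,
    ManifestFormatError,
    ManifestValidationError,
    StackError,
)
from canopyspec.spectral_io import (
    SUMMARY_COLUMNS,
    load_stack,
    parse_manifest,
    read_summaries,
    write_channel_image,
    write_summaries,
)
from canopyspec.summary_viz import CanopySummary
from canopyspec.synthetic import write_manifest, write_scene


def _write_manifest(tmp_path, rows):
    path = tmp_path / "manifest.csv"
    write_manifest(rows, path)
    return path


def _row(plant="p1", tp="t1", channel="red", file="img.png", treatment="1"):
    return {
        "plant_id": plant,
        "timepoint": tp,
        "treatment": treatment,
        "channel": channel,
        "file": file,
    }


class TestParseManifest:
    def test_five_channel_manifest_parses(self, tmp_path):
        rows = [_row(channel=c, file=f"{c}.png") for c in ("red", "green", "blue", "nir", "chlf")]
        manifest = parse_manifest(_write_manifest(tmp_path, rows))
        assert len(manifest.records) == 5
        assert manifest.stacks() == [("p1", "t1")]

    def test_duplicate_triple_rejected_with_named_triple(self, tmp_path):
        rows = [_row(), _row(file="other.png")]
        with pytest.raises(ManifestValidationError, match=r"\('p1', 't1', 'red'\)"):
            parse_manifest(_write_manifest(tmp_path, rows))

    def test_unknown_channel_rejected_listing_allowed_labels(self, tmp_path):
        rows = [_row(channel="red"), dict(_row(channel="red"), channel="uv")]
        with pytest.raises(ManifestValidationError, match="red, green, blue, nir, chlf"):
            parse_manifest(_write_manifest(tmp_path, rows))

    def test_missing_file_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("plant_id,timepoint,treatment,channel\np1,t1,1,red\n")
        with pytest.raises(ManifestFormatError, match="file"):
            parse_manifest(path)

    def test_missing_manifest_file(self, tmp_path):
        with pytest.raises(ManifestFormatError):
            parse_manifest(tmp_path / "nope.csv")


class TestLoadStack:
    def test_8bit_full_scale_normalizes_to_one(self, tmp_path):
        write_channel_image(tmp_path / "red.png", np.ones((4, 4)), bit_depth=8)
        manifest = parse_manifest(_write_manifest(tmp_path, [_row(file="red.png")]))
        stack = load_stack(manifest, "p1", "t1")
        assert np.all(stack.channel("red") == 1.0)
        assert stack.bit_depth_in == 8

    def test_16bit_midpoint_value(self, tmp_path):
        import imageio.v3 as iio

        arr = np.full((4, 4), 32767, dtype=np.uint16)
        iio.imwrite(tmp_path / "nir.png", arr)
        manifest = parse_manifest(
            _write_manifest(tmp_path, [_row(channel="nir", file="nir.png")])
        )
        stack = load_stack(manifest, "p1", "t1")
        assert stack.channel("nir")[0, 0] == pytest.approx(32767 / 65535)
        assert stack.bit_depth_in == 16

    @pytest.mark.parametrize("bit_depth", [8, 16])
    def test_generated_scene_round_trips_within_quantization(
        self, tmp_path, bit_depth
    ):
        """Write a synthetic scene to disk, reload, compare to the arrays."""
        from canopyspec.synthetic import SyntheticSceneSpec, generate_scene

        spec = SyntheticSceneSpec(height=48, width=48, bit_depth=bit_depth, seed=3)
        stack, _ = generate_scene(spec)
        rows = write_scene(stack, tmp_path)
        manifest = parse_manifest(_write_manifest(tmp_path, rows))
        reloaded = load_stack(manifest, stack.plant_id, stack.timepoint)
        step = 1.0 / (2**bit_depth - 1)
        for name, values in stack.channels.items():
            assert np.max(np.abs(reloaded.channel(name) - values)) <= step
        assert reloaded.treatment == stack.treatment

    def test_dimension_mismatch_is_stack_error(self, tmp_path):
        write_channel_image(tmp_path / "red.png", np.zeros((4, 4)))
        write_channel_image(tmp_path / "nir.png", np.zeros((5, 5)))
        manifest = parse_manifest(
            _write_manifest(
                tmp_path, [_row(file="red.png"), _row(channel="nir", file="nir.png")]
            )
        )
        with pytest.raises(StackError, match="dimensions"):
            load_stack(manifest, "p1", "t1")

    def test_rgb_file_is_channel_error(self, tmp_path):
        import imageio.v3 as iio

        iio.imwrite(tmp_path / "rgb.png", np.zeros((4, 4, 3), dtype=np.uint8))
        manifest = parse_manifest(_write_manifest(tmp_path, [_row(file="rgb.png")]))
        with pytest.raises(ChannelError, match="grayscale"):
            load_stack(manifest, "p1", "t1")

    def test_normalization_is_monotone(self, tmp_path):
        raw = np.arange(16, dtype=np.uint8).reshape(4, 4)
        import imageio.v3 as iio

        iio.imwrite(tmp_path / "red.png", raw)
        manifest = parse_manifest(_write_manifest(tmp_path, [_row(file="red.png")]))
        norm = load_stack(manifest, "p1", "t1").channel("red").ravel()
        assert np.all(np.diff(norm) > 0)


def _summary(i=0):
    return CanopySummary(
        plant_id=f"p{i}",
        timepoint="t1",
        treatment=float(i % 6),
        canopy_size_px=1000 + i,
        ndvi_mean=0.123456789 + i * 1e-4,
        ndvi_sd=0.0123456,
        aci_mean=0.42,
        aci_sd=0.05,
        chlf_mean=0.7,
    )


class TestWriteSummaries:
    def test_single_summary_gives_header_plus_row(self, tmp_path):
        path = tmp_path / "s.csv"
        write_summaries([_summary()], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 2
        assert lines[0] == ",".join(SUMMARY_COLUMNS)

    def test_round_trip_preserves_floats_to_6_significant_digits(self, tmp_path):
        path = tmp_path / "s.csv"
        originals = [_summary(i) for i in range(5)]
        write_summaries(originals, path)
        df = read_summaries(path)
        for i, s in enumerate(originals):
            assert df.loc[i, "ndvi_mean"] == pytest.approx(s.ndvi_mean, rel=1e-6)
            assert df.loc[i, "canopy_size_px"] == s.canopy_size_px

    def test_full_experiment_row_count(self, tmp_path):
        path = tmp_path / "s.csv"
        write_summaries([_summary(i) for i in range(48)], path)
        assert len(path.read_text().strip().splitlines()) == 49

    def test_empty_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_summaries([], tmp_path / "s.csv")

    def test_undefined_means_written_as_empty_fields(self, tmp_path):
        s = CanopySummary("p", "t", None, 0)
        path = tmp_path / "s.csv"
        write_summaries([s], path)
        row = path.read_text().strip().splitlines()[1]
        assert row == "p,t,,0,,,,,"


class TestMultiPageTiff:
    def test_channels_loaded_from_pages_in_manifest_order(self, tmp_path):
        import tifffile

        pages = np.stack(
            [np.full((6, 6), v, dtype=np.uint8) for v in (10, 20, 30)]
        )
        tifffile.imwrite(tmp_path / "stack.tif", pages)
        rows = [
            _row(channel=c, file="stack.tif")
            for c in ("red", "nir", "chlf")
        ]
        manifest = parse_manifest(_write_manifest(tmp_path, rows))
        stack = load_stack(manifest, "p1", "t1")
        assert stack.channel("red")[0, 0] == pytest.approx(10 / 255)
        assert stack.channel("nir")[0, 0] == pytest.approx(20 / 255)
        assert stack.channel("chlf")[0, 0] == pytest.approx(30 / 255)

    def test_page_count_mismatch_is_stack_error(self, tmp_path):
        import tifffile

        tifffile.imwrite(
            tmp_path / "stack.tif",
            np.zeros((2, 6, 6), dtype=np.uint8),
        )
        rows = [_row(channel=c, file="stack.tif") for c in ("red", "nir", "chlf")]
        manifest = parse_manifest(_write_manifest(tmp_path, rows))
        with pytest.raises(StackError, match="pages"):
            load_stack(manifest, "p1", "t1")

    def test_shared_non_tiff_file_rejected(self, tmp_path):
        write_channel_image(tmp_path / "img.png", np.zeros((4, 4)))
        rows = [_row(channel=c, file="img.png") for c in ("red", "nir")]
        manifest = parse_manifest(_write_manifest(tmp_path, rows))
        with pytest.raises(ManifestValidationError, match="multi-page TIFF"):
            load_stack(manifest, "p1", "t1")
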