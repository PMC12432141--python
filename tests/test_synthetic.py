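import numpy as np
import pytest

from caescreen.errors import ValidationError
from caescreen.preprocess import gaussian_blur
from caescreen.synthetic import (ARTIFACT_KINDS, ArtifactSpec, SceneSpec,
                                 dataset_checksum, default_artifact,
                                 emitter_footprint_radius,
                                 generate_artifact_image, generate_clean_image,
                                 generate_dataset)


class TestCleanScenes:
    def test_noise_free_signal_free_limit_is_constant(self):
        spec = SceneSpec(side=64, n_signals=0, background_mean=100,
                         background_sd=0.0, seed=5)
        img = generate_clean_image(spec)
        assert img.label == "clean"
        assert img.artifact_mask is None
        assert (img.image == 100).all()

    def test_deterministic_for_fixed_seed(self):
        spec = SceneSpec(side=128, n_signals=50, seed=7)
        a = generate_clean_image(spec)
        b = generate_clean_image(spec)
        assert (a.image == b.image).all()
        assert (a.emitters == b.emitters).all()

    def test_different_seeds_differ(self):
        spec = SceneSpec(side=128, n_signals=50)
        a = generate_clean_image(spec.replace(seed=1))
        b = generate_clean_image(spec.replace(seed=2))
        assert (a.image != b.image).any()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_intensity_bounds(self, seed):
        spec = SceneSpec(side=128, n_signals=30, seed=seed)
        img = generate_clean_image(spec).image
        assert img.dtype == np.uint16
        assert img.min() >= 0 and img.max() <= spec.full_scale

    def test_bright_pixels_confined_to_emitter_footprints(self):
        """Pixels above mean + 5 SD of the blurred image sit inside emitter
        footprints, and there are at least as many as emitters (each emitter
        contributes >= 1 bright pixel at these amplitudes)."""
        spec = SceneSpec(side=512, n_signals=50,
                         signal_amplitude_range=(2000, 8000),
                         background_mean=500, background_sd=50, seed=11)
        img = generate_clean_image(spec)
        blurred = gaussian_blur(img.image)
        t = blurred.mean() + 5 * blurred.std()
        bright = blurred >= t  # pixel count check, not the zeroing rule
        n_bright = int(bright.sum())
        # brute-force footprint bookkeeping: mark pixels near any emitter,
        # allowing for the extra spread of the 5x5 preprocessing blur
        r = emitter_footprint_radius(spec.psf_sigma) + 2
        inside = np.zeros_like(bright)
        ys, xs = np.mgrid[:spec.side, :spec.side]
        for cy, cx, _ in img.emitters:
            inside |= (ys - cy) ** 2 + (xs - cx) ** 2 <= r**2
        footprint = (2 * r + 1) ** 2
        assert spec.n_signals <= n_bright <= spec.n_signals * footprint
        assert not (bright & ~inside).any()

    def test_background_statistics_match_spec(self):
        """Signal-free pixels reproduce the configured background mean/SD
        within three standard errors."""
        spec = SceneSpec(side=256, n_signals=10, seed=21)
        img = generate_clean_image(spec)
        r = emitter_footprint_radius(spec.psf_sigma)
        ys, xs = np.mgrid[:spec.side, :spec.side]
        signal = np.zeros(img.image.shape, dtype=bool)
        for cy, cx, _ in img.emitters:
            signal |= (ys - cy) ** 2 + (xs - cx) ** 2 <= r**2
        bg = img.image[~signal].astype(float)
        n = bg.size
        se_mean = spec.background_sd / np.sqrt(n)
        assert abs(bg.mean() - spec.background_mean) < 3 * se_mean
        se_sd = spec.background_sd / np.sqrt(2 * n)
        # rounding to integer counts adds ~1/12 variance, well under 3 SE
        assert abs(bg.std() - spec.background_sd) < 3 * se_sd + 0.1

    def test_poisson_noise_variant(self):
        spec = SceneSpec(side=64, n_signals=0, background_mean=400,
                         noise="poisson", seed=2)
        img = generate_clean_image(spec).image.astype(float)
        assert abs(img.mean() - 400) < 3 * np.sqrt(400 / img.size) * 20
        assert img.std() > 0

    @pytest.mark.parametrize("field,value", [
        ("side", 63), ("side", 62), ("background_mean", -1.0),
        ("n_signals", -1), ("signal_amplitude_range", (100.0, 50.0)),
        ("psf_sigma", 0.0), ("noise", "laplace"),
    ])
    def test_invalid_spec_fields_rejected(self, field, value):
        spec = SceneSpec(side=64).replace(**{field: value})
        with pytest.raises(ValidationError):
            generate_clean_image(spec)

    def test_artifact_spec_present_rejected(self):
        spec = SceneSpec(side=64, artifact=default_artifact("blob", 64))
        with pytest.raises(ValidationError):
            generate_clean_image(spec)


class TestArtifactScenes:
    def test_blob_isolated_on_empty_scene(self):
        spec = SceneSpec(side=128, n_signals=0, background_mean=0,
                         background_sd=0.0, seed=3,
                         artifact=ArtifactSpec("blob", amplitude=6000, extent=40))
        img = generate_artifact_image(spec)
        assert img.label == "artifact"
        inside = img.image[img.artifact_mask]
        outside = img.image[~img.artifact_mask]
        assert inside.max() >= 6000 * 0.5
        assert (outside == 0).all()

    def test_scratch_is_horizontal_band(self):
        spec = SceneSpec(side=512, n_signals=0, background_mean=0,
                         background_sd=0.0, seed=4,
                         artifact=ArtifactSpec("scratch", amplitude=5000,
                                               extent=300, orientation=0.0))
        img = generate_artifact_image(spec)
        rows, cols = np.where(img.artifact_mask)
        assert cols.max() - cols.min() + 1 >= 300      # spans >= extent horizontally
        assert rows.max() - rows.min() < 20            # thin in the other direction
        from scipy import ndimage
        _, n_components = ndimage.label(img.artifact_mask)
        assert n_components == 1                       # connected band

    def test_agglomerate_emitter_count_matches_density(self):
        for density, extent in [(0.05, 20), (0.1, 30), (0.02, 50)]:
            spec = SceneSpec(side=256, n_signals=5, seed=9,
                             artifact=ArtifactSpec("agglomerate", amplitude=1,
                                                   extent=extent, density=density))
            img = generate_artifact_image(spec)
            assert len(img.artifact_emitters) == round(density * extent**2)

    @pytest.mark.parametrize("kind", ARTIFACT_KINDS)
    def test_each_kind_renders_nonempty_mask_and_label(self, kind):
        spec = SceneSpec(side=128, n_signals=5, seed=13,
                         artifact=default_artifact(kind, 128))
        img = generate_artifact_image(spec)
        assert img.label == "artifact"
        assert img.artifact_mask is not None and img.artifact_mask.any()
        assert img.image.max() <= spec.full_scale

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            ArtifactSpec("vortex", amplitude=10, extent=5).validate()
        with pytest.raises(ValidationError):
            default_artifact("vortex", 128)

    def test_missing_artifact_rejected(self):
        with pytest.raises(ValidationError):
            generate_artifact_image(SceneSpec(side=64))


class TestDatasets:
    def test_empty_dataset(self, tmp_path):
        manifest = generate_dataset(0, 0, SceneSpec(side=64), seed=1,
                                    out_dir=tmp_path / "d")
        assert len(manifest) == 0
        assert not list((tmp_path / "d").glob("*.tif"))

    def test_counts_and_labels(self, tmp_path):
        manifest = generate_dataset(3, 2, SceneSpec(side=64, n_signals=3),
                                    seed=1, out_dir=tmp_path / "d")
        assert len(manifest) == 5
        assert (manifest["label"] == "clean").sum() == 3
        assert (manifest["label"] == "artifact").sum() == 2
        assert manifest["path"].is_unique

    def test_reproducible_bytes(self, tmp_path):
        spec = SceneSpec(side=64, n_signals=5)
        m1 = generate_dataset(2, 2, spec, seed=42, out_dir=tmp_path / "a")
        m2 = generate_dataset(2, 2, spec, seed=42, out_dir=tmp_path / "b")
        assert m1.equals(m2)
        assert dataset_checksum(tmp_path / "a") == dataset_checksum(tmp_path / "b")

    def test_negative_counts_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            generate_dataset(-1, 0, SceneSpec(side=64), seed=0, out_dir=tmp_path)
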