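"""Phantom rendering, counting statistics and dataset assembly."""

import numpy as np
import pytest

from xfctdn.phantom import (CleanImage, CountImage, PhantomSpec, TubeSpec,
                            augment_rotations, build_dataset, child_rng,
                            counts_to_float, default_phantom_spec,
                            hexagon_mask, random_phantom_spec, render_phantom,
                            sample_counts, thin_counts)

from conftest import make_pair


def flat_spec(**kw):
    base = dict(image_size=(64, 64), hexagon_circumradius=28.0,
                water_level=4.0, compton_level=0.0, signal_gain=1000.0,
                psf_sigma=0.0, tubes=())
    base.update(kw)
    return PhantomSpec(**base)


class TestRenderPhantom:
    def test_zero_tubes_uniform_hexagon(self):
        spec = flat_spec()
        img = render_phantom(spec).pixels
        mask = hexagon_mask(spec.image_size, spec.hexagon_circumradius)
        assert np.all(img[mask] == 4.0)
        assert np.all(img[~mask] == 0.0)

    def test_zero_concentration_tube_is_invisible(self):
        tube = TubeSpec(center=(31.5, 31.5), radius=5.0, concentration=0.0)
        img = render_phantom(flat_spec(tubes=(tube,))).pixels
        ref = render_phantom(flat_spec()).pixels
        assert np.array_equal(img, ref)

    def test_disc_pixel_count_matches_brute_force(self):
        radius = 10.0
        tube = TubeSpec(center=(31.5, 31.5), radius=radius, concentration=0.001)
        img = render_phantom(flat_spec(tubes=(tube,))).pixels
        above = int(np.sum(img > 4.0))
        # independent enumeration of the disc mask
        rr, cc = np.mgrid[0:64, 0:64]
        expect = int(np.sum((rr - 31.5) ** 2 + (cc - 31.5) ** 2 <= radius ** 2))
        assert above == expect
        assert abs(above - np.pi * radius ** 2) <= 2 * (2 * np.pi * radius)

    def test_tube_outside_hexagon_names_tube(self):
        tube = TubeSpec(center=(5.0, 5.0), radius=4.0, concentration=0.001)
        with pytest.raises(ValueError, match="tube 0"):
            render_phantom(flat_spec(tubes=(tube,)))

    def test_deterministic(self):
        spec = default_phantom_spec((64, 64))
        assert np.array_equal(render_phantom(spec).pixels,
                              render_phantom(spec).pixels)

    def test_blur_preserves_nonnegativity(self):
        spec = default_phantom_spec((64, 64))
        assert np.all(render_phantom(spec).pixels >= 0)


class TestSampleCounts:
    def test_zero_expectation_gives_zero_counts(self):
        clean = CleanImage(pixels=np.zeros((32, 32)), pixel_size_mm=0.2)
        assert sample_counts(clean, 0.5, 1.0, 3).counts.sum() == 0

    def test_same_seed_bit_identical(self):
        clean = CleanImage(pixels=np.full((32, 32), 7.0), pixel_size_mm=0.2)
        a = sample_counts(clean, 0.1, 2.0, 11)
        b = sample_counts(clean, 0.1, 2.0, 11)
        assert np.array_equal(a.counts, b.counts)

    def test_poisson_mean_law(self):
        clean = CleanImage(pixels=np.full((100, 100), 10.0), pixel_size_mm=0.2)
        img = sample_counts(clean, 0.5, 1.0, 5)
        assert abs(img.counts.mean() - 10.0) < 3 * np.sqrt(10.0 / 1e4)

    def test_bin_width_scales_expectation(self):
        clean = CleanImage(pixels=np.full((100, 100), 20.0), pixel_size_mm=0.2)
        img = sample_counts(clean, 0.05, 1.0, 5)   # 10x fewer photons
        assert abs(img.counts.mean() - 2.0) < 3 * np.sqrt(2.0 / 1e4)

    def test_nonpositive_exposure_rejected(self):
        clean = CleanImage(pixels=np.ones((32, 32)), pixel_size_mm=0.2)
        with pytest.raises(ValueError):
            sample_counts(clean, 0.5, 0.0, 1)


class TestThinCounts:
    def _img(self, value=100, size=100):
        return CountImage(counts=np.full((size, size), value, dtype=np.int64),
                          dose_fraction=1.0, bin_width_keV=0.5, seed=0)

    def test_keep_one_is_identity(self):
        img = self._img()
        out = thin_counts(img, 1.0, 9)
        assert np.array_equal(out.counts, img.counts)
        assert out.dose_fraction == 1.0

    def test_keep_zero_empties_image(self):
        out = thin_counts(self._img(), 0.0, 9)
        assert out.counts.sum() == 0

    def test_binomial_total_within_three_sigma(self):
        img = self._img(value=100, size=100)      # total 10^6
        total = img.counts.sum()
        out = thin_counts(img, 0.25, 13)
        sigma = np.sqrt(total * 0.25 * 0.75)
        assert abs(out.counts.sum() - 0.25 * total) <= 3 * sigma
        assert out.dose_fraction == 0.25

    def test_invalid_keep_fraction(self):
        with pytest.raises(ValueError):
            thin_counts(self._img(), 1.5, 0)

    def test_thinned_poisson_stays_poisson(self):
        # variance/mean of thinned Poisson ~ 1
        clean = CleanImage(pixels=np.full((100, 100), 100.0), pixel_size_mm=0.2)
        img = sample_counts(clean, 0.5, 1.0, 21)
        out = thin_counts(img, 0.5, 22)           # lambda*p = 50 >= 25
        ratio = out.counts.var() / out.counts.mean()
        assert 0.9 <= ratio <= 1.1

    def test_thinning_composes_multiplicatively(self):
        clean = CleanImage(pixels=np.full((128, 128), 200.0), pixel_size_mm=0.2)
        img = sample_counts(clean, 0.5, 1.0, 31)
        once = thin_counts(img, 0.3, 33)
        twice = thin_counts(thin_counts(img, 0.6, 34), 0.5, 35)
        m1, m2 = once.counts.mean(), twice.counts.mean()
        v1, v2 = once.counts.var(), twice.counts.var()
        se = np.sqrt(2 * 60.0 / once.counts.size)   # ~ sqrt(2 lambda p / n)
        assert abs(m1 - m2) < 4 * se
        assert abs(v1 - v2) / v1 < 0.1
        assert once.dose_fraction == pytest.approx(twice.dose_fraction)


class TestCountsToFloat:
    def _img(self, counts):
        return CountImage(counts=np.asarray(counts, dtype=np.int64),
                          dose_fraction=1.0, bin_width_keV=0.5, seed=0)

    def test_fixed_range_divides_by_cmax(self):
        img = self._img(np.arange(101).reshape(1, 101))
        out = counts_to_float(img, 100.0)
        assert np.allclose(out, img.counts / 100.0)

    def test_all_zero_image_warns_and_returns_zeros(self):
        img = self._img(np.zeros((8, 8)))
        with pytest.warns(UserWarning):
            out = counts_to_float(img, "per_image_max")
        assert np.all(out == 0)

    def test_per_image_max_hits_one(self):
        img = self._img(np.array([[0, 512], [1, 2]]))
        assert counts_to_float(img, "per_image_max").max() == 1.0

    def test_fixed_range_clips(self):
        img = self._img(np.array([[500]]))
        assert counts_to_float(img, 100.0).max() == 1.0


class TestNormalizationProperties:
    """Monotone [0,1] rescaling holds for arbitrary count images."""

    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @given(counts=arrays(np.int64, (6, 6),
                         elements=st.integers(0, 10_000)),
           cmax=st.floats(1.0, 5_000.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_fixed_range_monotone_and_bounded(self, counts, cmax):
        img = CountImage(counts=counts, dose_fraction=1.0,
                         bin_width_keV=0.5, seed=0)
        out = counts_to_float(img, float(cmax))
        assert out.min() >= 0.0 and out.max() <= 1.0
        flat_c = counts.ravel()
        flat_o = out.ravel()
        order = np.argsort(flat_c, kind="stable")
        assert np.all(np.diff(flat_o[order]) >= 0)

    @given(value=st.integers(0, 1000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_thinning_keep_one_identity_any_counts(self, value):
        img = CountImage(counts=np.full((4, 4), value, dtype=np.int64),
                         dose_fraction=1.0, bin_width_keV=0.1, seed=0)
        assert np.array_equal(thin_counts(img, 1.0, 5).counts, img.counts)


class TestAugmentation:
    def test_four_times_as_many_pairs(self, rng):
        pairs = [make_pair(rng) for _ in range(3)]
        assert len(augment_rotations(pairs)) == 12

    def test_rotation_group_property(self, rng):
        pair = make_pair(rng)
        out = augment_rotations([pair])
        r90 = out[1].noisy
        # three further quarter turns undo the augmentation's quarter turn
        assert np.array_equal(np.rot90(r90, 3), pair.noisy)
        # and four quarter turns are the identity
        assert np.array_equal(np.rot90(pair.noisy, 4), pair.noisy)

    def test_rotation_preserves_pixel_multiset(self, rng):
        pair = make_pair(rng)
        for aug in augment_rotations([pair]):
            assert np.array_equal(np.sort(aug.noisy.ravel()),
                                  np.sort(pair.noisy.ravel()))

    def test_non_square_rejected(self, rng):
        from xfctdn.phantom import ImagePair, PairMeta
        bad = ImagePair(noisy=np.zeros((4, 6)), clean=np.zeros((4, 6)),
                        meta=PairMeta(0.25, 0.5, "r0", 0))
        with pytest.raises(ValueError):
            augment_rotations([bad])


class TestBuildDataset:
    def test_grid_pair_and_split_counts(self, small_dataset):
        pairs, split = small_dataset
        # 5 specs x 3 bins x 3 levels x 4 rotations
        assert len(pairs) == 180
        # 1 of 5 phantoms held out -> 36 test pairs, 8 per category... 4/cat
        assert len(split.test_ids) == 36
        assert len(split.train_ids) == 144

    def test_ten_spec_grid_matches_published_protocol(self):
        specs = [random_phantom_spec((64, 64), child_rng(3, 10, i))
                 for i in range(10)]
        pairs, split = build_dataset(specs, seed=3)
        assert len(pairs) == 360
        assert len(split.test_ids) == 72
        assert len(split.train_ids) == 288

    def test_split_disjoint_and_complete(self, small_dataset):
        pairs, split = small_dataset
        ids = set(split.train_ids) | set(split.test_ids)
        assert not (set(split.train_ids) & set(split.test_ids))
        assert ids == set(range(len(pairs)))

    def test_same_seed_is_bit_identical(self):
        specs = [random_phantom_spec((64, 64), child_rng(5, 10, i))
                 for i in range(3)]
        p1, s1 = build_dataset(specs, seed=42)
        p2, s2 = build_dataset(specs, seed=42)
        assert s1 == s2
        for a, b in zip(p1, p2):
            assert np.array_equal(a.noisy, b.noisy)
            assert np.array_equal(a.clean, b.clean)

    def test_values_in_unit_interval(self, small_dataset):
        pairs, _ = small_dataset
        for p in pairs[::17]:
            assert p.noisy.min() >= 0 and p.noisy.max() <= 1
            assert p.clean.min() >= 0 and p.clean.max() <= 1

    def test_clean_shared_within_phantom_bin(self, small_dataset):
        pairs, _ = small_dataset
        by_key = {}
        for p in pairs:
            if p.meta.augmentation_tag != "r0":
                continue
            key = (p.meta.phantom_id, p.meta.bin_width_keV)
            by_key.setdefault(key, []).append(p.clean)
        for cleans in by_key.values():
            for c in cleans[1:]:
                assert np.array_equal(c, cleans[0])

    def test_empty_specs_rejected(self):
        with pytest.raises(ValueError):
            build_dataset([], seed=0)
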