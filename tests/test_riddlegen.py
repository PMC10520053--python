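"""Riddle generator: rendering oracle, frame/sample invariants, datasets."""

import json

import numpy as np
import pytest
from scipy.stats import chisquare

from oddity.riddlegen import (BACKGROUND_RANGE, INK_RANGE, DatasetConfig,
                              Disk, Frame, GenerationError, GeneratorSpec,
                              SceneSpec, Segment, build_dataset,
                              default_registry, generate_riddle, ink_mask,
                              load_dataset, place_oddity, render_frame,
                              split_sizes, write_dataset)


def brute_force_segment_pixels(p0, p1, side=100):
    """Independent rasterization oracle for axis-aligned segments under the
    documented floor-based coordinate mapping."""
    to_px = lambda u: min(int(np.floor(u * side)), side - 1)
    (x0, y0), (x1, y1) = p0, p1
    assert y0 == y1, "oracle covers horizontal segments"
    row = to_px(y0)
    cols = range(min(to_px(x0), to_px(x1)), max(to_px(x0), to_px(x1)) + 1)
    return {(row, c) for c in cols}


class TestRenderFrame:
    def test_empty_scene_is_pure_background(self):
        f = render_frame([], background_shade=240, ink_shade=10)
        assert (f.pixels == 240).all()

    def test_horizontal_segment_matches_rasterization_oracle(self):
        p0, p1 = (0.2, 0.5), (0.8, 0.5)
        f = render_frame([Segment(p0, p1)], background_shade=250, ink_shade=30)
        got = set(zip(*np.nonzero(f.pixels == 30)))
        expected = brute_force_segment_pixels(p0, p1)
        assert got == expected
        assert len(expected) == 61          # columns 20..80 inclusive at row 50

    def test_same_seed_renders_identically(self):
        scene = [Segment((0.1, 0.1), (0.9, 0.8)), Disk((0.5, 0.5), 0.1)]
        f1 = render_frame(scene, np.random.default_rng(42))
        f2 = render_frame(scene, np.random.default_rng(42))
        np.testing.assert_array_equal(f1.pixels, f2.pixels)
        assert (f1.background_shade, f1.ink_shade) == (f2.background_shade, f2.ink_shade)

    def test_out_of_bounds_primitive_rejected(self):
        with pytest.raises(ValueError, match="outside the unit square"):
            render_frame([Segment((0.5, 0.5), (1.2, 0.5))],
                         background_shade=240, ink_shade=10)

    def test_antialiased_values_between_ink_and_background(self):
        f = render_frame([Segment((0.11, 0.13), (0.83, 0.77))],
                         background_shade=250, ink_shade=20, antialias=True)
        vals = np.unique(f.pixels)
        assert vals.min() >= 20 and vals.max() == 250
        middles = vals[(vals > 20) & (vals < 250)]
        assert middles.size > 0     # oblique stroke produces blended edges

    def test_shade_invariants_over_many_seeded_frames(self):
        """Every emitted frame uses shades from the allowed ranges only."""
        rng = np.random.default_rng(0)
        reg = default_registry()
        concepts = list(reg)
        for i in range(120):
            s = generate_riddle(concepts[i % len(concepts)], rng)
            for f in s.frames:
                assert BACKGROUND_RANGE[0] <= f.background_shade <= BACKGROUND_RANGE[1]
                assert INK_RANGE[0] <= f.ink_shade <= INK_RANGE[1]
                vals = set(np.unique(f.pixels).tolist())
                assert vals <= {f.background_shade, f.ink_shade}


class TestGenerateRiddle:
    @pytest.mark.parametrize("concept_id", sorted(default_registry()))
    def test_checker_separates_oddity(self, concept_id):
        """The concept checker accepts exactly the five non-oddities."""
        reg = default_registry()
        spec = reg[concept_id]
        rng = np.random.default_rng(5)
        for _ in range(40):
            s = generate_riddle(concept_id, rng)
            verdicts = [spec.checker(f, m) for f, m in zip(s.frames, s.metas)]
            assert sum(verdicts) == 5
            assert not verdicts[s.oddity_index]

    def test_vertical_symmetry_reflection_residual(self):
        """Non-oddities have a small mirror residual, the oddity a large one."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            s = generate_riddle("vertical_symmetry", rng)
            for i, f in enumerate(s.frames):
                m = ink_mask(f)
                residual = np.logical_xor(m, m[:, ::-1]).sum() / (2 * m.sum())
                if i == s.oddity_index:
                    assert residual > 0.10
                else:
                    assert residual < 0.10

    def test_frames_pairwise_distinct(self):
        rng = np.random.default_rng(2)
        for cid in ("circle", "rotation", "parallel_lines"):
            s = generate_riddle(cid, rng)
            for i in range(6):
                for j in range(i + 1, 6):
                    assert not np.array_equal(s.frames[i].pixels, s.frames[j].pixels)

    def test_oddity_position_uniform(self):
        """Chi-square uniformity of the label over {0..5} (alpha = 0.01)."""
        rng = np.random.default_rng(3)
        counts = np.zeros(6)
        for _ in range(6000):
            _, idx = place_oddity(list(range(5)), "odd", rng)
            counts[idx] += 1
        assert chisquare(counts).pvalue > 0.01

    def test_unknown_concept_raises(self):
        with pytest.raises(ValueError, match="unknown concept"):
            generate_riddle("moebius_strip", np.random.default_rng(0))

    def test_uniqueness_retries_on_identical_scenes(self):
        """A constant-scene generator still yields distinct frames (shade
        resampling) and a generator that cannot separate raises."""
        fixed_scene = SceneSpec([Disk((0.5, 0.5), 0.2)], {"ok": True})
        reg = {"const": GeneratorSpec(
            "const", "test", lambda rng, odd: SceneSpec(
                fixed_scene.primitives, {"odd": odd}),
            lambda f, m: not m["odd"])}
        s = generate_riddle("const", np.random.default_rng(0), registry=reg)
        for i in range(6):
            for j in range(i + 1, 6):
                assert not np.array_equal(s.frames[i].pixels, s.frames[j].pixels)

        bad = {"bad": GeneratorSpec(
            "bad", "test", lambda rng, odd: SceneSpec([], {}),
            lambda f, m: True)}     # never rejects, so no oddity can be made
        with pytest.raises(GenerationError, match="bad"):
            generate_riddle("bad", np.random.default_rng(0), registry=bad)


def _tiny_registry():
    """Cheap concept generators for dataset-level tests (1 disc vs 2 discs)."""
    def scene(rng, odd):
        prims = [Disk((rng.uniform(0.3, 0.7), rng.uniform(0.3, 0.7)), 0.1)]
        if odd:
            prims.append(Disk((rng.uniform(0.1, 0.25), rng.uniform(0.1, 0.25)), 0.05))
        return SceneSpec(prims, {"odd": odd})

    return {f"c{i}": GeneratorSpec(f"c{i}", "test", scene,
                                   lambda f, m: not m["odd"])
            for i in range(12)}


class TestDataset:
    def test_split_sizes_follow_ratio(self):
        assert split_sizes(3840) == (2560, 640, 640)
        assert split_sizes(108000) == (72000, 18000, 18000)
        with pytest.raises(ValueError, match="divisible"):
            split_sizes(100)

    def test_separate_mode_requires_single_concept(self):
        with pytest.raises(ValueError, match="exactly one concept"):
            DatasetConfig(mode="separate", concepts=("a", "b"), size=6, seed=0)

    def test_build_dataset_splits_disjoint_and_deterministic(self):
        reg = _tiny_registry()
        cfg = DatasetConfig(mode="joint", concepts=tuple(reg), size=60, seed=9)
        d1 = build_dataset(cfg, registry=reg)
        d2 = build_dataset(cfg, registry=reg)
        assert (len(d1.train), len(d1.val), len(d1.test)) == (40, 10, 10)
        for s1, s2 in zip(d1.train + d1.val + d1.test, d2.train + d2.val + d2.test):
            assert s1.oddity_index == s2.oddity_index
            assert s1.concept_id == s2.concept_id
            for f1, f2 in zip(s1.frames, s2.frames):
                np.testing.assert_array_equal(f1.pixels, f2.pixels)

    def test_joint_mode_concepts_uniform(self):
        """Concept draw uniform across the registry (chi-square, alpha 0.01)."""
        from oddity.riddlegen.dataset import sample_concept_ids
        reg = _tiny_registry()
        cfg = DatasetConfig(mode="joint", concepts=tuple(reg), size=10800, seed=4)
        ids = sample_concept_ids(cfg, np.random.default_rng(4))
        counts = [ids.count(c) for c in reg]
        assert chisquare(counts).pvalue > 0.01

    @pytest.mark.parametrize("fmt", ["png", "npz"])
    def test_round_trip_is_lossless(self, fmt, tmp_path):
        reg = _tiny_registry()
        cfg = DatasetConfig(mode="separate", concepts=("c0",), size=12, seed=1)
        splits = build_dataset(cfg, registry=reg)
        manifest = write_dataset(splits, tmp_path / "ds", fmt=fmt)
        assert manifest["counts"] == {"train": 8, "val": 2, "test": 2}
        loaded = load_dataset(tmp_path / "ds")
        for orig, back in zip(splits.train, loaded.train):
            assert back.oddity_index == orig.oddity_index
            assert back.concept_id == orig.concept_id
            for f1, f2 in zip(orig.frames, back.frames):
                np.testing.assert_array_equal(f1.pixels, f2.pixels)
                assert f1.background_shade == f2.background_shade

    def test_loading_missing_labels_raises(self, tmp_path):
        reg = _tiny_registry()
        cfg = DatasetConfig(mode="separate", concepts=("c0",), size=6, seed=1)
        splits = build_dataset(cfg, registry=reg)
        write_dataset(splits, tmp_path / "ds")
        (tmp_path / "ds" / "val" / "labels.jsonl").unlink()
        with pytest.raises(FileNotFoundError, match="labels"):
            load_dataset(tmp_path / "ds")

    def test_loading_version_mismatch_raises(self, tmp_path):
        reg = _tiny_registry()
        cfg = DatasetConfig(mode="separate", concepts=("c0",), size=6, seed=1)
        write_dataset(build_dataset(cfg, registry=reg), tmp_path / "ds")
        mpath = tmp_path / "ds" / "manifest.json"
        manifest = json.loads(mpath.read_text())
        manifest["format_version"] = 99
        mpath.write_text(json.dumps(manifest))
        with pytest.raises(ValueError, match="version"):
            load_dataset(tmp_path / "ds")
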