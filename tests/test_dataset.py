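"""Dataset construction: Labelme conversion, augmentation geometry,
6x multiplication, and 7:2:1 splitting."""

import numpy as np
import pytest

from chickseg import dataset as D


def triangle_doc(label="chicken-whole", h=64, w=64):
    return {
        "imagePath": "img.png", "imageHeight": h, "imageWidth": w,
        "shapes": [{"label": label,
                    "points": [[0, 0], [10, 0], [0, 10]],
                    "shape_type": "polygon"}],
    }


class TestLabelmeToCoco:
    def test_empty_input(self):
        ds = D.labelme_to_coco([])
        assert ds.images == [] and ds.annotations == []
        assert [c["name"] for c in ds.categories] == list(D.CATEGORY_NAMES)

    def test_triangle_bbox_and_rasterized_area(self):
        ds = D.labelme_to_coco([triangle_doc()])
        ann = ds.annotations[0]
        assert ann["bbox"] == [0.0, 0.0, 10.0, 10.0]
        oracle = D.rasterize_polygons(
            [np.array([[0, 0], [10, 0], [0, 10]])], 64, 64).sum()
        assert ann["area"] == oracle
        assert ann["category_id"] == D.CATEGORY_IDS["chicken-whole"]

    def test_fixed_category_id_order(self):
        assert [D.CATEGORY_IDS[n] for n in D.CATEGORY_NAMES] == [1, 2, 3, 4]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            D.labelme_to_coco([triangle_doc(label="duck")])

    def test_degenerate_polygon_rejected(self):
        doc = triangle_doc()
        doc["shapes"][0]["points"] = [[0, 0], [5, 5]]
        with pytest.raises(ValueError, match="degenerate"):
            D.labelme_to_coco([doc])

    def test_round_trip_serialization(self, tmp_path):
        ds = D.labelme_to_coco([triangle_doc(), triangle_doc("chicken-few")])
        ds.save(tmp_path / "coco.json")
        again = D.CocoDataset.load(tmp_path / "coco.json")
        assert again.to_dict() == ds.to_dict()


def _item(rng, h=64, w=64):
    img = rng.integers(0, 256, (h, w), dtype=np.uint8)
    inst = D.PolygonInstance("chicken-whole",
                             [[10, 20], [40, 22], [38, 50], [12, 48]])
    return D.AnnotatedImage(img, [inst], "src")


class TestAugmentation:
    def test_flip_is_involution(self, rng):
        item = _item(rng)
        twice = D.apply_augmentation(
            D.apply_augmentation(item, "mirror_flip", 0), "mirror_flip", 0)
        assert (twice.image == item.image).all()
        assert np.allclose(twice.instances[0].vertices,
                           item.instances[0].vertices)

    def test_flip_vertex_arithmetic(self, rng):
        item = D.AnnotatedImage(
            np.zeros((512, 512), np.uint8),
            [D.PolygonInstance("chicken-half",
                               [[10, 20], [30, 20], [20, 40]])], "s")
        out = D.apply_augmentation(item, "mirror_flip", 0)
        assert tuple(out.instances[0].vertices[0]) == (502.0, 20.0)

    @pytest.mark.parametrize("op", ["brightness", "gaussian_noise",
                                    "salt_pepper"])
    def test_photometric_ops_preserve_geometry(self, rng, op):
        item = _item(rng)
        out = D.apply_augmentation(item, op, seed=3)
        assert np.array_equal(out.instances[0].vertices,
                              item.instances[0].vertices)
        assert out.image.shape == item.image.shape

    def test_augmentation_deterministic_under_seed(self, rng):
        item = _item(rng)
        a = D.apply_augmentation(item, "gaussian_noise", seed=5)
        b = D.apply_augmentation(item, "gaussian_noise", seed=5)
        assert (a.image == b.image).all()

    def test_unknown_op_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown augmentation"):
            D.apply_augmentation(_item(rng), "rotate", 0)

    def test_flip_mask_consistency(self, rng):
        """Rasterising flipped polygons equals flipping the rasterised
        original mask (IoU exactly 1)."""
        item = _item(rng)
        h, w = item.image.shape
        out = D.apply_augmentation(item, "mirror_flip", 0)
        orig = D.rasterize_polygons([item.instances[0].vertices], h, w)
        flipped = D.rasterize_polygons([out.instances[0].vertices], h, w)
        assert np.array_equal(flipped, orig[:, ::-1])

    def test_shift_consistency_on_unclipped_region(self):
        rng = np.random.default_rng(0)
        item = _item(rng)
        h, w = item.image.shape
        out = D.apply_augmentation(item, "random_shift", seed=11)
        if not out.instances:
            pytest.skip("shift removed the instance")
        orig = D.rasterize_polygons([item.instances[0].vertices], h, w)
        moved = D.rasterize_polygons([out.instances[0].vertices], h, w)
        # recover the shift from the pixel payload
        ys, xs = np.nonzero(out.image == item.image[20, 10])
        # shift is encoded in the vertex displacement of the first vertex
        dx = int(out.instances[0].vertices[:, 0].max()
                 - item.instances[0].vertices[:, 0].max())
        dy = int(out.instances[0].vertices[:, 1].max()
                 - item.instances[0].vertices[:, 1].max())
        rolled = np.zeros_like(orig)
        src = orig[max(0, -dy):h - max(dy, 0), max(0, -dx):w - max(dx, 0)]
        rolled[max(0, dy):max(0, dy) + src.shape[0],
               max(0, dx):max(0, dx) + src.shape[1]] = src
        inter = (rolled & moved).sum()
        union = (rolled | moved).sum()
        assert inter / union > 0.99


class TestAugmentedDataset:
    def _dataset(self, n, rng, size=64):
        docs = []
        for _ in range(n):
            docs.append({
                "imagePath": "x.png", "imageHeight": size,
                "imageWidth": size,
                "shapes": [{"label": "chicken-whole",
                            "points": [[5, 5], [30, 8], [28, 30], [6, 28]]}],
            })
        ds = D.labelme_to_coco(docs)
        pixels = {im["id"]: rng.integers(0, 256, (size, size),
                                         dtype=np.uint8)
                  for im in ds.images}
        return ds, pixels

    def test_one_image_becomes_six(self, rng):
        ds, pixels = self._dataset(1, rng)
        out, out_pix = D.build_augmented_dataset(ds, pixels, seed=1)
        assert len(out.images) == 6
        assert len(out_pix) == 6
        out.validate()

    def test_multiplicity_and_integrity(self, rng):
        ds, pixels = self._dataset(7, rng)
        out, _ = D.build_augmented_dataset(ds, pixels, seed=2)
        assert len(out.images) == 6 * 7
        out.validate()

    def test_photometric_ops_preserve_instance_counts(self, rng):
        ds, pixels = self._dataset(5, rng)
        out, _ = D.build_augmented_dataset(ds, pixels, seed=3)
        photometric = {"brightness", "gaussian_noise", "salt_pepper",
                       "orig"}
        per_image = {}
        for a in out.annotations:
            per_image[a["image_id"]] = per_image.get(a["image_id"], 0) + 1
        for im in out.images:
            tag = im["file_name"].rsplit("_", 1)[-1].removesuffix(".png")
            if tag in photometric:
                assert per_image.get(im["id"], 0) == 1

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            D.build_augmented_dataset(D.CocoDataset(), {}, seed=0)


class TestSplit:
    def _ds(self, n):
        return D.CocoDataset(images=[
            {"id": i + 1, "file_name": f"{i}.png", "height": 8, "width": 8}
            for i in range(n)])

    def test_ten_images_split_7_2_1(self):
        parts = D.split_dataset(self._ds(10), D.SplitSpec(seed=0))
        assert tuple(len(p.images) for p in parts) == (7, 2, 1)

    def test_partitions_disjoint_and_exhaustive(self):
        ds = self._ds(37)
        parts = D.split_dataset(ds, D.SplitSpec(seed=5))
        ids = [frozenset(im["id"] for im in p.images) for p in parts]
        assert sum(len(s) for s in ids) == 37
        assert frozenset.union(*ids) == {im["id"] for im in ds.images}

    def test_seed_reproducibility(self):
        ds = self._ds(20)
        a = D.split_dataset(ds, D.SplitSpec(seed=9))
        b = D.split_dataset(ds, D.SplitSpec(seed=9))
        for pa, pb in zip(a, b):
            assert [im["id"] for im in pa.images] == \
                [im["id"] for im in pb.images]

    def test_rounding_rule_at_scale(self):
        parts = D.split_dataset(self._ds(9288), D.SplitSpec(seed=1))
        sizes = tuple(len(p.images) for p in parts)
        assert sizes == (6502, 1858, 928)
        assert sum(sizes) == 9288

    def test_invalid_ratios_rejected(self):
        with pytest.raises(ValueError):
            D.SplitSpec(ratios=(0.5, 0.2, 0.2))

    def test_group_split_keeps_augmented_copies_together(self, rng):
        docs = [{"imagePath": "x.png", "imageHeight": 32, "imageWidth": 32,
                 "shapes": [{"label": "chicken-whole",
                             "points": [[2, 2], [20, 4], [18, 20]]}]}
                for _ in range(10)]
        ds = D.labelme_to_coco(docs)
        pixels = {im["id"]: rng.integers(0, 256, (32, 32), dtype=np.uint8)
                  for im in ds.images}
        aug, _ = D.build_augmented_dataset(ds, pixels, seed=4)
        parts = D.split_dataset(aug, D.SplitSpec(seed=2),
                                group_by_source=True)
        sources = [set(im["source_id"] for im in p.images) for p in parts]
        assert not (sources[0] & sources[1])
        assert not (sources[0] & sources[2])
        assert not (sources[1] & sources[2])
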