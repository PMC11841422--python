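"""Scene generator, augmentation, splitting and annotation conversion."""

import json

import numpy as np
import pytest

from seedlingcounter.annotations import (AnnotationError, boxes_to_coco,
                                         coco_to_boxes, labelme_to_coco)
from seedlingcounter.boxes import box_areas
from seedlingcounter.metrics import size_class
from seedlingcounter.synthetic import (AugmentConfig, FieldConfig,
                                       SyntheticScene, altitude_rescale,
                                       augment_scene, generate_dataset,
                                       generate_scene, split_dataset,
                                       split_sizes)


def plant_pixels_in_box(image, box):
    x0, y0, x1, y1 = [int(round(v)) for v in box]
    patch = image[y0:y1, x0:x1]
    return (patch[..., 1].astype(int) > patch[..., 0].astype(int) + 10).sum()


class TestGenerateScene:
    def test_deterministic(self):
        cfg = FieldConfig(image_size=128, n_rows=3, plants_per_row=4, seed=5)
        s1, s2 = generate_scene(cfg), generate_scene(cfg)
        np.testing.assert_array_equal(s1.image, s2.image)
        np.testing.assert_array_equal(s1.boxes, s2.boxes)
        assert s1.size_labels == s2.size_labels

    def test_annotation_count_matches_grid(self):
        # generous spacing so no placement failures
        cfg = FieldConfig(image_size=256, n_rows=3, plants_per_row=5,
                          seed=11, position_jitter=0.05, small_fraction=1.0)
        scene = generate_scene(cfg)
        assert len(scene.boxes) == 15

    def test_boxes_are_tight_and_rendered(self):
        cfg = FieldConfig(image_size=128, n_rows=3, plants_per_row=3, seed=9)
        scene = generate_scene(cfg)
        for box in scene.boxes:
            assert plant_pixels_in_box(scene.image, box) > 0
            x0, y0, x1, y1 = [int(v) for v in box]
            # every edge row/column of a tight box touches the plant
            patch_green = (scene.image[y0:y1, x0:x1, 1].astype(int)
                           > scene.image[y0:y1, x0:x1, 0].astype(int) + 10)
            assert patch_green[0].any() and patch_green[-1].any()
            assert patch_green[:, 0].any() and patch_green[:, -1].any()

    def test_size_labels_match_partition(self, small_scene):
        for box, label in zip(small_scene.boxes, small_scene.size_labels):
            assert size_class(box_areas(box[None])[0]) == label

    def test_small_fraction_statistics(self):
        """Realized small-object share across 200 seeded scenes."""
        cfg = FieldConfig(image_size=128, n_rows=3, plants_per_row=4,
                          small_fraction=0.89, seed=1000, min_box_side=5)
        labels = []
        for scene in generate_dataset(200, cfg):
            labels.extend(scene.size_labels)
        share = labels.count("small") / len(labels)
        assert abs(share - 0.89) <= 0.03

    def test_boxes_inside_image(self, scene_batch):
        for s in scene_batch:
            assert (s.boxes[:, 0] >= 0).all() and (s.boxes[:, 1] >= 0).all()
            assert (s.boxes[:, 2] <= s.width).all()
            assert (s.boxes[:, 3] <= s.height).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FieldConfig(image_size=32)
        with pytest.raises(ValueError):
            FieldConfig(small_fraction=1.5)


class TestAltitudeRescale:
    def test_identity(self, small_scene):
        out = altitude_rescale(small_scene, 0.32, 0.32)
        np.testing.assert_array_equal(out.image, small_scene.image)
        np.testing.assert_array_equal(out.boxes, small_scene.boxes)

    def test_doubling_gsd_halves_boxes(self):
        image = np.zeros((128, 128, 3), np.uint8)
        image[40:80, 40:80, 1] = 200  # a 40x40 object
        scene = SyntheticScene(image, np.array([[40.0, 40, 80, 80]]), ["medium"])
        out = altitude_rescale(scene, 0.32, 0.64)
        assert out.image.shape[:2] == (64, 64)
        np.testing.assert_allclose(out.boxes, [[20, 20, 40, 40]])
        assert out.size_labels == ["small"]  # area 1600 -> 400

    def test_small_objects_dropped_with_warning(self):
        image = np.zeros((64, 64, 3), np.uint8)
        scene = SyntheticScene(image, np.array([[10.0, 10, 13, 13]]), ["small"])
        with pytest.warns(UserWarning, match="dropped"):
            out = altitude_rescale(scene, 0.32, 0.64)
        assert len(out.boxes) == 0

    def test_count_preserved_when_objects_large_enough(self, small_scene):
        out = altitude_rescale(small_scene, 0.32, 0.54)
        assert len(out.boxes) == len(small_scene.boxes)

    def test_invalid_gsd_rejected(self, small_scene):
        with pytest.raises(ValueError):
            altitude_rescale(small_scene, 0.0, 0.64)


class TestAugmentation:
    def test_horizontal_flip_box_arithmetic(self, small_scene):
        aug = AugmentConfig(scales=(1.0,), crop_fraction=1.0)
        out = augment_scene(small_scene, aug, seed=0,
                            decisions={"flip_h": True, "flip_v": False,
                                       "scale": 1.0, "crop_origin": (0, 0)})
        W = small_scene.width
        expected = small_scene.boxes.copy()
        expected[:, [0, 2]] = W - small_scene.boxes[:, [2, 0]]
        order = np.lexsort(out.boxes.T)
        order_e = np.lexsort(expected.T)
        np.testing.assert_allclose(out.boxes[order], expected[order_e])

    def test_double_flip_is_involution(self, small_scene):
        aug = AugmentConfig(scales=(1.0,), crop_fraction=1.0)
        forced = {"flip_h": True, "flip_v": True, "scale": 1.0, "crop_origin": (0, 0)}
        once = augment_scene(small_scene, aug, seed=0, decisions=forced)
        twice = augment_scene(once, aug, seed=0, decisions=forced)
        np.testing.assert_array_equal(twice.image, small_scene.image)
        order = np.lexsort(twice.boxes.T)
        order_o = np.lexsort(small_scene.boxes.T)
        np.testing.assert_allclose(twice.boxes[order], small_scene.boxes[order_o],
                                   atol=1e-9)

    def test_flip_frequency(self, small_scene):
        aug = AugmentConfig(scales=(1.0,), crop_fraction=1.0)
        flips = sum(augment_scene(small_scene, aug, seed=s).provenance["augment"]["flip_h"]
                    for s in range(1000))
        assert abs(flips / 1000 - 0.5) <= 0.05

    def test_surviving_boxes_enclose_plant_pixels(self, scene_batch):
        aug = AugmentConfig()
        for i, scene in enumerate(scene_batch):
            out = augment_scene(scene, aug, seed=100 + i)
            for box in out.boxes:
                assert plant_pixels_in_box(out.image, box) > 0

    def test_output_size_fixed(self, small_scene):
        aug = AugmentConfig(output_size=64)
        out = augment_scene(small_scene, aug, seed=3)
        assert out.image.shape == (64, 64, 3)

    def test_empty_result_is_legal(self):
        # a scene with one object in a corner; crop the opposite corner
        image = np.zeros((100, 100, 3), np.uint8)
        image[:, :, 0] = 120
        image[2:10, 2:10] = (40, 180, 40)
        scene = SyntheticScene(image, np.array([[2.0, 2, 10, 10]]), ["small"])
        aug = AugmentConfig(scales=(1.0,), crop_fraction=0.5)
        out = augment_scene(scene, aug, seed=0,
                            decisions={"flip_h": False, "flip_v": False,
                                       "scale": 1.0, "crop_origin": (50, 50)})
        assert len(out.boxes) == 0


class TestSplit:
    def test_ten_scenes(self):
        train, val, test = split_dataset(list(range(10)), seed=1)
        assert (len(train), len(val), len(test)) == (7, 2, 1)

    def test_large_dataset_allocation(self):
        assert split_sizes(1233) == (864, 246, 123)

    def test_partition_disjoint_exhaustive(self):
        scenes = list(range(57))
        train, val, test = split_dataset(scenes, seed=9)
        assert sorted(train + val + test) == scenes
        assert not (set(train) & set(val) or set(val) & set(test)
                    or set(train) & set(test))

    def test_deterministic(self):
        a = split_dataset(list(range(20)), seed=4)
        b = split_dataset(list(range(20)), seed=4)
        assert a == b

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(list(range(9)))

    @pytest.mark.parametrize("n", [10, 11, 19, 100, 1233])
    def test_floor_remainder_rule(self, n):
        tr, va, te = split_sizes(n)
        assert tr + va + te == n
        assert va == n * 2 // 10 and te == n * 1 // 10


class TestLabelmeConversion:
    def test_rectangle_to_bbox(self):
        doc = {"shapes": [{"shape_type": "rectangle",
                           "points": [[10, 20], [42, 52]], "label": "s"}],
               "imageWidth": 512, "imageHeight": 512, "imagePath": "a.png"}
        coco = labelme_to_coco(doc)
        ann = coco["annotations"][0]
        assert ann["bbox"] == [10, 20, 32, 32]
        assert ann["area"] == 1024

    def test_polygon_extrema(self):
        doc = {"shapes": [{"shape_type": "polygon",
                           "points": [[0, 0], [10, 0], [0, 8]], "label": "s"}]}
        coco = labelme_to_coco(doc)
        assert coco["annotations"][0]["bbox"] == [0, 0, 10, 8]

    def test_consecutive_ids(self):
        shapes = [{"shape_type": "rectangle", "points": [[i, i], [i + 5, i + 5]]}
                  for i in range(0, 50, 10)]
        coco = labelme_to_coco({"shapes": shapes})
        assert [a["id"] for a in coco["annotations"]] == [1, 2, 3, 4, 5]

    def test_malformed_shapes_itemized(self):
        doc = {"shapes": [
            {"shape_type": "rectangle", "points": [[0, 0], [5, 5]]},
            {"shape_type": "circle", "points": [[1, 1], [2, 2]]},
            {"shape_type": "polygon", "points": [[0, 0], [1, 1]]},
        ]}
        with pytest.raises(AnnotationError) as exc:
            labelme_to_coco(doc)
        assert len(exc.value.problems) == 2

    def test_coco_roundtrip_lossless(self, rng):
        boxes = {"img1.png": rng.uniform(0, 100, (5, 4))}
        boxes["img1.png"][:, 2:] = boxes["img1.png"][:, :2] + 5
        coco = boxes_to_coco(boxes)
        back = coco_to_boxes(coco)
        np.testing.assert_allclose(back["img1.png"], boxes["img1.png"])

    def test_json_serializable(self, small_scene):
        from seedlingcounter.synthetic import scenes_to_coco
        coco = scenes_to_coco([small_scene])
        json.dumps(coco)  # must not raise
        assert len(coco["annotations"]) == len(small_scene.boxes)
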