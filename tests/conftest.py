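"""Shared fixtures: the default synthetic scene and benchmark artifacts.

Heavy artifacts (segmentation of the default scene, the pooled
classification benchmark, the trained CNN) are session-scoped so the
end-to-end checks share one computation.
"""

import warnings

import pytest

from crownmap.classify import TrainConfig, make_fold_plan, train_cnn, train_svm_grid
from crownmap.pipeline import extract_object_images, label_objects_by_reference
from crownmap.raster import compute_slope, stack_layers
from crownmap.segmentation import (SegmentationParams, multiresolution_segment,
                                   polygonize_segments)
from crownmap.synthforest import SceneSpec, generate_scene, rasterize_references
from crownmap.texture import object_feature_table

BENCHMARK_WEIGHTS = (1.0, 1.0, 1.0, 0.3, 4.0)


@pytest.fixture(scope="session")
def default_scene():
    """The default synthetic forest scene (seed 0)."""
    return generate_scene(SceneSpec(seed=0))


@pytest.fixture(scope="session")
def default_segmap(default_scene):
    """Tuned-parameter segmentation of the default scene."""
    slope = compute_slope(default_scene.dsm)
    stack = stack_layers(default_scene.ortho, default_scene.dsm, slope,
                         BENCHMARK_WEIGHTS)
    return multiresolution_segment(stack, SegmentationParams(), seed=0)


@pytest.fixture(scope="session")
def default_polygons(default_segmap):
    return polygonize_segments(default_segmap)


def pooled_benchmark_objects(master_seed: int = 0, n_scenes: int = 3,
                             min_area: int = 600):
    """Objects pooled from several seeded scenes (multi-area campaign)."""
    out = []
    for si in range(n_scenes):
        scene = generate_scene(SceneSpec(seed=master_seed + si))
        slope = compute_slope(scene.dsm)
        stack = stack_layers(scene.ortho, scene.dsm, slope, BENCHMARK_WEIGHTS)
        segmap = multiresolution_segment(stack, SegmentationParams(),
                                         seed=master_seed + si)
        objs = extract_object_images(scene.ortho, segmap, min_area=min_area)
        ref_raster = rasterize_references(scene.references, scene.ortho.shape)
        objs = label_objects_by_reference(objs, segmap, ref_raster,
                                          scene.labels)
        for o in objs:
            o.id = si * 100000 + o.id
        out.extend(objs)
    return out


@pytest.fixture(scope="session")
def benchmark_objects():
    return pooled_benchmark_objects()


@pytest.fixture(scope="session")
def benchmark_features(benchmark_objects):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return object_feature_table(benchmark_objects, kernel_size=51)


@pytest.fixture(scope="session")
def svm_benchmark(benchmark_features):
    plan = make_fold_plan(list(benchmark_features.index), seed=0)
    return train_svm_grid(benchmark_features, plan, seed=0)


@pytest.fixture(scope="session")
def cnn_benchmark(benchmark_objects):
    images = {o.id: o.rgb for o in benchmark_objects}
    labels = {o.id: o.label for o in benchmark_objects}
    plan = make_fold_plan(sorted(images), seed=0)
    cfg = TrainConfig(patch_size=64, resize_size=72, epochs=10,
                      channels=(16, 32, 32), seed=0)
    return train_cnn(images, labels, plan, cfg), images, labels, cfg
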