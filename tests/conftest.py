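import numpy as np
import pytest

from myofiber_morph import (PixelScale, SceneSpec, SegmentationParams,
                            SizeLimits, apply_size_filter,
                            generate_cross_section, measure_regions,
                            preprocess_boundary, segment_fiber_maps,
                            write_fixture_batch)


@pytest.fixture(scope="session")
def clean_scene():
    """One noise-free field: 50 fibers, 40% central / 40% peripheral nuclei,
    known per-fiber intensity means."""
    spec = SceneSpec(n_fibers=50, seed=7,
                     central_fraction_of_fibers=0.4,
                     peripheral_fraction_of_fibers=0.4,
                     intensity_mean_range=(50.0, 200.0))
    return generate_cross_section(spec)


@pytest.fixture(scope="session")
def pipeline():
    """Run segmentation + morphometry on a scene; returns (maps, fibers)."""

    def _run(scene, quality="high", lower=200.0, upper=4800.0,
             um_per_pixel=1.0):
        pre = preprocess_boundary(scene.boundary, quality)
        maps = segment_fiber_maps(pre, SegmentationParams(quality=quality))
        cands = measure_regions(maps.measured, PixelScale(um_per_pixel))
        fibers = apply_size_filter(cands, SizeLimits(lower, upper))
        return maps, fibers

    return _run


@pytest.fixture(scope="session")
def clean_result(clean_scene, pipeline):
    return pipeline(clean_scene)


@pytest.fixture()
def fixture_batch(tmp_path):
    """Small on-disk batch of two scenes with all three channels."""
    specs = [SceneSpec(n_fibers=12, seed=s, area_mean_um2=1500.0,
                       central_fraction_of_fibers=0.5,
                       peripheral_fraction_of_fibers=0.25,
                       intensity_mean_range=(50.0, 200.0))
             for s in (3, 4)]
    root = tmp_path / "batch"
    write_fixture_batch(specs, root)
    return root


def match_to_truth(truth, maps, fibers):
    """Pair ground-truth fibers with detected fibers by mask IoU."""
    from myofiber_morph import MatchObject, match_objects

    ref = [MatchObject(centroid=f.centroid_rc, mask=truth.label_map == f.id)
           for f in truth.fibers]
    det = [MatchObject(centroid=f.centroid, mask=maps.measured == f.label)
           for f in fibers]
    return match_objects(ref, det)


@pytest.fixture(scope="session")
def truth_matcher():
    return match_to_truth
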