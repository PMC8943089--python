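import numpy as np
import pytest

from htoplan.geometry import LandmarkSet


def make_coronal(
    head=(0.0, 800.0),
    knee=(0.0, 400.0),
    ankle=(0.0, 0.0),
    medial=(-40.0, 400.0),
    lateral=(40.0, 400.0),
    condyle_medial=None,
    condyle_lateral=None,
) -> LandmarkSet:
    """Hand-built coronal view; condyles default to parallel the plateau."""
    if condyle_medial is None:
        condyle_medial = (medial[0] * 0.9, medial[1] + 3.0)
    if condyle_lateral is None:
        condyle_lateral = (lateral[0] * 0.9, lateral[1] + 3.0)
    return LandmarkSet(
        "coronal",
        {
            "femoral_head_center": head,
            "knee_center": knee,
            "ankle_center": ankle,
            "plateau_medial_edge": medial,
            "plateau_lateral_edge": lateral,
            "femoral_condyle_medial": condyle_medial,
            "femoral_condyle_lateral": condyle_lateral,
        },
    )


def make_sagittal(
    anterior=(25.0, 0.0),
    posterior=(-25.0, 0.0),
    cortex_proximal=(0.0, -10.0),
    cortex_distal=(0.0, -90.0),
) -> LandmarkSet:
    return LandmarkSet(
        "sagittal",
        {
            "plateau_tangent_anterior": anterior,
            "plateau_tangent_posterior": posterior,
            "posterior_cortex_proximal": cortex_proximal,
            "posterior_cortex_distal": cortex_distal,
        },
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20220323)
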