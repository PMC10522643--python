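"""Shared fixtures: synthetic scenes and cached feature sets.

Feature detection is the slow part of the suite, so speckle scenes and
their SIFT features are computed once per session.
"""

import numpy as np
import pytest

from glowlabel import barcode
from glowlabel.fixtures import (
    SerialFixtureSpec,
    SpeckleFixtureSpec,
    gen_serial_sequence,
    gen_speckle_scene,
)

PROJECTIVE_MATRIX = (
    (1.02, 0.015, 6.0),
    (0.01, 0.985, -4.0),
    (4e-6, -6e-6, 1.0),
)


@pytest.fixture(scope="session")
def serial_fixture():
    return gen_serial_sequence(
        SerialFixtureSpec(n_frames=10, occlusion_frames=frozenset({4, 5}), seed=0)
    )


@pytest.fixture(scope="session")
def speckle_identity():
    return gen_speckle_scene(SpeckleFixtureSpec(n_frames=1, warp="identity", seed=0))


@pytest.fixture(scope="session")
def speckle_translated():
    return gen_speckle_scene(
        SpeckleFixtureSpec(n_frames=1, warp="translation", translation=(30.0, 0.0), seed=0)
    )


@pytest.fixture(scope="session")
def speckle_projective():
    return gen_speckle_scene(
        SpeckleFixtureSpec(n_frames=1, warp="projective", matrix=PROJECTIVE_MATRIX, seed=1)
    )


@pytest.fixture(scope="session")
def speckle_features(speckle_identity):
    return barcode.detect_features(speckle_identity.template, image_id="template")


@pytest.fixture(scope="session")
def translated_features(speckle_translated):
    return barcode.detect_features(speckle_translated.frames[0], image_id="translated")


@pytest.fixture(scope="session")
def projective_pair_features(speckle_projective):
    fa = barcode.detect_features(speckle_projective.template, image_id="template")
    fb = barcode.detect_features(speckle_projective.frames[0], image_id="frame0")
    return fa, fb


@pytest.fixture(scope="session")
def unrelated_features():
    scene = gen_speckle_scene(SpeckleFixtureSpec(n_frames=1, warp="identity", seed=99))
    return barcode.detect_features(scene.template, image_id="unrelated")
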