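import numpy as np
import pytest

from shiftcheck.dicom_io import StructureContour
from shiftcheck.geometry import Frame, Vector3


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)


def vec(x, y, z, frame=Frame.DICOM_PATIENT):
    return Vector3(float(x), float(y), float(z), frame)


def contour(name, *points):
    return StructureContour(
        roi_name=name, points=tuple(vec(*p) for p in points)
    )


@pytest.fixture
def make_contour():
    return contour
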