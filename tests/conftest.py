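import numpy as np
import pytest

from pfqa.analyze import (
    absolute_center_config,
    analyze_image,
    relative_global_config,
    relative_local_config,
)
from pfqa.mlc import build_mlc_model, build_reference_plan
from pfqa.simulate import BeamModel, ImagerSpec, render_image


@pytest.fixture(scope="session", params=["M120", "HD120"])
def mlc(request):
    return build_mlc_model(request.param)


@pytest.fixture(scope="session")
def m120():
    return build_mlc_model("M120")


@pytest.fixture(scope="session")
def hd120():
    return build_mlc_model("HD120")


@pytest.fixture(scope="session")
def m120_plan(m120):
    return build_reference_plan(m120)


@pytest.fixture(scope="session")
def hd120_plan(hd120):
    return build_reference_plan(hd120)


@pytest.fixture(scope="session")
def beam():
    return BeamModel()


@pytest.fixture(scope="session")
def imager():
    return ImagerSpec()


@pytest.fixture(scope="session")
def reference_image_m120(m120_plan, imager, beam):
    """Noiseless full-resolution render of the unaltered M120 plan."""
    return render_image(m120_plan, imager, beam, noise=False)


@pytest.fixture(scope="session")
def reference_image_hd120(hd120_plan, imager, beam):
    return render_image(hd120_plan, imager, beam, noise=False)


@pytest.fixture(scope="session")
def reference_result_m120(reference_image_m120, m120_plan, m120):
    return analyze_image(reference_image_m120, m120_plan, m120, relative_local_config())


@pytest.fixture(scope="session")
def reference_absolute_m120(reference_image_m120, m120):
    return analyze_image(reference_image_m120, None, m120, absolute_center_config())
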