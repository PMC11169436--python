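import numpy as np
import pytest

from scoutreid import phantom as ph


@pytest.fixture(scope="session")
def latent():
    return ph.make_patient(42, "P001")


def neutral_params(vendor="S-like", dh=0.0, noise=0.0, exam_index=0):
    """Exam state with every nuisance at its neutral value."""
    return ph.ExamParams(
        vendor=vendor,
        table_offset_dh=dh,
        scan_range_shift=0.0,
        lung_inflation=1.0,
        gas_blobs=(),
        arms_raised=True,
        noise_sigma=noise,
        exam_index=exam_index,
    )


@pytest.fixture(scope="session")
def clean_render(latent):
    return ph.render_exam(latent, neutral_params())
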