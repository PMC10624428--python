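import numpy as np
import pytest

import sarcquant as sq
from sarcquant import phantoms as ph


@pytest.fixture(scope="session")
def default_params():
    return sq.QuantParams()


@pytest.fixture(scope="session")
def cal01():
    return sq.PixelCalibration(0.1)


@pytest.fixture(scope="session")
def composite():
    """Rendered three-modality composite cell plus its ground truth."""
    spec, truth = ph.composite_cell()
    masks, cell = ph.render(spec)
    return spec, truth, masks, cell


@pytest.fixture(scope="session")
def composite_results(composite, default_params):
    """Full pipeline results for the composite cell, all three modalities."""
    spec, truth, masks, cell = composite
    outline = sq.extract_outline(cell, spec.cal)
    results = {
        "actinin": sq.quantify_actinin(masks["actinin"], spec.cal, default_params, outline),
        "titin": sq.quantify_titin(masks["titin"], spec.cal, default_params, outline),
        "myomesin": sq.quantify_myomesin(masks["myomesin"], spec.cal, default_params, outline),
    }
    return spec, truth, results, outline


@pytest.fixture(scope="session")
def composite_bundle(composite_results):
    spec, truth, results, outline = composite_results
    return truth, sq.build_reports(results, cell_id="composite")


def render_and_quantify_actinin(spec, params, with_outline=True):
    """Helper: render a phantom and run the α-actinin-2 pipeline."""
    masks, cell = ph.render(spec)
    outline = None
    if with_outline and cell is not None:
        outline = sq.extract_outline(cell, spec.cal)
    return sq.quantify_actinin(masks["actinin"], spec.cal, params, outline)
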