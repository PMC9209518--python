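import warnings

import pytest


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # generators and fits warn deliberately (clamping, skipped placements);
    # tests assert on values, not warnings, unless they say otherwise
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
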