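import pytest

from photoacclim.presets import CONTROL, EL


@pytest.fixture(params=["control", "EL"], ids=["control", "EL"])
def preset(request):
    return {"control": CONTROL, "EL": EL}[request.param]
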