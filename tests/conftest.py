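import numpy as np
import pytest

from canaryresp import get_preset, list_presets, run_pattern

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


@pytest.fixture(scope="session")
def preset_runs():
    """One simulated trajectory per published preset (reused across tests)."""
    return {name: run_pattern(name) for name in list_presets()}


@pytest.fixture(scope="session")
def p0_params():
    return get_preset("P0").params
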