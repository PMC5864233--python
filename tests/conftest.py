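from __future__ import annotations

import pytest

from rhodosurvey.reference import load_reference
from rhodosurvey.synthetic import make_bundle


@pytest.fixture(scope="session")
def reference():
    """The bundled proteorhodopsin numbering frame with called TM segments."""
    return load_reference()


@pytest.fixture(scope="session")
def small_bundle():
    """One seeded synthetic survey shared by the pipeline-level tests."""
    return make_bundle(n_opsins=15, n_decoys=6, seed=42)
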