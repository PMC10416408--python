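import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from prehtn_cea import gen_fixture_bundle


@pytest.fixture(scope="session")
def bundle():
    return gen_fixture_bundle()


@pytest.fixture(scope="session")
def ctx(bundle):
    return bundle.context()


@pytest.fixture(scope="session")
def interventions(bundle):
    return bundle.interventions


@pytest.fixture(scope="session")
def base_results(ctx, interventions):
    from prehtn_cea import evaluate_strategy

    return [evaluate_strategy(ctx, iv) for iv in interventions.values()]
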