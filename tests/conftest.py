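import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rdnadiv import (VariantCall, synthetic_prototype,
                     synthetic_structure_annotation)

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def prototype():
    return synthetic_prototype()


@pytest.fixture(scope="session")
def annotation():
    return synthetic_structure_annotation()


def other_base(base: str) -> str:
    return "T" if base != "T" else "A"


@pytest.fixture(scope="session")
def snv_at(prototype):
    """Factory for a valid SNV call at a unit position (alt differs from ref)."""

    def make(position, ivf, isolate_id="iso", depth=3000, sb_phred=0.0,
             alt=None, hrun=None):
        ref = prototype.sequence[position - 1]
        return VariantCall(
            isolate_id=isolate_id, position=position, ref_seq=ref,
            alt_seq=alt or other_base(ref), ivf=ivf, depth=depth,
            sb_phred=sb_phred, hrun=hrun,
        )

    return make


@pytest.fixture(scope="session")
def call_row(prototype):
    """Factory for one row of the tabular call representation."""

    def make(position, ivf, isolate_id="iso", ref=None, alt=None, depth=3000):
        ref = ref or prototype.sequence[position - 1]
        return {
            "isolate_id": isolate_id, "position": position, "ref": ref,
            "alt": alt or other_base(ref), "ivf": ivf, "depth": depth,
        }

    return make


def table(rows) -> pd.DataFrame:
    return pd.DataFrame(rows)
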