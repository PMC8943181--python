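import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from orsmoke.design import OperationDesign
from orsmoke.registry import load_registry
from orsmoke.signal import OperationSummary

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry():
    return load_registry("packaged")


@pytest.fixture
def short_design():
    """Factory for a compact operation design (fast to simulate)."""

    def make(op_id="op0", approach="open", ses="without_ses",
             location="surgeon_level", duration=300.0):
        return OperationDesign(
            op_id=op_id, approach=approach, ses=ses, location=location, duration=duration
        )

    return make


def make_summary(op_id, ses="without_ses", approach="open", location="surgeon_level",
                 channel_stats=None, duration=300.0, **totals):
    """Build an OperationSummary directly (no simulation) for stats tests.

    ``channel_stats`` maps channel name -> (mean_ppb, max_ppb, argmax_fraction).
    """
    if channel_stats is None:
        channel_stats = {"c0": (1.0, 2.0, 0.5)}
    cs = pd.DataFrame.from_dict(
        channel_stats, orient="index",
        columns=["mean_ppb", "max_ppb", "argmax_time_fraction"],
    )
    defaults = dict(
        total_voc_mean_ppb=float(cs["mean_ppb"].sum()),
        total_voc_max_ppb=float(cs["max_ppb"].sum()),
        harmful_total_mean_ppb=float(cs["mean_ppb"].sum()),
        harmful_total_max_ppb=float(cs["max_ppb"].sum()),
    )
    defaults.update(totals)
    return OperationSummary(
        op_id=op_id,
        channel_stats=cs,
        design=OperationDesign(
            op_id=op_id, approach=approach, ses=ses, location=location, duration=duration
        ),
        **defaults,
    )


def uniform_argmax_summaries(rng: np.random.Generator, n_ops=30, n_channels=10):
    """Summaries whose argmax fractions are iid uniform (the no-pattern null)."""
    out = []
    for i in range(n_ops):
        stats = {
            f"c{j}": (0.0, float(rng.uniform(1.0, 100.0)), float(rng.uniform()))
            for j in range(n_channels)
        }
        out.append(make_summary(f"op{i:03d}", channel_stats=stats))
    return out
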