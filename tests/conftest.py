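import numpy as np
import pandas as pd
import pytest

from mirscreen import synthgen
from mirscreen.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def default_report(tmp_path_factory):
    """One full default pipeline run shared by integration-level tests."""
    out = tmp_path_factory.mktemp("pipeline_run")
    report = run_pipeline(PipelineConfig(), rng_seed=0, outdir=out)
    return report, out


@pytest.fixture(scope="session")
def small_screen():
    """A compact screen (400 miRs, 5 plates) with two deeply planted miRs."""
    effects = {
        "syn-mir-007": synthgen.EffectSize(-5.0, -5.0, 1.0),
        "syn-mir-008": synthgen.EffectSize(-5.0, -5.0, 0.5),
    }
    cfg = synthgen.SyntheticConfig(n_mirs=400, effect_sizes=effects, rng_seed=123)
    return synthgen.gen_well_data(cfg)


def make_measurements(values_by_plate, screen="migration", replicate=1):
    """Build a measurements/layout pair from {plate: [(well, content, mir, value)]}."""
    rows = []
    lay = []
    for plate, wells in values_by_plate.items():
        for well, content, mir, value in wells:
            rows.append((plate, well, replicate, screen, content, mir, value))
            lay.append((plate, well, content, mir))
    meas = pd.DataFrame(
        rows, columns=["plate", "well", "replicate", "screen", "content", "mir_name", "value"]
    )
    layout = pd.DataFrame(lay, columns=["plate", "well", "content", "mir_name"])
    return meas, layout
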