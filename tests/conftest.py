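import numpy as np
import pandas as pd
import pytest

import vo2arm as v


@pytest.fixture(scope="session")
def tiny_script():
    """Three short bouts with increasing intensity/load, 10 s rests."""
    return v.ActivityScript(
        bouts=[
            v.Bout(start_s=10, duration_s=20, intensity=0.3, load=2.0, motion_rate=1.0),
            v.Bout(start_s=40, duration_s=20, intensity=0.6, load=5.0, motion_rate=1.5),
            v.Bout(start_s=70, duration_s=20, intensity=0.9, load=10.0, motion_rate=2.0),
        ],
        tail_rest_s=10,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_script):
    return v.generate_cohort(3, script_template=tiny_script, seed=11)


@pytest.fixture(scope="session")
def tiny_table(tiny_cohort):
    return pd.concat(
        [v.build_feature_table(rec) for rec in tiny_cohort], ignore_index=True
    )


@pytest.fixture(scope="session")
def fast_model_config():
    """Small, quick training profile for wiring-level tests."""
    return v.ModelConfig(
        recurrent_units=8, dense_units=8, batch_size=32, max_epochs=3, patience=2, seed=3
    )
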