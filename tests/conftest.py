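import numpy as np
import pandas as pd
import pytest

import immunocontext as ic


@pytest.fixture(scope="session")
def small_cohort():
    """A 24-patient cohort with moderate planted effects, shared across tests."""
    cfg = ic.CohortConfig(
        n_patients=24,
        seed=7,
        effect_sizes={"TB_density_core": 1.0, "cytotoxic_T_density_frontin": -1.0},
    )
    return cfg, ic.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    _, cohort = small_cohort
    return ic.assemble_features(cohort)


def make_cells(points, cls="general_T", **flag_overrides):
    """Build a minimal cells table for unit tests."""
    from immunocontext.synthetic import _CLASS_FLAGS

    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    flags = dict(_CLASS_FLAGS[cls])
    frame = pd.DataFrame({"x_um": pts[:, 0], "y_um": pts[:, 1]})
    frame["class"] = cls
    for k, v in flags.items():
        frame[k] = v
    frame["pdl1"] = flag_overrides.pop("pdl1", cls == "PDL1_cell")
    for k, v in flag_overrides.items():
        frame[k] = v
    frame["bud_id"] = np.arange(len(frame)) if cls == "TB" else -1
    frame["is_bud"] = cls == "TB"
    return frame
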