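import warnings

import numpy as np
import pytest

from lznpk import CohortDesign, PopulationModel, generate_pk_dataset
from lznpk.io import CalibrationWarning

warnings.simplefilter("ignore", CalibrationWarning)


@pytest.fixture(scope="session")
def final_model() -> PopulationModel:
    """The final-model parameter set used as generating truth throughout."""
    return PopulationModel()


@pytest.fixture(scope="session")
def small_cohort(final_model):
    """A 12-child synthetic cohort with both sampling designs."""
    ds, truth = generate_pk_dataset(CohortDesign(n_subjects=12), final_model,
                                    seed=42)
    return ds, truth


@pytest.fixture(scope="session")
def rich_design():
    """Dense once-daily steady-state design for recovery checks."""
    times = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 18.0, 23.0)

    def build(n_subjects, seed, model, sigma_scale=1.0, weight_range=(5, 56)):
        import pandas as pd
        from lznpk.io import make_pk_dataset
        from lznpk.simulate import generate_concentrations
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_subjects):
            w = float(rng.uniform(*weight_range))
            base = dict(ID=f"R{i:03d}", OCC=1, WT=w, AGE=8.0, SEX="M",
                        ETHN="black", HIV=0, FORM="suspension", ROUTE="oral",
                        COHORT="MDRPK2")
            rows.append(dict(base, TIME=0.0, EVID=1, AMT=10.0 * w, DV=np.nan,
                             SS=1, II=24.0))
            for t in times:
                rows.append(dict(base, TIME=t, EVID=0, AMT=0.0, DV=np.nan,
                                 SS=0, II=0.0))
        skel = pd.DataFrame(rows)
        gen_model = model.with_updates(
            sigma2_prop=model.sigma2_prop * sigma_scale ** 2,
            sigma2_add=model.sigma2_add * sigma_scale ** 2)
        return generate_concentrations(skel, gen_model, seed=seed)

    return build
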