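import numpy as np
import pytest

import vwmchange as v
from vwmchange.comparison import marginal_from_table
from vwmchange.fitting import default_grid, fit_model

#: Study conditions for the recovery experiments: 1800 trials per simulated
#: observer, set sizes {2,4,6,8}, 50% change trials, reference generator
#: parameters, five independent synthetic observers.
RECOVERY_SEEDS = tuple(range(5))
N_TRIALS = 1800
RECOVERY_N_MC = 500


@pytest.fixture(scope="session")
def vp_recovery_study():
    """Five VP-generated datasets, each fitted by all five models.

    Shared by the parameter-recovery, model-recovery and summary-ordering
    tests because the fits are the expensive part.  VP is fitted with local
    refinement (its point estimates feed parameter recovery); all models'
    coarse-grid tables feed the marginal likelihoods.
    """
    records = []
    for seed in RECOVERY_SEEDS:
        trials = v.generate_experiment(N_TRIALS, seed=1000 + seed)
        responses = v.simulate_observer(
            "VP", v.REFERENCE_PARAMS["VP"], trials, seed=2000 + seed
        )
        fits, marginals = {}, {}
        for model in v.MODELS:
            fits[model] = fit_model(
                model,
                trials,
                responses,
                grid=default_grid(model, coarse=True),
                n_mc=RECOVERY_N_MC,
                seed=3000 + seed,
                refine=(model == "VP"),
            )
            marginals[model] = marginal_from_table(fits[model].log_likelihood_table)
        records.append(
            dict(
                seed=seed,
                trials=trials,
                responses=responses,
                fits=fits,
                marginals=marginals,
            )
        )
    return records
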