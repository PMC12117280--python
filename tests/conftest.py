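import numpy as np
import pandas as pd
import pytest

from memiselect import GeneratorConfig, OutcomeModel, generate_trial
from memiselect.predictors import PREDICTOR_NAMES
from memiselect.synthetic_rct import TrialDataset


@pytest.fixture(scope="session")
def trial200() -> "TrialDataset":
    """Default-condition synthetic trial, n=200, 10% missingness."""
    return generate_trial(GeneratorConfig(n_participants=200, seed=5))


@pytest.fixture(scope="session")
def null_trial() -> "TrialDataset":
    """Trial with no predictor-outcome association at all."""
    cfg = GeneratorConfig(
        n_participants=200,
        seed=17,
        outcome_model=OutcomeModel(main_effects={}, moderators={}),
    )
    return generate_trial(cfg)


def make_manual_trial(n: int, seed: int, remit_rule, missing: bool = False) -> TrialDataset:
    """Hand-built trial: predictors standard normal (plus the schema's
    binary/categorical columns), remission decided by ``remit_rule(df)``
    identically in both arms, severity back-filled around the cutoff."""
    rng = np.random.default_rng(seed)
    cols = {}
    for name in PREDICTOR_NAMES:
        if name in ("gender", "ethnicity", "education"):
            levels = {
                "gender": ["female", "male"],
                "ethnicity": ["chinese", "malay", "indian", "other"],
                "education": ["junior_college", "diploma", "university", "graduate"],
            }[name]
            cols[name] = rng.choice(levels, size=n)
        elif name in ("dx_depression_anxiety", "current_psychotherapy", "psychotropic_medication"):
            cols[name] = rng.integers(0, 2, size=n)
        else:
            cols[name] = rng.normal(size=n)
    df = pd.DataFrame(cols)
    df.insert(0, "arm", rng.integers(0, 2, size=n))
    df.insert(0, "participant_id", [f"M{i:05d}" for i in range(n)])
    remit = np.asarray(remit_rule(df)).astype(bool)
    spdq = np.where(remit, 5.0, 25.0)
    df["spdq_post"] = spdq
    df["spdq_1mfu"] = spdq
    df["prompts_completed"] = rng.integers(0, 71, size=n)
    return TrialDataset(df=df, truth=None, config=None)
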