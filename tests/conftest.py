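import numpy as np
import pandas as pd
import pytest

from ptrkit import TrialData, toy_trial
from ptrkit.trial import ROLE_MODERATOR, ROLE_PROGNOSTIC


@pytest.fixture
def toy() -> TrialData:
    return toy_trial()


def make_trial(Y, A, bio: dict, roles: dict, pi: float = 0.5) -> TrialData:
    """Small helper to assemble a TrialData from plain lists."""
    n = len(Y)
    return TrialData(
        subject_id=tuple(f"S{i + 1}" for i in range(n)),
        Y=np.asarray(Y, dtype=float),
        A=np.asarray(A, dtype=float),
        biomarkers=pd.DataFrame({k: np.asarray(v, dtype=float)
                                 for k, v in bio.items()}),
        roles=roles,
        pi=pi,
    )


def random_trial(rng: np.random.Generator, n: int = 40,
                 n_mod: int = 2, n_prog: int = 1) -> TrialData:
    """Random valid trial with both arms guaranteed."""
    A = np.where(rng.random(n) < 0.5, 0.5, -0.5)
    A[0], A[1] = 0.5, -0.5
    bio = {f"Z{j + 1}": rng.standard_normal(n) for j in range(n_mod)}
    bio.update({f"X{j + 1}": rng.standard_normal(n) for j in range(n_prog)})
    roles = {k: (ROLE_MODERATOR if k.startswith("Z") else ROLE_PROGNOSTIC)
             for k in bio}
    return make_trial(rng.standard_normal(n), A, bio, roles)
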