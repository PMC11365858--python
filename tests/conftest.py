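import numpy as np
import pytest

from myelotype.phantom import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def small_params():
    """Small-grid phantom parameters: fast to generate, ~36k WM voxels."""
    return PhantomParams(grid_shape=(48, 60, 48), target_t2_volume_ml=3.0,
                         t1_core_fraction=0.2, seed=11)


@pytest.fixture(scope="session")
def small_phantom(small_params):
    return generate_phantom(small_params)


@pytest.fixture(scope="session")
def lesion_free_phantom():
    return generate_phantom(PhantomParams(grid_shape=(48, 60, 48),
                                          target_t2_volume_ml=0.0, seed=5))


def auc_pair_oracle(scores, labels, positive="pos"):
    """Exhaustive pair-count concordance: (wins + 0.5 ties) / (n_pos*n_neg).

    Lower scores indicate the positive class, matching the classifier's
    operating convention.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    pos = s[lab == positive]
    neg = s[lab != positive]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p < n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
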