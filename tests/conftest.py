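import numpy as np
import pytest

from mosaicfit.inference import MCACall
from mosaicfit.synthetic import CohortSpec
from mosaicfit.theory import UKB_AGE_MIXTURE


@pytest.fixture
def small_cohort() -> CohortSpec:
    return CohortSpec(n_people=50_000)


def make_calls(
    fractions,
    label: str = "20q-",
    mca_class: str = "loss",
    sex: str = "female",
    ages=None,
    rng: np.random.Generator | None = None,
) -> list[MCACall]:
    """Wrap raw cell fractions into MCACall records for estimator tests."""
    fractions = np.asarray(fractions, dtype=float)
    if ages is None:
        rng = rng or np.random.default_rng(0)
        groups = UKB_AGE_MIXTURE.groups
        gi = rng.choice(len(groups), size=len(fractions), p=UKB_AGE_MIXTURE.weights)
        lo = np.array([g.lo for g in groups])[gi]
        hi = np.array([g.hi for g in groups])[gi]
        ages = lo + rng.random(len(fractions)) * (hi - lo)
    return [
        MCACall(
            person_id=f"P{i:06d}",
            age=float(a),
            sex=sex,
            label=label,
            mca_class=mca_class,
            cell_fraction=float(f),
        )
        for i, (f, a) in enumerate(zip(fractions, np.broadcast_to(ages, fractions.shape)))
    ]
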