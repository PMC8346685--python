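import numpy as np
import pytest

from roiclass.schemas import Feature, FeatureSchema, Hemisphere, Measure, Modality
from roiclass.synthetic import GeneratorConfig, generate_cohort


def make_tiny_schema(n: int = 6) -> FeatureSchema:
    """Small FA-style schema for fast tests (alternating hemispheres)."""
    hemis = [Hemisphere.left, Hemisphere.right]
    features = tuple(
        Feature(f"tract{i:02d}", Measure.FA, hemis[i % 2]) for i in range(n)
    )
    return FeatureSchema(modality=Modality.diffusion_FA, atlas="toy", features=features)


@pytest.fixture
def tiny_schema() -> FeatureSchema:
    return make_tiny_schema()


@pytest.fixture
def make_cohort():
    """Factory for standard-normal synthetic cohorts on a tiny schema."""

    def _make(
        schema=None,
        n_sites=1,
        n_hc=30,
        n_case=30,
        case_group="TLE-HS-L",
        seed=0,
        **kwargs,
    ):
        schema = schema or make_tiny_schema()
        counts = {g: n for g, n in {"HC": n_hc, case_group: n_case}.items() if n > 0}
        config = GeneratorConfig(
            schema=schema,
            n_sites=n_sites,
            n_per_site=counts,
            baseline=kwargs.pop("baseline", 0.0),
            noise_sd=kwargs.pop("noise_sd", 1.0),
            seed=seed,
            **kwargs,
        )
        return generate_cohort(config)

    return _make


@pytest.fixture
def separable_data():
    """Two well-separated 2-D Gaussian clouds."""
    rng = np.random.default_rng(42)
    X0 = rng.normal(-2.0, 0.5, (40, 2))
    X1 = rng.normal(2.0, 0.5, (40, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * 40 + [1] * 40)
    return X, y
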