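import numpy as np
import pytest

from sliceleak.preprocess import SliceRecord
from sliceleak.synthetic import SyntheticConfig, generate_cohort


def make_slices(
    n_subjects: int = 10,
    n_slices: int = 8,
    shape: tuple[int, int] = (8, 8),
    label_fn=None,
    seed: int = 0,
) -> list[SliceRecord]:
    """Hand-built slice records for split/CV tests (pixels are plain noise)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_subjects):
        label = label_fn(i) if label_fn is not None else i % 2
        for j in range(n_slices):
            out.append(
                SliceRecord(
                    subject_id=f"s{i:02d}",
                    label=int(label),
                    pixels=rng.standard_normal(shape),
                    slice_index=j,
                    entropy_bits=1.0,
                )
            )
    return out


@pytest.fixture(scope="session")
def tiny_cohort():
    """10 subjects, small volumes: fast input for preprocessing/CV tests."""
    config = SyntheticConfig(
        n_subjects_per_class=5,
        volume_shape=(10, 24, 24),
        template_smoothness=2.0,
        slice_noise_sd=0.2,
        seed=123,
    )
    return generate_cohort(config)
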