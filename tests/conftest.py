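import numpy as np
import pytest

from cgsnet.patch_sampler import QuotaConfig, build_dataset, extract_pair
from cgsnet.synthetic_wsi import generate_cohort


@pytest.fixture(scope="session")
def small_quotas():
    return QuotaConfig(noncancer_per_cancer_slide=6, cancer_per_cancer_slide=6,
                       cancer_boundary=8, island_boundary=4,
                       noncancer_per_noncancer_slide=6, attempt_cap=2500,
                       min_cancer_patches=10)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(2, 2, 1, seed=11, level2_size=704,
                           ambiguous_texture_fraction=0.3)


@pytest.fixture(scope="session")
def small_manifest(small_cohort, small_quotas):
    return build_dataset(small_cohort, quotas=small_quotas, seed=3)


@pytest.fixture(scope="session")
def small_pairs(small_cohort, small_manifest):
    slides = {s.slide_id: s for s in small_cohort}
    pairs = {"train": [], "val": [], "test": []}
    for rec in small_manifest.records:
        pairs[rec.split].append(extract_pair(slides[rec.slide_id], rec))
    for split in ("val", "test"):
        if not pairs[split]:
            pairs[split] = pairs["train"][-4:]
    return pairs


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
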