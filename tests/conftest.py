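import numpy as np
import pandas as pd
import pytest

from paircohort import CohortMetadata, CohortSpec, MetaboliteSpec, generate_human_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-family synthetic cohort shared by read-only tests."""
    spec = CohortSpec(n_families=12, n_taxa=80, depth_mean=4000.0, seed=42)
    mspec = MetaboliteSpec(n_metabolites=8, seed=42)
    return generate_human_cohort(spec, mspec)


def make_metadata(rows):
    """Build CohortMetadata from (sample_id, family_id, role, date) tuples."""
    return CohortMetadata(
        pd.DataFrame(
            [
                {
                    "sample_id": s,
                    "subject_id": s,
                    "family_id": f,
                    "role": r,
                    "collection_date": d,
                }
                for s, f, r, d in rows
            ]
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
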