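"""Shared fixtures; the expensive phantom cohorts are session-scoped."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from iish import ClusteringConfig, cludiss_for_patient
from iish.cohort import cohort_measures_table
from iish.phantom import CohortSpec, make_multisite_patient


@pytest.fixture(scope="session")
def small_phantom_patient():
    """A 2-lesion, 2-class patient used by cheap smoke/roundtrip tests."""
    return make_multisite_patient(n_lesions=2, n_classes=2, seed=42)


@pytest.fixture(scope="session")
def lesion_count_cohort():
    """40 patients differing only in the number of texturally distinct lesions.

    Lesion counts cycle 2..8; every lesion carries its own texture class, so
    the ground-truth heterogeneity knob is exactly the lesion count.
    """
    counts, values = [], []
    for i in range(40):
        n = 2 + i % 7
        volume, lesions, _ = make_multisite_patient(n_lesions=n, seed=1000 + i)
        res = cludiss_for_patient(volume, lesions, ClusteringConfig(seed=i))
        counts.append(n)
        values.append(res.value)
    return np.array(counts), np.array(values)


@pytest.fixture(scope="session")
def homogeneity_arms():
    """30 homogeneous vs 30 heterogeneous 4-lesion patients (matched design)."""
    hom, het = [], []
    for s in range(30):
        volume, lesions, _ = make_multisite_patient(
            4, n_classes=1, seed=3000 + s, radii=(6, 6, 2.5)
        )
        hom.append(cludiss_for_patient(volume, lesions, ClusteringConfig(seed=s)).value)
        volume, lesions, _ = make_multisite_patient(
            4, n_classes=4, seed=4000 + s, radii=(6, 6, 2.5)
        )
        het.append(cludiss_for_patient(volume, lesions, ClusteringConfig(seed=s)).value)
    return np.array(hom), np.array(het)


@pytest.fixture(scope="session")
def outcome_cohort() -> pd.DataFrame:
    """Outcome-linked phantom cohort with computed imaging measures.

    Resistance probability rises with the ground-truth number of texture
    classes while the lesion count varies independently, so the heterogeneity
    statistic carries outcome signal that conventional measures lack.
    """
    spec = CohortSpec(n_patients=60, seed=11)
    return cohort_measures_table(spec, clustering_seed=11)
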