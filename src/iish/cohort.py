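"""Cohort-level convenience pipeline: phantom generation to measure tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .heterogeneity import ClusteringConfig, cludiss_for_patient, conventional_measures
from .phantom import CohortSpec, generate_cohort, make_patient


def cohort_measures_table(
    spec: CohortSpec, clustering_seed: int = 0, scope: str = "all"
) -> pd.DataFrame:
    """Generate a phantom cohort and compute cluDiss + conventional measures.

    Returns one row per patient with imaging measures, clinical variables and
    the generator's ground truth, ready for risk scoring and classification.
    """
    rows = []
    for i, (pspec, clinical, truth) in enumerate(generate_cohort(spec)):
        volume, lesions, _ = make_patient(pspec)
        cfg = ClusteringConfig(seed=(clustering_seed + i) % 2**31)
        res = cludiss_for_patient(volume, lesions, clustering_config=cfg, scope=scope)
        conv = conventional_measures(lesions, volume.spacing)
        rows.append(
            {
                **clinical,
                "cluDiss": res.value,
                "cluDiss_evaluable": res.evaluable,
                "n_subregions": res.n_subregions,
                "ttv_cc": conv.ttv_cc,
                "n_sites": conv.n_sites,
                **{k: v for k, v in truth.items() if k != "patient_id"},
            }
        )
    return pd.DataFrame(rows)
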