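import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import kinscreen as ks


@pytest.fixture(scope="session")
def small_cohort():
    """Mixed 5k-marker cohort with every relationship class, error-free."""
    ped, focal = ks.standard_cohort(
        n_mz=5, n_po=5, n_fs=5, n_half_sib=5, n_unrelated_pairs=5
    )
    cfg = ks.SimulationConfig(n_markers_autosomal=5_000, n_markers_x=600, seed=11)
    ds, truth = ks.gene_drop(ped, cfg)
    return ped, focal, ds, truth


def quoted_family_calls():
    """The worked five-member family: PO, FS and second-degree calls."""
    import pandas as pd

    rows = [
        ("49", "45", "first", "PO"),
        ("50", "45", "first", "PO"),
        ("49", "48", "first", "PO"),
        ("50", "48", "first", "PO"),
        ("42", "49", "first", "PO"),
        ("48", "45", "first", "FS"),
        ("42", "45", "second", None),
        ("42", "48", "second", None),
    ]
    return pd.DataFrame(
        [
            {
                "id_i": a,
                "id_j": b,
                "degree": d,
                "subtype": s,
                "rule_fired": "kinship_band_default",
                "cross_population": False,
                "cross_subset": False,
                "inconsistent": False,
            }
            for a, b, d, s in rows
        ]
    )


FAMILY_SEXES = {"49": "female", "50": "male", "48": "female", "45": "male", "42": "male"}
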