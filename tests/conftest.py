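import numpy as np
import pandas as pd
import pytest

from stress_vbm import (
    AtlasSpec,
    CortisolSample,
    SubjectCortisolSeries,
    generate_atlas,
)

# printed summary statistics of the study cohort (inputs, not expectations)
UHR_FULL = (223.84, 233.52, 22)
UHR_NO_OUTLIER = (190.29, 176.77, 21)
UHR_TRANSITION = (24.75, 49.50, 4)
CONTROLS = (320.97, 253.85, 17)


def make_series(
    c0, c30, c60, volumes=(400.0, 400.0, 400.0), actual=(0.0, 30.0, 60.0),
    subject_id="S1",
):
    """Build a three-sample series; pass None to drop a sample."""
    samples = []
    for t, c, v, a in zip((0, 30, 60), (c0, c30, c60), volumes, actual):
        if c is None:
            continue
        samples.append(
            CortisolSample(
                subject_id=subject_id,
                nominal_time_min=t,
                concentration_nmol_l=c,
                volume_ul=v,
                actual_time_min=a,
            )
        )
    return SubjectCortisolSeries.from_samples(subject_id, samples)


@pytest.fixture(scope="session")
def small_atlas():
    return generate_atlas(AtlasSpec(grid_shape=(12, 12, 12), n_regions=6, seed=7))


@pytest.fixture()
def expression_rows():
    """Minimal two-region, two-donor, two-probe GR/MR table."""
    rows = []
    for region, base in ((1, 10.0), (2, 6.0)):
        for donor in ("D01", "D02"):
            for gene in ("GR", "MR"):
                for probe in (f"{gene}_p1", f"{gene}_p2"):
                    rows.append(
                        {
                            "donor_id": donor,
                            "probe_id": probe,
                            "gene": gene,
                            "region_label": region,
                            "expression": base,
                        }
                    )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
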