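import numpy as np
import pandas as pd
import pytest

from napmap.catalogue import catalogue_frame, make_catalogue
from napmap.cohort import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_params():
    """12-parameter panel over the two analysed coronal sections."""
    return make_catalogue({"B+0.98": 6, "B-1.34": 6}, seed=3)


@pytest.fixture(scope="session")
def small_catalogue(small_params):
    return catalogue_frame(small_params)


@pytest.fixture(scope="session")
def null_cohort(small_params):
    """All-null screen: 40 lines x 3 replicates against 60 shared WTs."""
    spec = CohortSpec(n_lines=40, n_wt=60, n_batches=6, fraction_nap=0.0, seed=1234)
    table, truth = simulate_cohort(spec, small_params)
    return table, truth


@pytest.fixture(scope="session")
def signal_cohort(small_params):
    """Screen with 25% planted lines in the severe band."""
    spec = CohortSpec(
        n_lines=40, n_wt=60, n_batches=6, fraction_nap=0.25,
        effect_band_weights=(0.0, 0.0, 1.0, 0.0), seed=77,
    )
    table, truth = simulate_cohort(spec, small_params)
    return table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_manual_table(groups: dict[str, list[float]], parameter: str = "p1",
                      background: str = "pure_B6N",
                      dates: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Tiny hand-built phenotype table; one parameter, explicit values."""
    rows = []
    i = 0
    for line, values in groups.items():
        ds = dates.get(line) if dates else None
        for j, v in enumerate(values):
            i += 1
            rows.append(
                {
                    "animal_id": f"A{i:03d}",
                    "line_id": line,
                    "gene": "Gene_" + line,
                    "zygosity": "wt" if line == "WT" else "hom",
                    "background": background,
                    "necropsy_date": (ds[j] if ds else "2009-01-05"),
                    parameter: v,
                }
            )
    return pd.DataFrame(rows)
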