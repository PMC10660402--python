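import numpy as np
import pandas as pd
import pytest

from methylpanel.calling import WellRecord
from methylpanel.simulate import TissueSimSpec, simulate_tissue_cohort


def make_well(sample_id="S1", well_index=1, msept9=None, malx4=None, msdc2=None, actb=30.0):
    """Build a WellRecord; None means the channel is undetermined."""
    nan = float("nan")
    return WellRecord(
        sample_id,
        well_index,
        {
            "mSEPT9": nan if msept9 is None else msept9,
            "mALX4": nan if malx4 is None else malx4,
            "mSDC2": nan if msdc2 is None else msdc2,
            "ACTB": nan if actb is None else actb,
        },
    )


def wells_to_table(pairs):
    """Long well table from a list of (well1, well2) WellRecord pairs."""
    rows = []
    for wells in pairs:
        for w in wells:
            rows.append(
                {
                    "sample_id": w.sample_id,
                    "well": w.well_index,
                    "ct_msept9": w.ct["mSEPT9"],
                    "ct_malx4": w.ct["mALX4"],
                    "ct_msdc2": w.ct["mSDC2"],
                    "ct_actb": w.ct["ACTB"],
                }
            )
    return pd.DataFrame(rows)


def random_grid_cohort(rng, n_samples, invalid_fraction=0.05):
    """Random two-well cohort with CTs on a coarse grid (incl. boundary
    values exactly at the cutoffs) and frequent undetermined channels."""
    grid = np.array(
        [25.0, 30.0, 34.0, 36.23, 36.8, 37.0, 38.0, 39.0, 40.0, 40.67, 41.0, 43.0, 44.0, 45.0, 46.0]
    )
    pairs = []
    for i in range(n_samples):
        wells = []
        for w in (1, 2):
            def channel(p_missing=0.35):
                if rng.random() < p_missing:
                    return None
                return float(rng.choice(grid))

            actb = 30.0 if rng.random() > invalid_fraction else float(rng.choice([40.0, 40.5, 41.0]))
            if rng.random() < 0.05:
                actb = None
            wells.append(
                make_well(f"S{i:05d}", w, channel(), channel(), channel(), actb)
            )
        pairs.append(tuple(wells))
    return pairs


@pytest.fixture(scope="session")
def small_tissue_cohort():
    """60 tumor / 30 normal, 300 probes, 10 planted informative markers."""
    spec = TissueSimSpec(
        n_tumor=60,
        n_normal=30,
        n_probes=300,
        n_informative=10,
        delta_beta_effect=0.45,
        control_beta_level=0.05,
        seed=11,
    )
    return simulate_tissue_cohort(spec)
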