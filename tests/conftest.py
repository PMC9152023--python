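import numpy as np
import pandas as pd
import pytest

from fosnet import RegionCountTable


def make_table(cell_values: dict, regions=None) -> RegionCountTable:
    """Build a RegionCountTable from {(sex, condition): [[row per animal]]}."""
    rows, ids, sexes, conds = [], [], [], []
    for (sex, cond), values in cell_values.items():
        for i, row in enumerate(np.atleast_2d(np.asarray(values, float))):
            rows.append(row)
            ids.append(f"{sex[0]}{cond[0]}{i}".upper())
            sexes.append(sex)
            conds.append(cond)
    rows = np.asarray(rows)
    regions = regions or [f"REG{j}" for j in range(rows.shape[1])]
    return RegionCountTable(
        counts=pd.DataFrame(rows, index=ids, columns=regions),
        factors=pd.DataFrame({"sex": sexes, "condition": conds}, index=ids),
    )


@pytest.fixture
def balanced_table():
    """Balanced 2x2 with n=3 per cell and two regions; pure training shift in REG0."""
    rng = np.random.default_rng(42)
    base = rng.uniform(40, 60, size=(12, 2))
    table = make_table({
        ("male", "naive"): base[0:3],
        ("female", "naive"): base[3:6],
        ("male", "trained"): base[6:9] + [30.0, 0.0],
        ("female", "trained"): base[9:12] + [30.0, 0.0],
    })
    return table


@pytest.fixture
def unbalanced_table():
    """Unbalanced 2x2 (5/4/3/4 animals) with 6 regions of random counts."""
    rng = np.random.default_rng(7)
    return make_table({
        ("male", "naive"): rng.uniform(20, 80, size=(5, 6)),
        ("female", "naive"): rng.uniform(20, 80, size=(4, 6)),
        ("male", "trained"): rng.uniform(20, 80, size=(3, 6)),
        ("female", "trained"): rng.uniform(20, 80, size=(4, 6)),
    })


@pytest.fixture
def raw_records():
    """Long-format per-section records for two animals x two regions."""
    rows = [
        # animal A1, REGA: sections (L=4,R=6) and (L=10,R=10) -> 7.5
        ("A1", "male", "naive", "REGA", 0.5, 4, 6),
        ("A1", "male", "naive", "REGA", 0.2, 10, 10),
        # animal A1, REGB: single section, right missing -> 8
        ("A1", "male", "naive", "REGB", -1.0, 8, None),
        ("A2", "female", "trained", "REGA", 0.5, 3, 5),
        ("A2", "female", "trained", "REGB", -1.0, 7, 9),
    ]
    return pd.DataFrame(rows, columns=["animal_id", "sex", "condition",
                                       "region", "bregma_mm",
                                       "left_count", "right_count"])
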