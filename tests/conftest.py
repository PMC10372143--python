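import numpy as np
import pandas as pd
import pytest

from zipswap.isotope import fit_crosstalk
from zipswap.seqgroups import SeqRecord, build_grouped_msa


def msa_from_rows(rows: dict[str, str], groups: dict[str, str], ref_id: str):
    records = [SeqRecord(id=k, seq=v) for k, v in rows.items()]
    return build_grouped_msa(records, groups, ref_id)


@pytest.fixture
def tiny_msa():
    """Four multi-metal + four Zn-preferring rows; columns 1 and 3 are DCRs.

    Group labels sort so the multi-metal (target) group is first, matching
    the scanner's default target/reference designation.
    """
    rows = {
        "t1": "MQAEL", "t2": "MQAEL", "t3": "MQAEL", "t4": "MQAEL",
        "r1": "MHAHL", "r2": "MHAHL", "r3": "MHAHL", "r4": "MHAHL",
    }
    groups = {k: ("multi_metal" if k.startswith("t") else "zn_preferring")
              for k in rows}
    return msa_from_rows(rows, groups, "t1")


@pytest.fixture
def noiseless_calib():
    """Exact 0.235-slope calibration from noiseless standards."""
    zn = np.array([0.0, 12500.0, 25000.0, 50000.0, 100000.0])
    return fit_crosstalk(pd.DataFrame({
        "standard_conc_uM": [0, 2.5, 5, 10, 20],
        "zn_window_cpm": zn,
        "cd_window_cpm": 0.235 * zn,
    }))


def make_wells(rows):
    """Shorthand: rows of (experiment, construct, zn, cd) -> tidy well table."""
    return pd.DataFrame(
        [{"experiment_id": e, "well_id": f"{e}_{c}_{i}", "construct": c,
          "zn_window_cpm": zn, "cd_window_cpm": cd}
         for i, (e, c, zn, cd) in enumerate(rows)])
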