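import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_connectivity():
    """4-TF, 40-gene identifiable connectivity with singleton anchors per TF."""
    from evotol import synth

    tfs = ["FlhDC", "GadE", "MarA", "PhoP"]
    return synth.sample_connectivity(40, tfs, seed=3, n_conditions=4)


@pytest.fixture
def two_by_two_design():
    rows = []
    for cond in ["mut_ctl", "mut_trt", "ref_ctl", "ref_trt"]:
        for b in (1, 2, 3):
            rows.append({"sample": f"{cond}_rep{b}", "condition": cond, "replicate": b})
    df = pd.DataFrame(rows)
    df["strain"] = df["condition"].str.split("_").str[0]
    df["treated"] = df["condition"].str.endswith("trt")
    return df
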