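import pandas as pd
import pytest

import ribodense as rd


@pytest.fixture(scope="session")
def scheme():
    return rd.FractionScheme.default()


@pytest.fixture(scope="session")
def quiet_noise():
    return rd.NoiseConfig(seed=0)


@pytest.fixture()
def small_truth():
    return rd.generate_truth(
        60, (0.2, 0.5, 0.3),
        rd.RbpConfig(sizes={"HuR": 12, "PCBP1": 12},
                     overlaps={("HuR", "PCBP1"): 4},
                     output_effect=0.7, te_effect=0.25),
        seed=42)


@pytest.fixture(scope="session")
def tiny_scheme():
    # one fraction per compartment; handy for arithmetic checks
    return rd.FractionScheme(
        ("a", "b", "c"),
        {"a": "free", "b": "monosome", "c": "polysome"})


def make_fpkm(rows):
    """rows: (gene_id, sample_id, fraction_id, fpkm)"""
    return pd.DataFrame(rows, columns=["gene_id", "sample_id",
                                       "fraction_id", "fpkm"])
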