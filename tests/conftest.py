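import numpy as np
import pandas as pd
import pytest

from era3 import CanonicalMiRNA, IsomiRTable, MiRNACatalog

MIR338_SEQ = "UCCAGCAUCAGUGAUUUUGUUG"


@pytest.fixture
def mir338() -> CanonicalMiRNA:
    return CanonicalMiRNA("miR-338-3p", MIR338_SEQ, arm="3p")


@pytest.fixture
def mir338_catalog(mir338) -> MiRNACatalog:
    return MiRNACatalog([mir338])


def make_table(rows, catalog=None) -> IsomiRTable:
    """Build a validated IsomiRTable from (mirna, sample, trim, tail, reads)
    tuples, computing ratios within each (miRNA, sample) group."""
    df = pd.DataFrame(
        rows, columns=["mirna_id", "sample_id", "len_trim", "tail_seq", "reads"]
    )
    df["len_5p"] = 0
    totals = df.groupby(["mirna_id", "sample_id"])["reads"].transform("sum")
    df["ratio"] = df["reads"] / totals
    if catalog is None:
        catalog = MiRNACatalog(
            [
                CanonicalMiRNA(m, "ACGUACGUACGUACGUACGUAC")
                for m in df["mirna_id"].unique()
            ]
        )
    cols = ["mirna_id", "sample_id", "len_trim", "tail_seq", "len_5p", "reads", "ratio"]
    return IsomiRTable(df[cols], catalog)


def random_table(rng: np.random.Generator, n_mirnas=5, n_samples=4) -> IsomiRTable:
    """Small random isomiR table for oracle comparisons."""
    rows = []
    for m in range(n_mirnas):
        mid = f"mir-{m}"
        for s in range(n_samples):
            n_iso = rng.integers(1, 5)
            trims = rng.integers(0, 4, size=n_iso)
            for i in range(int(n_iso)):
                tail = "".join(rng.choice(list("ACGU"), size=rng.integers(0, 3)))
                rows.append(
                    (mid, f"s{s}", int(trims[i]) if not tail else 0, tail,
                     int(rng.integers(10, 500)))
                )
    df = pd.DataFrame(
        rows, columns=["mirna_id", "sample_id", "len_trim", "tail_seq", "reads"]
    )
    df = df.drop_duplicates(subset=["mirna_id", "sample_id", "len_trim", "tail_seq"])
    return make_table(list(df.itertuples(index=False, name=None)))
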