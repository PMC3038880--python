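import pandas as pd
import pytest

from imprintqc import catalog as cat


@pytest.fixture(scope="session")
def packaged_catalog():
    return cat.load_assay_catalog()


@pytest.fixture
def tiny_methylation_table(tmp_path):
    """One assay, one sample, three CpGs (40, 50, 60)."""
    path = tmp_path / "tiny.csv"
    pd.DataFrame(
        {
            "assay": ["A1"] * 3,
            "sample": ["s1"] * 3,
            "cpg_index": [1, 2, 3],
            "percent": [40.0, 50.0, 60.0],
            "tissue": ["blood"] * 3,
        }
    ).to_csv(path, index=False)
    return path


def make_dataset(records, **extra_cols):
    """Build a MethylationDataset from (assay, sample, cpg, percent) tuples."""
    df = pd.DataFrame(records, columns=["assay", "sample", "cpg_index", "percent"])
    for col, values in extra_cols.items():
        df[col] = values
    return cat.MethylationDataset(df)
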