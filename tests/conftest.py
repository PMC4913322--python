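import numpy as np
import pandas as pd
import pytest

from oncoscape import OmicsMatrix, SampleMap


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_paired_map(n_pairs, cancer_type="TEST", n_extra_tumors=0):
    """Deduplicated sample map with n_pairs tumor/normal pairs."""
    patients = [f"P{i:03d}" for i in range(n_pairs + n_extra_tumors)]
    tumor_ids = [f"{p}-T" for p in patients]
    normal_ids = [f"{p}-N" for p in patients[:n_pairs]]
    return SampleMap(
        pd.DataFrame(
            {
                "patient_id": patients + patients[:n_pairs],
                "sample_id": tumor_ids + normal_ids,
                "sample_class": ["tumor_primary"] * len(patients)
                + ["normal"] * n_pairs,
                "cancer_type": cancer_type,
            }
        )
    ).deduplicate()


def make_matrix(values, genes, tumor_n, normal_n, tag="expression"):
    """Matrix whose columns follow make_paired_map's naming."""
    cols = [f"P{i:03d}-T" for i in range(tumor_n)] + [
        f"P{i:03d}-N" for i in range(normal_n)
    ]
    return OmicsMatrix(pd.DataFrame(values, index=genes, columns=cols), tag)
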