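import numpy as np
import pandas as pd
import pytest

from compseq.simulate import (SimConfig, generate_cohort, generate_design,
                              simulate_counts)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_subjects_cancer=6, n_subjects_control=6, n_assays=6,
                     n_genes=3, n_informative_assays=2, depth_mean=300,
                     base_error_rate=0.0, seed=42)


@pytest.fixture(scope="session")
def small_run(small_config):
    design = generate_design(small_config)
    subjects, truth = generate_cohort(small_config, design)
    tally = simulate_counts(truth, subjects, design, small_config)
    return {"config": small_config, "design": design, "subjects": subjects,
            "truth": truth, "tally": tally}


@pytest.fixture(scope="session")
def default_run():
    """Cohort at the default scale (115 subjects x 68 assays), no FASTQ."""
    config = SimConfig(seed=1)
    design = generate_design(config)
    subjects, truth = generate_cohort(config, design)
    tally = simulate_counts(truth, subjects, design, config)
    return {"config": config, "design": design, "subjects": subjects,
            "truth": truth, "tally": tally}


def make_matrix(values: np.ndarray, labels, gene_prefix="g"):
    """Hand-built AbundanceMatrix for filter/transform tests."""
    from compseq.quantify import ABSENT, MEASURED, AbundanceMatrix
    n, p = values.shape
    cols = [f"{gene_prefix}{j}" for j in range(p)]
    idx = [f"S{i:03d}" for i in range(n)]
    df = pd.DataFrame(values, index=idx, columns=cols)
    prov = pd.DataFrame(np.where(df.isna(), ABSENT, MEASURED),
                        index=idx, columns=cols)
    return AbundanceMatrix(df, prov, pd.Series(labels, index=idx), cols)
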