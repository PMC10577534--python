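import numpy as np
import pandas as pd
import pytest

import secretoclock as sc


@pytest.fixture(scope="session")
def small_config():
    return sc.SimulationConfig(seed=7, n_aptamers=150)


@pytest.fixture(scope="session")
def small_panel(small_config):
    panel = sc.simulate_panel(small_config)
    fpanel, _, _ = sc.filter_panel(panel)
    return fpanel


@pytest.fixture(scope="session")
def small_cohorts(small_config, small_panel):
    ref_m, ref_meta, truth = sc.simulate_aging_cohort(small_panel, small_config)
    st_m, st_meta, _ = sc.simulate_progeria_cohorts(small_panel, small_config)
    return ref_m, ref_meta, st_m, st_meta, truth


def make_two_group_matrix(values_a, values_b, n_aptamers=1, prefix="apt"):
    """Matrix with one aptamer column repeated, plus matching metadata:
    wildtype samples carry values_a, progeroid samples values_b."""
    vals = list(values_a) + list(values_b)
    sample_ids = [f"s{i}" for i in range(len(vals))]
    data = {f"{prefix}{j}": vals for j in range(n_aptamers)}
    matrix = sc.ProteomeMatrix(pd.DataFrame(data, index=sample_ids, dtype=float))
    meta = sc.SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "genotype": ["wildtype"] * len(values_a) + ["progeroid"] * len(values_b),
                "model": "LmnaG609G",
                "sex": ["male", "female"] * (len(vals) // 2) + ["male"] * (len(vals) % 2),
                "cohort": "c1",
                "age_months": 5.0,
            }
        )
    )
    return matrix, meta


def make_de_table(aptamer_ids, log2fc, fdr, p=None, gene_symbols=None):
    fdr = np.asarray(fdr, dtype=float)
    return pd.DataFrame(
        {
            "aptamer_id": aptamer_ids,
            "gene_symbol": gene_symbols if gene_symbols is not None else aptamer_ids,
            "log2FC": np.asarray(log2fc, dtype=float),
            "t": 0.0,
            "p": np.asarray(p, dtype=float) if p is not None else fdr,
            "fdr": fdr,
            "is_de": fdr < 0.05,
            "direction": np.where(np.asarray(log2fc, dtype=float) >= 0, "up", "down"),
        }
    )
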