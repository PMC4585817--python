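import numpy as np
import pandas as pd
import pytest

from admeta.expression import Contrast, ExpressionStudy
from admeta.synthetic import SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """Scaled-down simulation for fast end-to-end tests."""
    return SimulationConfig(
        seed=7,
        n_studies=3,
        probesets_per_study=600,
        samples_per_group=8,
        planted_down_genes=("NEUROD6", "SNAP25", "GOT2", "MRPS11"),
        compendium_size=60,
        compendium_male_fraction=0.5,
        compendium_probesets=300,
        snps_per_study=40,
        cases_per_study=150,
        controls_per_study=150,
        risk_or=6.0,  # small cohorts need a stronger planted effect to replicate
        n_profiles=20,
        profile_probesets=300,
    )


@pytest.fixture
def two_group_study() -> tuple[ExpressionStudy, Contrast]:
    """Tiny study with one strongly shifted probeset (control 10, case 6)."""
    rng = np.random.default_rng(42)
    n = 10
    sample_ids = [f"case{i}" for i in range(n)] + [f"ctrl{i}" for i in range(n)]
    values = rng.normal(8.0, 0.5, size=(50, 2 * n))
    values[0, :n] = rng.normal(6.0, 0.5, size=n)
    values[0, n:] = rng.normal(10.0, 0.5, size=n)
    matrix = pd.DataFrame(values, index=[f"ps{i:03d}" for i in range(50)], columns=sample_ids)
    samples = pd.DataFrame(
        {
            "group": ["case"] * n + ["control"] * n,
            "gender": ["M", "F"] * n,
            "compartment": ["cortex"] * 2 * n,
            "score": list(range(2 * n)),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    probe_map = pd.Series(
        [f"G{i:03d}" for i in range(50)], index=matrix.index, name="gene_symbol"
    )
    study = ExpressionStudy(
        name="toy", matrix=matrix, samples=samples, probe_map=probe_map
    )
    contrast = Contrast(case_ids=tuple(sample_ids[:n]), control_ids=tuple(sample_ids[n:]))
    return study, contrast
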