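import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import phyloscreen as ps

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_config() -> ps.SimConfig:
    """2 phyla x 2 bioregions x 1 category, balanced, noise-free cells."""
    return ps.SimConfig(
        phyla=("Porifera", "Chordata"),
        bioregions=("1", "2"),
        categories={"CYTOTOX": ("C1", "C2", "C3")},
        cell_n=5,
        cell_noise_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_screen(tiny_config):
    return ps.generate_screen(tiny_config)


@pytest.fixture(scope="session")
def random_records() -> pd.DataFrame:
    """1,000 random screening records over 4 phyla x 3 regions x 2 categories."""
    rng = np.random.default_rng(2024)
    n = 1000
    phyla = rng.choice(["Porifera", "Cnidaria", "Mollusca", "Chordata"], n)
    rows = []
    for i in range(n):
        category = ["CYTOTOX", "ANTIMICRO"][i % 2]
        assays = {"CYTOTOX": ["C1", "C2", "C3"], "ANTIMICRO": ["A1", "A2"]}[category]
        rows.append(
            {
                "sample_id": f"s{i // 3}",  # ~3 assay rows per sample
                "phylum": phyla[i // 3 % n],
                "genus": f"{phyla[i // 3 % n]}_g{i % 2}",
                "bioregion": str(rng.integers(1, 4)),
                "category": category,
                "assay_id": assays[i % len(assays)],
                "response": float(np.round(rng.normal(95, 20), 3)),
            }
        )
    df = pd.DataFrame(rows)
    # one response per (sample, assay): drop accidental duplicates
    df = df.drop_duplicates(["sample_id", "assay_id"]).reset_index(drop=True)
    df["response"] = df["response"].clip(lower=0.0)
    return df
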