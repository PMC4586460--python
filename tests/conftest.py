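import numpy as np
import pandas as pd
import pytest

from episcan.config import CATEGORIES, SimulationConfig
from episcan.pipeline import run_synthetic
from episcan.simulate import generate_cohort, generate_manifest


def small_sim_config(seed: int = 11, **overrides) -> SimulationConfig:
    """A scaled-down cohort that keeps the full statistical structure."""
    base = dict(
        n_probes=15_000,
        n_sex_chrom_probes=300,
        n_detection_fail_probes=20,
        burden_per_category={
            cat: ((46, 74) if cat == "normal_adequate" else (44, 90))
            for cat in CATEGORIES
        },
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_config():
    return small_sim_config()


@pytest.fixture(scope="session")
def small_manifest(small_config):
    return generate_manifest(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_manifest):
    return generate_cohort(small_config, small_manifest)


@pytest.fixture(scope="session")
def small_pipeline(small_config):
    return run_synthetic(small_config)


@pytest.fixture
def toy_manifest():
    """Hand-built sorted manifest: 10 probes over two chromosomes + extras."""
    return pd.DataFrame({
        "IlmnID": [f"cg{i:08d}" for i in range(1, 8)]
        + ["cg00000008", "cg00000009", "rs1000001"],
        "CHR": ["1", "1", "1", "1", "2", "2", "2", "X", "X", ""],
        "MAPINFO": [100, 200, 300, 400, 100, 150, 900, 500, 600, 0],
        "UCSC_RefGene_Name": ["GENEA;GENEB", "GENEA", "GENEA", "",
                              "GENEC", "GENEC", "BGENE1", "", "", ""],
        "UCSC_RefGene_Group": ["TSS200;Body", "TSS1500", "1stExon", "",
                               "5'UTR", "TSS200", "Body", "", "", ""],
        "Relation_to_UCSC_CpG_Island": ["Island", "Island", "N_Shore", "",
                                        "Island", "Island", "", "", "", ""],
        "Probe_SNPs": ["", "", "rs123", "", "", "", "", "", "", ""],
        "Probe_SNPs_10": ["", "", "", "", "", "rs456", "", "", "", ""],
    })


def make_beta(values: np.ndarray, probes=None, samples=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    probes = probes or [f"cg{i:08d}" for i in range(1, values.shape[0] + 1)]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=probes, columns=samples)
    df.index.name = "IlmnID"
    return df
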