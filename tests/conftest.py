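import numpy as np
import pandas as pd
import pytest

from igvprog.core_io import BetaMatrix, ClinicalTable, ProbeManifest
from igvprog.synthetic_data import SimConfig, gen_cohort, gen_manifest


def make_manifest(rows):
    df = pd.DataFrame(rows)
    return ProbeManifest(df.set_index("probe_id"))


def manifest_row(probe_id, gene="G1", region="Body", chromosome="chr1",
                 position=100, cgi_relation="open_sea", enhancer=False,
                 blacklisted=False):
    return dict(probe_id=probe_id, gene=gene, region=region,
                chromosome=chromosome, position=position,
                cgi_relation=cgi_relation, enhancer=enhancer,
                blacklisted=blacklisted)


@pytest.fixture
def toy_beta():
    """3 probes x 2 samples, fully observed."""
    values = np.array([[0.1, 0.2], [0.5, 0.6], [0.9, 0.8]])
    return BetaMatrix(
        probe_ids=np.array(["p1", "p2", "p3"], dtype=object),
        sample_ids=np.array(["s1", "s2"], dtype=object),
        values=values,
        missing_mask=np.zeros((3, 2), dtype=bool),
    )


@pytest.fixture
def small_clinical():
    rng = np.random.default_rng(0)
    n = 40
    df = pd.DataFrame({
        "time": rng.exponential(500.0, n) + 1,
        "event": rng.random(n) < 0.7,
        "age": rng.integers(45, 80, n),
        "stage": rng.integers(1, 5, n),
        "grade": rng.integers(1, 4, n),
        "residual": rng.integers(0, 2, n),
    }, index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"))
    return ClinicalTable(df)


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced synthetic cohort for pipeline-level unit tests."""
    cfg = SimConfig(n_samples=120, n_genes=100, n_signature_genes=10, seed=5)
    beta, clinical, truth = gen_cohort(cfg)
    return cfg, gen_manifest(cfg), beta, clinical, truth


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at the generator's default study-design scale."""
    cfg = SimConfig(seed=1)
    beta, clinical, truth = gen_cohort(cfg)
    return cfg, gen_manifest(cfg), beta, clinical, truth
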