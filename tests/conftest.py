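import pytest

from ptmtopo.sequence_features import build_feature_table, features_to_frame
from ptmtopo.synthetic_data import SyntheticConfig, generate_proteome


@pytest.fixture(scope="session")
def small_proteome(tmp_path_factory):
    """150-protein proteome with injected conflicts, written to disk."""
    cfg = SyntheticConfig(
        n_proteins=150,
        seed=42,
        conflict_rate_ss=0.08,
        conflict_rate_nglyc=0.06,
        conflict_rate_free_cys=0.08,
        conflict_rate_free_sequon=0.10,
        tmhmm2_flip_rate=0.15,
    )
    proteome = generate_proteome(cfg)
    out = tmp_path_factory.mktemp("small_proteome")
    paths = proteome.write(out)
    return proteome, paths


@pytest.fixture(scope="session")
def clean_proteome():
    """300-protein proteome with no injected conflicts (in memory only)."""
    return generate_proteome(SyntheticConfig(n_proteins=300, seed=9))


@pytest.fixture(scope="session")
def study_proteome():
    """2000-protein proteome at the study conditions (rate-recovery scale)."""
    return generate_proteome(SyntheticConfig(n_proteins=2000, seed=1))


@pytest.fixture(scope="session")
def study_frame(study_proteome):
    rows = build_feature_table(
        study_proteome.records, study_proteome.annotations, study_proteome.topologies
    )
    return features_to_frame(rows)
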