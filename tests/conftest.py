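import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def proteome(rng):
    """Small random proteome for natural-peptide sampling."""
    from mhc2deconv.blosum import AMINO_ACIDS

    local = np.random.default_rng(99)
    return {
        f"P{i:02d}": "".join(AMINO_ACIDS[j] for j in local.integers(0, 20, size=400))
        for i in range(10)
    }


@pytest.fixture(scope="session")
def tiny_study():
    """A small two-molecule study with one heterozygous sample: enough signal
    for parameter-recovery checks at unit-test scale."""
    from mhc2deconv.synthetic import MaSampleSpec, StudyConfig, generate_study

    cfg = StudyConfig(
        sa_molecules=("DQA10101-DQB10501", "DQA10303-DQB10301"),
        sa_n_pos=600,
        ma_samples=(
            MaSampleSpec("MA1", ("DQA10101-DQB10501", "DQA10303-DQB10301"), (0.55, 0.45), 400),
        ),
        n_ba_per_molecule=80,
        negative_multiplier=2,
        seed=11,
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def tiny_model(tiny_study):
    """A small trained ensemble (1 seed x 2 architectures x 5 folds) on the
    tiny study, with calibrations."""
    import pandas as pd

    from mhc2deconv.calibration import build_calibrations
    from mhc2deconv.datasets import partition_common_motif
    from mhc2deconv.nnalign import TrainingConfig, train

    b = tiny_study
    peptides = pd.concat([b.el["peptide"], b.ba["peptide"]], ignore_index=True)
    part = partition_common_motif(peptides, k=5, seed=11)
    cfg = TrainingConfig(
        epochs=15, burn_in_epochs=3, n_seeds=1, hidden_sizes=(40, 60), n_folds=5, seed=11
    )
    model = train(b.el, b.ba, b.samples, part, b.pseudo_table, config=cfg)
    mols = sorted({m for s in b.samples.values() for m in s.molecules})
    model.calibrations.update(
        build_calibrations(model, mols, b.proteome, n=2000, seed=11)
    )
    model._partitioning = part  # stashed for tests that need CV folds
    return model
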