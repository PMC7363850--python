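import numpy as np
import pytest

from flipkit import predictor, readproc, synthdata


@pytest.fixture(scope="session")
def small_experiment(tmp_path_factory):
    """A small noiseless simulated experiment on disk plus its truth."""
    out = tmp_path_factory.mktemp("simexp")
    cfg = synthdata.SimConfig(
        n_variants=25,
        substitution_error_rate=0.0,
        depth_lognormal_params=(np.log(80.0), 0.0),
        seed=11,
    )
    variants, r1, r2, idx = synthdata.simulate_to_fastq(cfg, out)
    return {"config": cfg, "variants": variants, "r1": r1, "r2": r2,
            "indexes": idx}


@pytest.fixture(scope="session")
def activity_dataset():
    """Synthetic sequence-activity map, desk size for fast model tests."""
    seqs, y, mu = synthdata.synthetic_sequence_activity(2500, seed=7)
    X = predictor.encode_batch(seqs)
    split = predictor.stratified_split(y, seed=3)
    return {"sequences": seqs, "X": X, "y": y, "mu": mu, "split": split}


@pytest.fixture(scope="session")
def tiny_net(activity_dataset):
    """One small trained network shared across model-dependent tests."""
    cfg = predictor.NetConfig(
        n_blocks=2, filters=12, kernel_sizes=(9, 1), fc_units=24,
        batch_size=256, max_epochs=10, patience=4, seed=0,
    )
    d = activity_dataset
    return predictor.build_and_train(d["X"], d["y"], cfg, d["split"])


@pytest.fixture(scope="session")
def tiny_ensemble(activity_dataset):
    """A 1-config x 2-seed ensemble for mixture/attribution tests."""
    cfg = predictor.NetConfig(
        n_blocks=2, filters=12, kernel_sizes=(9, 1), fc_units=24,
        batch_size=256, max_epochs=8, patience=4, seed=5,
    )
    d = activity_dataset
    return predictor.train_ensemble(
        d["X"], d["y"], [cfg], seeds_per_config=2, split=d["split"]
    )


@pytest.fixture()
def sites():
    return readproc.SiteDefinitions()
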