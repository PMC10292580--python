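"""Shared fixtures: trained models and synthetic runs are expensive, so
they are session-scoped and reused by module and acceptance tests."""

import numpy as np
import pytest

from deardia import embed_vae, groupscore, synthdia

TRAIN_SEED = 0


@pytest.fixture(scope="session")
def trained_vae():
    """VAE trained on 20,000 synthetic triplets for 5 epochs."""
    xics = synthdia.make_training_xics(n_peptides=300, seed=TRAIN_SEED)
    triplets = synthdia.make_triplets(xics, n=20000, seed=TRAIN_SEED + 1)
    params, history = embed_vae.train_vae(
        triplets, epochs=5, batch_size=256, seed=TRAIN_SEED)
    return {"params": params, "history": history}


@pytest.fixture(scope="session")
def trained_cnn():
    """CNN trained on 2,000 labeled synthetic fragment groups, 5 epochs."""
    pairs = synthdia.make_group_examples(2000, seed=TRAIN_SEED)
    params, history = groupscore.train_classifier(
        pairs, epochs=5, batch_size=64, seed=TRAIN_SEED)
    return {"params": params, "history": history}


@pytest.fixture(scope="session")
def small_run():
    """10-peptide, 30-cycle synthetic SWATH run with ground truth."""
    sim = synthdia.SimConfig(n_peptides=10, n_cycles=30, seed=3)
    run, truths = synthdia.simulate_run(sim)
    return run, truths, sim


@pytest.fixture(scope="session")
def e2e_run():
    """20-peptide, 45-cycle run used by the end-to-end recovery tests."""
    sim = synthdia.SimConfig(n_peptides=20, n_cycles=45, seed=42)
    run, truths = synthdia.simulate_run(sim)
    return run, truths, sim
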