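import numpy as np
import pytest

import lipidmsm as lm


@pytest.fixture(scope="session")
def hierarchy_model():
    return lm.build_preset_generator("paper-hierarchy")


@pytest.fixture(scope="session")
def two_state_model():
    """Symmetric two-state exchange with a 500 ns relaxation time."""
    k = 0.001  # per ns, both directions
    K = np.array([[-k, k], [k, -k]])
    return lm.GroundTruthModel(
        state_names=("a", "b"),
        centers=np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]]),
        rate_matrix=K,
        jitter_sigma=1.0,
        stationary=np.array([0.5, 0.5]),
        exact_timescales=np.array([500.0]),
    )


@pytest.fixture(scope="session")
def three_state_model():
    """Small asymmetric reversible chain used for propagation/consistency tests."""
    pi = np.array([0.2, 0.3, 0.5])
    K = np.zeros((3, 3))
    for a, (i, j) in zip((0.02, 0.005), ((0, 1), (1, 2))):
        K[i, j] = a * pi[i]
        K[j, i] = a * pi[j]
    K -= np.diag(K.sum(axis=0))
    from lipidmsm.synthetic import _timescales_from_rate_matrix

    return lm.GroundTruthModel(
        state_names=("x", "y", "z"),
        centers=np.array([[0.0, 0, 0], [8.0, 0, 0], [0, 8.0, 0]]),
        rate_matrix=K,
        jitter_sigma=0.8,
        stationary=pi,
        exact_timescales=_timescales_from_rate_matrix(K),
    )


@pytest.fixture(scope="session")
def recovery_run(hierarchy_model):
    """The full default-plan recovery run shared by the acceptance tests.

    100 trajectories x 300 us at 10 ns frames (seeds 0..99), regular-space
    clustering at 4 Å, sliding counts at lag 30 ns, reversible MLE.
    """
    model = hierarchy_model
    trajs = [
        lm.sample_jump_trajectory(model, 300_000.0, 10.0, seed=i, ligand_id=f"lig{i}")
        for i in range(100)
    ]
    positions = np.concatenate([t.positions for t in trajs])
    clusters = lm.regular_space_cluster(positions, 4.0)
    labels = lm.assign(positions, clusters)
    seqs = np.split(labels, np.cumsum([t.n_frames for t in trajs])[:-1])
    counts = lm.count_matrix(seqs, 10.0, 30.0, n_states=clusters.n_clusters)
    tmodel = lm.reversible_mle(counts)
    return {
        "model": model,
        "trajectories": trajs,
        "positions": positions,
        "clusters": clusters,
        "labels": labels,
        "label_seqs": seqs,
        "counts": counts,
        "tmodel": tmodel,
    }
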