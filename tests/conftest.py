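import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def easy3_truth():
    from hamadl.synthetic import scenario_fixtures, simulate_scenario, with_seed

    return simulate_scenario(with_seed(scenario_fixtures("easy3"), 1))


@pytest.fixture(scope="session")
def easy3_trained(easy3_truth):
    from hamadl import pipeline
    from hamadl.config import PipelineConfig

    train_seqs = easy3_truth.sequences[:6]
    return pipeline.train(
        [st.sequence for st in train_seqs],
        {st.sequence.subject_id: st.descriptor_segments for st in train_seqs},
        PipelineConfig(k_high=3, seed=1),
    )


def make_topology(centers, level="high"):
    """Topology from bare centers (unit sigma, equal weights)."""
    from hamadl.scene_model import SceneRegion, Topology

    centers = np.asarray(centers, dtype=float)
    w = 1.0 / len(centers)
    return Topology(
        level,
        [SceneRegion(i, c, np.ones(2), w) for i, c in enumerate(centers)],
    )


def random_scene_das(seed, n_points=120, fps=25.0):
    """Discovered activities of a random walk over a small random scene.

    Used to produce structurally varied model/test tree pairs.
    """
    from hamadl.pipeline import sequence_das
    from hamadl.scene_model import SceneModel
    from hamadl.trajectory_io import TrajectorySequence

    rng = np.random.default_rng(seed)
    sm = SceneModel(
        {
            lvl: make_topology(rng.uniform(0, 10, (k, 2)), lvl)
            for lvl, k in (("high", 2), ("mid", 4), ("low", 6))
        }
    )
    xy = np.cumsum(rng.normal(0, 0.8, (n_points, 2)), axis=0) + 5.0
    seq = TrajectorySequence("r", np.arange(n_points), xy, fps=fps)
    return sequence_das(seq, sm)
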