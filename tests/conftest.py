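import numpy as np
import pytest

from circml import synth
from circml.seqio import FeatureTable, IntervalTrack, ScoreTrack, TranscriptRecord

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "ci", derandomize=True, deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("ci")
except ImportError:  # hypothesis is an optional test dependency
    pass


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def record():
    return TranscriptRecord("tx1", "ACGTACGTACGTACGTACGT", "chr1", 101, 120, "+")


@pytest.fixture
def small_table():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(40, 4))
    y = np.repeat([0, 1], 20)
    X[y == 1, 0] += 3.0
    return FeatureTable(
        transcript_ids=[f"t{i}" for i in range(40)],
        feature_names=["a", "b", "c", "d"],
        values=X,
        group_of={n: "g" for n in "abcd"},
        labels=y,
    )


@pytest.fixture(scope="session")
def synth_pipeline_inputs():
    """One small synthetic universe shared by assembly-level tests."""
    cfg = synth.SynthConfig(n_per_class=30, seed=11)
    records, labels = synth.gen_sequences(cfg)
    tracks = synth.gen_tracks(cfg, records, labels)
    ids = [r.id for r in records]
    graph, ranking = synth.gen_graph_matrix(cfg, ids, labels)
    annotations = synth.gen_regulatory_annotations(cfg, ids)
    return dict(
        config=cfg, records=records, labels=labels, tracks=tracks,
        graph=graph, ranking=ranking, annotations=annotations,
    )
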