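import numpy as np
import pytest

from gelminer.features import extract_features
from gelminer.figure_model import (
    BoundingBox,
    Segment,
    SegmentKind,
    SegmentSource,
    figure_from_array,
)
from gelminer import gel_classifier
from gelminer.synthetic_figures import GeneratorConfig, generate_figure


def make_segment(
    sid: str,
    box: tuple[int, int, int, int],
    kind: SegmentKind = SegmentKind.GRAPHIC,
    text: str = "",
    is_gel: bool | None = None,
) -> Segment:
    return Segment(
        segment_id=sid,
        bbox=BoundingBox(*box),
        kind=kind,
        text=text,
        source=SegmentSource.ANNOTATION,
        is_gel=is_gel,
    )


def corpus_features(seed: int, start: int, stop: int, **cfg_kwargs):
    """Feature matrix + labels over generated figures [start, stop)."""
    cfg = GeneratorConfig(seed=seed, **cfg_kwargs)
    X, y = [], []
    for i in range(start, stop):
        fig, ann = generate_figure(cfg, i)
        for seg in ann.segments:
            if seg.kind is SegmentKind.GRAPHIC:
                X.append(extract_features(fig, seg).to_array())
                y.append(bool(seg.is_gel))
    return np.array(X), np.array(y)


@pytest.fixture(scope="session")
def synth_model():
    """A default classifier trained on a small synthetic corpus."""
    X, y = corpus_features(101, 0, 60)
    return gel_classifier.train(X, y, seed=0)


@pytest.fixture(scope="session")
def synth_probe():
    """Held-out labeled probe set from the same generator distribution."""
    return corpus_features(101, 60, 90)
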