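import json
from pathlib import Path

import numpy as np
import pytest

from mstai import EvaluationGrid, MembershipVector, build_reference
from mstai.io import default_swatch_path


@pytest.fixture(scope="session")
def palette() -> list:
    """The ten shipped MST swatch RGB triples."""
    payload = json.loads(Path(default_swatch_path()).read_text())
    return [s["rgbs"][0] for s in sorted(payload["scales"], key=lambda s: s["id"])]


@pytest.fixture(scope="session")
def reference(palette):
    """Fitted reference densities, shared across the whole run."""
    return build_reference(palette, n_pixels=2000, seed=11)


@pytest.fixture(scope="session")
def small_grid() -> EvaluationGrid:
    return EvaluationGrid(32)


def mv_from_ranking(ranking, scores_by_rank=None, n_scales=10) -> MembershipVector:
    """Build a membership vector whose ranking and per-rank scores are prescribed."""
    ranking = np.asarray(ranking, dtype=int)
    assert len(ranking) == n_scales
    if scores_by_rank is None:
        raw = np.linspace(0.2, 0.05, n_scales)
        scores_by_rank = raw / raw.sum()
    scores = np.empty(n_scales)
    for pos, scale_id in enumerate(ranking):
        scores[scale_id - 1] = scores_by_rank[pos]
    divergences = 1.0 - scores / scores.max()
    return MembershipVector(scores=scores, divergences=divergences, ranking=ranking)
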