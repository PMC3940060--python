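import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pathcloud import (
    ExpressionStudy,
    GeneRole,
    PathwayCloud,
    RoleAnnotatedPathway,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_cloud() -> PathwayCloud:
    """Two small pathways with mixed activator/repressor roles."""
    return PathwayCloud(pathways=(
        RoleAnnotatedPathway(
            pathway_id="P1", name="pathway one",
            members=(
                GeneRole("ACT1", 1.0),
                GeneRole("ACT2", 0.5),
                GeneRole("REP1", -1.0),
            ),
        ),
        RoleAnnotatedPathway(
            pathway_id="P2", name="pathway two",
            members=(GeneRole("ACT3", 1.0), GeneRole("REP2", -0.5)),
        ),
    ))


@pytest.fixture
def tiny_study() -> ExpressionStudy:
    """5 genes x 4 samples; old samples equal the young mean (null case)."""
    genes = ("ACT1", "ACT2", "REP1", "ACT3", "REP2")
    young = np.array([
        [10.0, 10.0],
        [4.0, 4.0],
        [8.0, 8.0],
        [6.0, 6.0],
        [2.0, 2.0],
    ])
    old = young.copy()
    return ExpressionStudy(
        genes=genes,
        samples=("Y1", "Y2", "O1", "O2"),
        values=np.hstack([young, old]),
        cohort={"Y1": "young", "Y2": "young", "O1": "old", "O2": "old"},
    )


def perturb_old(study: ExpressionStudy, gene: str, factor: float,
                sample: str | None = None) -> ExpressionStudy:
    """Multiply one gene's old value(s) by a factor (helper for tests)."""
    values = study.values.copy()
    row = study.genes.index(gene)
    cols = ([study.sample_index(sample)] if sample is not None
            else [study.sample_index(s) for s in study.old_samples])
    values[row, cols] *= factor
    return study.with_values(values)
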