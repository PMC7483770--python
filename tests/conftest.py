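import numpy as np
import pandas as pd
import pytest

from cnaprofiles import GeneratorFunction, SimulatedCohort

# Five-subject worked example: binary alteration statuses over five
# 1,000-bp regions, and the per-subject segment rows they expand to.
EXAMPLE_MATRIX = np.array(
    [
        [0, 0, 0, 0, 1],
        [0, 0, 0, 1, 1],
        [0, 1, 1, 1, 0],
        [0, 0, 0, 1, 1],
        [0, 0, 1, 0, 1],
    ],
    dtype=np.int8,
)

EXAMPLE_SEGMENTS = [
    ("S1", 4000, 5000),
    ("S2", 3000, 4000),
    ("S2", 4000, 5000),
    ("S3", 1000, 2000),
    ("S3", 2000, 3000),
    ("S3", 3000, 4000),
    ("S4", 3000, 4000),
    ("S4", 4000, 5000),
    ("S5", 2000, 3000),
    ("S5", 4000, 5000),
]

# Five example patient vectors over ten regions (binary alteration status).
PATIENT_VECTORS = np.array(
    [
        [0, 1, 1, 1, 0, 0, 0, 0, 0, 0],
        [0, 0, 1, 1, 0, 0, 0, 0, 0, 0],
        [0, 0, 1, 1, 1, 0, 0, 0, 0, 0],
        [0, 1, 0, 1, 1, 0, 0, 0, 0, 0],
        [0, 1, 0, 1, 1, 1, 0, 0, 0, 0],
    ],
    dtype=np.int8,
)

# Ten-region unimodal alteration signature used across the simulator docs.
EXAMPLE_PHI = (0.0, 0.2, 0.7, 0.8, 0.6, 0.4, 0.1, 0.0, 0.0, 0.0)


@pytest.fixture
def example_cohort() -> SimulatedCohort:
    gen = GeneratorFunction(probs=(0.0,) * 5, region_size=1000)
    return SimulatedCohort(EXAMPLE_MATRIX.copy(), gen, seed=0)


@pytest.fixture
def example_segments(example_cohort) -> pd.DataFrame:
    from cnaprofiles import matrix_to_segments

    return matrix_to_segments(example_cohort)


@pytest.fixture
def example_generator() -> GeneratorFunction:
    return GeneratorFunction(probs=EXAMPLE_PHI, region_size=1000, label="example")


def per_base_coverage(segments: pd.DataFrame, hi: int | None = None) -> np.ndarray:
    """Brute-force per-base subject-coverage counts over [0, hi).

    Independent oracle for the sweep-line partition: adds 1 over every
    segment's span with a plain boolean-free accumulation loop.
    """
    if hi is None:
        hi = int(segments["end"].max()) if len(segments) else 0
    cov = np.zeros(hi, dtype=np.int64)
    for start, end in zip(segments["start"], segments["end"]):
        cov[int(start): int(end)] += 1
    return cov


def per_subject_coverage(segments: pd.DataFrame, hi: int | None = None) -> dict:
    """Per-subject boolean coverage masks (brute force)."""
    if hi is None:
        hi = int(segments["end"].max()) if len(segments) else 0
    masks: dict = {}
    for sid, group in segments.groupby("sample_id"):
        mask = np.zeros(hi, dtype=np.int64)
        for start, end in zip(group["start"], group["end"]):
            mask[int(start): int(end)] += 1
        masks[sid] = mask
    return masks


def segments_frame(rows, chromosome="1", call="ALTERED") -> pd.DataFrame:
    """Build an altered-segment table from (sample_id, start, end) tuples."""
    return pd.DataFrame(
        [(sid, chromosome, s, e, call) for sid, s, e in rows],
        columns=["sample_id", "chromosome", "start", "end", "call"],
    )
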