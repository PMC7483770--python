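"""Bernoulli cohort simulator for validating the partition estimator.

A generator function assigns each fixed-size genomic region an alteration
probability Phi(r).  A simulated subject is one independent Bernoulli draw
per region; a cohort is a subjects x regions binary status matrix.  The
matrix converts to a per-subject segment dataset (each altered region
becomes one segment; adjacent altered regions stay as separate book-ended
segments, mimicking how real segmented data carries its own breakpoints),
which feeds the partition sweep so the whole estimation path can be tested
against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .segments import CALL_COLUMNS, SEG_COLUMNS, ALTERED, GAIN, LOSS


@dataclass(frozen=True)
class GeneratorFunction:
    """Discrete per-region alteration probabilities defining a population.

    ``probs[r]`` is the probability that region ``r`` is altered in a
    subject drawn from this population; all regions share one size in
    base pairs.  Region ``r`` spans ``[r * region_size, (r+1) * region_size)``.
    """

    probs: tuple[float, ...]
    region_size: int = 1000
    label: str = ""

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.probs)
        object.__setattr__(self, "probs", probs)
        if len(probs) < 1:
            raise ValueError("generator function needs at least one region")
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.region_size <= 0:
            raise ValueError(f"region_size must be positive, got {self.region_size}")

    @property
    def n_regions(self) -> int:
        return len(self.probs)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)


@dataclass
class SimulatedCohort:
    """Binary subjects x regions alteration matrix with its provenance."""

    matrix: np.ndarray
    generator: GeneratorFunction
    seed: int
    call: str = ALTERED
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("cohort matrix must be 2-D (subjects x regions)")
        if self.matrix.shape[1] != self.generator.n_regions:
            raise ValueError("matrix column count must equal the number of regions")
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1}" for i in range(self.matrix.shape[0])]

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]


def _subject_streams(seed: int, n_subjects: int) -> list[np.random.Generator]:
    # one child stream per subject so cohorts are reproducible regardless of
    # subject iteration order
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_subjects)]


def sample_cohort(
    gen: GeneratorFunction, n_subjects: int, seed: int, call: str = ALTERED
) -> SimulatedCohort:
    """Draw a cohort: one independent Bernoulli per (subject, region)."""
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    probs = gen.as_array()
    rows = [
        (stream.random(gen.n_regions) < probs).astype(np.int8)
        for stream in _subject_streams(seed, n_subjects)
    ]
    return SimulatedCohort(np.vstack(rows), gen, seed, call=call)


def three_state_cohort(
    gen_gain: GeneratorFunction,
    gen_loss: GeneratorFunction,
    n_subjects: int,
    seed: int,
) -> tuple[SimulatedCohort, SimulatedCohort]:
    """Draw gain/loss/normal states per cell; a cell is never both.

    Per cell one uniform draw lands in the gain band [0, p_gain), the loss
    band [p_gain, p_gain + p_loss) or remains normal.  Requires
    ``p_gain + p_loss <= 1`` at every region.
    """
    if gen_gain.n_regions != gen_loss.n_regions:
        raise ValueError("gain and loss generators must cover the same regions")
    if gen_gain.region_size != gen_loss.region_size:
        raise ValueError("gain and loss generators must share region_size")
    pg, pl = gen_gain.as_array(), gen_loss.as_array()
    over = np.nonzero(pg + pl > 1.0 + 1e-12)[0]
    if len(over):
        raise ValueError(
            f"gain + loss probability exceeds 1 at region {int(over[0])}"
        )
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    gains, losses = [], []
    for stream in _subject_streams(seed, n_subjects):
        u = stream.random(gen_gain.n_regions)
        gains.append((u < pg).astype(np.int8))
        losses.append(((u >= pg) & (u < pg + pl)).astype(np.int8))
    return (
        SimulatedCohort(np.vstack(gains), gen_gain, seed, call=GAIN),
        SimulatedCohort(np.vstack(losses), gen_loss, seed, call=LOSS),
    )


def matrix_to_segments(cohort: SimulatedCohort, chromosome: str = "1") -> pd.DataFrame:
    """Convert a status matrix to per-subject segments on region coordinates.

    Each altered cell (s, r) becomes one segment
    ``[r * region_size, (r+1) * region_size)``.  Runs of adjacent altered
    regions are emitted as separate book-ended segments, not merged, so
    every region boundary survives as a breakpoint — the partition sweep
    must recover the original grid exactly.  Ordered by subject then start.
    """
    size = cohort.generator.region_size
    rows = []
    for sid, status in zip(cohort.sample_ids, cohort.matrix):
        for r in np.nonzero(status)[0]:
            rows.append((sid, chromosome, int(r) * size, (int(r) + 1) * size, cohort.call))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def cohort_to_seg_frame(cohort: SimulatedCohort, chromosome: str = "1") -> pd.DataFrame:
    """Render a simulated cohort as a SEG-style segment table.

    Placeholder log2 segment means of +1 (gains/altered) or -1 (losses) and
    a probe count of one per kilobase (floored, minimum 1) let simulated
    cohorts exercise the full file I/O and calling path.
    """
    segs = matrix_to_segments(cohort, chromosome)
    seg_mean = -1.0 if cohort.call == LOSS else 1.0
    num_probes = max(1, cohort.generator.region_size // 1000)
    out = segs.rename(columns={"call": "seg_mean"})
    out["seg_mean"] = seg_mean
    out["num_probes"] = num_probes
    return out[SEG_COLUMNS]


def load_generator(path) -> GeneratorFunction:
    """Read a generator function from a YAML/JSON config.

    Expected keys: ``probs`` (list of probabilities), optional
    ``region_size`` (bp, default 1000) and ``label``.
    """
    with open(str(path)) as fh:
        cfg = yaml.safe_load(fh)
    return GeneratorFunction(
        probs=tuple(cfg["probs"]),
        region_size=int(cfg.get("region_size", 1000)),
        label=str(cfg.get("label", "")),
    )


#: Example generator over ten equal regions used throughout the docs/tests.
EXAMPLE_GENERATOR = GeneratorFunction(
    probs=(0.0, 0.2, 0.7, 0.8, 0.6, 0.4, 0.1, 0.0, 0.0, 0.0),
    region_size=1000,
    label="example-unimodal",
)

#: Four built-in generator functions for convergence studies: the example
#: unimodal signature plus three shapes chosen to cover distinct profiles
#: (two separated peaks, a flat mid-level plateau, a monotone ramp).
BUILTIN_GENERATORS = (
    EXAMPLE_GENERATOR,
    GeneratorFunction(
        probs=(0.1, 0.6, 0.9, 0.3, 0.0, 0.0, 0.3, 0.9, 0.6, 0.1),
        region_size=1000,
        label="bimodal",
    ),
    GeneratorFunction(
        probs=(0.0, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.0),
        region_size=1000,
        label="plateau",
    ),
    GeneratorFunction(
        probs=(0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
        region_size=1000,
        label="ramp",
    ),
)
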