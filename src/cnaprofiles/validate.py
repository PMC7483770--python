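"""Error metrics between true and estimated generator functions.

With a known truth Phi(r) and a cohort estimate Phihat(r) the estimator is
scored by a squared error normalised by cohort size,

    epsilon   = Sum_r (Phi(r) - Phihat(r))^2 / N_subjects,

and a percentage (relative) error over the supported regions,

    epsilon_p = Sum_{r: Phi(r) > 0} (Phi(r) - Phihat(r))^2 / Phi(r).

Since Var(Phihat) = Phi(1 - Phi)/n per region, the expected value of
Sum_r (Phi - Phihat)^2 is Sum_r Phi(1-Phi)/n and both metrics shrink as
cohorts grow; the convergence study measures that decay empirically by
running the full simulate -> segments -> partition -> estimate pipeline at
increasing cohort sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .partition import partition_segments
from .profile import estimate_profile
from .simulate import GeneratorFunction, matrix_to_segments, sample_cohort


@dataclass(frozen=True)
class ErrorReport:
    """Error metrics of one estimated profile against its known truth."""

    epsilon: float
    epsilon_pct: float
    n_subjects: int
    n_regions: int
    generator_id: str = ""
    n_unsupported: int = 0  # regions with Phi=0 but Phihat>0, excluded from epsilon_pct


def _check_lengths(true_phi, est_phi) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(true_phi, dtype=float)
    e = np.asarray(est_phi, dtype=float)
    if t.shape != e.shape:
        raise ValueError(
            f"probability vectors differ in length ({t.shape} vs {e.shape})"
        )
    return t, e


def error_sq(true_phi, est_phi, n_subjects: int) -> float:
    """Squared error between the vectors, normalised by cohort size."""
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    t, e = _check_lengths(true_phi, est_phi)
    return float(np.sum((t - e) ** 2) / n_subjects)


def error_pct(true_phi, est_phi) -> float:
    """Relative squared error over regions with Phi(r) > 0.

    Regions where both truth and estimate are zero contribute nothing;
    regions with Phi=0 but a nonzero estimate are excluded here and
    counted separately by :func:`evaluate_errors` rather than producing an
    infinite term.
    """
    t, e = _check_lengths(true_phi, est_phi)
    supported = t > 0
    return float(np.sum((t[supported] - e[supported]) ** 2 / t[supported]))


def count_unsupported(true_phi, est_phi) -> int:
    """Regions with zero true probability but a nonzero estimate."""
    t, e = _check_lengths(true_phi, est_phi)
    return int(np.sum((t == 0) & (e > 0)))


def evaluate_errors(
    true_phi, est_phi, n_subjects: int, generator_id: str = ""
) -> ErrorReport:
    """Bundle both error metrics and the unsupported-region count."""
    t, e = _check_lengths(true_phi, est_phi)
    return ErrorReport(
        epsilon=error_sq(t, e, n_subjects),
        epsilon_pct=error_pct(t, e),
        n_subjects=n_subjects,
        n_regions=len(t),
        generator_id=generator_id,
        n_unsupported=count_unsupported(t, e),
    )


def align_profile_to_grid(
    regions: pd.DataFrame, gen: GeneratorFunction, n_subjects: int
) -> np.ndarray:
    """Map partition output back onto a generator's fixed region grid.

    The partition emits only covered regions; on simulated data every
    emitted region aligns to one grid cell (all breakpoints are multiples
    of ``region_size``).  Grid cells absent from the partition get
    Phihat = 0.
    """
    phat = np.zeros(gen.n_regions, dtype=float)
    if regions.empty:
        return phat
    starts = regions["start"].to_numpy()
    ends = regions["end"].to_numpy()
    size = gen.region_size
    if ((starts % size) != 0).any() or ((ends - starts) != size).any():
        raise ValueError(
            "partition regions do not align to the generator's region grid"
        )
    idx = starts // size
    if (idx >= gen.n_regions).any():
        raise ValueError("partition region lies outside the generator's grid")
    phat[idx] = regions["n_occurrences"].to_numpy() / n_subjects
    return phat


def estimate_from_cohort(gen: GeneratorFunction, n_subjects: int, seed: int):
    """One pipeline pass: simulate, segment, partition, estimate on the grid."""
    cohort = sample_cohort(gen, n_subjects, seed)
    segments = matrix_to_segments(cohort)
    regions = partition_segments(segments, n_subjects)
    # estimate_profile validates counts and computes the exact ratio
    profile = estimate_profile(regions, n_subjects)
    return align_profile_to_grid(profile.table, gen, n_subjects)


def convergence_study(
    generators,
    sizes,
    replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Mean and SD of both error metrics over cohort sizes and replicates.

    For each (generator, size) cell the full pipeline runs ``replicates``
    times with independent child seeds spawned from ``seed``; the table
    reports the mean and standard deviation of epsilon and epsilon_pct.
    Reproducible for a fixed seed.
    """
    sizes = list(sizes)
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sizes must be strictly increasing")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    generators = list(generators)
    root = np.random.SeedSequence(seed)
    rows = []
    gen_seqs = root.spawn(len(generators))
    for gen, gen_seq in zip(generators, gen_seqs):
        truth = gen.as_array()
        label = gen.label or f"generator-{gen.n_regions}"
        size_seqs = gen_seq.spawn(len(sizes))
        for n, size_seq in zip(sizes, size_seqs):
            eps, eps_p = [], []
            for child in size_seq.spawn(replicates):
                rep_seed = int(child.generate_state(1)[0] % (2**31))
                phat = estimate_from_cohort(gen, n, rep_seed)
                eps.append(error_sq(truth, phat, n))
                eps_p.append(error_pct(truth, phat))
            rows.append(
                {
                    "generator_id": label,
                    "n_subjects": n,
                    "replicates": replicates,
                    "epsilon_mean": float(np.mean(eps)),
                    "epsilon_sd": float(np.std(eps, ddof=1)) if replicates > 1 else 0.0,
                    "epsilon_pct_mean": float(np.mean(eps_p)),
                    "epsilon_pct_sd": float(np.std(eps_p, ddof=1))
                    if replicates > 1
                    else 0.0,
                }
            )
    return pd.DataFrame(rows)
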