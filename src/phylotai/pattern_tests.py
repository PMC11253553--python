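"""Permutation tests for temporal index-profile shapes.

Three tests classify an iTAI/iTDI trajectory against a permutation
null in which gene ages (or Ka/Ks values) are shuffled across the gene
set while the induction weights |FC_it| stay fixed — the null states
that gene age is exchangeable given induction:

* flat-line test: statistic V = variance of the profile across
  timepoints; large V means the profile deviates from constancy.
* reductive hourglass test: with the timepoints partitioned into
  early / mid / late stages, D = min(min_early - min_mid,
  min_late - min_mid); large positive D means a mid-stage minimum
  flanked by higher values (high-low-high).
* reverse hourglass (vase) test: D' = min(max_mid - max_early,
  max_mid - max_late); large positive D' means a mid-stage maximum
  (low-high-low).

p-values are upper-tail probabilities of the observed statistic under
a distribution fitted to the permuted statistics — a moment-matched
gamma for the nonnegative, right-skewed variance of the flat-line
test, a Gaussian for the stage statistics — with the rank-based
empirical p reported alongside.  The whole procedure is repeated over
independent runs and the aggregate p is the arithmetic mean of the
per-run Gaussian p-values.  A means-over-stages variant of both stage
statistics is available via ``stage_stat="means"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from phylotai.data_model import InductionTable, StagePartition, ValidationError
from phylotai.indices import compute_index

__all__ = [
    "ProfileInputs",
    "PatternTestResult",
    "permuted_profiles",
    "flat_line_test",
    "reductive_hourglass_test",
    "reverse_hourglass_test",
]

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 10_000
DEFAULT_RUNS = 100


@dataclass
class ProfileInputs:
    """Strata and fixed |FC| weights defining an index profile.

    ``strata`` has one value per gene; ``weights`` is the genes x
    timepoints |FC| matrix.  The observed profile is the weighted mean
    of strata per timepoint, exactly as computed by
    :func:`phylotai.indices.compute_index`.
    """

    strata: np.ndarray
    weights: np.ndarray
    timepoints: np.ndarray

    def __post_init__(self) -> None:
        self.strata = np.asarray(self.strata, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if self.weights.shape != (self.strata.size, self.timepoints.size):
            raise ValidationError("weights shape does not match strata x timepoints")
        totals = self.weights.sum(axis=0)
        if (totals == 0).any():
            raise ValidationError("zero total |FC| weight at some timepoint")

    @classmethod
    def from_tables(
        cls,
        tab: InductionTable,
        strata: Mapping[str, float] | pd.Series,
        genes: Iterable[str],
        condition: str,
        timepoints: Sequence[float] | None = None,
    ) -> "ProfileInputs":
        strata = pd.Series(strata, dtype=float)
        genes = sorted(set(genes))
        have = [g for g in genes if g in strata.index and np.isfinite(strata[g])]
        if timepoints is None:
            timepoints = list(tab.timepoints)
        W = tab.abs_fc_matrix(condition, genes=have, timepoints=timepoints)
        return cls(
            strata=strata[W.index].to_numpy(),
            weights=W.to_numpy(),
            timepoints=np.asarray(timepoints, dtype=float),
        )

    def observed_profile(self) -> np.ndarray:
        return (self.strata @ self.weights) / self.weights.sum(axis=0)


@dataclass
class PatternTestResult:
    """Outcome of one pattern test."""

    kind: str  # "flt" | "rht" | "rvt"
    statistic: float
    null_mean: float
    null_sd: float
    p_per_run: np.ndarray
    p_empirical: float
    n_perm: int
    runs: int
    seed: int | None

    def __post_init__(self) -> None:
        self.p_per_run = np.asarray(self.p_per_run, dtype=float)
        if ((self.p_per_run < 0) | (self.p_per_run > 1)).any():
            raise ValidationError("per-run p-values outside [0, 1]")

    @property
    def p_value(self) -> float:
        """Aggregate p: arithmetic mean of the per-run Gaussian p-values."""
        return float(self.p_per_run.mean())

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "statistic": float(self.statistic),
            "null_mean": float(self.null_mean),
            "null_sd": float(self.null_sd),
            "p_gaussian": self.p_value,
            "p_empirical": float(self.p_empirical),
            "n_perm": self.n_perm,
            "runs": self.runs,
            "seed": self.seed,
        }


def permuted_profiles(
    inputs: ProfileInputs, n_perm: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Index profiles under ``n_perm`` shuffles of the stratum values.

    Weights stay fixed; each row of the result is the profile obtained
    after one independent permutation of strata across genes.
    Deterministic given the seed.
    """
    if inputs.strata.size < 3:
        raise ValidationError(
            f"gene set of size {inputs.strata.size} too small to permute (need >= 3)"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    perm = rng.permuted(
        np.broadcast_to(inputs.strata, (n_perm, inputs.strata.size)), axis=1
    )
    totals = inputs.weights.sum(axis=0)
    return (perm @ inputs.weights) / totals


def _flat_stat(profiles: np.ndarray) -> np.ndarray:
    return np.var(profiles, axis=-1)


def _stage_stat(
    profiles: np.ndarray,
    idx: dict[str, np.ndarray],
    kind: str,
    stage_stat: str,
) -> np.ndarray:
    e, m, l = profiles[..., idx["early"]], profiles[..., idx["mid"]], profiles[..., idx["late"]]
    if stage_stat == "minima":
        if kind == "rht":
            return np.minimum(e.min(-1) - m.min(-1), l.min(-1) - m.min(-1))
        return np.minimum(m.max(-1) - e.max(-1), m.max(-1) - l.max(-1))
    if stage_stat == "means":
        de = e.mean(-1) - m.mean(-1) if kind == "rht" else m.mean(-1) - e.mean(-1)
        dl = l.mean(-1) - m.mean(-1) if kind == "rht" else m.mean(-1) - l.mean(-1)
        return np.minimum(de, dl)
    raise ValueError(f"unknown stage_stat {stage_stat!r}")


def rht_statistic(
    profile: np.ndarray, stages: StagePartition, timepoints: Sequence[float],
    stage_stat: str = "minima",
) -> float:
    """Reductive-hourglass statistic D of a single profile."""
    idx = stages.indices(timepoints)
    return float(_stage_stat(np.asarray(profile, float), idx, "rht", stage_stat))


def rvt_statistic(
    profile: np.ndarray, stages: StagePartition, timepoints: Sequence[float],
    stage_stat: str = "minima",
) -> float:
    """Reverse-hourglass (vase) statistic D' of a single profile."""
    idx = stages.indices(timepoints)
    return float(_stage_stat(np.asarray(profile, float), idx, "rvt", stage_stat))


def _run_test(
    inputs: ProfileInputs,
    kind: str,
    stat_fn,
    n_perm: int,
    runs: int,
    seed: int | None,
    null_dist: str = "norm",
) -> PatternTestResult:
    rng = np.random.default_rng(seed)
    obs = float(stat_fn(inputs.observed_profile()))
    p_runs = np.empty(runs)
    null_means = np.empty(runs)
    null_sds = np.empty(runs)
    exceed = 0
    for r in range(runs):
        null = stat_fn(permuted_profiles(inputs, n_perm, rng))
        mu, sd = float(null.mean()), float(null.std(ddof=1))
        null_means[r] = mu
        null_sds[r] = sd
        if sd == 0.0:
            if obs > mu:
                logger.warning(
                    "%s: degenerate null (sd = 0) with statistic above the null mean; "
                    "p reported as 0", kind,
                )
                p_runs[r] = 0.0
            else:
                p_runs[r] = 1.0
        elif null_dist == "gamma":
            # moment-matched gamma: the right fit for a nonnegative,
            # right-skewed variance statistic
            shape = mu * mu / (sd * sd)
            scale = sd * sd / mu
            p_runs[r] = stats.gamma.sf(obs, shape, scale=scale)
        else:
            p_runs[r] = stats.norm.sf(obs, loc=mu, scale=sd)
        exceed += int((null >= obs).sum())
    p_emp = (1 + exceed) / (1 + runs * n_perm)
    return PatternTestResult(
        kind=kind,
        statistic=obs,
        null_mean=float(null_means.mean()),
        null_sd=float(null_sds.mean()),
        p_per_run=p_runs,
        p_empirical=p_emp,
        n_perm=n_perm,
        runs=runs,
        seed=seed,
    )


def flat_line_test(
    inputs: ProfileInputs,
    n_perm: int = DEFAULT_N_PERM,
    runs: int = DEFAULT_RUNS,
    seed: int | None = None,
) -> PatternTestResult:
    """Does the profile deviate from a flat line?

    Statistic: variance of the index across timepoints.  Requires at
    least 3 timepoints.
    """
    if inputs.timepoints.size < 3:
        raise ValidationError("flat-line test needs >= 3 timepoints")
    return _run_test(inputs, "flt", _flat_stat, n_perm, runs, seed, null_dist="gamma")


def reductive_hourglass_test(
    inputs: ProfileInputs,
    stages: StagePartition,
    n_perm: int = DEFAULT_N_PERM,
    runs: int = DEFAULT_RUNS,
    seed: int | None = None,
    stage_stat: str = "minima",
) -> PatternTestResult:
    """Does the profile follow an hourglass (high-low-high) pattern?"""
    idx = stages.indices(inputs.timepoints)

    def stat(profiles: np.ndarray) -> np.ndarray:
        return _stage_stat(profiles, idx, "rht", stage_stat)

    return _run_test(inputs, "rht", stat, n_perm, runs, seed)


def reverse_hourglass_test(
    inputs: ProfileInputs,
    stages: StagePartition,
    n_perm: int = DEFAULT_N_PERM,
    runs: int = DEFAULT_RUNS,
    seed: int | None = None,
    stage_stat: str = "minima",
) -> PatternTestResult:
    """Does the profile follow a vase (low-high-low) pattern?"""
    idx = stages.indices(inputs.timepoints)

    def stat(profiles: np.ndarray) -> np.ndarray:
        return _stage_stat(profiles, idx, "rvt", stage_stat)

    return _run_test(inputs, "rvt", stat, n_perm, runs, seed)
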