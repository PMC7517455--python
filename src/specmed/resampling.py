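"""Nonparametric bootstrap confidence intervals and stratified-permutation
null tests for the plug-in measure estimators.

The bootstrap draws whole-row resamples of size n with replacement and
reports percentile intervals of the replicate estimates.  The permutation
null destroys exactly one causal link: to break an edge (a, b) of the
mediation triangle, the parent column a is shuffled within strata of the
remaining third variable, preserving the other two links; the estimate is
declared significant when it exceeds the configured percentile of the null
replicates.

Percentiles use the nearest-rank method on the sorted replicate values
(deterministic, no interpolation).  A single seeded generator drives each
report: the bootstrap consumes one length-n index draw per replicate in
order, and the permutation test consumes one within-stratum shuffle per
stratum per replicate, strata in sorted order — so fixed seeds give
bit-identical reports.  Replicates on which the estimator is undefined
(empty required cell) are excluded and counted, never imputed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .discrete_model import ModelError
from .effects import EffectValue
from .estimation import InestimableError, SampleTable

Estimator = Callable[[SampleTable], "float | EffectValue"]


@dataclass(frozen=True)
class ResamplingConfig:
    replicates: int = 10_000
    ci_lower: float = 5.0
    ci_upper: float = 95.0
    null_percentile: float = 95.0
    seed: int = 0

    def __post_init__(self):
        for p in (self.ci_lower, self.ci_upper, self.null_percentile):
            if not 0.0 <= p <= 100.0:
                raise ModelError(f"percentile {p} outside [0, 100]")
        if self.ci_lower >= self.ci_upper:
            raise ModelError("ci_lower must be below ci_upper")
        if self.replicates < 1:
            raise ModelError("replicates must be positive")


@dataclass(frozen=True)
class ResamplingReport:
    point: float
    ci: tuple[float, float] | None = None
    null_threshold: float | None = None
    significant: bool | None = None
    n_replicates: int = 0
    n_excluded: int = 0
    replicate_values: tuple = ()

    def to_dict(self) -> dict:
        def enc(v):
            if v is None:
                return None
            return "inf" if isinstance(v, float) and math.isinf(v) else v

        rec = {
            "point": enc(self.point),
            "n_replicates": self.n_replicates,
            "n_excluded": self.n_excluded,
        }
        if self.ci is not None:
            rec["ci"] = [enc(self.ci[0]), enc(self.ci[1])]
        if self.null_threshold is not None:
            rec["null_threshold"] = enc(self.null_threshold)
            rec["significant"] = self.significant
        return rec

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def dump_replicates(self, path: str | Path):
        """TSV dump of replicate values for external plotting."""
        Path(path).write_text(
            "replicate\tvalue\n"
            + "".join(f"{i}\t{v}\n" for i, v in enumerate(self.replicate_values))
        )


def _as_value(result) -> float:
    return result.value if isinstance(result, EffectValue) else float(result)


def nearest_rank_percentile(values: Sequence[float], pct: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * m)-th smallest value."""
    ordered = sorted(values)
    if not ordered:
        raise ModelError("no values to take a percentile of")
    rank = math.ceil(pct / 100.0 * len(ordered))
    return ordered[max(rank, 1) - 1]


def bootstrap_ci(samples: SampleTable, estimator: Estimator,
                 config: ResamplingConfig = ResamplingConfig(),
                 keep_replicates: bool = False) -> ResamplingReport:
    """Percentile bootstrap CI of an estimator over row resamples."""
    point = _as_value(estimator(samples))  # raises if undefined on the data
    rng = np.random.default_rng(config.seed)
    values = []
    excluded = 0
    for _ in range(config.replicates):
        idx = rng.integers(0, samples.n, samples.n)
        try:
            values.append(_as_value(estimator(samples.take(idx))))
        except InestimableError:
            excluded += 1
    lo = nearest_rank_percentile(values, config.ci_lower)
    hi = nearest_rank_percentile(values, config.ci_upper)
    return ResamplingReport(
        point=point, ci=(lo, hi), n_replicates=len(values),
        n_excluded=excluded,
        replicate_values=tuple(values) if keep_replicates else (),
    )


def permutation_null(samples: SampleTable, estimator: Estimator,
                     break_link: tuple[str, str],
                     config: ResamplingConfig = ResamplingConfig(),
                     columns: Sequence[str] | None = None,
                     shuffle_child: bool = False,
                     keep_replicates: bool = False) -> ResamplingReport:
    """Stratified-permutation null for one broken mediation link.

    ``break_link`` is an ordered edge (parent, child) among the three
    mediation columns (``columns``, defaulting to the table's columns when
    there are exactly three).  The parent column is permuted within strata
    of the remaining third variable — or the child column instead, with
    ``shuffle_child=True``.  The threshold is the configured percentile of
    the null replicate estimates.
    """
    if columns is None:
        if len(samples.columns) != 3:
            raise ModelError(
                "pass columns=(x, z, y) when the table has extra columns"
            )
        columns = samples.columns
    columns = tuple(columns)
    a, b = break_link
    if a not in columns or b not in columns or a == b:
        raise ModelError(f"break_link {break_link!r} is not an edge of {columns}")
    (stratum,) = [c for c in columns if c not in (a, b)]
    permute_col = b if shuffle_child else a

    point = _as_value(estimator(samples))
    rng = np.random.default_rng(config.seed)
    values = []
    excluded = 0
    for _ in range(config.replicates):
        shuffled = samples.permuted_within(permute_col, stratum, rng)
        try:
            values.append(_as_value(estimator(shuffled)))
        except InestimableError:
            excluded += 1
    threshold = nearest_rank_percentile(values, config.null_percentile)
    return ResamplingReport(
        point=point, null_threshold=threshold,
        significant=bool(point > threshold),
        n_replicates=len(values), n_excluded=excluded,
        replicate_values=tuple(values) if keep_replicates else (),
    )
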