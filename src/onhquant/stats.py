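"""Evaluation statistics for the ONH measures.

Implements the single-measure consistency intraclass correlation ICC(3,1)
from the two-way mixed-effects ANOVA (subjects random, sessions fixed), the
rank/pair-counting ROC AUC between two groups, normative percentile cutoffs
with exceedance counts, and the lumbar-puncture distance weighting factor
w = 100 / (months + 1) used to down-weight OCT scans acquired long after
the pressure measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError


@dataclass
class RepeatedMeasures:
    """Complete subjects x sessions measurement matrix (no missing cells)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ParameterError("values must be a 2D (subjects x sessions) matrix")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ParameterError("need >= 2 subjects and >= 2 sessions")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("matrix must be complete and finite")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_sessions(self) -> int:
        return self.values.shape[1]


@dataclass
class GroupedValues:
    """Measurements with binary group labels and optional subject clusters.

    ``labels`` uses 1 for the positive group (patients) and 0 for controls.
    ``cluster_id`` carries the subject each eye belongs to, so users can
    export to a statistics environment for cluster-aware models (GEE); the
    statistics here do not use it.
    """

    values: np.ndarray
    labels: np.ndarray
    cluster_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.values.shape != self.labels.shape or self.values.ndim != 1:
            raise ParameterError("values and labels must be congruent 1D arrays")
        uniq = set(np.unique(self.labels).tolist())
        if not uniq <= {0, 1} or len(uniq) != 2:
            raise ParameterError("labels must contain both groups (0 and 1)")
        if self.cluster_id is not None:
            self.cluster_id = np.asarray(self.cluster_id)
            if self.cluster_id.shape != self.values.shape:
                raise ParameterError("cluster_id must be congruent with values")


@dataclass
class NormativeCutoff:
    """Percentile cutoff of a control distribution, with optional exceedance."""

    cutoff: float
    q: float
    n_controls: int
    n_exceeding: int | None = None
    frac_exceeding: float | None = None


def icc_two_way_mixed(data: RepeatedMeasures | np.ndarray) -> float:
    """Single-measure consistency ICC(3,1) from the two-way mixed model.

    With subjects random and sessions fixed, the two-way ANOVA without
    replication gives mean squares for subjects (rows) and error
    (interaction residual); then

        ICC(3,1) = (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error)

    with k the number of sessions.  Zero total variance is undefined.
    """
    if not isinstance(data, RepeatedMeasures):
        data = RepeatedMeasures(values=data)
    x = data.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    if ss_total == 0.0:
        raise ParameterError("ICC undefined: zero total variance")
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)


def mann_whitney_auc(
    data: GroupedValues | None = None,
    *,
    values: Sequence[float] | None = None,
    labels: Sequence[int] | None = None,
) -> float:
    """ROC AUC by exhaustive cross-group pair counting.

    AUC = (#{patient > control} + 0.5 #{ties}) / (n_p * n_c) — the
    Mann-Whitney U statistic normalised by the number of pairs.  Invariant
    under strictly monotone transforms; swapping the labels maps it to
    1 - AUC exactly.
    """
    if data is None:
        data = GroupedValues(values=np.asarray(values), labels=np.asarray(labels))
    pos = data.values[data.labels == 1]
    neg = data.values[data.labels == 0]
    diff = pos[:, None] - neg[None, :]
    wins = np.count_nonzero(diff > 0)
    ties = np.count_nonzero(diff == 0)
    return (wins + 0.5 * ties) / (pos.size * neg.size)


def normative_percentile(
    control_values: Sequence[float],
    q: float,
    comparison_values: Sequence[float] | None = None,
) -> NormativeCutoff:
    """q-th percentile of a control distribution, linear-interpolation rule.

    The cutoff interpolates linearly between closest ranks (the ``linear``
    quantile method).  When ``comparison_values`` is supplied, the count and
    fraction of comparison values strictly above the cutoff are reported —
    e.g. patient eyes above the 95th percentile of controls.
    """
    vals = np.asarray(control_values, dtype=np.float64)
    if vals.size < 2:
        raise ParameterError("need >= 2 control values")
    if not 0 < q < 100:
        raise ParameterError("q must be in (0, 100)")
    cutoff = float(np.percentile(vals, q, method="linear"))
    result = NormativeCutoff(cutoff=cutoff, q=q, n_controls=vals.size)
    if comparison_values is not None:
        comp = np.asarray(comparison_values, dtype=np.float64)
        result.n_exceeding = int(np.count_nonzero(comp > cutoff))
        result.frac_exceeding = result.n_exceeding / comp.size if comp.size else 0.0
    return result


def lp_weight(distance_months: float) -> float:
    """Weighting factor w = 100 / (measurement distance in months + 1)."""
    if distance_months < 0:
        raise ParameterError("distance_months must be >= 0")
    return 100.0 / (distance_months + 1.0)
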