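"""Selection-probability profiles and between-group similarity statistics.

For each case, a group's *selection profile* is the fraction of its raters
whose prescription included each acupoint.  Two groups are compared by

* the asymmetric *percentage overlap* at a cutoff — the share of the
  reference group's above-cutoff acupoints that are also above-cutoff for
  the test group,
* its average over a grid of cutoffs, and
* the Spearman rank correlation of the two probability profiles over the
  acupoints either group selected at least once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core_data import CaseDataset, ValidationError

__all__ = [
    "SelectionProfile",
    "OverlapResult",
    "CorrelationResult",
    "GroupSummary",
    "DEFAULT_CUTOFFS",
    "selection_probabilities",
    "percentage_overlap",
    "average_overlap",
    "spearman_selection_correlation",
    "top_k",
    "group_summary",
]

#: cutoff grid used for the averaged overlap: 10% .. 50%
DEFAULT_CUTOFFS: tuple[float, ...] = (0.10, 0.20, 0.30, 0.40, 0.50)


@dataclass(frozen=True)
class SelectionProfile:
    """Per-acupoint selection probabilities for one case and one group."""

    case_id: str
    group: str
    n_raters: int
    prob: Mapping[str, float]

    def threshold_set(self, cutoff: float) -> frozenset[str]:
        """Codes selected at a rate at or above ``cutoff`` (inclusive)."""
        return frozenset(c for c, p in self.prob.items() if p >= cutoff)

    def positive_codes(self) -> frozenset[str]:
        return frozenset(c for c, p in self.prob.items() if p > 0)


@dataclass(frozen=True)
class OverlapResult:
    case_id: str
    cutoff: float
    reference_set: frozenset[str]
    test_set: frozenset[str]
    value: float | None  # percentage in [0, 100]; None when no code clears
    # the cutoff in the reference group (empty denominator)


@dataclass(frozen=True)
class CorrelationResult:
    case_id: str
    rho: float | None
    p_value: float | None
    n_items: int
    warning: str | None = None


def selection_probabilities(
    dataset: CaseDataset,
    case_id: str,
    group: str,
    divisor: str = "declared",
) -> SelectionProfile:
    """Selection probabilities for one (case, group) pair.

    Each rater contributes each code at most once.  The divisor is the
    group's declared panel size by default (``divisor="declared"``), so a
    missing response lowers probabilities rather than renormalising them;
    ``divisor="observed"`` divides by the number of responses present.
    """
    if group not in dataset.groups:
        raise ValidationError(f"unknown group {group!r}")
    responses = dataset.case_responses(case_id, group)
    if divisor == "declared":
        n = int(dataset.group_sizes.get(group, 0))
    elif divisor == "observed":
        n = len(responses)
    else:
        raise ValueError(f"divisor must be 'declared' or 'observed', got {divisor!r}")
    if n <= 0:
        raise ValidationError(
            f"zero divisor for group {group!r} in case {case_id!r}"
        )
    counts: dict[str, int] = {}
    for r in responses:
        for code in r.acupoints:
            counts[code] = counts.get(code, 0) + 1
    return SelectionProfile(
        case_id=case_id,
        group=group,
        n_raters=n,
        prob={c: k / n for c, k in sorted(counts.items())},
    )


def percentage_overlap(
    reference: SelectionProfile, test: SelectionProfile, cutoff: float
) -> OverlapResult:
    """Percentage overlap at one cutoff.

    ``100 * |ref>=cutoff ∩ test>=cutoff| / |ref>=cutoff|`` — asymmetric:
    the denominator is the reference (clinician) group's threshold set.
    ``None`` when the reference group has no code at or above the cutoff.
    """
    if reference.case_id != test.case_id:
        raise ValidationError(
            f"profiles compare different cases: {reference.case_id!r} vs {test.case_id!r}"
        )
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
    ref_set = reference.threshold_set(cutoff)
    test_set = test.threshold_set(cutoff)
    value = 100.0 * len(ref_set & test_set) / len(ref_set) if ref_set else None
    return OverlapResult(reference.case_id, cutoff, ref_set, test_set, value)


def average_overlap(
    reference: SelectionProfile,
    test: SelectionProfile,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> float | None:
    """Mean percentage overlap over a cutoff grid.

    Cutoffs at which the reference threshold set is empty carry no
    information about agreement and are excluded from the mean; the
    result is ``None`` only if every cutoff is empty.
    """
    if not cutoffs:
        raise ValueError("cutoff grid must be non-empty")
    values = [
        percentage_overlap(reference, test, c).value for c in cutoffs
    ]
    present = [v for v in values if v is not None]
    return float(np.mean(present)) if present else None


def spearman_selection_correlation(
    a: SelectionProfile, b: SelectionProfile
) -> CorrelationResult:
    """Spearman correlation of two selection profiles.

    The item domain is the union of acupoints selected at least once by
    either group; acupoints selected by neither are excluded.  Ties get
    average ranks and the two-sided p-value uses the t approximation on
    ``n_items - 2`` degrees of freedom.
    """
    if a.case_id != b.case_id:
        raise ValidationError(
            f"profiles compare different cases: {a.case_id!r} vs {b.case_id!r}"
        )
    items = sorted(a.positive_codes() | b.positive_codes())
    n = len(items)
    if n < 3:
        return CorrelationResult(a.case_id, None, None, n, warning="too_few_items")
    xs = np.array([a.prob.get(c, 0.0) for c in items])
    ys = np.array([b.prob.get(c, 0.0) for c in items])
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return CorrelationResult(a.case_id, None, None, n, warning="constant_profile")
    res = stats.spearmanr(xs, ys)
    return CorrelationResult(a.case_id, float(res.statistic), float(res.pvalue), n)


def top_k(profile: SelectionProfile, k: int) -> list[str]:
    """The ``k`` most-selected acupoints, probability descending, ties
    broken lexicographically; only positively selected codes appear."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(
        (c for c, p in profile.prob.items() if p > 0),
        key=lambda c: (-profile.prob[c], c),
    )
    return ranked[:k]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group and overall means of a per-case statistic."""

    group_means: Mapping[str, float | None]
    overall: float | None


def group_summary(
    per_case_values: Mapping[str, float | None],
    grouping: Mapping[str, str],
) -> GroupSummary:
    """Average a per-case statistic within disease groups and overall.

    Missing values are excluded from every mean; a group whose cases are
    all missing gets a ``None`` mean.  The overall mean runs over cases,
    not over group means.
    """
    missing = [c for c in per_case_values if c not in grouping]
    if missing:
        raise ValidationError(f"cases without a disease group: {sorted(missing)}")
    by_group: dict[str, list[float]] = {}
    for case, value in per_case_values.items():
        by_group.setdefault(grouping[case], [])
        if value is not None:
            by_group[grouping[case]].append(float(value))
    present = [float(v) for v in per_case_values.values() if v is not None]
    return GroupSummary(
        group_means={
            g: (float(np.mean(vs)) if vs else None) for g, vs in by_group.items()
        },
        overall=float(np.mean(present)) if present else None,
    )
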