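"""Synthetic rater-panel generator.

Emulates the statistical structure the analysis assumes: for each
clinical case there is a ground-truth selection tendency over acupoints
(a few "major" codes shared across cases, some case-specific codes, and
a long low-weight tail), every rater prescribes a set of 3-5 distinct
acupoints, and rater groups differ in heterogeneity.  Heterogeneity is
a single knob η: each rater's weights are perturbed multiplicatively by
independent log-Laplace noise ``exp(η · Laplace(0, 1))`` before sampling,
so η = 0 reproduces the shared profile exactly and larger η scatters
selections into the tail.  The heavy tail of the Laplace log-noise
matters: a strongly heterogeneous rater occasionally promotes a
rarely-used acupoint into their personal top ranks — the idiosyncratic
picks of individual clinicians — while a near-homogeneous group (small
η) is left essentially untouched.

Acupoints are drawn by sequential weighted sampling without replacement
(draw one code with probability proportional to weight, remove it,
renormalise, repeat).  Inclusion probabilities under this scheme are not
exactly proportional to the weights; :func:`exact_inclusion_probabilities`
computes them by enumeration for small problems.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core_data import (
    FLAG_SIZE,
    SIZE_RANGE,
    AcupointVocabulary,
    CaseDataset,
    ResponseSet,
    default_vocabulary,
)

__all__ = [
    "GroupSpec",
    "CaseGeneratorSpec",
    "simulate_rater",
    "simulate_case",
    "simulate_study",
    "exact_inclusion_probabilities",
    "GenerationError",
]

#: widely indicated acupoints given high weight in every simulated case
MAJOR_CODES: tuple[str, ...] = ("SP6", "LR3", "LI4", "ST36")

# default base-weight tiers: major / case-specific / tail
WEIGHT_MAJOR = 8.0
WEIGHT_SPECIFIC = 2.0
WEIGHT_TAIL = 0.025
N_SPECIFIC = 6
N_TAIL = 200


class GenerationError(RuntimeError):
    """Raised when a spec cannot produce a valid response."""


@dataclass(frozen=True)
class GroupSpec:
    """Per-group generation parameters."""

    n_raters: int
    eta: float  # log-scale spread of rater-level weight noise, >= 0
    kmin: int = SIZE_RANGE[0]
    kmax: int = SIZE_RANGE[1]

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("heterogeneity eta must be >= 0")
        if not 1 <= self.kmin <= self.kmax:
            raise ValueError("need 1 <= kmin <= kmax")


@dataclass(frozen=True)
class CaseGeneratorSpec:
    """Ground truth for one simulated case."""

    case_id: str
    vocabulary: AcupointVocabulary
    base_weights: Mapping[str, float]
    group_specs: Mapping[str, GroupSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.base_weights.values()):
            raise ValueError("base weights must be nonnegative")
        n_pos = sum(1 for w in self.base_weights.values() if w > 0)
        kmax = max(g.kmax for g in self.group_specs.values())
        if n_pos < kmax:
            raise GenerationError(
                f"only {n_pos} positive-weight codes but sets of up to {kmax} requested"
            )
        unknown = set(self.base_weights) - set(self.vocabulary.codes)
        if unknown:
            raise ValueError(f"weights for codes outside vocabulary: {sorted(unknown)}")


def _weighted_subset(
    codes: Sequence[str], weights: np.ndarray, k: int, rng: np.random.Generator
) -> frozenset[str]:
    """Sequential weighted sampling without replacement of ``k`` codes."""
    w = weights.astype(float).copy()
    picked: list[str] = []
    for _ in range(k):
        total = w.sum()
        if total <= 0:
            raise GenerationError("ran out of positive-weight codes")
        i = rng.choice(len(codes), p=w / total)
        picked.append(codes[i])
        w[i] = 0.0
    return frozenset(picked)


def simulate_rater(
    spec: CaseGeneratorSpec,
    group: str,
    rater_id: str = "r0",
    rng: np.random.Generator | None = None,
) -> ResponseSet:
    """Draw one rater's response for one case.

    The set size k is uniform on [kmin, kmax]; the rater's private
    weights are ``base_weight * exp(eta * Laplace(0, 1))`` per code.
    """
    g = spec.group_specs[group]
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    codes = [c for c, w in spec.base_weights.items() if w > 0]
    w = np.array([spec.base_weights[c] for c in codes])
    k = int(rng.integers(g.kmin, g.kmax + 1))
    if g.eta > 0:
        w = w * np.exp(g.eta * rng.laplace(0.0, 1.0, len(w)))
    acupoints = _weighted_subset(codes, w, k, rng)
    flags = () if SIZE_RANGE[0] <= k <= SIZE_RANGE[1] else (FLAG_SIZE,)
    return ResponseSet(spec.case_id, rater_id, group, acupoints, flags)


def simulate_case(
    spec: CaseGeneratorSpec, rng: np.random.Generator | None = None
) -> list[ResponseSet]:
    """All responses of all groups for one case."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    out: list[ResponseSet] = []
    for group in spec.group_specs:
        n = spec.group_specs[group].n_raters
        for i in range(n):
            out.append(simulate_rater(spec, group, rater_id=f"{group.lower()}{i+1:03d}", rng=rng))
    return out


def _case_weights(
    vocabulary: AcupointVocabulary, rng: np.random.Generator
) -> dict[str, float]:
    """Base weights for one case: shared major codes, case-specific codes
    of intermediate weight, and a long low-weight tail."""
    remaining = [c for c in vocabulary.codes if c not in MAJOR_CODES]
    chosen = rng.choice(len(remaining), size=N_SPECIFIC + N_TAIL, replace=False)
    weights = {c: WEIGHT_MAJOR for c in MAJOR_CODES}
    for j in chosen[:N_SPECIFIC]:
        weights[remaining[j]] = WEIGHT_SPECIFIC
    for j in chosen[N_SPECIFIC:]:
        weights[remaining[j]] = WEIGHT_TAIL
    return weights


def simulate_study(
    n_cases: int = 10,
    doctor_n: int = 80,
    llm_n: int = 10,
    eta_doctor: float = 1.2,
    eta_llm: float = 0.2,
    seed: int = 0,
    doctor_group: str = "KMD",
    llm_group: str = "GPT",
    vocabulary: AcupointVocabulary | None = None,
) -> CaseDataset:
    """Simulate a full two-group study.

    Defaults mirror the study design this package analyses: 10 cases,
    a panel of 80 clinicians and 10 LLM runs per case, 3-5 acupoints
    per response, with the clinician group substantially more
    heterogeneous (eta 1.2 vs 0.2).  Fully reproducible under ``seed``.
    """
    if doctor_n < 2 or llm_n < 2:
        raise ValueError("group sizes must be >= 2")
    if eta_doctor < 0 or eta_llm < 0:
        raise ValueError("heterogeneity eta must be >= 0")
    vocabulary = default_vocabulary() if vocabulary is None else vocabulary
    rng = np.random.default_rng(seed)
    group_specs = {
        doctor_group: GroupSpec(n_raters=doctor_n, eta=eta_doctor),
        llm_group: GroupSpec(n_raters=llm_n, eta=eta_llm),
    }
    responses: list[ResponseSet] = []
    cases = tuple(f"case{i+1}" for i in range(n_cases))
    for case_id in cases:
        spec = CaseGeneratorSpec(
            case_id=case_id,
            vocabulary=vocabulary,
            base_weights=_case_weights(vocabulary, rng),
            group_specs=group_specs,
        )
        responses.extend(simulate_case(spec, rng=rng))
    return CaseDataset(
        vocabulary=vocabulary,
        responses=tuple(responses),
        cases=cases,
        groups=(doctor_group, llm_group),
        group_sizes={doctor_group: doctor_n, llm_group: llm_n},
    )


def exact_inclusion_probabilities(
    weights: Mapping[str, float], k: int
) -> dict[str, float]:
    """Exact inclusion probability of each code in a sequential weighted
    sample without replacement of size ``k``.

    Enumerates all ordered draw sequences — O(m!/(m-k)!) — so it is only
    practical for small problems; it serves as ground truth for
    parameter-recovery checks of the generator.
    """
    codes = [c for c, w in weights.items() if w > 0]
    w = np.array([weights[c] for c in codes], dtype=float)
    m = len(codes)
    if k > m:
        raise GenerationError(f"cannot draw {k} from {m} positive-weight codes")
    incl = np.zeros(m)
    for seq in itertools.permutations(range(m), k):
        p = 1.0
        total = w.sum()
        for i in seq:
            p *= w[i] / total
            total -= w[i]
        for i in seq:
            incl[i] += p
    return {c: float(incl[i]) for i, c in enumerate(codes)}
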