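"""End-to-end analysis orchestration and figure/table outputs.

``run_analysis`` composes the per-case statistics (selection profiles,
percentage overlap at each cutoff and averaged, Spearman correlation,
top-k lists, mean pairwise Jaccard dissimilarities, size-matched
bootstrap CI for the group difference, PERMDISP) into one
:class:`StudySummary` and serialises it to JSON/TSV; ``build_heatmap``
draws the selection-probability heatmap of the most-used acupoints.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import agreement, variability
from .agreement import DEFAULT_CUTOFFS, GroupSummary, SelectionProfile
from .core_data import CaseDataset, ValidationError
from .variability import BootstrapCI, DispersionTestResult

__all__ = [
    "AnalysisConfig",
    "CaseResult",
    "StudySummary",
    "run_analysis",
    "summary_to_json",
    "per_case_table",
    "build_heatmap",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis parameters; defaults follow the two-panel study design."""

    reference_group: str = "KMD"
    test_group: str = "GPT"
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    divisor: str = "declared"
    n_perm: int = 9999
    n_boot: int = 2000
    match_size: bool = True
    seed: int = 20240501
    top_k: int = 3
    disease_groups: Mapping[str, str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "cutoffs" in raw:
            raw["cutoffs"] = tuple(float(c) for c in raw["cutoffs"])
        if "disease_groups" in raw and raw["disease_groups"] is not None:
            raw["disease_groups"] = dict(raw["disease_groups"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cutoffs"] = list(self.cutoffs)
        if d["disease_groups"] is not None:
            d["disease_groups"] = dict(d["disease_groups"])
        return d


@dataclass(frozen=True)
class CaseResult:
    case_id: str
    overlap_by_cutoff: Mapping[float, float | None]
    overlap_10: float | None
    overlap_avg: float | None
    rho: float | None
    p: float | None
    n_items: int
    top_by_group: Mapping[str, list[str]]
    mean_dissimilarity: Mapping[str, float]
    bootstrap: BootstrapCI
    dispersion: DispersionTestResult


@dataclass(frozen=True)
class StudySummary:
    config: AnalysisConfig
    per_case: Mapping[str, CaseResult]
    overall_overlap_10: float | None
    overall_overlap_avg: float | None
    disease_group_overlap_10: GroupSummary | None
    disease_group_overlap_avg: GroupSummary | None


def run_analysis(dataset: CaseDataset, config: AnalysisConfig) -> StudySummary:
    """Compute every per-case and aggregate statistic of the pipeline.

    Deterministic given ``config.seed``: per-case seeds for the bootstrap
    and the permutation test are drawn from one seeded sequence.
    """
    for g in (config.reference_group, config.test_group):
        if g not in dataset.groups:
            raise ValidationError(f"unknown group {g!r} in config")
    seed_seq = np.random.SeedSequence(config.seed)
    case_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(2 * len(dataset.cases))]

    per_case: dict[str, CaseResult] = {}
    for i, case_id in enumerate(dataset.cases):
        ref = agreement.selection_probabilities(
            dataset, case_id, config.reference_group, divisor=config.divisor
        )
        test = agreement.selection_probabilities(
            dataset, case_id, config.test_group, divisor=config.divisor
        )
        overlaps = {
            c: agreement.percentage_overlap(ref, test, c).value for c in config.cutoffs
        }
        corr = agreement.spearman_selection_correlation(ref, test)
        matrix = variability.pairwise_distance_matrix(dataset, case_id)
        mean_d = {
            g: variability.mean_pairwise_dissimilarity(matrix, g)
            for g in (config.reference_group, config.test_group)
        }
        ci = variability.bootstrap_difference_ci(
            dataset,
            case_id,
            config.reference_group,
            config.test_group,
            n_boot=config.n_boot,
            match_size=config.match_size,
            seed=case_seeds[2 * i],
        )
        disp = variability.permdisp(
            matrix, n_perm=config.n_perm, seed=case_seeds[2 * i + 1]
        )
        per_case[case_id] = CaseResult(
            case_id=case_id,
            overlap_by_cutoff=overlaps,
            overlap_10=overlaps.get(config.cutoffs[0]),
            overlap_avg=agreement.average_overlap(ref, test, config.cutoffs),
            rho=corr.rho,
            p=corr.p_value,
            n_items=corr.n_items,
            top_by_group={
                config.reference_group: agreement.top_k(ref, config.top_k),
                config.test_group: agreement.top_k(test, config.top_k),
            },
            mean_dissimilarity=mean_d,
            bootstrap=ci,
            dispersion=disp,
        )

    o10 = {c: r.overlap_10 for c, r in per_case.items()}
    oavg = {c: r.overlap_avg for c, r in per_case.items()}
    present10 = [v for v in o10.values() if v is not None]
    presentavg = [v for v in oavg.values() if v is not None]
    dg10 = dgavg = None
    if config.disease_groups is not None:
        dg10 = agreement.group_summary(o10, config.disease_groups)
        dgavg = agreement.group_summary(oavg, config.disease_groups)
    return StudySummary(
        config=config,
        per_case=per_case,
        overall_overlap_10=float(np.mean(present10)) if present10 else None,
        overall_overlap_avg=float(np.mean(presentavg)) if presentavg else None,
        disease_group_overlap_10=dg10,
        disease_group_overlap_avg=dgavg,
    )


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def summary_to_json(summary: StudySummary) -> str:
    """Serialise a :class:`StudySummary` (config echoed) to JSON text."""
    payload = {
        "config": summary.config.to_dict(),
        "per_case": {c: _jsonable(r) for c, r in summary.per_case.items()},
        "overall": {
            "overlap_10": summary.overall_overlap_10,
            "overlap_avg": summary.overall_overlap_avg,
        },
        "disease_groups": {
            "overlap_10": _jsonable(summary.disease_group_overlap_10),
            "overlap_avg": _jsonable(summary.disease_group_overlap_avg),
        },
    }
    return json.dumps(_jsonable(payload), indent=2, sort_keys=True)


def per_case_table(summary: StudySummary) -> pd.DataFrame:
    """Long-format per-case table: one row per (case, cutoff)."""
    rows = []
    for case_id, r in summary.per_case.items():
        for cutoff, value in r.overlap_by_cutoff.items():
            rows.append(
                {
                    "case_id": case_id,
                    "cutoff": cutoff,
                    "overlap": value,
                    "avg_overlap": r.overlap_avg,
                    "rho": r.rho,
                    "p": r.p,
                    "n_items": r.n_items,
                }
            )
    return pd.DataFrame(rows)


def build_heatmap(
    dataset: CaseDataset,
    out_path: str | Path,
    top_n: int = 30,
    divisor: str = "declared",
) -> Path:
    """Selection-probability heatmap of the ``top_n`` most-used acupoints.

    Rows are group x case (one block per group), columns the acupoints
    ranked by selection probability summed over every case and group
    (ties lexicographic) so both group blocks share one column order.
    Output format follows the file extension (png or svg).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    profiles: dict[tuple[str, str], SelectionProfile] = {}
    totals: dict[str, float] = {}
    for group in dataset.groups:
        for case_id in dataset.cases:
            prof = agreement.selection_probabilities(dataset, case_id, group, divisor)
            profiles[(group, case_id)] = prof
            for code, p in prof.prob.items():
                totals[code] = totals.get(code, 0.0) + p
    ranked = sorted(
        (c for c, t in totals.items() if t > 0), key=lambda c: (-totals[c], c)
    )[:top_n]
    index = [f"{g} {c}" for g in dataset.groups for c in dataset.cases]
    mat = pd.DataFrame(
        [
            [profiles[(g, c)].prob.get(code, 0.0) for code in ranked]
            for g in dataset.groups
            for c in dataset.cases
        ],
        index=index,
        columns=ranked,
    )
    fig, ax = plt.subplots(
        figsize=(max(6.0, 0.32 * len(ranked) + 2), max(3.0, 0.3 * len(index) + 1.5))
    )
    sns.heatmap(mat, ax=ax, cmap="Greys", vmin=0.0, vmax=1.0, cbar_kws={"label": "selection probability"})
    ax.set_xlabel("acupoint")
    ax.set_ylabel("group / case")
    fig.tight_layout()
    out_path = Path(out_path)
    try:
        fig.savefig(out_path)
    except OSError as exc:
        raise OSError(f"cannot write heatmap to {out_path}: {exc}") from exc
    finally:
        plt.close(fig)
    return out_path
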