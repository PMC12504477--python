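"""Vocabulary handling, response parsing and terminology reconciliation.

The unit of analysis is a *response set*: the set of acupoints one rater
prescribed for one clinical case.  Raters may record an acupoint in up to
three alternative terminologies (e.g. WHO code, Korean name, Chinese name);
these alternatives are reconciled against a closed vocabulary of standard
WHO acupoint codes before any statistics are computed.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "AcupointVocabulary",
    "RawResponse",
    "ResponseSet",
    "CaseDataset",
    "ReconcileOutcome",
    "load_vocabulary",
    "default_vocabulary",
    "reconcile_labels",
    "reconcile_response",
    "parse_responses",
    "write_responses",
    "InputError",
    "ValidationError",
]

# quality flags attached to a ResponseSet
FLAG_SIZE = "size_out_of_range"
FLAG_REJECTED = "had_rejected_labels"

#: prescription size range the raters were instructed to use
SIZE_RANGE = (3, 5)


class InputError(ValueError):
    """Unreadable or structurally invalid input file."""


class ValidationError(ValueError):
    """Input that parses but violates a dataset invariant."""


@dataclass(frozen=True)
class AcupointVocabulary:
    """Closed set of valid acupoint codes plus an alias lookup table.

    Parameters
    ----------
    codes
        Ordered, unique, uppercase standard codes (e.g. ``"ST36"``).
    aliases
        Mapping from alternative labels in any terminology (case-folded)
        to a canonical code present in ``codes``.
    """

    codes: tuple[str, ...]
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.codes)) != len(self.codes):
            raise ValidationError("vocabulary codes are not unique")
        unknown = {c for c in self.aliases.values() if c not in set(self.codes)}
        if unknown:
            raise ValidationError(f"aliases map to unknown codes: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: object) -> bool:
        return code in set(self.codes)

    def resolve(self, label: str) -> str | None:
        """Resolve one spelling to a canonical code, or ``None``.

        Matching is case-insensitive; codes take precedence over aliases.
        """
        label = label.strip()
        if not label:
            return None
        up = label.upper()
        if up in set(self.codes):
            return up
        return self.aliases.get(label.casefold())


@dataclass(frozen=True)
class RawResponse:
    """One rater's answer before reconciliation.

    ``labels`` holds one tuple per intended acupoint; each tuple carries
    1-3 alternative spellings of that acupoint.
    """

    case_id: str
    rater_id: str
    group: str
    labels: tuple[tuple[str, ...], ...]


@dataclass(frozen=True)
class ResponseSet:
    """One rater's reconciled acupoint set for one case."""

    case_id: str
    rater_id: str
    group: str
    acupoints: frozenset[str]
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class CaseDataset:
    """All responses for all cases, partitioned by rater group.

    ``group_sizes`` records the *intended* panel size per group (e.g. 80
    doctors, 10 LLM runs per case); it is the default divisor for
    selection probabilities even when some responses are missing.
    """

    vocabulary: AcupointVocabulary
    responses: tuple[ResponseSet, ...]
    cases: tuple[str, ...]
    groups: tuple[str, ...]
    group_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        cases, groups = set(self.cases), set(self.groups)
        seen: set[tuple[str, str, str]] = set()
        vocab = set(self.vocabulary.codes)
        for r in self.responses:
            if r.case_id not in cases or r.group not in groups:
                raise ValidationError(
                    f"response ({r.case_id}, {r.rater_id}, {r.group}) references "
                    "an undeclared case or group"
                )
            key = (r.case_id, r.rater_id, r.group)
            if key in seen:
                raise ValidationError(f"duplicate response key {key}")
            seen.add(key)
            if not r.acupoints <= vocab:
                raise ValidationError(
                    f"response {key} contains codes outside the vocabulary"
                )

    def case_responses(self, case_id: str, group: str | None = None) -> list[ResponseSet]:
        """Responses for one case, optionally restricted to one group."""
        if case_id not in set(self.cases):
            raise ValidationError(f"unknown case {case_id!r}")
        return [
            r
            for r in self.responses
            if r.case_id == case_id and (group is None or r.group == group)
        ]


@dataclass(frozen=True)
class ReconcileOutcome:
    """Result of reconciling one label tuple: a code or a reasoned rejection."""

    code: str | None
    reason: str | None = None  # "conflict" or "unresolvable" when rejected

    @property
    def accepted(self) -> bool:
        return self.code is not None


def reconcile_labels(
    label_tuple: Sequence[str], vocabulary: AcupointVocabulary
) -> ReconcileOutcome:
    """Reconcile up to three alternative spellings of one acupoint.

    A single spelling resolves directly (single-terminology sources such
    as clinician free text).  With two or more spellings, at least two
    must resolve to the same code — the majority rule used to screen
    machine output that mixes terminologies and may corrupt any one of
    them.  Order of spellings never matters.
    """
    labels = [l for l in label_tuple if l.strip()]
    if not labels:
        raise ValidationError("empty label tuple")
    resolved = [vocabulary.resolve(l) for l in labels]
    hits = Counter(c for c in resolved if c is not None)
    if len(labels) == 1:
        code = resolved[0]
        return (
            ReconcileOutcome(code)
            if code
            else ReconcileOutcome(None, "unresolvable")
        )
    for code, n in hits.most_common(1):
        if n >= 2:
            return ReconcileOutcome(code)
    if len(hits) >= 2:
        return ReconcileOutcome(None, "conflict")
    return ReconcileOutcome(None, "unresolvable")


def load_vocabulary(path: str | Path) -> AcupointVocabulary:
    """Read a vocabulary file: one code per line, optional tab-separated
    alias column holding space-separated alternative labels.

    Duplicate code lines collapse; an alias naming an unknown code is an
    error reported with its line number.
    """
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:  # pragma: no cover - OS specific message
        raise InputError(f"cannot read vocabulary file {path}: {exc}") from exc
    codes: list[str] = []
    seen: set[str] = set()
    alias_rows: list[tuple[int, str, list[str]]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        code = parts[0].strip().upper()
        if code not in seen:
            seen.add(code)
            codes.append(code)
        if len(parts) > 1:
            alias_rows.append((lineno, code, parts[1].split()))
    if not codes:
        raise ValidationError(f"vocabulary file {path} contains no codes")
    aliases: dict[str, str] = {}
    for lineno, code, labels in alias_rows:
        if code not in seen:  # unreachable by construction; kept for clarity
            raise ValidationError(f"line {lineno}: alias for unknown code {code}")
        for label in labels:
            aliases[label.casefold()] = code
    return AcupointVocabulary(tuple(codes), aliases)


def default_vocabulary() -> AcupointVocabulary:
    """The 361 standard WHO acupoint codes shipped with the package."""
    with resources.as_file(
        resources.files("acupanel.data") / "who_acupoints.tsv"
    ) as p:
        vocab = load_vocabulary(p)
    if len(vocab) != 361:  # pragma: no cover - packaging defect guard
        raise ValidationError("packaged vocabulary does not hold 361 codes")
    return vocab


def reconcile_response(raw: RawResponse, vocabulary: AcupointVocabulary) -> ResponseSet:
    """Reconcile every labelled item of a raw response into a canonical
    acupoint set, flagging rejected items and out-of-range sizes."""
    acupoints: set[str] = set()
    rejected = False
    for label_tuple in raw.labels:
        outcome = reconcile_labels(label_tuple, vocabulary)
        if outcome.accepted:
            acupoints.add(outcome.code)  # type: ignore[arg-type]
        else:
            rejected = True
    flags: list[str] = []
    if not SIZE_RANGE[0] <= len(acupoints) <= SIZE_RANGE[1]:
        flags.append(FLAG_SIZE)
    if rejected:
        flags.append(FLAG_REJECTED)
    return ResponseSet(
        raw.case_id, raw.rater_id, raw.group, frozenset(acupoints), tuple(flags)
    )


REQUIRED_COLUMNS = ("case_id", "rater_id", "group", "acupoints")


def _sniff_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def parse_responses(
    path: str | Path,
    vocabulary: AcupointVocabulary,
    group_sizes: Mapping[str, int] | None = None,
) -> CaseDataset:
    """Parse a response table into a validated :class:`CaseDataset`.

    Expected columns: ``case_id, rater_id, group, acupoints`` where the
    acupoints cell is ``;``-separated and each item may carry up to three
    ``|``-separated alternative spellings.  Items that fail reconciliation
    or fall outside the vocabulary are dropped (and the response flagged),
    never silently kept; responses are retained whatever their final size,
    with a flag when it leaves the instructed 3-5 range.

    ``group_sizes`` overrides the intended per-case panel size per group;
    by default the maximum observed per-case count is used.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    try:
        fh = path.open("r", encoding="utf-8", newline="")
    except OSError as exc:
        raise InputError(f"cannot read response table {path}: {exc}") from exc
    with fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise InputError(f"{path}: missing required column(s) {missing}")
        rows = list(reader)

    responses: list[ResponseSet] = []
    cases: list[str] = []
    groups: list[str] = []
    counts: Counter[tuple[str, str]] = Counter()
    seen: set[tuple[str, str, str]] = set()
    for row in rows:
        case_id = row["case_id"].strip()
        rater_id = row["rater_id"].strip()
        group = row["group"].strip()
        key = (case_id, rater_id, group)
        if key in seen:
            raise ValidationError(f"duplicate (case, rater, group) row {key}")
        seen.add(key)
        if case_id not in cases:
            cases.append(case_id)
        if group not in groups:
            groups.append(group)
        counts[(case_id, group)] += 1

        labels = tuple(
            tuple(item.strip().split("|"))
            for item in row["acupoints"].split(";")
            if item.strip()
        )
        raw = RawResponse(case_id, rater_id, group, labels)
        responses.append(reconcile_response(raw, vocabulary))

    if group_sizes is None:
        group_sizes = {
            g: max((n for (c, gg), n in counts.items() if gg == g), default=0)
            for g in groups
        }
    return CaseDataset(
        vocabulary=vocabulary,
        responses=tuple(responses),
        cases=tuple(cases),
        groups=tuple(groups),
        group_sizes=dict(group_sizes),
    )


def write_responses(dataset: CaseDataset, path: str | Path) -> None:
    """Write a dataset back to the response-table format read by
    :func:`parse_responses` (codes sorted within each cell)."""
    path = Path(path)
    delim = _sniff_delimiter(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(REQUIRED_COLUMNS)
        for r in dataset.responses:
            writer.writerow(
                [r.case_id, r.rater_id, r.group, ";".join(sorted(r.acupoints))]
            )
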