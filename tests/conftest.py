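import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from acupanel.core_data import AcupointVocabulary, CaseDataset, ResponseSet

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def vocab():
    """Small vocabulary with aliases in two extra terminologies."""
    return AcupointVocabulary(
        codes=("ST36", "LI4", "SP6", "LR3", "CV12", "BL23", "GB30", "KI3", "PC6", "HT7"),
        aliases={
            "zusanli": "ST36",
            "足三里": "ST36",
            "hegu": "LI4",
            "合谷": "LI4",
            "sanyinjiao": "SP6",
            "三阴交": "SP6",
        },
    )


def make_dataset(vocab, case_sets, group_sizes=None):
    """Build a CaseDataset from {case: {group: [set, ...]}}."""
    responses = []
    cases = list(case_sets)
    groups = []
    for case_id, by_group in case_sets.items():
        for group, sets in by_group.items():
            if group not in groups:
                groups.append(group)
            for i, s in enumerate(sets):
                responses.append(
                    ResponseSet(case_id, f"{group.lower()}{i+1}", group, frozenset(s))
                )
    if group_sizes is None:
        group_sizes = {
            g: max(len(bg.get(g, [])) for bg in case_sets.values()) for g in groups
        }
    return CaseDataset(
        vocabulary=vocab,
        responses=tuple(responses),
        cases=tuple(cases),
        groups=tuple(groups),
        group_sizes=group_sizes,
    )


@pytest.fixture
def two_group_dataset(vocab):
    """One case, two groups with visibly different heterogeneity."""
    return make_dataset(
        vocab,
        {
            "case1": {
                "KMD": [
                    {"ST36", "LI4", "SP6"},
                    {"LR3", "CV12", "BL23"},
                    {"GB30", "KI3", "PC6"},
                    {"ST36", "BL23", "HT7"},
                    {"LI4", "GB30", "CV12"},
                ],
                "GPT": [
                    {"ST36", "LI4", "SP6"},
                    {"ST36", "LI4", "SP6"},
                    {"ST36", "LI4", "SP6"},
                    {"ST36", "LI4", "LR3"},
                ],
            }
        },
    )
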