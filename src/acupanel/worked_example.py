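"""Worked example: published per-case agreement summary.

A published comparison of acupoint prescriptions between a panel of 80
Korean Medicine doctors and 10 GPT-4 runs over 10 standardized clinical
cases reported, per case, the percentage overlap of above-cutoff
acupoints at the 10% cutoff and averaged over the 10-50% cutoff grid,
together with a disease-type grouping of the cases.  These printed
per-case values are inputs here: aggregating them with
:func:`acupanel.agreement.group_summary` reproduces the study's overall
and disease-group means and exercises the aggregation path on real
numbers.  The underlying raw responses were not published; case-level
statistics that require them come from the synthetic generator instead.
"""

from __future__ import annotations

__all__ = [
    "PER_CASE_OVERLAP_10",
    "PER_CASE_OVERLAP_AVG",
    "DISEASE_GROUPS",
    "MUSCULOSKELETAL",
    "PSYCHIATRIC",
    "INTERNAL",
]

MUSCULOSKELETAL = "musculoskeletal"
PSYCHIATRIC = "psychiatric"
INTERNAL = "internal"

#: per-case percentage overlap at the 10% cutoff
PER_CASE_OVERLAP_10: dict[str, float] = {
    "case1": 42.0,
    "case2": 56.0,
    "case3": 70.0,
    "case4": 71.0,
    "case5": 67.0,
    "case6": 29.0,
    "case7": 73.0,
    "case8": 27.0,
    "case9": 47.0,
    "case10": 31.0,
}

#: per-case percentage overlap averaged over the 10-50% cutoffs
PER_CASE_OVERLAP_AVG: dict[str, float] = {
    "case1": 32.0,
    "case2": 76.0,
    "case3": 56.0,
    "case4": 53.0,
    "case5": 79.0,
    "case6": 18.0,
    "case7": 39.0,
    "case8": 37.0,
    "case9": 58.0,
    "case10": 37.0,
}

#: disease-type grouping of the 10 cases
DISEASE_GROUPS: dict[str, str] = {
    "case1": INTERNAL,        # benign paroxysmal positional vertigo
    "case2": INTERNAL,        # gastroesophageal reflux disease
    "case3": PSYCHIATRIC,     # menopausal climacteric states
    "case4": MUSCULOSKELETAL, # derangement of meniscus
    "case5": INTERNAL,        # diabetic neuropathy
    "case6": MUSCULOSKELETAL, # chronic prostatitis
    "case7": PSYCHIATRIC,     # panic disorder
    "case8": MUSCULOSKELETAL, # intervertebral disc disorders
    "case9": PSYCHIATRIC,     # fibromyalgia
    "case10": INTERNAL,       # puerperal disorder
}
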