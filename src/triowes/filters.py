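"""Variant-level inclusion filters.

Each variant is screened on its annotation (site filter: functional
consequence or proximity to a splice site, rare in both population
panels, CADD above threshold) and, per trio, on proband genotype
evidence (carrier of the alternate allele with sufficient genotype
quality).  Decisions carry machine-readable reason codes and are never
raised as exceptions; a decision log covers every evaluated variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .cohort import AnnotatedVariant, FilterThresholds, TrioPedigree

# reason codes
NOT_FUNCTIONAL_REGION = "NOT_FUNCTIONAL_REGION"
POP_FREQ_HIGH = "POP_FREQ_HIGH"
CADD_LOW = "CADD_LOW"
PROBAND_GQ_LOW = "PROBAND_GQ_LOW"
GENOTYPE_MISSING = "GENOTYPE_MISSING"
ANNOTATION_MISSING = "ANNOTATION_MISSING"

#: consequence classes counting as "within the transcript region"
#: irrespective of splice distance
FUNCTIONAL_TYPES = frozenset({"missense", "nonsense", "frameshift"})


@dataclass(frozen=True)
class FilterDecision:
    variant_key: str
    passed: bool
    reasons: tuple[str, ...] = ()
    stage: str = "site"
    trio: str = ""

    def __post_init__(self) -> None:
        assert self.passed == (len(self.reasons) == 0)


def site_filter(v: AnnotatedVariant, t: FilterThresholds) -> FilterDecision:
    """Annotation-level inclusion decision.

    Pass requires: consequence in {missense, nonsense, frameshift} or
    within ``splice_window_bp`` of a splice site; maximum population
    frequency over both reference panels strictly below
    ``max_pop_freq``; CADD Phred strictly above ``min_cadd``.  Missing
    annotation excludes the variant with an explicit reason.
    """
    reasons: list[str] = []
    if v.annotation_missing or v.cadd_phred is None:
        return FilterDecision(v.key_str, False, (ANNOTATION_MISSING,))
    splice_ok = (v.splice_distance_bp is not None
                 and v.splice_distance_bp <= t.splice_window_bp)
    if v.variant_type not in FUNCTIONAL_TYPES and not splice_ok:
        reasons.append(NOT_FUNCTIONAL_REGION)
    freqs = [f for f in (v.pop_freq_1kg, v.pop_freq_evs) if f is not None]
    if freqs and max(freqs) >= t.max_pop_freq:
        reasons.append(POP_FREQ_HIGH)
    if not v.cadd_phred > t.min_cadd:
        reasons.append(CADD_LOW)
    return FilterDecision(v.key_str, not reasons, tuple(reasons))


def proband_quality_filter(v: AnnotatedVariant, trio: TrioPedigree,
                           t: FilterThresholds) -> FilterDecision:
    """Proband-side decision: alternate-allele carrier with GQ strictly
    above ``min_gq_proband``."""
    obs = v.genotype_of(trio.proband_id)
    reasons: list[str] = []
    if not obs.is_carrier:
        reasons.append(GENOTYPE_MISSING)
    elif not obs.genotype_quality > t.min_gq_proband:
        reasons.append(PROBAND_GQ_LOW)
    return FilterDecision(v.key_str, not reasons, tuple(reasons),
                          stage="proband", trio=trio.family_id)


def apply_filters(cohort: Iterable[AnnotatedVariant],
                  pedigree: Iterable[TrioPedigree],
                  t: FilterThresholds,
                  ) -> tuple[list[AnnotatedVariant], list[FilterDecision]]:
    """Run site and proband filters over a cohort.

    Returns the variants passing the site filter and the proband filter
    in at least one trio, plus a decision log covering 100% of the
    input (one site decision per variant; one proband decision per
    carrier-evaluated trio of each site-passing variant).
    """
    pedigree = list(pedigree)
    survivors: list[AnnotatedVariant] = []
    log: list[FilterDecision] = []
    for v in cohort:
        sd = site_filter(v, t)
        log.append(sd)
        if not sd.passed:
            continue
        any_pass = False
        for trio in pedigree:
            pdcs = proband_quality_filter(v, trio, t)
            log.append(pdcs)
            any_pass = any_pass or pdcs.passed
        if any_pass:
            survivors.append(v)
    return survivors, log


def decisions_to_frame(decisions: Iterable[FilterDecision]) -> pd.DataFrame:
    """Decision log as a tidy DataFrame (TSV-ready)."""
    return pd.DataFrame([
        {"variant_key": d.variant_key, "trio": d.trio, "stage": d.stage,
         "passed": d.passed, "reasons": ";".join(d.reasons)}
        for d in decisions
    ], columns=["variant_key", "trio", "stage", "passed", "reasons"])


def write_decision_log(decisions: Iterable[FilterDecision],
                       path: str | Path) -> None:
    decisions_to_frame(decisions).to_csv(path, sep="\t", index=False)
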