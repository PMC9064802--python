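"""Trio inheritance classification.

Within each parent-offspring trio every surviving proband variant is
assigned exactly one of: de novo, transmitted (maternal / paternal /
biparental) or unresolved.  De novo calls demand positive read
evidence in the child (depth >= 10, >= 3 alternate reads, allelic
balance above a mode-dependent threshold) and clean homozygous-
reference parents (GQ >= 50, zero alternate reads).  Independently,
parental carrier variants absent from the child are reported as
non-transmitted, labeled by the carrier parent — the within-family
negative control for the burden analysis.

Two analysis modes differ only in the allelic-balance floor for
de novo evidence: 0.25 exome-wide, relaxed to 0.1 inside targeted
gene panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .cohort import (AnnotatedVariant, FilterThresholds, GenePanel,
                     GenotypeObservation, TrioPedigree)
from .filters import site_filter

# fail reason codes for de novo evidence
DP_LOW = "DP_LOW"
ALT_READS_LOW = "ALT_READS_LOW"
AB_LOW = "AB_LOW"
PARENT_GQ_LOW = "PARENT_GQ_LOW"
PARENT_HAS_ALT = "PARENT_HAS_ALT"
PARENT_MISSING = "PARENT_MISSING"

_EXCLUDED_CHROMS = frozenset({"Y", "chrY", "MT", "chrM", "chrMT", "M"})


@dataclass(frozen=True)
class ModeProfile:
    """Analysis mode: only the de novo allelic-balance floor differs."""

    name: str
    ab_threshold: float


EXOME_WIDE = ModeProfile("exome_wide", 0.25)
TARGETED_PANEL = ModeProfile("targeted_panel", 0.1)

MODES = {m.name: m for m in (EXOME_WIDE, TARGETED_PANEL)}


@dataclass(frozen=True)
class InheritanceCall:
    variant_key: str
    family_id: str
    call: str
    mode: str
    evidence: dict = field(default_factory=dict, hash=False, compare=False)
    fail_reasons: tuple[str, ...] = ()

    @property
    def is_de_novo(self) -> bool:
        return self.call == "de_novo"

    @property
    def is_transmitted(self) -> bool:
        return self.call.startswith("transmitted")


def _evidence(proband: GenotypeObservation, mother: GenotypeObservation,
              father: GenotypeObservation) -> dict:
    return {
        "proband_dp": proband.total_depth,
        "proband_alt": proband.alt_depth,
        "proband_ab": proband.allelic_balance,
        "proband_gq": proband.genotype_quality,
        "mother_gq": mother.genotype_quality,
        "mother_alt": mother.alt_depth,
        "father_gq": father.genotype_quality,
        "father_alt": father.alt_depth,
    }


def check_de_novo(v: AnnotatedVariant, trio: TrioPedigree,
                  t: FilterThresholds, mode: ModeProfile = EXOME_WIDE,
                  ) -> tuple[bool, tuple[str, ...]]:
    """Evaluate the positive de novo evidence criteria.

    True iff proband depth >= ``min_depth_denovo``, alternate reads >=
    ``min_alt_reads_denovo``, allelic balance strictly above the mode
    threshold, and both parents are homozygous reference with GQ >=
    ``min_gq_parent`` and at most ``max_parent_alt_reads`` (default 0)
    alternate reads.
    """
    reasons: list[str] = []
    p = v.genotype_of(trio.proband_id)
    if p.total_depth < t.min_depth_denovo:
        reasons.append(DP_LOW)
    if p.alt_depth < t.min_alt_reads_denovo:
        reasons.append(ALT_READS_LOW)
    ab = p.allelic_balance
    if ab is None or not ab > mode.ab_threshold:
        reasons.append(AB_LOW)
    for parent_id in (trio.mother_id, trio.father_id):
        o = v.genotype_of(parent_id)
        if o.genotype == "missing":
            reasons.append(PARENT_MISSING)
            continue
        if not o.is_hom_ref:
            reasons.append(PARENT_HAS_ALT)
            continue
        if o.genotype_quality < t.min_gq_parent:
            reasons.append(PARENT_GQ_LOW)
        if o.alt_depth > t.max_parent_alt_reads:
            reasons.append(PARENT_HAS_ALT)
    return (not reasons), tuple(dict.fromkeys(reasons))


def classify_inheritance(v: AnnotatedVariant, trio: TrioPedigree,
                         t: FilterThresholds, mode: ModeProfile = EXOME_WIDE,
                         ) -> InheritanceCall:
    """Assign de novo / transmitted / unresolved for one proband-carrier
    variant in one trio.

    A parent carrying the allele makes the variant transmitted from
    that parent (biparental when both carry it; an X-hemizygous son of
    a heterozygous mother is maternal).  With both parents homozygous
    reference the variant is de novo when the evidence criteria hold,
    otherwise unresolved with the failing reasons.  Y-chromosome and
    mitochondrial records are not classified (unresolved).
    """
    p = v.genotype_of(trio.proband_id)
    m = v.genotype_of(trio.mother_id)
    f = v.genotype_of(trio.father_id)
    ev = _evidence(p, m, f)

    def call(c: str, reasons: tuple[str, ...] = ()) -> InheritanceCall:
        return InheritanceCall(v.key_str, trio.family_id, c, mode.name, ev, reasons)

    if v.chrom in _EXCLUDED_CHROMS:
        return call("unresolved", ("UNSUPPORTED_CHROM",))
    if not p.is_carrier:
        return call("unresolved", ("PROBAND_NOT_CARRIER",))
    if m.genotype == "missing" or f.genotype == "missing":
        return call("unresolved", (PARENT_MISSING,))
    if m.is_carrier and f.is_carrier:
        return call("transmitted_biparental")
    if m.is_carrier:
        return call("transmitted_maternal")
    if f.is_carrier:
        return call("transmitted_paternal")
    ok, reasons = check_de_novo(v, trio, t, mode)
    if ok:
        return call("de_novo")
    return call("unresolved", reasons)


def classify_cohort(cohort: Iterable[AnnotatedVariant],
                    pedigree: Iterable[TrioPedigree],
                    t: FilterThresholds, mode: ModeProfile = EXOME_WIDE,
                    ) -> list[InheritanceCall]:
    """Classify every proband-carrier (variant, trio) pair in a cohort."""
    pedigree = list(pedigree)
    calls: list[InheritanceCall] = []
    for v in cohort:
        for trio in pedigree:
            if v.genotype_of(trio.proband_id).is_carrier:
                calls.append(classify_inheritance(v, trio, t, mode))
    return calls


def find_non_transmitted(cohort: Iterable[AnnotatedVariant],
                         pedigree: Iterable[TrioPedigree],
                         t: FilterThresholds,
                         mode: ModeProfile = TARGETED_PANEL,
                         panel: GenePanel | None = None,
                         ) -> list[InheritanceCall]:
    """Detect parental carrier variants not passed to the proband.

    One call per carrier parent of each site-filter-passing variant
    (restricted to ``panel`` genes when given) whose proband is
    homozygous reference; carrier parents need GQ strictly above
    ``min_gq_proband`` (the carrier-side quality rule).
    """
    pedigree = list(pedigree)
    calls: list[InheritanceCall] = []
    for v in cohort:
        if panel is not None and v.gene not in panel:
            continue
        if not site_filter(v, t).passed:
            continue
        for trio in pedigree:
            p = v.genotype_of(trio.proband_id)
            if not p.is_hom_ref:
                continue  # transmitted or unevaluable, not non-transmitted
            for parent_id, side in ((trio.mother_id, "maternal"),
                                    (trio.father_id, "paternal")):
                o = v.genotype_of(parent_id)
                if o.is_carrier and o.genotype_quality > t.min_gq_proband:
                    m = v.genotype_of(trio.mother_id)
                    f = v.genotype_of(trio.father_id)
                    calls.append(InheritanceCall(
                        v.key_str, trio.family_id, f"non_transmitted_{side}",
                        mode.name, _evidence(p, m, f)))
    return calls


def calls_to_frame(calls: Iterable[InheritanceCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"variant_key": c.variant_key, "family_id": c.family_id,
               "call": c.call, "mode": c.mode,
               "fail_reasons": ";".join(c.fail_reasons)}
        row.update(c.evidence)
        rows.append(row)
    cols = ["variant_key", "family_id", "call", "mode",
            "proband_dp", "proband_alt", "proband_ab", "proband_gq",
            "mother_gq", "mother_alt", "father_gq", "father_alt",
            "fail_reasons"]
    return pd.DataFrame(rows, columns=cols)


def write_calls(calls: Iterable[InheritanceCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)
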