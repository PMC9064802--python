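"""Targeted gene-panel burden analyses.

The primary analysis restricts the exome to an epilepsy gene panel,
classifies inheritance in targeted-panel mode (allelic-balance floor
0.1), and counts probands carrying at least one qualifying variant —
a variant passing all quality filters whose curated ACMG label is
pathogenic or likely pathogenic.  A disease-unrelated panel (coronary
artery disease) serves as a specificity control, and non-transmitted
parental qualifying variants as a within-family negative control.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .cohort import (AnnotatedVariant, CohortError, FilterThresholds,
                     GenePanel, QUALIFYING_CLASSES, TrioPedigree)
from .filters import apply_filters
from .inheritance import (InheritanceCall, TARGETED_PANEL, classify_cohort,
                          find_non_transmitted)
from .stats import BurdenResult, ContingencyTable, build_exposure_table, compute_burden


@dataclass
class QualifyingVariant:
    variant_key: str
    family_id: str
    gene: str
    call: str
    curated_class: str
    variant_type: str
    cadd_phred: float | None
    polyphen_humdiv: float | None
    polyphen_humvar: float | None


@dataclass
class PanelAnalysisResult:
    panel: GenePanel
    panel_variants: list[AnnotatedVariant]
    proband_variants: list[AnnotatedVariant]
    panel_calls: list[InheritanceCall]
    qualifying_variants: list[QualifyingVariant]
    exposure_table: ContingencyTable
    exposure_burden: BurdenResult
    non_transmitted_calls: list[InheritanceCall]
    non_transmitted_table: ContingencyTable
    non_transmitted_burden: BurdenResult

    @property
    def exposed_probands(self) -> set[str]:
        return {q.family_id for q in self.qualifying_variants}

    def to_dict(self) -> dict:
        return {
            "panel": self.panel.name,
            "panel_size": len(self.panel),
            "n_panel_variants": len(self.panel_variants),
            "n_proband_variants": len(self.proband_variants),
            "qualifying_variants": [vars(q) for q in self.qualifying_variants],
            "exposure": self.exposure_burden.to_dict(),
            "non_transmitted": self.non_transmitted_burden.to_dict(),
        }


def restrict_to_panel(cohort: Iterable[AnnotatedVariant],
                      panel: GenePanel) -> list[AnnotatedVariant]:
    """Keep variants whose gene symbol is in the panel (idempotent)."""
    return [v for v in cohort if v.gene in panel]


def run_panel_analysis(cohort: Iterable[AnnotatedVariant],
                       pedigree: Iterable[TrioPedigree],
                       panel: GenePanel,
                       thresholds: FilterThresholds | None = None,
                       ) -> PanelAnalysisResult:
    """Run the full targeted analysis for one gene panel.

    Steps: restrict to panel genes; apply site and proband quality
    filters; classify inheritance in targeted-panel mode; qualifying =
    curated class pathogenic / likely pathogenic on a de novo or
    transmitted call; build the proband-level exposure table and the
    family-level non-transmitted table with their burden statistics.
    """
    if panel is None or len(panel) == 0:
        raise CohortError("panel analysis requires a non-empty panel")
    t = thresholds or FilterThresholds()
    pedigree = list(pedigree)
    panel_variants = restrict_to_panel(cohort, panel)
    probands = {trio.proband_id for trio in pedigree}
    proband_variants = [
        v for v in panel_variants
        if any(v.genotype_of(p).is_carrier for p in probands)]
    survivors, _log = apply_filters(panel_variants, pedigree, t)
    calls = classify_cohort(survivors, pedigree, t, TARGETED_PANEL)

    by_key = {v.key_str: v for v in survivors}
    qualifying: list[QualifyingVariant] = []
    for c in calls:
        v = by_key[c.variant_key]
        if v.curated_class in QUALIFYING_CLASSES and (c.is_de_novo or c.is_transmitted):
            qualifying.append(QualifyingVariant(
                variant_key=c.variant_key, family_id=c.family_id,
                gene=v.gene, call=c.call, curated_class=v.curated_class,
                variant_type=v.variant_type, cadd_phred=v.cadd_phred,
                polyphen_humdiv=v.polyphen_humdiv,
                polyphen_humvar=v.polyphen_humvar))

    exposed = {q.family_id for q in qualifying}
    exposure_table = build_exposure_table(
        pedigree, lambda trio: trio.family_id in exposed,
        label=f"{panel.name}:proband_qualifying")

    # non-transmitted negative control, family-level exposure
    nt_calls = find_non_transmitted(cohort, pedigree, t, TARGETED_PANEL, panel)
    by_key_all = {v.key_str: v for v in panel_variants}
    nt_qualifying_families = {
        c.family_id for c in nt_calls
        if by_key_all[c.variant_key].curated_class in QUALIFYING_CLASSES
    }
    nt_table = build_exposure_table(
        pedigree, lambda trio: trio.family_id in nt_qualifying_families,
        label=f"{panel.name}:family_non_transmitted")

    return PanelAnalysisResult(
        panel=panel, panel_variants=panel_variants,
        proband_variants=proband_variants, panel_calls=calls,
        qualifying_variants=qualifying, exposure_table=exposure_table,
        exposure_burden=compute_burden(exposure_table),
        non_transmitted_calls=nt_calls, non_transmitted_table=nt_table,
        non_transmitted_burden=compute_burden(nt_table))


def summarize_variant_classes(variants: Iterable[AnnotatedVariant]
                              ) -> dict[str, dict[str, float]]:
    """Tally curated ACMG classes with within-cohort percentages.

    Pathogenic with likely pathogenic and benign with likely benign are
    additionally reported as combined tiers.  Empty input yields an
    empty tally (no division error).
    """
    counts = Counter(v.curated_class for v in variants)
    total = sum(counts.values())
    if total == 0:
        return {}
    out: dict[str, dict[str, float]] = {}
    for cls, n in sorted(counts.items()):
        out[cls] = {"count": n, "percent": round(100.0 * n / total, 1)}
    combined = {
        "pathogenic_or_likely": counts["pathogenic"] + counts["likely_pathogenic"],
        "benign_or_likely": counts["benign"] + counts["likely_benign"],
        "VUS": counts["VUS"],
    }
    for name, n in combined.items():
        out[name] = {"count": n, "percent": round(100.0 * n / total, 1)}
    return out
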