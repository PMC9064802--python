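"""KEGG-orthology categorization of exome-wide de novo variant genes.

Genes harboring de novo pathogenic / likely pathogenic / VUS variants
found anywhere in the exome are mapped onto KEGG orthology (KO)
categories and tallied per case/control group.  Following the analysis
design, the human-disease branch (09160) and the organismal-systems
branch (09150) are excluded from categorization, except the nervous
system sub-branch (09156) which is retained.  Counting is per gene
(a gene contributes once per category per group, but may belong to
several categories); no significance test is attached — the output is
descriptive counts and within-group proportions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .cohort import AnnotatedVariant, CohortError, TrioPedigree
from .inheritance import InheritanceCall

#: KO codes excluded from categorization
HUMAN_DISEASE = "09160"
ORGANISMAL_SYSTEMS = "09150"
NERVOUS_SYSTEM = "09156"

#: curated classes whose de novo variants enter the categorization
DENOVO_CLASSES = frozenset({"pathogenic", "likely_pathogenic", "VUS"})

_CODE_RE = re.compile(r"^\d{5}$")


@dataclass(frozen=True)
class KoCategory:
    code: str
    name: str
    parent_code: str = ""   # empty for top-level branches


@dataclass
class KoMapping:
    """gene symbol -> KO categories, plus the category hierarchy."""

    categories: dict[str, KoCategory]
    gene_to_codes: dict[str, tuple[str, ...]]

    def codes_of(self, gene: str) -> tuple[str, ...]:
        return self.gene_to_codes.get(gene.upper(), ())

    def is_descendant(self, code: str, ancestor: str) -> bool:
        """True if ``code`` equals or descends from ``ancestor``."""
        seen: set[str] = set()
        while code and code not in seen:
            if code == ancestor:
                return True
            seen.add(code)
            cat = self.categories.get(code)
            code = cat.parent_code if cat else ""
        return False

    def excluded(self, code: str) -> bool:
        """Exclusion rule: drop 09160 and its descendants, and 09150
        and its descendants apart from 09156 (and its descendants)."""
        if self.is_descendant(code, NERVOUS_SYSTEM):
            return False
        return (self.is_descendant(code, HUMAN_DISEASE)
                or self.is_descendant(code, ORGANISMAL_SYSTEMS))


def load_ko_mapping(path: str | Path) -> KoMapping:
    """Read a gene -> KO mapping TSV (gene, category_code,
    category_name, parent_code)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    needed = {"gene", "category_code", "category_name", "parent_code"}
    missing = needed - set(df.columns)
    if missing:
        raise CohortError(f"KO mapping {path} lacks columns {sorted(missing)}")
    categories: dict[str, KoCategory] = {}
    gene_to_codes: dict[str, list[str]] = {}
    for i, row in df.iterrows():
        code = row["category_code"].strip()
        if not _CODE_RE.match(code):
            raise CohortError(
                f"KO mapping row {i + 2}: malformed category code {code!r}")
        parent = row["parent_code"].strip()
        if parent and not _CODE_RE.match(parent):
            raise CohortError(
                f"KO mapping row {i + 2}: malformed parent code {parent!r}")
        categories.setdefault(code, KoCategory(code, row["category_name"], parent))
        gene = row["gene"].strip().upper()
        if gene:
            gene_to_codes.setdefault(gene, [])
            if code not in gene_to_codes[gene]:
                gene_to_codes[gene].append(code)
    return KoMapping(categories,
                     {g: tuple(cs) for g, cs in gene_to_codes.items()})


def select_exome_wide_de_novo(cohort: Iterable[AnnotatedVariant],
                              calls: Iterable[InheritanceCall],
                              pedigree: Iterable[TrioPedigree],
                              ) -> list[tuple[str, str, str]]:
    """Genes of exome-wide de novo variants in the qualifying curated
    classes (pathogenic / likely pathogenic / VUS), as
    (gene, family_id, group) records — one per de novo variant call.
    """
    by_key = {v.key_str: v for v in cohort}
    group_of = {t.family_id: t.proband_affected for t in pedigree}
    out: list[tuple[str, str, str]] = []
    for c in calls:
        if not c.is_de_novo:
            continue
        v = by_key.get(c.variant_key)
        if v is None or v.curated_class not in DENOVO_CLASSES:
            continue
        out.append((v.gene, c.family_id, group_of.get(c.family_id, "unknown")))
    return out


@dataclass
class EnrichmentTable:
    """Per-category gene counts and within-group proportions."""

    table: pd.DataFrame           # category_code, category_name, counts, props
    unmapped: dict[str, list[str]]    # group -> genes without any KO mapping
    excluded: dict[str, list[str]]    # group -> genes mapping only to excluded codes

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def categorize(gene_records: Iterable[tuple[str, str, str]],
               mapping: KoMapping) -> EnrichmentTable:
    """Tally (gene, family, group) records into retained KO categories.

    Per-gene counting within each group; proportions are relative to
    the number of categorized genes in the group.  Genes without a
    mapping, or whose every category is excluded, are reported in
    side buckets rather than silently dropped.
    """
    groups = ("epilepsy", "no_epilepsy")
    genes_by_group: dict[str, set[str]] = {g: set() for g in groups}
    for gene, _family, group in gene_records:
        if group in genes_by_group:
            genes_by_group[group].add(gene.upper())

    unmapped: dict[str, list[str]] = {g: [] for g in groups}
    excluded: dict[str, list[str]] = {g: [] for g in groups}
    counts: dict[str, dict[str, set[str]]] = {}
    categorized: dict[str, set[str]] = {g: set() for g in groups}
    for group in groups:
        for gene in sorted(genes_by_group[group]):
            codes = mapping.codes_of(gene)
            if not codes:
                unmapped[group].append(gene)
                continue
            kept = [c for c in codes if not mapping.excluded(c)]
            if not kept:
                excluded[group].append(gene)
                continue
            categorized[group].add(gene)
            for code in kept:
                counts.setdefault(code, {g: set() for g in groups})
                counts[code][group].add(gene)

    rows = []
    for code in sorted(counts):
        cat = mapping.categories.get(code, KoCategory(code, ""))
        n_epi = len(counts[code]["epilepsy"])
        n_no = len(counts[code]["no_epilepsy"])
        denom_epi = len(categorized["epilepsy"]) or 1
        denom_no = len(categorized["no_epilepsy"]) or 1
        rows.append({
            "category_code": code,
            "category_name": cat.name,
            "count_epilepsy": n_epi,
            "count_no_epilepsy": n_no,
            "prop_epilepsy": n_epi / denom_epi,
            "prop_no_epilepsy": n_no / denom_no,
        })
    table = pd.DataFrame(rows, columns=[
        "category_code", "category_name", "count_epilepsy",
        "count_no_epilepsy", "prop_epilepsy", "prop_no_epilepsy"])
    return EnrichmentTable(table=table, unmapped=unmapped, excluded=excluded)


def write_ko_mapping(rows: Iterable[tuple[str, str, str, str]],
                     path: str | Path) -> None:
    """Write (gene, category_code, category_name, parent_code) rows."""
    pd.DataFrame(list(rows), columns=[
        "gene", "category_code", "category_name", "parent_code"
    ]).to_csv(path, sep="\t", index=False)
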