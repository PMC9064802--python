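"""Domain types and file IO for trio whole-exome cohorts.

A cohort consists of a multi-sample VCF (GT/DP/AD/GQ per sample), a
6-column PED pedigree defining parent-offspring trios, a per-variant
annotation table (gene, consequence class, splice distance, population
allele frequencies, CADD Phred, optional Polyphen-2 scores, optional
curated ACMG label), and plain-text gene-panel files.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

#: canonical annotation-table column order
ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "variant_type",
    "splice_distance_bp", "af_1kg", "af_evs", "cadd_phred",
    "polyphen_humdiv", "polyphen_humvar", "curated_class",
]

VARIANT_TYPES = {
    "missense", "nonsense", "frameshift", "inframe_indel",
    "splice", "synonymous", "other",
}
CURATED_CLASSES = {
    "pathogenic", "likely_pathogenic", "VUS", "likely_benign",
    "benign", "none",
}
QUALIFYING_CLASSES = {"pathogenic", "likely_pathogenic"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigree files."""


class CohortError(ValueError):
    """Raised when VCF / annotation / panel inputs are inconsistent."""


# ---------------------------------------------------------------------------
# pedigree


@dataclass(frozen=True)
class TrioPedigree:
    """One proband plus both biological parents.

    ``proband_affected`` carries the case/control outcome
    (post-neonatal epilepsy yes/no); ``parent_phenotype`` maps each
    parent ID to its own affection status so that inherited variants
    can be checked against parental history.
    """

    family_id: str
    proband_id: str
    mother_id: str
    father_id: str
    proband_sex: str = "unknown"           # male | female | unknown
    proband_affected: str = "unknown"      # epilepsy | no_epilepsy | unknown
    parent_phenotype: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = (self.proband_id, self.mother_id, self.father_id)
        if any(not i or i == "0" for i in ids):
            raise PedigreeError(
                f"family {self.family_id}: incomplete trio (IDs {ids})")
        if len(set(ids)) != 3:
            raise PedigreeError(
                f"family {self.family_id}: proband/mother/father IDs must be distinct")

    @property
    def members(self) -> tuple[str, str, str]:
        return (self.proband_id, self.mother_id, self.father_id)


_SEX = {"1": "male", "2": "female"}
_AFFECTED = {"2": "epilepsy", "1": "no_epilepsy"}
_PARENT_PHENO = {"2": "affected", "1": "unaffected"}


def read_pedigree(path: str | Path) -> list[TrioPedigree]:
    """Read a 6-column whitespace-delimited PED file into trios.

    Columns: family, individual, father, mother, sex, phenotype
    (phenotype 2 = affected/epilepsy, 1 = unaffected).  One trio is
    produced per individual whose father and mother IDs are both set;
    a row naming only one parent is rejected as an incomplete trio.
    """
    rows: dict[str, tuple[str, ...]] = {}
    order: list[tuple[str, ...]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise PedigreeError(f"{path}:{ln}: expected 6 columns, got {len(parts)}")
            fam, iid, fat, mot, sex, pheno = parts[:6]
            if iid in rows:
                raise PedigreeError(f"{path}:{ln}: duplicate individual ID {iid!r}")
            rows[iid] = (fam, iid, fat, mot, sex, pheno)
            order.append(rows[iid])

    trios: list[TrioPedigree] = []
    for fam, iid, fat, mot, sex, pheno in order:
        has_fat, has_mot = fat != "0", mot != "0"
        if not (has_fat or has_mot):
            continue  # founder
        if has_fat != has_mot:
            raise PedigreeError(
                f"family {fam}: incomplete trio for {iid} (father={fat!r}, mother={mot!r})")
        for pid, role in ((fat, "father"), (mot, "mother")):
            if pid not in rows:
                raise PedigreeError(
                    f"family {fam}: {role} {pid!r} of {iid} has no pedigree record")
        parent_pheno = {
            pid: _PARENT_PHENO.get(rows[pid][5], "unknown") for pid in (fat, mot)
        }
        trios.append(TrioPedigree(
            family_id=fam,
            proband_id=iid,
            mother_id=mot,
            father_id=fat,
            proband_sex=_SEX.get(sex, "unknown"),
            proband_affected=_AFFECTED.get(pheno, "unknown"),
            parent_phenotype=parent_pheno,
        ))
    return trios


def write_pedigree(trios: Iterable[TrioPedigree], path: str | Path) -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    aff_code = {"epilepsy": "2", "no_epilepsy": "1", "unknown": "0"}
    par_code = {"affected": "2", "unaffected": "1", "unknown": "0"}
    with open(path, "w") as fh:
        for t in trios:
            fh.write(f"{t.family_id}\t{t.father_id}\t0\t0\t1\t"
                     f"{par_code.get(t.parent_phenotype.get(t.father_id, 'unknown'), '0')}\n")
            fh.write(f"{t.family_id}\t{t.mother_id}\t0\t0\t2\t"
                     f"{par_code.get(t.parent_phenotype.get(t.mother_id, 'unknown'), '0')}\n")
            fh.write(f"{t.family_id}\t{t.proband_id}\t{t.father_id}\t{t.mother_id}\t"
                     f"{sex_code[t.proband_sex]}\t{aff_code[t.proband_affected]}\n")


# ---------------------------------------------------------------------------
# genotype observations


@dataclass(frozen=True)
class GenotypeObservation:
    """Per-sample read evidence for one alternate allele."""

    sample_id: str
    genotype: str          # hom_ref|het|hom_alt|hemi_alt|hemi_ref|missing
    total_depth: int = 0
    alt_depth: int = 0
    genotype_quality: int = 0

    def __post_init__(self) -> None:
        if self.alt_depth > self.total_depth:
            raise CohortError(
                f"{self.sample_id}: alt_depth {self.alt_depth} exceeds "
                f"total_depth {self.total_depth}")

    @property
    def allelic_balance(self) -> float | None:
        """alt_depth / total_depth; ``None`` when depth is zero (flagged)."""
        if self.total_depth <= 0:
            return None
        return self.alt_depth / self.total_depth

    @property
    def is_carrier(self) -> bool:
        return self.genotype in ("het", "hom_alt", "hemi_alt")

    @property
    def is_hom_ref(self) -> bool:
        return self.genotype in ("hom_ref", "hemi_ref")


# ---------------------------------------------------------------------------
# annotated variants


def normalize_variant_key(chrom: str, pos: int, ref: str, alt: str
                          ) -> tuple[str, int, str, str]:
    """Canonicalize an allele pair by trimming shared suffix then prefix.

    This is the reference-free component of left-alignment: it makes
    (chrom,pos,ref,alt) keys comparable across callers that pad indel
    representations differently.  At least one base of each allele is
    always retained.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt


@dataclass
class AnnotatedVariant:
    """A bi-allelic site (multi-allelics split upstream) with its
    annotation fields and per-sample genotype observations."""

    chrom: str
    pos: int                       # 1-based, as in VCF
    ref: str
    alt: str
    gene: str = ""
    variant_type: str = "other"
    splice_distance_bp: int | None = None
    pop_freq_1kg: float | None = None
    pop_freq_evs: float | None = None
    cadd_phred: float | None = None
    polyphen_humdiv: float | None = None
    polyphen_humvar: float | None = None
    curated_class: str = "none"
    genotypes: dict[str, GenotypeObservation] = field(default_factory=dict)
    annotation_missing: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CohortError(f"pos must be >= 1, got {self.pos}")
        if self.curated_class not in CURATED_CLASSES:
            raise CohortError(f"unknown curated_class {self.curated_class!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return normalize_variant_key(self.chrom, self.pos, self.ref, self.alt)

    @property
    def key_str(self) -> str:
        c, p, r, a = self.key
        return f"{c}:{p}:{r}:{a}"

    @property
    def max_pop_freq(self) -> float | None:
        fs = [f for f in (self.pop_freq_1kg, self.pop_freq_evs) if f is not None]
        return max(fs) if fs else None

    def genotype_of(self, sample_id: str) -> GenotypeObservation:
        obs = self.genotypes.get(sample_id)
        if obs is None:
            return GenotypeObservation(sample_id=sample_id, genotype="missing")
        return obs


# ---------------------------------------------------------------------------
# filter thresholds


@dataclass(frozen=True)
class FilterThresholds:
    """Variant-level inclusion thresholds.

    Inequality directions follow the stated criteria exactly: CADD,
    proband GQ and allelic balance are strict (>), population
    frequency is strict (<), while depth, alternate-read and parental
    GQ minima are inclusive (>=).
    """

    max_pop_freq: float = 0.001
    min_cadd: float = 20.0
    min_gq_proband: int = 50
    min_depth_denovo: int = 10
    min_alt_reads_denovo: int = 3
    min_ab_exome: float = 0.25
    min_ab_targeted: float = 0.1
    min_gq_parent: int = 50
    max_parent_alt_reads: int = 0
    splice_window_bp: int = 3

    def __post_init__(self) -> None:
        for name in ("max_pop_freq", "min_cadd", "min_gq_proband",
                     "min_depth_denovo", "min_alt_reads_denovo",
                     "min_ab_exome", "min_ab_targeted", "min_gq_parent",
                     "max_parent_alt_reads", "splice_window_bp"):
            if getattr(self, name) < 0:
                raise CohortError(f"threshold {name} must be non-negative")
        if self.min_ab_targeted > self.min_ab_exome:
            raise CohortError("min_ab_targeted must not exceed min_ab_exome")

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "FilterThresholds":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise CohortError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**known)  # type: ignore[arg-type]

    def replace(self, **kw: object) -> "FilterThresholds":
        return replace(self, **kw)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# gene panels


@dataclass(frozen=True)
class GenePanel:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise CohortError(f"panel {self.name!r} is empty")
        bad = [g for g in self.genes if not g or g != g.upper()]
        if bad:
            raise CohortError(f"panel {self.name!r}: non-normalized symbols {bad[:5]}")

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes

    def __len__(self) -> int:
        return len(self.genes)


def load_panel(path: str | Path, name: str) -> GenePanel:
    """Load a plain-text gene list (one symbol per line, '#' comments).

    Symbols are upper-cased and deduplicated; duplicates are logged.
    """
    symbols: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                symbols.append(line.upper())
    if not symbols:
        raise CohortError(f"panel file {path} contains no gene symbols")
    if len(set(symbols)) != len(symbols):
        dups = sorted({s for s in symbols if symbols.count(s) > 1})
        log.warning("panel %s: duplicated symbols %s", name, dups)
    return GenePanel(name=name, genes=frozenset(symbols))


def assert_non_overlap(a: GenePanel, b: GenePanel) -> bool:
    """True iff the two panels share no gene; overlaps are logged."""
    shared = a.genes & b.genes
    if shared:
        log.warning("panels %s and %s overlap: %s", a.name, b.name, sorted(shared))
        return False
    return True


# ---------------------------------------------------------------------------
# annotation table


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the per-variant annotation TSV, indexed by (chrom,pos,ref,alt)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise CohortError(f"annotation table {path} lacks columns {sorted(missing)}")
    df["curated_class"] = df["curated_class"].fillna("none")
    df = df.set_index(["chrom", "pos", "ref", "alt"], drop=False)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()[:3]
        raise CohortError(f"annotation table has duplicate variant keys, e.g. {dups}")
    return df


def write_annotations(variants: Iterable[AnnotatedVariant], path: str | Path) -> None:
    recs = []
    for v in variants:
        recs.append({
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "gene": v.gene, "variant_type": v.variant_type,
            "splice_distance_bp": v.splice_distance_bp,
            "af_1kg": v.pop_freq_1kg, "af_evs": v.pop_freq_evs,
            "cadd_phred": v.cadd_phred,
            "polyphen_humdiv": v.polyphen_humdiv,
            "polyphen_humvar": v.polyphen_humvar,
            "curated_class": v.curated_class,
        })
    pd.DataFrame(recs, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def _opt_float(x: object) -> float | None:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    return float(x)  # type: ignore[arg-type]


def _opt_int(x: object) -> int | None:
    f = _opt_float(x)
    return None if f is None else int(f)


# ---------------------------------------------------------------------------
# VCF reading


def _classify_alleles(alleles: list[int], alt_index: int) -> str:
    """Map the called alleles of one sample to a genotype class for the
    given (1-based, pre-split) alternate allele index."""
    called = [a for a in alleles if a >= 0]
    if len(called) < len(alleles) or not called:
        return "missing"
    n_alt = sum(1 for a in called if a == alt_index)
    if len(called) == 1:
        return "hemi_alt" if n_alt == 1 else "hemi_ref"
    if n_alt == 0:
        return "hom_ref"
    if n_alt == len(called):
        return "hom_alt"
    return "het"


def read_trio_vcf(vcf_path: str | Path,
                  pedigree: Iterable[TrioPedigree],
                  annotations: pd.DataFrame | None = None,
                  ) -> Iterator[AnnotatedVariant]:
    """Stream AnnotatedVariants from a multi-sample VCF.

    Multi-allelic records are split into one variant per alternate
    allele with the AD field decomposed accordingly.  Records without
    a row in ``annotations`` are flagged (``annotation_missing``) with
    ``curated_class='none'``, never dropped.
    """
    pedigree = list(pedigree)
    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    sample_idx = {s: i for i, s in enumerate(samples)}
    needed = {m for t in pedigree for m in t.members}
    absent = sorted(needed - set(samples))
    if absent:
        raise CohortError(
            f"pedigree samples missing from VCF header {vcf_path}: {absent}")

    for rec in vcf:
        alts = rec.ALT or []
        depths = rec.format("DP")
        ads = rec.format("AD")
        gqs = rec.format("GQ")
        genos = rec.genotypes  # [[a1, a2, phased], ...] (or [a, phased])
        for ai, alt in enumerate(alts, start=1):
            obs: dict[str, GenotypeObservation] = {}
            for s in needed:
                i = sample_idx[s]
                g = genos[i]
                alleles = [int(a) for a in g[:-1]]
                gclass = _classify_alleles(alleles, ai)
                dp = 0 if depths is None else max(int(depths[i][0]), 0)
                alt_dp = 0
                if ads is not None and ads.shape[1] > ai:
                    alt_dp = max(int(ads[i][ai]), 0)
                gq = 0 if gqs is None else int(gqs[i][0]) if gqs[i][0] >= 0 else 0
                if ads is not None and dp == 0:
                    dp = int(sum(max(int(x), 0) for x in ads[i]))
                obs[s] = GenotypeObservation(
                    sample_id=s, genotype=gclass,
                    total_depth=dp, alt_depth=min(alt_dp, dp),
                    genotype_quality=gq)
            v = AnnotatedVariant(
                chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt,
                genotypes=obs)
            if annotations is not None:
                ikey = (rec.CHROM, rec.POS, rec.REF, alt)
                if ikey in annotations.index:
                    row = annotations.loc[ikey]
                    v.gene = str(row["gene"]).upper()
                    v.variant_type = str(row["variant_type"])
                    v.splice_distance_bp = _opt_int(row["splice_distance_bp"])
                    v.pop_freq_1kg = _opt_float(row["af_1kg"])
                    v.pop_freq_evs = _opt_float(row["af_evs"])
                    v.cadd_phred = _opt_float(row["cadd_phred"])
                    v.polyphen_humdiv = _opt_float(row["polyphen_humdiv"])
                    v.polyphen_humvar = _opt_float(row["polyphen_humvar"])
                    v.curated_class = str(row["curated_class"])
                else:
                    v.annotation_missing = True
            else:
                v.annotation_missing = True
            yield v
    vcf.close()


# ---------------------------------------------------------------------------
# VCF writing (text, VCF 4.2)

_GT_STRING = {
    "hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1",
    "hemi_alt": "1", "hemi_ref": "0", "missing": "./.",
}

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""

_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25, "M": 25}


def _chrom_rank(c: str) -> tuple[int, str]:
    c = c.removeprefix("chr")
    return (_CHROM_ORDER.get(c, 99), c)


def write_cohort_vcf(variants: Iterable[AnnotatedVariant],
                     samples: list[str],
                     path: str | Path,
                     extra_header: Iterable[str] = ()) -> None:
    """Write bi-allelic variants to an uncompressed VCF 4.2 file."""
    variants = sorted(variants, key=lambda v: (_chrom_rank(v.chrom), v.pos, v.ref, v.alt))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for line in extra_header:
            fh.write(line.rstrip("\n") + "\n")
        seen_contigs: list[str] = []
        for v in variants:
            if v.chrom not in seen_contigs:
                seen_contigs.append(v.chrom)
        for c in seen_contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for v in variants:
            cols = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS", ".",
                    "GT:DP:AD:GQ"]
            for s in samples:
                o = v.genotype_of(s)
                if o.genotype == "missing" and s not in v.genotypes:
                    cols.append("./.:0:0,0:0")
                    continue
                ref_dp = max(o.total_depth - o.alt_depth, 0)
                cols.append(f"{_GT_STRING[o.genotype]}:{o.total_depth}:"
                            f"{ref_dp},{o.alt_depth}:{o.genotype_quality}")
            fh.write("\t".join(cols) + "\n")
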