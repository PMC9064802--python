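"""Synthetic trio-cohort generator.

Emits complete, self-consistent cohorts — multi-sample VCF, PED
pedigree, annotation TSV, gene-panel files, KO mapping and a truth
table — with the statistical structure the pipeline assumes: Mendelian
trio genotypes except at planted de novo sites, read evidence (depth,
alternate reads, genotype quality) drawn around configurable means,
annotation spectra (CADD, population frequency) that straddle the
filter thresholds, and a group-specific probability that a proband
carries a pathogenic panel variant.  Every emitted variant has exactly
one truth row, so recall and precision of each pipeline stage are
measurable without any real sequencing data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .cohort import (AnnotatedVariant, CohortError, FilterThresholds,
                     GenotypeObservation, TrioPedigree, write_annotations,
                     write_cohort_vcf, write_pedigree)
from .kegg import write_ko_mapping
from .stats import ContingencyTable

TRUTH_COLUMNS = ["chrom", "pos", "ref", "alt", "variant_key", "family_id",
                 "planted_class", "planted_curated_class", "panel",
                 "should_pass_filters"]


@dataclass(frozen=True)
class CohortPaths:
    """File locations of one written cohort."""

    vcf: Path
    ped: Path
    annotations: Path
    epilepsy_panel: Path
    cad_panel: Path
    ko_mapping: Path
    truth_variants: Path
    truth_trios: Path


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults mirror the study conditions: 10 case and 10 control
    trios, a 200-gene epilepsy panel and a disjoint 89-gene CAD panel,
    a 0.5 / 0.1 probability that a case / control proband carries a
    pathogenic panel variant, exome depth around 60x and heterozygous
    allelic balance around 0.5.
    """

    n_case_trios: int = 10
    n_control_trios: int = 10
    seed: int = 0
    p_panel_pathogenic_case: float = 0.5
    p_panel_pathogenic_control: float = 0.1
    n_background_variants_per_trio: int = 30
    denovo_rate_per_trio: float = 1.0
    nontransmitted_rate: float = 1.0
    depth_mean: float = 60.0
    ab_het_mean: float = 0.5
    gq_pass_prob: float = 0.98
    cadd_pass_prob: float = 0.5         # background CADD mixture weight > 20
    af_zero_prob: float = 0.7           # background AF point mass at 0
    n_panel_genes: int = 200
    n_cad_genes: int = 89
    n_background_genes: int = 400
    denovo_ab_range: tuple[float, float] = (0.35, 0.60)
    noise_free: bool = False            # force all planted evidence above thresholds

    def __post_init__(self) -> None:
        for p in (self.p_panel_pathogenic_case, self.p_panel_pathogenic_control,
                  self.gq_pass_prob, self.cadd_pass_prob, self.af_zero_prob):
            if not 0.0 <= p <= 1.0:
                raise CohortError(f"probability out of [0,1]: {p}")
        if self.n_case_trios < 1 or self.n_control_trios < 1:
            raise CohortError("need at least one trio per group")
        if self.n_panel_genes < 1:
            raise CohortError("panel must contain at least one gene")


def _panel_genes(cfg: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    epi = [f"EPG{i:03d}" for i in range(1, cfg.n_panel_genes + 1)]
    cad = [f"CADG{i:03d}" for i in range(1, cfg.n_cad_genes + 1)]
    bg = [f"BGG{i:04d}" for i in range(1, cfg.n_background_genes + 1)]
    return epi, cad, bg


def _make_trios(cfg: SimulationConfig) -> list[TrioPedigree]:
    trios = []
    for i in range(cfg.n_case_trios + cfg.n_control_trios):
        fam = f"FAM{i + 1:03d}"
        affected = "epilepsy" if i < cfg.n_case_trios else "no_epilepsy"
        trios.append(TrioPedigree(
            family_id=fam, proband_id=f"{fam}-p",
            mother_id=f"{fam}-m", father_id=f"{fam}-f",
            proband_sex="male" if i % 2 == 0 else "female",
            proband_affected=affected,
            parent_phenotype={f"{fam}-m": "unaffected", f"{fam}-f": "unaffected"}))
    return trios


_BASES = np.array(list("ACGT"))


class _VariantFactory:
    """Deterministic allocator of unique variant sites and evidence."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        self.rng = rng
        self._counter = 0

    def site(self) -> tuple[str, int, str, str]:
        i = self._counter
        self._counter += 1
        chrom = str(i % 22 + 1)
        pos = 100_000 + (i // 22) * 997 + int(self.rng.integers(0, 500))
        ref, alt = self.rng.choice(4, 2, replace=False)
        return chrom, pos, str(_BASES[ref]), str(_BASES[alt])

    def depth(self, floor: int = 1) -> int:
        dp = int(self.rng.poisson(self.cfg.depth_mean))
        if self.cfg.noise_free:
            dp = max(dp, 2 * floor, 20)
        return max(dp, floor)

    def gq(self, passing: bool | None = None) -> int:
        if passing is None:
            passing = bool(self.rng.random() < self.cfg.gq_pass_prob)
        if self.cfg.noise_free:
            passing = True
        return int(self.rng.integers(60, 100)) if passing \
            else int(self.rng.integers(10, 50))

    def het_obs(self, sample: str, ab_range: tuple[float, float] | None = None,
                min_alt: int = 1) -> GenotypeObservation:
        """Heterozygous observation; when ``ab_range`` is given the
        realized alt count is chosen so alt/dp lies strictly inside
        (lo, hi]."""
        dp = self.depth(floor=max(10, min_alt))
        if ab_range is None:
            alt = int(self.rng.binomial(dp, self.cfg.ab_het_mean))
            alt = min(max(alt, min_alt), dp)
        else:
            lo, hi = ab_range
            kmin = math.floor(lo * dp) + 1
            kmax = math.floor(hi * dp)
            if kmax < kmin:       # no integer count in range; widen depth
                dp = max(dp, math.ceil(2.0 / (hi - lo)))
                kmin = math.floor(lo * dp) + 1
                kmax = math.floor(hi * dp)
            kmin = max(kmin, min_alt)
            alt = int(self.rng.integers(kmin, max(kmax, kmin) + 1))
            alt = min(alt, dp)
        return GenotypeObservation(sample, "het", dp, alt, self.gq())

    def hom_ref_obs(self, sample: str, clean: bool = False) -> GenotypeObservation:
        dp = self.depth()
        alt = 0
        gq = self.gq(passing=True) if clean else self.gq()
        if clean:
            gq = max(gq, 60)
        return GenotypeObservation(sample, "hom_ref", dp, alt, gq)

    def cadd(self, passing: bool) -> float:
        return float(self.rng.uniform(20.5, 45.0)) if passing \
            else float(self.rng.uniform(3.0, 19.9))

    def af_pair(self, rare: bool) -> tuple[float, float]:
        if rare:
            if self.rng.random() < self.cfg.af_zero_prob:
                return 0.0, 0.0
            return (round(float(self.rng.uniform(0, 0.0009)), 6),
                    round(float(self.rng.uniform(0, 0.0009)), 6))
        return (round(float(self.rng.uniform(0.002, 0.05)), 6),
                round(float(self.rng.uniform(0.0, 0.05)), 6))


_FUNCTIONAL = ("missense", "nonsense", "frameshift")


def simulate_cohort(cfg: SimulationConfig, out_dir: str | Path
                    ) -> tuple[CohortPaths, pd.DataFrame, pd.DataFrame]:
    """Generate and write a complete synthetic cohort.

    Returns the file paths, the per-variant truth table and the
    per-trio truth table.  Output is byte-deterministic for a fixed
    config (including seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    fac = _VariantFactory(cfg, rng)
    trios = _make_trios(cfg)
    epi_genes, cad_genes, bg_genes = _panel_genes(cfg)
    samples = [s for t in trios for s in (t.father_id, t.mother_id, t.proband_id)]

    variants: list[AnnotatedVariant] = []
    truth_rows: list[dict] = []
    trio_rows: list[dict] = []

    def fill_background(v: AnnotatedVariant) -> None:
        for s in samples:
            if s not in v.genotypes:
                v.genotypes[s] = fac.hom_ref_obs(s)

    def add_variant(trio: TrioPedigree, gene: str, planted_class: str,
                    curated: str, panel: str, *,
                    passing_annotation: bool = True,
                    proband_obs: GenotypeObservation | None = None,
                    mother_obs: GenotypeObservation | None = None,
                    father_obs: GenotypeObservation | None = None,
                    variant_type: str | None = None,
                    should_pass: bool | None = None) -> None:
        chrom, pos, ref, alt = fac.site()
        vt = variant_type or _FUNCTIONAL[int(rng.integers(0, 3))]
        v = AnnotatedVariant(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
            variant_type=vt,
            splice_distance_bp=int(rng.integers(0, 3)) if vt == "splice"
            else int(rng.integers(4, 500)),
            cadd_phred=fac.cadd(passing_annotation),
            curated_class=curated)
        v.pop_freq_1kg, v.pop_freq_evs = fac.af_pair(rare=passing_annotation)
        if proband_obs is not None:
            v.genotypes[trio.proband_id] = proband_obs
        if mother_obs is not None:
            v.genotypes[trio.mother_id] = mother_obs
        if father_obs is not None:
            v.genotypes[trio.father_id] = father_obs
        fill_background(v)
        variants.append(v)
        if should_pass is None:
            should_pass = passing_annotation
        truth_rows.append({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "variant_key": v.key_str, "family_id": trio.family_id,
            "planted_class": planted_class, "planted_curated_class": curated,
            "panel": panel, "should_pass_filters": bool(should_pass)})

    for trio in trios:
        group = trio.proband_affected
        p_exposed = (cfg.p_panel_pathogenic_case if group == "epilepsy"
                     else cfg.p_panel_pathogenic_control)
        exposed = bool(rng.random() < p_exposed)
        trio_rows.append({"family_id": trio.family_id, "group": group,
                          "exposure_truth": exposed})

        # planted pathogenic panel variant driving group burden
        if exposed:
            gene = epi_genes[int(rng.integers(0, len(epi_genes)))]
            curated = "pathogenic" if rng.random() < 0.5 else "likely_pathogenic"
            if rng.random() < 0.5:   # transmitted from one parent
                side = "maternal" if rng.random() < 0.5 else "paternal"
                parent = trio.mother_id if side == "maternal" else trio.father_id
                kw = {"mother_obs" if side == "maternal" else "father_obs":
                      fac.het_obs(parent)}
                add_variant(trio, gene, f"transmitted_{side}", curated,
                            "epilepsy",
                            proband_obs=fac.het_obs(
                                trio.proband_id,
                                ab_range=(0.3, 0.7) if cfg.noise_free else None,
                                min_alt=1),
                            **kw)
            else:                    # de novo
                add_variant(trio, gene, "de_novo", curated, "epilepsy",
                            proband_obs=fac.het_obs(
                                trio.proband_id, ab_range=cfg.denovo_ab_range,
                                min_alt=3),
                            mother_obs=fac.hom_ref_obs(trio.mother_id, clean=True),
                            father_obs=fac.hom_ref_obs(trio.father_id, clean=True))

        # exome-wide de novo variants
        for _ in range(int(rng.poisson(cfg.denovo_rate_per_trio))):
            gene = bg_genes[int(rng.integers(0, len(bg_genes)))]
            curated = ("likely_pathogenic", "VUS")[int(rng.integers(0, 2))]
            add_variant(trio, gene, "de_novo", curated, "none",
                        proband_obs=fac.het_obs(
                            trio.proband_id, ab_range=cfg.denovo_ab_range,
                            min_alt=3),
                        mother_obs=fac.hom_ref_obs(trio.mother_id, clean=True),
                        father_obs=fac.hom_ref_obs(trio.father_id, clean=True))

        # non-transmitted parental panel variants
        for _ in range(int(rng.poisson(cfg.nontransmitted_rate))):
            gene = epi_genes[int(rng.integers(0, len(epi_genes)))]
            side = "maternal" if rng.random() < 0.5 else "paternal"
            parent = trio.mother_id if side == "maternal" else trio.father_id
            curated = "likely_pathogenic" if rng.random() < 0.3 else "benign"
            kw = {"mother_obs" if side == "maternal" else "father_obs":
                  fac.het_obs(parent)}
            add_variant(trio, gene, f"non_transmitted_{side}", curated,
                        "epilepsy",
                        proband_obs=fac.hom_ref_obs(trio.proband_id, clean=True),
                        **kw)

        # inherited background spectrum (mixed annotation quality)
        for _ in range(cfg.n_background_variants_per_trio):
            gene = bg_genes[int(rng.integers(0, len(bg_genes)))]
            passing = bool(rng.random() < cfg.cadd_pass_prob)
            side = "maternal" if rng.random() < 0.5 else "paternal"
            parent = trio.mother_id if side == "maternal" else trio.father_id
            transmitted = bool(rng.random() < 0.5)
            kw = {"mother_obs" if side == "maternal" else "father_obs":
                  fac.het_obs(parent)}
            if transmitted:
                add_variant(trio, gene, f"transmitted_{side}",
                            ("benign", "VUS")[int(rng.integers(0, 2))], "none",
                            passing_annotation=passing,
                            proband_obs=fac.het_obs(trio.proband_id), **kw)
            else:
                add_variant(trio, gene, f"non_transmitted_{side}",
                            ("benign", "VUS")[int(rng.integers(0, 2))], "none",
                            passing_annotation=passing,
                            proband_obs=fac.hom_ref_obs(trio.proband_id), **kw)

    # KO mapping over all genes used, deterministic layout
    ko_rows: list[tuple[str, str, str, str]] = [
        ("", "09140", "Cellular Processes", ""),
        ("", "09143", "Cell growth and death", "09140"),
        ("", "09150", "Organismal Systems", ""),
        ("", "09156", "Nervous system", "09150"),
        ("", "09160", "Human Diseases", ""),
        ("", "09180", "Brite Hierarchies", ""),
    ]
    cycle = ["09156", "09143", "09180", "09160"]
    names = {"09156": "Nervous system", "09143": "Cell growth and death",
             "09180": "Brite Hierarchies", "09160": "Human Diseases"}
    parents = {"09156": "09150", "09143": "09140", "09180": "", "09160": ""}
    for i, gene in enumerate(bg_genes + epi_genes):
        code = cycle[i % len(cycle)]
        ko_rows.append((gene, code, names[code], parents[code]))

    paths = CohortPaths(
        vcf=out / "cohort.vcf", ped=out / "cohort.ped",
        annotations=out / "annotations.tsv",
        epilepsy_panel=out / "epilepsy_panel.txt",
        cad_panel=out / "cad_panel.txt",
        ko_mapping=out / "ko_mapping.tsv",
        truth_variants=out / "truth_variants.tsv",
        truth_trios=out / "truth_trios.tsv")

    write_cohort_vcf(variants, samples, paths.vcf,
                     extra_header=[f"##triowes_simulation_seed={cfg.seed}"])
    write_pedigree(trios, paths.ped)
    write_annotations(variants, paths.annotations)
    paths.epilepsy_panel.write_text(
        "# synthetic epilepsy panel\n" + "\n".join(epi_genes) + "\n")
    paths.cad_panel.write_text(
        "# synthetic CAD panel\n" + "\n".join(cad_genes) + "\n")
    write_ko_mapping(ko_rows, paths.ko_mapping)

    truth_variants = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth_trios = pd.DataFrame(trio_rows,
                               columns=["family_id", "group", "exposure_truth"])
    truth_variants.to_csv(paths.truth_variants, sep="\t", index=False)
    truth_trios.to_csv(paths.truth_trios, sep="\t", index=False)
    return paths, truth_variants, truth_trios


# ---------------------------------------------------------------------------
# lightweight exposure sampler (burden calibration at large n)


def simulate_exposure_table(n_cases: int, n_controls: int,
                            p_case: float, p_control: float,
                            rng: np.random.Generator | int | None = None,
                            ) -> ContingencyTable:
    """Draw a 2x2 exposure table directly from the two Bernoulli rates.

    This is the burden-generating process of the full simulator with
    the genotype layer marginalized out; it is what odds-ratio
    coverage experiments at hundreds of trios per arm need.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    a = int(rng.binomial(n_cases, p_case))
    c = int(rng.binomial(n_controls, p_control))
    return ContingencyTable(a, n_cases - a, c, n_controls - c,
                            label="simulated_exposure")


# ---------------------------------------------------------------------------
# truth-vs-pipeline scoring


def score_recovery(truth: pd.DataFrame,
                   calls: Iterable,
                   survivor_keys: Iterable[str] | None = None,
                   ) -> pd.DataFrame:
    """Recall and precision per planted inheritance class.

    ``calls`` are InheritanceCalls (proband-carrier classifications
    plus non-transmitted detections); truth rows are matched on
    (variant_key, family_id).  Only truth rows with
    ``should_pass_filters`` enter the recall denominator, since the
    pipeline never classifies variants it has filtered out.  When
    ``survivor_keys`` is given a filter-confusion row is appended.
    """
    predicted: dict[str, set[tuple[str, str]]] = {}
    for c in calls:
        predicted.setdefault(c.call, set()).add((c.variant_key, c.family_id))

    rows = []
    classes = sorted((set(truth["planted_class"]) | set(predicted))
                     - {"unresolved"})
    for cls in classes:
        t_rows = truth[(truth["planted_class"] == cls)
                       & truth["should_pass_filters"]]
        t_set = set(zip(t_rows["variant_key"], t_rows["family_id"]))
        p_set = predicted.get(cls, set())
        tp = len(t_set & p_set)
        rows.append({
            "class": cls, "n_truth": len(t_set), "n_called": len(p_set),
            "tp": tp,
            "recall": tp / len(t_set) if t_set else math.nan,
            "precision": tp / len(p_set) if p_set else math.nan})
    if survivor_keys is not None:
        surv = set(survivor_keys)
        should = set(truth.loc[truth["should_pass_filters"], "variant_key"])
        tp = len(should & surv)
        rows.append({
            "class": "filter_pass", "n_truth": len(should),
            "n_called": len(surv), "tp": tp,
            "recall": tp / len(should) if should else math.nan,
            "precision": tp / len(surv) if surv else math.nan})
    return pd.DataFrame(rows, columns=["class", "n_truth", "n_called", "tp",
                                       "recall", "precision"])
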