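"""Curated synthetic demonstration cohorts.

Two fixed 20-trio cohorts (10 probands with post-neonatal epilepsy,
10 without) whose variant content is curated rather than sampled:

* the *panel* cohort carries 29 proband variants in epilepsy-panel
  genes — 6 pathogenic/likely-pathogenic (2 de novo, 4 maternally
  inherited, one of them X-linked in a hemizygous son), 6 VUS and 17
  benign/likely-benign — plus two pathogenic CAD-panel variants (one
  case, one control) and one non-transmitted pathogenic variant in
  each panel, both in parents of children with epilepsy;

* the *de novo* cohort carries 17 exome-wide de novo pathogenic /
  likely-pathogenic / VUS variants: 7 distributed over 6 probands
  with epilepsy and 10 over 6 probands without.

All read evidence is synthetic and set comfortably above the quality
thresholds, so the downstream counts are exactly the curated ones.
Gene symbols of the highlighted variants are real; panel filler
symbols are synthetic.
"""

from __future__ import annotations

from pathlib import Path

from .cohort import (AnnotatedVariant, GenotypeObservation, TrioPedigree,
                     write_annotations, write_cohort_vcf, write_pedigree)
from .kegg import write_ko_mapping
from .simulate import CohortPaths

N_EPILEPSY_PANEL = 200
N_CAD_PANEL = 89

#: probands with post-neonatal epilepsy (case numbers)
EPILEPSY_CASES = (1, 2, 3, 4, 5, 7, 9, 10, 16, 17)
NO_EPILEPSY_CASES = (6, 8, 11, 12, 13, 14, 15, 18, 19, 20)


def make_curated_trios() -> list[TrioPedigree]:
    trios = []
    for i in sorted(EPILEPSY_CASES + NO_EPILEPSY_CASES):
        fam = f"case{i:02d}"
        trios.append(TrioPedigree(
            family_id=fam, proband_id=f"{fam}-p", mother_id=f"{fam}-m",
            father_id=f"{fam}-f",
            proband_sex="male" if i % 2 == 1 else "female",
            proband_affected=("epilepsy" if i in EPILEPSY_CASES
                              else "no_epilepsy"),
            parent_phenotype={f"{fam}-m": "unaffected",
                              f"{fam}-f": "unaffected"}))
    return trios


def _obs(sample: str, gt: str, dp: int, alt: int, gq: int = 99
         ) -> GenotypeObservation:
    return GenotypeObservation(sample, gt, dp, alt, gq)


def _set_trio_genotypes(v: AnnotatedVariant, fam: str, inheritance: str) -> None:
    """Install qualifying-evidence genotypes for one trio.

    inheritance: de_novo | mat | pat | mat_hemi (X-linked het mother,
    hemizygous son) | non_transmitted_mat | non_transmitted_pat
    """
    p, m, f = f"{fam}-p", f"{fam}-m", f"{fam}-f"
    clean_ref = lambda s: _obs(s, "hom_ref", 45, 0)
    if inheritance == "de_novo":
        v.genotypes[p] = _obs(p, "het", 40, 18)
        v.genotypes[m] = clean_ref(m)
        v.genotypes[f] = clean_ref(f)
    elif inheritance == "mat":
        v.genotypes[p] = _obs(p, "het", 48, 22)
        v.genotypes[m] = _obs(m, "het", 52, 26)
        v.genotypes[f] = clean_ref(f)
    elif inheritance == "pat":
        v.genotypes[p] = _obs(p, "het", 48, 22)
        v.genotypes[m] = clean_ref(m)
        v.genotypes[f] = _obs(f, "het", 52, 26)
    elif inheritance == "mat_hemi":
        v.genotypes[p] = _obs(p, "hemi_alt", 40, 39)
        v.genotypes[m] = _obs(m, "het", 52, 26)
        v.genotypes[f] = _obs(f, "hemi_ref", 38, 0)
    elif inheritance == "non_transmitted_mat":
        v.genotypes[p] = clean_ref(p)
        v.genotypes[m] = _obs(m, "het", 52, 26)
        v.genotypes[f] = clean_ref(f)
    elif inheritance == "non_transmitted_pat":
        v.genotypes[p] = clean_ref(p)
        v.genotypes[m] = clean_ref(m)
        v.genotypes[f] = _obs(f, "het", 52, 26)
    else:  # pragma: no cover
        raise ValueError(inheritance)


def _fill_hom_ref(v: AnnotatedVariant, samples: list[str]) -> None:
    for s in samples:
        if s not in v.genotypes:
            v.genotypes[s] = _obs(s, "hom_ref", 40, 0)


def _variant(case: int, gene: str, chrom: str, pos: int, ref: str, alt: str,
             vtype: str, inheritance: str, cadd: float,
             ppdiv: float | None, ppvar: float | None, curated: str,
             samples: list[str]) -> AnnotatedVariant:
    v = AnnotatedVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        variant_type=vtype,
        splice_distance_bp=1 if vtype == "splice" else 150,
        pop_freq_1kg=0.0, pop_freq_evs=0.0, cadd_phred=cadd,
        polyphen_humdiv=ppdiv, polyphen_humvar=ppvar, curated_class=curated)
    _set_trio_genotypes(v, f"case{case:02d}", inheritance)
    _fill_hom_ref(v, samples)
    return v


# (case, gene, chrom, pos, ref, alt, type, inheritance, CADD, ppdiv, ppvar, class)
PANEL_PATHOGENIC_ROWS = [
    (1, "CASK",   "X",  41500000, "C", "T", "missense", "mat_hemi", 21.4, 1.00, 1.00, "likely_pathogenic"),
    (2, "MAGI2",  "7",  77694888, "T", "G", "splice",   "de_novo",  21.1, None, None, "likely_pathogenic"),
    (3, "PRRT2",  "16", 29825000, "C", "A", "missense", "mat",      24.4, 0.99, 0.94, "likely_pathogenic"),
    (4, "RBFOX3", "17", 77090000, "C", "T", "missense", "de_novo",  34.0, 0.98, 0.67, "likely_pathogenic"),
    (5, "KCNT1",  "9", 138650000, "G", "A", "missense", "mat",      27.6, 1.00, 1.00, "likely_pathogenic"),
    (6, "CPA6",   "8",  68420000, "C", "T", "nonsense", "mat",      46.0, None, None, "pathogenic"),
]

#: the further 23 panel variants: 2 de novo VUS in one gene, 4 inherited
#: VUS and 17 inherited benign/likely-benign, spread over the cohort
PANEL_OTHER_ROWS = (
    [(7, "RYR3", "15", 33600000, "G", "A", "missense", "de_novo", 23.0, 0.60, 0.40, "VUS"),
     (12, "RYR3", "15", 33610000, "C", "T", "missense", "de_novo", 21.9, 0.55, 0.35, "VUS")]
    + [(c, f"EPG{100 + k:03d}", str(k % 22 + 1), 5_000_000 + 1000 * k, "A", "G",
        "missense", ("mat" if k % 2 else "pat"), 22.0 + 0.1 * k, 0.5, 0.5, "VUS")
       for k, c in enumerate((8, 9, 13, 16), start=1)]
    # 17 benign/likely-benign inherited variants in 15 genes (two genes
    # recur in a second family)
    + [(c, f"EPG{110 + (k if k <= 15 else k - 15):03d}",
        str((k + 3) % 22 + 1), 6_000_000 + 1000 * k, "G", "C", "missense",
        ("mat" if k % 2 else "pat"), 20.5 + 0.05 * k, 0.2, 0.1,
        ("benign" if k % 2 else "likely_benign"))
       for k, c in enumerate((1, 2, 3, 4, 5, 6, 7, 9, 10, 11, 12, 14, 15,
                              17, 18, 19, 20), start=1)]
)

CAD_PROBAND_ROWS = [
    (2,  "LDLR", "19", 11210000, "G", "A", "missense", "pat", 28.0, 0.99, 0.98, "likely_pathogenic"),
    (18, "APOB", "2",  21230000, "C", "T", "missense", "mat", 26.5, 0.98, 0.95, "likely_pathogenic"),
]

NON_TRANSMITTED_ROWS = [
    (3, "SCN8A", "12", 52080000, "C", "T", "nonsense", "non_transmitted_mat",
     38.0, None, None, "pathogenic"),
    (4, "PCSK9", "1",  55510000, "G", "A", "missense", "non_transmitted_pat",
     27.0, 0.99, 0.97, "likely_pathogenic"),
]

# (case, gene, chrom, pos, ref, alt, type, CADD, ppdiv, ppvar, class) — all de novo
DENOVO_ROWS = [
    (2,  "ENOX1",   "13",  45560000, "C", "T", "missense",   31.0, 1.00, 0.99, "likely_pathogenic"),
    (2,  "PTPN14",  "1",  214530000, "G", "C", "missense",   23.1, 0.99, 0.97, "likely_pathogenic"),
    (3,  "ATF6B",   "6",   32080000, "G", "A", "missense",   25.5, 0.98, 0.70, "likely_pathogenic"),
    (4,  "SNRPB",   "20",   2440000, "G", "A", "missense",   23.7, 0.84, 0.49, "likely_pathogenic"),
    (7,  "MIF4GD",  "17",  73280000, "G", "T", "nonsense",   42.0, None, None, "pathogenic"),
    (9,  "GNB3",    "12",   6950000, "C", "T", "missense",   24.9, 0.95, 0.52, "likely_pathogenic"),
    (10, "CAPN7",   "3",   15250000, "G", "A", "missense",   25.6, 0.99, 0.93, "likely_pathogenic"),
    (8,  "DHRS11",  "17",  34950000, "T", "G", "missense",   28.3, 0.99, 0.94, "likely_pathogenic"),
    (8,  "FAM186A", "12",  50750000, "T", "TGT", "frameshift", 22.6, None, None, "pathogenic"),
    (11, "HECTD4",  "12", 112819897, "C", "A", "splice",     20.2, None, None, "likely_pathogenic"),
    (11, "PCBP2",   "12",  53845910, "G", "A", "splice",     22.4, None, None, "VUS"),
    (11, "VPS37A",  "8",   17230000, "C", "G", "missense",   21.8, 0.97, 0.41, "likely_pathogenic"),
    (12, "ELF1",    "13",  41550000, "G", "A", "missense",   23.3, 0.99, 0.99, "VUS"),
    (13, "CSTF2T",  "10",  53450000, "G", "A", "missense",   32.0, 0.99, 0.99, "likely_pathogenic"),
    (13, "UBXN11",  "1",   26610000, "C", "CCCCGGCCCCA", "frameshift", 22.2, None, None, "pathogenic"),
    (14, "DCHS2",   "4",  155180000, "G", "T", "nonsense",   25.8, None, None, "pathogenic"),
    (15, "OSBP",    "11",  59340000, "G", "C", "missense",   31.0, 1.00, 0.99, "likely_pathogenic"),
]

#: synthetic KO assignment for the de novo cohort genes: nervous-system
#: membership for most case-proband genes, cell growth and death for
#: most control-proband genes, one human-disease-only gene (drops to
#: the excluded bucket) and one unmapped gene
KO_ASSIGNMENT = {
    "ENOX1": ["09156"], "PTPN14": ["09156"], "ATF6B": ["09156"],
    "SNRPB": ["09180"], "MIF4GD": ["09156"], "GNB3": ["09156", "09160"],
    "CAPN7": ["09143"],
    "DHRS11": ["09143"], "HECTD4": ["09143"], "PCBP2": ["09160"],
    "VPS37A": ["09143"], "ELF1": ["09180"], "CSTF2T": ["09143"],
    "UBXN11": ["09143"], "DCHS2": ["09143"], "OSBP": ["09143"],
    # FAM186A deliberately unmapped
}

_KO_NAMES = {"09140": "Cellular Processes", "09143": "Cell growth and death",
             "09150": "Organismal Systems", "09156": "Nervous system",
             "09160": "Human Diseases", "09180": "Brite Hierarchies"}
_KO_PARENTS = {"09143": "09140", "09156": "09150"}


def _epilepsy_panel_genes() -> list[str]:
    named = [r[1] for r in PANEL_PATHOGENIC_ROWS]
    named += ["RYR3", "SCN8A"]
    named += sorted({r[1] for r in PANEL_OTHER_ROWS if r[1].startswith("EPG")})
    filler = [f"EPG{i:03d}" for i in range(1, 100)
              if f"EPG{i:03d}" not in named]
    genes = named + filler
    genes += [f"EPX{i:03d}" for i in range(1, N_EPILEPSY_PANEL - len(genes) + 1)]
    return genes[:N_EPILEPSY_PANEL]


def _cad_panel_genes() -> list[str]:
    named = ["LDLR", "APOB", "PCSK9"]
    return named + [f"CADG{i:03d}" for i in range(1, N_CAD_PANEL - len(named) + 1)]


def _write_common(out: Path, trios: list[TrioPedigree],
                  variants: list[AnnotatedVariant],
                  ko_rows: list[tuple[str, str, str, str]]) -> CohortPaths:
    out.mkdir(parents=True, exist_ok=True)
    samples = [s for t in trios for s in (t.father_id, t.mother_id, t.proband_id)]
    paths = CohortPaths(
        vcf=out / "cohort.vcf", ped=out / "cohort.ped",
        annotations=out / "annotations.tsv",
        epilepsy_panel=out / "epilepsy_panel.txt",
        cad_panel=out / "cad_panel.txt",
        ko_mapping=out / "ko_mapping.tsv",
        truth_variants=out / "truth_variants.tsv",
        truth_trios=out / "truth_trios.tsv")
    write_cohort_vcf(variants, samples, paths.vcf)
    write_pedigree(trios, paths.ped)
    write_annotations(variants, paths.annotations)
    paths.epilepsy_panel.write_text(
        "# curated synthetic epilepsy panel\n"
        + "\n".join(_epilepsy_panel_genes()) + "\n")
    paths.cad_panel.write_text(
        "# curated synthetic CAD panel\n" + "\n".join(_cad_panel_genes()) + "\n")
    write_ko_mapping(ko_rows, paths.ko_mapping)
    return paths


def _base_ko_rows() -> list[tuple[str, str, str, str]]:
    return [("", code, _KO_NAMES[code], _KO_PARENTS.get(code, ""))
            for code in sorted(_KO_NAMES)]


def write_curated_panel_cohort(out_dir: str | Path
                               ) -> tuple[CohortPaths, list[TrioPedigree]]:
    """Write the curated targeted-panel cohort (29 proband panel
    variants, CAD controls, non-transmitted parental variants)."""
    trios = make_curated_trios()
    samples = [s for t in trios for s in (t.father_id, t.mother_id, t.proband_id)]
    rows = (PANEL_PATHOGENIC_ROWS + PANEL_OTHER_ROWS + CAD_PROBAND_ROWS
            + NON_TRANSMITTED_ROWS)
    variants = [_variant(*r, samples=samples) for r in rows]
    return _write_common(Path(out_dir), trios, variants, _base_ko_rows()), trios


def write_curated_denovo_cohort(out_dir: str | Path
                                ) -> tuple[CohortPaths, list[TrioPedigree]]:
    """Write the curated exome-wide de novo cohort (17 de novo
    pathogenic / likely-pathogenic / VUS variants over 12 probands)."""
    trios = make_curated_trios()
    samples = [s for t in trios for s in (t.father_id, t.mother_id, t.proband_id)]
    variants = [
        _variant(case, gene, chrom, pos, ref, alt, vtype, "de_novo",
                 cadd, ppdiv, ppvar, curated, samples=samples)
        for case, gene, chrom, pos, ref, alt, vtype, cadd, ppdiv, ppvar, curated
        in DENOVO_ROWS]
    ko_rows = _base_ko_rows()
    for gene in sorted(KO_ASSIGNMENT):
        for code in KO_ASSIGNMENT[gene]:
            ko_rows.append((gene, code, _KO_NAMES[code],
                            _KO_PARENTS.get(code, "")))
    return _write_common(Path(out_dir), trios, variants, ko_rows), trios
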