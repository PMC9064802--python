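"""Trio inheritance classification, including the brute-force text oracle."""

import numpy as np
import pytest

from triowes import (AnnotatedVariant, EXOME_WIDE, FilterThresholds,
                     GenotypeObservation, TARGETED_PANEL, check_de_novo,
                     classify_cohort, classify_inheritance,
                     find_non_transmitted, read_pedigree, read_trio_vcf)
from triowes.cohort import TrioPedigree
from triowes.inheritance import (AB_LOW, PARENT_HAS_ALT, PARENT_MISSING,
                                 calls_to_frame)
from trio_oracle import classify_vcf_text

TRIO = TrioPedigree("f1", "kid", "mom", "dad", proband_sex="male",
                    proband_affected="epilepsy")


def trio_variant(chrom="1", proband=("het", 40, 18, 99),
                 mother=("hom_ref", 40, 0, 99),
                 father=("hom_ref", 40, 0, 99)):
    v = AnnotatedVariant(chrom=chrom, pos=5000, ref="A", alt="G",
                         gene="GENE1", variant_type="missense",
                         cadd_phred=30.0, pop_freq_1kg=0.0, pop_freq_evs=0.0,
                         splice_distance_bp=200)
    for sid, spec in (("kid", proband), ("mom", mother), ("dad", father)):
        gt, dp, alt, gq = spec
        v.genotypes[sid] = GenotypeObservation(sid, gt, dp, alt, gq)
    return v


class TestDeNovoEvidence:
    def test_all_thresholds_cleared(self, thresholds):
        ok, reasons = check_de_novo(trio_variant(), TRIO, thresholds, EXOME_WIDE)
        assert ok and reasons == ()

    def test_ab_mode_switch(self, thresholds):
        """Allelic balance 0.2 fails exome-wide (floor 0.25) but passes
        the targeted-panel mode (floor 0.1)."""
        v = trio_variant(proband=("het", 40, 8, 99))  # AB = 0.2
        ok_exome, reasons = check_de_novo(v, TRIO, thresholds, EXOME_WIDE)
        assert not ok_exome and reasons == (AB_LOW,)
        ok_targeted, _ = check_de_novo(v, TRIO, thresholds, TARGETED_PANEL)
        assert ok_targeted

    def test_parent_alternate_read_vetoes(self, thresholds):
        v = trio_variant(father=("hom_ref", 40, 1, 60))
        ok, reasons = check_de_novo(v, TRIO, thresholds, EXOME_WIDE)
        assert not ok and PARENT_HAS_ALT in reasons

    def test_parent_gq_is_inclusive_minimum(self, thresholds):
        v = trio_variant(mother=("hom_ref", 40, 0, 50))
        ok, _ = check_de_novo(v, TRIO, thresholds, EXOME_WIDE)
        assert ok  # "a minimum GQ of 50" admits exactly 50
        v = trio_variant(mother=("hom_ref", 40, 0, 49))
        ok, reasons = check_de_novo(v, TRIO, thresholds, EXOME_WIDE)
        assert not ok

    def test_missing_parent(self, thresholds):
        v = trio_variant(mother=("missing", 0, 0, 0))
        ok, reasons = check_de_novo(v, TRIO, thresholds, EXOME_WIDE)
        assert not ok and PARENT_MISSING in reasons


class TestClassification:
    def test_x_hemizygous_son_of_het_mother_is_maternal(self, thresholds):
        v = trio_variant(chrom="X", proband=("hemi_alt", 40, 39, 99),
                         mother=("het", 50, 25, 99),
                         father=("hemi_ref", 38, 0, 99))
        call = classify_inheritance(v, TRIO, thresholds, EXOME_WIDE)
        assert call.call == "transmitted_maternal"

    def test_clean_de_novo(self, thresholds):
        call = classify_inheritance(trio_variant(), TRIO, thresholds, EXOME_WIDE)
        assert call.call == "de_novo" and call.fail_reasons == ()

    def test_biparental(self, thresholds):
        v = trio_variant(mother=("het", 40, 20, 99), father=("het", 40, 20, 99))
        call = classify_inheritance(v, TRIO, thresholds, EXOME_WIDE)
        assert call.call == "transmitted_biparental"

    def test_failed_evidence_is_unresolved_not_discarded(self, thresholds):
        v = trio_variant(proband=("het", 8, 2, 99))
        call = classify_inheritance(v, TRIO, thresholds, EXOME_WIDE)
        assert call.call == "unresolved" and call.fail_reasons

    def test_mito_and_y_not_classified(self, thresholds):
        for chrom in ("Y", "MT"):
            v = trio_variant(chrom=chrom)
            call = classify_inheritance(v, TRIO, thresholds, EXOME_WIDE)
            assert call.call == "unresolved"

    def test_partition_one_call_per_carrier_pair(self, panel_cohort, thresholds):
        calls = classify_cohort(panel_cohort.variants, panel_cohort.pedigree,
                                thresholds, TARGETED_PANEL)
        pairs = [(c.variant_key, c.family_id) for c in calls]
        assert len(pairs) == len(set(pairs))
        for c in calls:
            assert c.call in {"de_novo", "transmitted_maternal",
                              "transmitted_paternal", "transmitted_biparental",
                              "unresolved"}

    def test_mode_monotonicity(self, thresholds):
        """Exome-wide de novo calls are a subset of targeted-panel calls."""
        rng = np.random.default_rng(11)
        cohort = []
        for i in range(40):
            dp = int(rng.integers(10, 80))
            alt = int(rng.integers(1, dp + 1))
            v = trio_variant(proband=("het", dp, alt, 99))
            v.pos = 5000 + i
            cohort.append(v)
        exome = {c.variant_key for c in classify_cohort(cohort, [TRIO],
                                                        thresholds, EXOME_WIDE)
                 if c.is_de_novo}
        targeted = {c.variant_key
                    for c in classify_cohort(cohort, [TRIO], thresholds,
                                             TARGETED_PANEL)
                    if c.is_de_novo}
        assert exome <= targeted


class TestNonTransmitted:
    def test_definition_case(self, thresholds):
        v = trio_variant(proband=("hom_ref", 40, 0, 99),
                         mother=("het", 50, 25, 99))
        v.variant_type = "nonsense"
        calls = find_non_transmitted([v], [TRIO], thresholds)
        assert [c.call for c in calls] == ["non_transmitted_maternal"]

    def test_transmitted_variant_excluded(self, thresholds):
        v = trio_variant(mother=("het", 50, 25, 99))  # proband het
        assert find_non_transmitted([v], [TRIO], thresholds) == []

    def test_disjoint_from_carrier_calls(self, panel_cohort, thresholds):
        nt = find_non_transmitted(panel_cohort.variants, panel_cohort.pedigree,
                                  thresholds)
        carrier = classify_cohort(panel_cohort.variants, panel_cohort.pedigree,
                                  thresholds, TARGETED_PANEL)
        nt_pairs = {(c.variant_key, c.family_id) for c in nt}
        carrier_pairs = {(c.variant_key, c.family_id) for c in carrier}
        assert nt_pairs.isdisjoint(carrier_pairs)

    def test_planted_count_recovered(self, tmp_path, thresholds):
        """The simulator's planted non-transmitted variants are found
        exactly (noise-free evidence)."""
        from triowes import SimulationConfig, simulate_cohort
        from triowes.cohort import read_annotations
        cfg = SimulationConfig(seed=5, n_case_trios=4, n_control_trios=4,
                               n_background_variants_per_trio=0,
                               denovo_rate_per_trio=0.0,
                               nontransmitted_rate=2.0,
                               p_panel_pathogenic_case=0.0,
                               p_panel_pathogenic_control=0.0,
                               noise_free=True)
        paths, truth, _ = simulate_cohort(cfg, tmp_path)
        ped = read_pedigree(paths.ped)
        variants = list(read_trio_vcf(paths.vcf, ped,
                                      read_annotations(paths.annotations)))
        nt = find_non_transmitted(variants, ped, thresholds)
        planted = truth[truth["planted_class"].str.startswith("non_transmitted")]
        assert len(nt) == len(planted)
        got = {(c.variant_key, c.family_id, c.call) for c in nt}
        want = {(r.variant_key, r.family_id, r.planted_class)
                for r in planted.itertuples()}
        assert got == want


GT_POOL = ["0/0", "0/1", "1/1", "./."]


def random_trio_vcf(rng: np.random.Generator, n_variants: int) -> str:
    """Random small trio VCF with evidence straddling every threshold."""
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">',
             '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">',
             '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">',
             '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="q">',
             "##contig=<ID=1>", "##contig=<ID=X>",
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tkid\tmom\tdad"]
    for i in range(n_variants):
        cells = []
        for _ in range(3):
            gt = GT_POOL[rng.integers(0, len(GT_POOL))]
            dp = int(rng.integers(0, 60))
            n_alt_alleles = gt.count("1")
            if gt == "./." or dp == 0:
                alt = 0
            elif n_alt_alleles == 0:
                alt = int(rng.integers(0, 3))  # stray alternate reads
            else:
                alt = int(rng.integers(0, dp + 1))
            alt = min(alt, dp)
            gq = int(rng.integers(0, 100))
            cells.append(f"{gt}:{dp}:{dp - alt},{alt}:{gq}")
        lines.append(f"1\t{1000 + i}\t.\tA\tG\t.\tPASS\t.\tGT:DP:AD:GQ\t"
                     + "\t".join(cells))
    return "\n".join(lines) + "\n"


@pytest.mark.parametrize("mode", [EXOME_WIDE, TARGETED_PANEL])
def test_against_brute_force_oracle(tmp_path, thresholds, mode):
    """Classification agrees with an independent text-level
    re-implementation on 1,000 random small cohorts."""
    rng = np.random.default_rng(202_409)
    trio = TRIO
    n_cohorts = 500  # x2 parametrized modes = 1,000 random cohorts
    for i in range(n_cohorts):
        text = random_trio_vcf(rng, n_variants=4)
        vcf = tmp_path / f"c{mode.name}.vcf"
        vcf.write_text(text)
        variants = list(read_trio_vcf(vcf, [trio]))
        ours = {}
        for v in variants:
            if v.genotype_of("kid").is_carrier:
                c = classify_inheritance(v, trio, thresholds, mode)
                ours[c.variant_key] = c.call
        theirs = classify_vcf_text(text, "kid", "mom", "dad",
                                   ab_threshold=mode.ab_threshold)
        assert ours == theirs, f"cohort {i} disagrees"


def test_calls_frame_columns(panel_cohort, thresholds):
    calls = classify_cohort(panel_cohort.variants, panel_cohort.pedigree,
                            thresholds, TARGETED_PANEL)
    frame = calls_to_frame(calls)
    assert {"variant_key", "family_id", "call", "proband_ab"} <= set(frame.columns)
    assert len(frame) == len(calls)
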