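import pytest

from triowes import (FilterThresholds, load_panel, read_annotations,
                     read_pedigree, read_trio_vcf)
from triowes.curated import write_curated_denovo_cohort, write_curated_panel_cohort


class LoadedCohort:
    """Materialized cohort: files, pedigree, variants and panels."""

    def __init__(self, paths, trios):
        self.paths = paths
        self.pedigree = read_pedigree(paths.ped)
        ann = read_annotations(paths.annotations)
        self.variants = list(read_trio_vcf(paths.vcf, self.pedigree, ann))
        self.epilepsy_panel = load_panel(paths.epilepsy_panel, "epilepsy")
        self.cad_panel = load_panel(paths.cad_panel, "cad")


@pytest.fixture(scope="session")
def panel_cohort(tmp_path_factory) -> LoadedCohort:
    """Curated 20-trio targeted-panel cohort (29 proband panel variants)."""
    out = tmp_path_factory.mktemp("panel_cohort")
    paths, trios = write_curated_panel_cohort(out)
    return LoadedCohort(paths, trios)


@pytest.fixture(scope="session")
def denovo_cohort(tmp_path_factory) -> LoadedCohort:
    """Curated 20-trio exome-wide de novo cohort (17 de novo variants)."""
    out = tmp_path_factory.mktemp("denovo_cohort")
    paths, trios = write_curated_denovo_cohort(out)
    return LoadedCohort(paths, trios)


@pytest.fixture()
def thresholds() -> FilterThresholds:
    return FilterThresholds()
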