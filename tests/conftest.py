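import pytest

from haystack import CohortSimConfig, simulate_prioritization_cohort
from haystack.io import load_annotated_cohort, load_expression_table


class LoadedCohort:
    """A small synthetic cohort plus everything the cascade consumes."""

    def __init__(self, cfg, paths, truth, cases, controls, profiles):
        self.cfg = cfg
        self.paths = paths
        self.truth = truth
        self.cases = cases
        self.controls = controls
        self.profiles = profiles


def build_cohort(cfg, out_dir) -> LoadedCohort:
    paths, truth = simulate_prioritization_cohort(cfg, out_dir)
    cases = load_annotated_cohort(paths.case_vcf, paths.annotations, paths.frequencies)
    controls = load_annotated_cohort(paths.control_vcf, paths.annotations, paths.frequencies)
    profiles = load_expression_table(paths.expression)
    return LoadedCohort(cfg, paths, truth, cases, controls, profiles)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory) -> LoadedCohort:
    cfg = CohortSimConfig(seed=11, n_cases=16, n_controls=8, n_genes=30, n_planted=4)
    return build_cohort(cfg, tmp_path_factory.mktemp("cohort"))
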