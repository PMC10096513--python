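"""Shared fixtures: synthetic study cohorts run through the full pipeline."""

import biacomp as bc
import pytest


def build_feature_table(seed=0, **overrides):
    """Synthetic cohort -> assays -> dilution -> filter -> feature table."""
    cfg = bc.default_config(seed=seed, **overrides)
    cohort = bc.generate_cohort(cfg)
    assays = bc.generate_dilution_assays(cohort, cfg)
    results = bc.process_assays(assays, bc.participants_frame(cohort))
    kept, _ = bc.plausibility_filter(results)
    return bc.assemble_feature_table(
        bc.participants_frame(cohort), bc.bia_frame(cohort),
        kept[["id", "tbw_kg", "tbw_pct"]])


@pytest.fixture(scope="session")
def study_table():
    """Feature table at the study conditions (86 boys + 92 girls, seed 0)."""
    return build_feature_table(seed=0)


@pytest.fixture(scope="session")
def study_cohort():
    """(config, cohort) pair at the study conditions."""
    cfg = bc.default_config(seed=0)
    return cfg, bc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_table():
    """A small cohort for cheap cross-validation exercises."""
    return build_feature_table(seed=11, n_boys=50, n_girls=50)
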