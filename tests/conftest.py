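import numpy as np
import pytest

import sibscore as sb


@pytest.fixture(scope="session")
def panel10() -> sb.SNPPanel:
    return sb.load_default_panel()


@pytest.fixture(scope="session")
def panel1() -> sb.SNPPanel:
    return sb.SNPPanel([sb.SNPDef("rs1", "GENE1", "A", "G", 0.3)])


@pytest.fixture(scope="session")
def panel2() -> sb.SNPPanel:
    return sb.SNPPanel(
        [
            sb.SNPDef("rs1", "GENE1", "A", "G", 0.3),
            sb.SNPDef("rs2", "GENE2", "C", "T", 0.6),
        ]
    )


def make_trio(panel, father_counts, mother_counts, child_counts, child_sex="male",
              child_affection="affected", family_id="F1"):
    """One nuclear family from bare risk-allele count vectors."""
    father = sb.Individual(family_id, f"{family_id}_1", "0", "0", "male", "unknown",
                           np.asarray(father_counts, dtype=np.int8))
    mother = sb.Individual(family_id, f"{family_id}_2", "0", "0", "female", "unknown",
                           np.asarray(mother_counts, dtype=np.int8))
    child = sb.Individual(family_id, f"{family_id}_3", father.individual_id,
                          mother.individual_id, child_sex, child_affection,
                          np.asarray(child_counts, dtype=np.int8))
    return sb.Family(family_id, father, mother, [child])


@pytest.fixture
def trio_factory():
    return make_trio


@pytest.fixture(scope="session")
def fixture_cohort(panel10) -> sb.Cohort:
    """Exploratory-style cohort simulated under the default effect sizes
    (shared 1.25, male-specific 1.3, female-specific 2.3)."""
    gm, gf = sb.fixture_grrs(panel10)
    cfg = sb.SimulationConfig(
        n_families=480, panel=panel10, grr_male=gm, grr_female=gf, seed=20211021
    )
    cohort, _ = sb.simulate_cohort(cfg)
    return cohort
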