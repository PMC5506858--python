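import numpy as np
import pytest

from mengen.formats import JunctionRecord, MutationRecord, SampleMeta
from mengen.scna import ArmDefinition
from mengen.simdata import SimConfig, simulate_cohort


def make_mutation(**kw):
    base = dict(
        sample_id="S1",
        patient_id="P1",
        gene="GENE1",
        chrom="1",
        pos=1000,
        ref="C",
        alt="T",
        classification="missense",
        t_alt_count=10,
        t_depth=40,
    )
    base.update(kw)
    return MutationRecord(**base)


def make_junction(**kw):
    base = dict(
        sample_id="S1",
        chromA="1", posA=1_000_000, strandA="+",
        chromB="1", posB=2_000_000, strandB="-",
        sv_class="deletion",
        homology_len=0, insertion_len=0,
    )
    base.update(kw)
    return JunctionRecord(**base)


def make_meta(**kw):
    base = dict(
        sample_id="S1", patient_id="P1", resection_index=1, grade="II",
        histology="atypical", radiation_status="naive", purity=0.9,
        ploidy=2.0, mean_coverage=100.0,
    )
    base.update(kw)
    return SampleMeta(**base)


@pytest.fixture(scope="session")
def toy_arms():
    """Two-chromosome toy arm table for arm-calling tests."""
    return [
        ArmDefinition("1", "p", 1, 1000),
        ArmDefinition("1", "q", 1001, 3000),
        ArmDefinition("22", "p", 1, 500),
        ArmDefinition("22", "q", 501, 2000),
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """20-patient, 2-sample cohort at default study conditions."""
    return simulate_cohort(SimConfig(n_patients=20, samples_per_patient=2,
                                     clones_per_patient=2, seed=101))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
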