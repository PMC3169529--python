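import numpy as np
import pandas as pd
import pytest

from twinmqtl import simulate
from twinmqtl.design import CohortDesign, VCParams


@pytest.fixture(scope="session")
def small_cohort():
    """20 MZ + 10 DZ pairs + 2 singletons, 2 visits, 2 aliquots."""
    design = CohortDesign(20, 10, 2, visits_per_pair=2,
                          aliquots_per_sample=2, plates=3)
    return simulate.simulate_cohort(design, seed=11)


@pytest.fixture(scope="session")
def small_genotypes(small_cohort):
    return simulate.simulate_genotypes(small_cohort, 60, maf=0.3, seed=12)


@pytest.fixture(scope="session")
def vc_truth():
    """Variance components at biological proportions
    (SNP 0.40, familial 0.30, indiv-env 0.10, indiv-visit 0.15,
    common-visit 0.05) with experimental variance at 20% of total."""
    var_g = 2 * 0.3 * 0.7
    return VCParams(
        beta_g=np.sqrt(0.40 / var_g),
        sigma_f=np.sqrt(0.30), sigma_e=np.sqrt(0.10),
        sigma_vc=np.sqrt(0.05), sigma_vi=np.sqrt(0.15),
        sigma_eps=np.sqrt(0.25),
    )
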