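"""Published design constants and summary tables of the twin mQTL study
this package re-implements.

These are *inputs* — the study's sampling design, genotyping panel sizes,
and published variance-decomposition summaries — used to parameterize the
synthetic cohort, to size multiple-testing corrections, and as the reference
rows for cross-study familial-share arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# cohort composition (discovery twin cohort, after quality control)
N_PARTICIPANTS = 142
N_MZ_PAIRS = 51
N_DZ_PAIRS = 19
N_SINGLETONS = 2
N_MZ_PAIRS_TWO_VISITS = 33
ALIQUOTS_PER_SAMPLE = 2
VISIT_TIMES = (10.0, 14.0)

# genotyping panel
N_TYPED_SNPS = 296_017
N_IMPUTED_SNPS = 2_245_627
IMPUTATION_SCORE_MIN = 0.4
HWE_ALPHA = 1e-4

# spectral preprocessing
N_EXTRACTED_PEAKS = 526
PRESENCE_THRESHOLD = 0.80
TSP_PPM = 0.0        # urine chemical-shift reference
FORMATE_PPM = 8.452  # plasma chemical-shift reference

# scan and replication
N_PERMUTATIONS = 5000
N_NMR_REPLICATION_TESTS = 4
N_BIOCRATES_REPLICATION_TESTS = 15
REPLICATION_ALPHA = 0.05


def total_snps() -> int:
    """Size of the association panel: typed plus imputed SNPs."""
    return N_TYPED_SNPS + N_IMPUTED_SNPS


def decomposition_table() -> pd.DataFrame:
    """Published per-trait biological-variance decompositions (posterior
    mean percentages with 95% interval bounds for the SNP and familial
    components), NMR traits first, then the Biocrates replication traits.
    ``replicated`` flags traits whose mQTL replicated in either study."""
    with resources.files("twinmqtl.data").joinpath(
            "decomposition_table.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["replicated"] = df["replicated"].astype(bool)
    return df.set_index("trait")


def replicated_biocrates_rows() -> pd.DataFrame:
    """The replicated Biocrates traits used for familial-share summaries."""
    df = decomposition_table()
    return df[(df["platform"] == "Biocrates") & df["replicated"]]
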