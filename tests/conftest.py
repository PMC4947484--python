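import numpy as np
import pandas as pd
import pytest

from deltag import simulate as simu
from deltag.agreement import ConfusionMatrix

#: Published training-set cross-tabulation of experimental (rows) vs
#: imputed (columns) deletion genotypes: 291/309 concordant.
TRAINING_CONFUSION = np.array(
    [
        [119, 2, 0],
        [10, 127, 3],
        [0, 3, 45],
    ]
)


@pytest.fixture
def training_cm() -> ConfusionMatrix:
    return ConfusionMatrix(TRAINING_CONFUSION.copy())


@pytest.fixture(scope="session")
def sim_cohort_2000() -> simu.SimulatedCohort:
    """Default-condition cohort: deletion at freq 0.362, three planted tags
    (r^2 ~ 0.94/0.89/0.89), 100 unlinked noise SNPs, n=2000."""
    return simu.simulate_cohort(simu.SimulationConfig(n_samples=2000, seed=simu.DEFAULT_SEED))


@pytest.fixture
def small_vcf(tmp_path):
    """Hand-written 10-record VCF over 3 samples, including records the
    reader must skip (multi-allelic, indel) and missing/half calls."""
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr12>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC",
        "chr12\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t./.",
        "chr12\t200\trs2\tC\tT\t.\t.\t.\tGT\t1|1\t0|1\t0/0",
        "chr12\t300\trs3\tG\tA\t.\t.\t.\tGT\t0/1\t1/1\t0/1",
        "chr12\t400\trs4\tT\tC,G\t.\t.\t.\tGT\t0/1\t0/2\t0/0",  # multi-allelic: skip
        "chr12\t500\trs5\tAT\tA\t.\t.\t.\tGT\t0/1\t0/0\t0/0",  # indel: skip
        "chr12\t600\trs6\tG\tC\t.\t.\t.\tGT\t./1\t0/0\t1/1",  # half call -> missing
        "chr12\t700\trs7\tA\tT\t.\t.\t.\tGT\t0/0\t0/0\t0/1",
        "chr12\t800\trs8\tC\tG\t.\t.\t.\tGT\t1/1\t1/1\t1/1",
        "chr12\t900\trs9\tT\tA\t.\t.\t.\tGT\t0/1\t0/1\t0/1",
        "chr12\t1000\trs10\tG\tT\t.\t.\t.\tGT\t0/0\t1/1\t0/1",
    ]
    path = tmp_path / "small.vcf"
    path.write_text("\n".join(lines) + "\n")
    return path


def genotype_series(mapping: dict[str, float]) -> pd.Series:
    return pd.Series(mapping, name="dosage", dtype=float).rename_axis("sample_id")
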