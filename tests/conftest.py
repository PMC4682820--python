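import numpy as np
import pandas as pd
import pytest

from renalage import ExpressionMatrix, Peak, PeakSet, TSSRecord


@pytest.fixture
def tiny_tss():
    return [
        TSSRecord("G1", "chr1", "+", 10_000),
        TSSRecord("G2", "chr1", "-", 40_000),
        TSSRecord("G3", "chr2", "+", 10_000),
    ]


def make_peak(chrom="chr1", start=100, end=300, summit=None, sig=6.0,
              tf="TFA", cell_line="CL1", experiment_id="TFA_CL1"):
    if summit is None:
        summit = (start + end) // 2
    return Peak(chrom, start, end, summit, sig, tf, cell_line, experiment_id)


@pytest.fixture
def make_peakset():
    def _make(intervals, tf="TFA", cell_line="CL1", chrom="chr1", sig=6.0):
        exp = f"{tf}_{cell_line}"
        peaks = [
            Peak(chrom, s, e, (s + e) // 2, sig, tf, cell_line, exp)
            for s, e in intervals
        ]
        return PeakSet(peaks)

    return _make


@pytest.fixture
def small_expr():
    """4 genes x 6 samples with a clean age trend in the first gene."""
    rng = np.random.default_rng(7)
    samples = [f"S{i}" for i in range(1, 7)]
    ages = pd.Series([30.0, 40, 50, 60, 70, 80], index=samples)
    values = pd.DataFrame(
        rng.normal(8, 0.3, size=(4, 6)),
        index=["A", "B", "C", "D"],
        columns=samples,
    )
    values.loc["A"] = 5 + 0.05 * ages.to_numpy()
    return ExpressionMatrix(values=values, age=ages)
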