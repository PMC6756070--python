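import numpy as np
import pandas as pd
import pytest

from incis.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic cohort shared across cohort-level tests."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A small cohort for fast pipeline-level tests."""
    return simulate_cohort(
        SimConfig(seed=7, n_samples=60, n_genes=400, amp_width_genes=(2, 8),
                  program_size=40, stromal_program_size=30)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_segments(rows, sample="S1"):
    """Relative-segment frame from (chrom, start, end, value) tuples."""
    return pd.DataFrame(
        [{"sample": sample, "chrom": c, "start": s, "end": e, "value": v}
         for c, s, e, v in rows]
    )


def make_allelic(rows, sample="S1"):
    """Allelic-segment frame from (chrom, start, end, nA, nB) tuples."""
    return pd.DataFrame(
        [{"sample": sample, "chrom": c, "start": s, "end": e, "nA": a, "nB": b}
         for c, s, e, a, b in rows]
    )


def make_genes(rows):
    """Gene annotation frame from (gene_id, chrom, start, end[, arm]) tuples."""
    out = []
    for r in rows:
        gene_id, chrom, start, end = r[:4]
        arm = r[4] if len(r) > 4 else f"{chrom}q"
        out.append({"gene_id": gene_id, "symbol": gene_id, "chrom": chrom,
                    "start": start, "end": end, "arm": arm})
    return pd.DataFrame(out)
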