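import numpy as np
import pandas as pd
import pytest

from delfi.fragments import FragmentSet, GenomeResource
from delfi.synthetic_data import SimulationConfig, make_toy_genome, simulate_panel


def make_fragment_set(records, sample_id="s1", **flags) -> FragmentSet:
    """Build a FragmentSet from (chrom, start, end[, mapq[, gc]]) tuples."""
    rows = []
    for rec in records:
        chrom, start, end = rec[:3]
        mapq = rec[3] if len(rec) > 3 else np.nan
        gc = rec[4] if len(rec) > 4 else np.nan
        rows.append({"chrom": chrom, "start": start, "end": end, "mapq": mapq, "gc": gc})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "mapq", "gc"])
    if not rows:
        df = df.astype({"start": np.int64, "end": np.int64})
    return FragmentSet(sample_id=sample_id, records=df, **flags)


@pytest.fixture(scope="session")
def toy_genome():
    """Small deterministic genome: 2 chromosomes x 1 Mb, 50 kb bins."""
    return make_toy_genome(n_chrom=2, chrom_length=1_000_000, bin_size=50_000, seed=11)


@pytest.fixture(scope="session")
def medium_genome():
    """Cohort-scale toy genome: 2 chromosomes x 5 Mb, 50 kb bins."""
    return make_toy_genome(n_chrom=2, chrom_length=5_000_000, bin_size=50_000, seed=5)


@pytest.fixture(scope="session")
def small_panel(toy_genome):
    """Tumor-free reference panel on the small genome."""
    genome, _, _ = toy_genome
    return simulate_panel(genome, SimulationConfig(depth=30_000), n=12, seed=202)


@pytest.fixture
def flat_genome():
    """50% GC everywhere, no blacklist; handy for exact arithmetic."""
    seq = "GCAT" * 2500  # 10 kb, GC = 0.5
    return GenomeResource.from_sequences({"chrA": seq, "chrB": seq})
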