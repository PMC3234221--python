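import pandas as pd
import pytest

import noncpg as n
from noncpg.calling import SampleTable


def make_table(sample_id, rows):
    """Build a SampleTable from (chrom, pos0, strand, context, meth, total) rows."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos0", "strand", "context", "meth_count", "total_count"]
    )
    df["level"] = df["meth_count"] / df["total_count"]
    return SampleTable(sample_id=sample_id, df=df)


@pytest.fixture(scope="session")
def table_factory():
    return make_table


@pytest.fixture(scope="session")
def cohort():
    """A 20 kb genome with 5 simulated pluripotent-like samples at 25x."""
    g = n.generate_genome(20000, gc_background=0.4, n_islands=3, island_len=400,
                          msp1_spacing=140, seed=1)
    frags = n.size_select(n.digest_genome(g))
    truth = n.assign_methylation(g, seed=2)
    samples = [
        n.call(n.simulate_reads(g, truth, frags, mean_coverage=25, seed=10 + i),
               g, f"S{i}")
        for i in range(5)
    ]
    return {"genome": g, "fragments": frags, "truth": truth, "samples": samples}
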