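import numpy as np
import pandas as pd
import pytest

from tner.contexts import BASES, Panel


def make_pileup(panel: Panel, depth: int = 10000, alt_counts: dict | None = None) -> pd.DataFrame:
    """Pileup covering ``panel`` with all reads on the reference allele.

    ``alt_counts`` maps (chrom, pos, alt) -> count to move reads from the
    reference onto an alternate allele.
    """
    df = panel.positions[["chrom", "pos", "ref"]].copy()
    df["depth"] = depth
    for b in BASES:
        df[b] = 0
    for i, (ref) in enumerate(df["ref"]):
        if ref in BASES:
            df.iloc[i, df.columns.get_loc(ref)] = depth
    if alt_counts:
        df = df.set_index(["chrom", "pos"])
        for (chrom, pos, alt), count in alt_counts.items():
            ref = df.at[(chrom, pos), "ref"]
            df.at[(chrom, pos), alt] += count
            df.at[(chrom, pos), ref] -= count
        df = df.reset_index()
    return df


@pytest.fixture
def tiny_panel() -> Panel:
    # 12 target bases on one contig, flanked so none sit at a contig edge
    return Panel.from_sequences({"chr1": "GACGTACGTTCAGA"}, [("chr1", 1, 13)])


@pytest.fixture
def pileup_factory():
    return make_pileup
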