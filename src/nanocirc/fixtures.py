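"""Packaged reference tables.

Two tables transcribed from the published catalog of BCL2L12 circRNAs in
colorectal cancer cell lines: per-sample expression presence of the 46
circRNAs, and the 40 distinct back-splice junctions with genomic
coordinates (1-based inclusive, GRCh38 chr19), the donor/acceptor
dinucleotides and the flank-similarity motif (>= 4 nt; R = purine,
Y = pyrimidine) where one was observed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath("fixtures", name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def table1_presence() -> pd.DataFrame:
    """Expression presence ('+'/'-') of 46 circRNAs across 7 CRC cell lines."""
    return _load("table1_presence.tsv")


def table2_bsj() -> pd.DataFrame:
    """The 40 distinct BSJs: members, coordinates, site dinucleotides,
    similarity motifs."""
    df = _load("table2_bsj.tsv")
    df["similarity"] = df["similarity"].where(df["similarity"].notna(), None)
    return df
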