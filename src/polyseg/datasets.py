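"""Bundled per-locus count data from the two bermudagrass S1 study
populations, shipped so the whole analysis runs offline.

Three small tab-separated tables:

* ``zebra_s1_counts.tsv`` — 21 two-band SSR loci scored in 228 selfed
  progenies of 'Zebra' (classes AA/Aa/aa plus a separate missing tally),
  with the archived chi-square and P columns for the disomic (1:2:1) and
  tetrasomic (1:34:1) hypotheses.
* ``a12359_s1_counts.tsv`` — 12 SSR loci (13 rows: the four-band marker
  CDAAC7-2693/2694 appears as its two decomposed subgenome loci) scored in
  273 selfed progenies of A12359.
* ``cdaac7_four_band_phenotypes.tsv`` — the joint band-phenotype counts of
  the four-band marker in 272 scored A12359 progenies, with the archived
  expected counts under a one-locus tetrasomic ABCD parent (one-decimal
  rounding) and under two independent disomic loci AB & CD.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import LocusCounts

__all__ = [
    "load_counts",
    "load_zebra_counts",
    "load_a12359_counts",
    "load_four_band_phenotypes",
]

_CLASSES = ("AA", "Aa", "aa")


def _read(name: str) -> pd.DataFrame:
    with resources.files("polyseg.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_counts(name: str) -> tuple[list[LocusCounts], pd.DataFrame]:
    """Return (LocusCounts list, full archived DataFrame) for a bundled
    two-band count table."""
    df = _read(name)
    counts = [
        LocusCounts(
            marker=row["marker"],
            classes=_CLASSES,
            observed=(int(row["AA"]), int(row["Aa"]), int(row["aa"])),
            missing=int(row["missing"]),
        )
        for _, row in df.iterrows()
    ]
    return counts, df


def load_zebra_counts() -> tuple[list[LocusCounts], pd.DataFrame]:
    return load_counts("zebra_s1_counts.tsv")


def load_a12359_counts() -> tuple[list[LocusCounts], pd.DataFrame]:
    return load_counts("a12359_s1_counts.tsv")


def load_four_band_phenotypes() -> pd.DataFrame:
    """Joint phenotype counts of the four-band marker (n = 272 scored)."""
    return _read("cdaac7_four_band_phenotypes.tsv")
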