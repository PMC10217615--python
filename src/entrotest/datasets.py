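"""Packaged example data.

The shipped table records, for three waves of a social survey, the counts of
five ordered levels of agreement with the assertion that religious people are
often too intolerant.  It is the worked example for the two-sample entropy
tests, including the cross-k comparison after collapsing the 1998 wave to
three categories (agreement / indifference / disagreement).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .counts import CountTable, collapse_categories

__all__ = ["load_gss", "load_gss_frame", "GSS_COLLAPSE_BLOCKS", "gss_collapsed_1998"]

#: Ordered contiguous blocks collapsing the five agreement levels into
#: agreement (strongly agree + agree), indifference, disagreement
#: (disagree + strong disagree).
GSS_COLLAPSE_BLOCKS = ((0, 1), (2,), (3, 4))

_YEARS = ("1998", "2008", "2018")


def load_gss_frame() -> pd.DataFrame:
    """The raw survey table as a DataFrame (label + one column per year)."""
    with resources.files(__package__).joinpath(
        "data/gss_religious_intolerance.csv"
    ).open() as fh:
        return pd.read_csv(fh, dtype={"label": str})


def load_gss() -> dict[str, CountTable]:
    """One ordered :class:`CountTable` per survey year ('1998', '2008', '2018')."""
    df = load_gss_frame()
    labels = df["label"].tolist()
    return {
        year: CountTable(df[year].to_numpy(), labels=labels) for year in _YEARS
    }


def gss_collapsed_1998() -> CountTable:
    """The 1998 wave collapsed to three categories (k=3 worked example)."""
    return collapse_categories(load_gss()["1998"], GSS_COLLAPSE_BLOCKS)
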