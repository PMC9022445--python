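"""Published per-species vocalization totals from the Hubbard Brook / Jeffers
Brook dawn-chorus study (2016: 200 recordings; 2018: 210 recordings).

The table ships with the package so that headline community statistics (e.g.
dominance shares) can be recomputed without the deposited audio.  Mammal rows
(red squirrel, Eastern chipmunk) were only enumerated in 2018 and carry no
2016 total.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .ingest import CountMatrix

_FILENAME = "hubbard_brook_vocalization_totals.csv"


def load_totals() -> pd.DataFrame:
    """The published species totals: common_name, code, taxon_class, per-year totals."""
    with resources.files("pamkit.data").joinpath(_FILENAME).open() as fh:
        return pd.read_csv(fh)


def totals_as_count_matrix(year: int) -> CountMatrix:
    """One-row count matrix of a year's aggregate totals, for summary statistics."""
    df = load_totals()
    col = f"total_{year}"
    if col not in df.columns:
        raise KeyError(f"no published totals for year {year}")
    sub = df.dropna(subset=[col])
    counts = pd.DataFrame(
        [sub[col].astype(int).to_numpy()],
        index=[f"aggregate_{year}"],
        columns=sub["code"].tolist(),
    )
    taxa = dict(zip(sub["code"], sub["taxon_class"]))
    return CountMatrix(counts, taxa)
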