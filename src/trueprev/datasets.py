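"""Bundled example datasets.

``dementia_9``
    The nine European dementia prevalence studies (DSM-IV diagnoses,
    participants aged over 65) from a published systematic review,
    with study labels, countries and survey years as metadata; totals
    are 18263 participants of whom 2137 were diagnosed.

``toy_24pct`` / ``toy_5pct``
    Single-population toy surveys of 500 subjects with 120 and 25
    positives (24% and 5% apparent prevalence), a standard worked
    example for misclassification-adjusted prevalence estimation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .data import ClusterTable, SurveyCounts

__all__ = ["load_fixture", "FIXTURES"]

FIXTURES = ("dementia_9", "toy_24pct", "toy_5pct")


def _dementia() -> ClusterTable:
    with resources.files("trueprev").joinpath("data_files/dementia_eu9.csv").open() as fh:
        df = pd.read_csv(fh)
    return ClusterTable(
        labels=tuple(df["study"]),
        y=df["positive"].to_numpy(),
        n=df["n"].to_numpy(),
        metadata=df[["id", "country", "years"]],
    )


def load_fixture(name: str) -> SurveyCounts | ClusterTable:
    """Return a bundled dataset by name (see module docstring)."""
    if name == "dementia_9":
        return _dementia()
    if name == "toy_24pct":
        return SurveyCounts(y=120, n=500)
    if name == "toy_5pct":
        return SurveyCounts(y=25, n=500)
    raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
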