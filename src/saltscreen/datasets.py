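"""Packaged reference fixtures: the published per-genotype screening results.

Two small tables transcribed from the published screen of 74 rice
genotypes ship with the package:

* :func:`load_tssri_table` — each genotype's total salt stress response
  index (TSSRI) together with the tolerance column it was printed under.
* :func:`load_pca_scores` — each genotype's first two principal-component
  scores and printed tolerance group.

Caveats carried over from the source tables (and flagged here rather
than silently fixed): the TSSRI table prints IR78221 (26.75) in the
sensitive column although 26.75 exceeds the printed sensitive ceiling of
26.54, and FED 2000 (32.16) in the moderate column although it exceeds
the printed moderate ceiling of 32.10 — strict application of the
printed band edges reclassifies both (7 sensitive, 27 low).  A few
genotype labels repeat (IR86174 appears three times in each table);
labels are kept exactly as printed, so treat rows positionally rather
than as a unique key.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Printed band edges of the TSSRI classification (sensitive/low/moderate
#: ceilings; the high class is unbounded above).
PRINTED_BOUNDARIES = {"b1": 26.54, "b2": 29.32, "b3": 32.10, "nominal_top": 34.88}


def _read(name: str) -> pd.DataFrame:
    with resources.files("saltscreen.data").joinpath(name).open("rt", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_tssri_table() -> pd.DataFrame:
    """The 74 published TSSRI values (columns: genotype, tssri, printed_class)."""
    return _read("reference_screen_tssri.csv")


def load_pca_scores() -> pd.DataFrame:
    """The 74 published PC1/PC2 scores (columns: genotype, pc1, pc2, printed_class)."""
    return _read("reference_screen_pca.csv")
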