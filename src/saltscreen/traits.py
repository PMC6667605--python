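"""Long-format trait tables: validation, I/O and replicate aggregation.

The canonical input is a tidy CSV with one measured value per row and the
five columns ``genotype, treatment, replicate, trait, value``.  Treatment
labels follow the three salinity levels of the screening design —
control (EC 0), moderate (EC 6 dS/m) and high (EC 12 dS/m) — and the
common shorthand labels (``C``/``MSS``/``HSS`` or the EC numbers) are
normalised on read.  A wide-format convenience reader (one column per
trait) normalises to the same long form.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import TraitRegistry, default_registry

TREATMENTS = ("control", "moderate", "high")

#: Accepted spellings for each treatment level (case-insensitive).
TREATMENT_ALIASES = {
    "control": "control", "c": "control", "0": "control",
    "moderate": "moderate", "mss": "moderate", "6": "moderate",
    "high": "high", "hss": "high", "12": "high",
}

REQUIRED_COLUMNS = ("genotype", "treatment", "replicate", "trait", "value")


class TraitTableError(ValueError):
    """Raised when a trait table fails validation; carries per-row messages."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        preview = "\n  ".join(problems[:20])
        more = f"\n  ... and {len(problems) - 20} more" if len(problems) > 20 else ""
        super().__init__(f"invalid trait table ({len(problems)} problem(s)):\n  {preview}{more}")


def normalize_treatment(label) -> str | None:
    """Map a raw treatment label onto the 3-level enum, or None if unknown."""
    return TREATMENT_ALIASES.get(str(label).strip().lower())


def _validate(df: pd.DataFrame, registry: TraitRegistry) -> pd.DataFrame:
    problems: list[str] = []
    out = df.copy()

    out["genotype"] = out["genotype"].astype(str).str.strip()
    out["trait"] = out["trait"].astype(str).str.strip()

    norm = out["treatment"].map(normalize_treatment)
    for i in out.index[norm.isna()]:
        problems.append(
            f"row {i + 2}: unknown treatment {df.at[i, 'treatment']!r}; "
            f"allowed labels normalise to {TREATMENTS}"
        )
    out["treatment"] = norm

    rep = pd.to_numeric(out["replicate"], errors="coerce")
    bad_rep = rep.isna() | (rep != rep.round()) | (rep < 1)
    for i in out.index[bad_rep]:
        problems.append(f"row {i + 2}: replicate {df.at[i, 'replicate']!r} is not a positive integer")
    out["replicate"] = rep

    val = pd.to_numeric(out["value"], errors="coerce")
    for i in out.index[val.isna() | ~np.isfinite(val.fillna(np.inf))]:
        problems.append(f"row {i + 2}: non-numeric or non-finite value {df.at[i, 'value']!r}")
    neg = val < 0
    for i in out.index[neg.fillna(False)]:
        problems.append(f"row {i + 2}: negative value {df.at[i, 'value']!r} for size/count trait")
    out["value"] = val

    known = set(registry.codes)
    for i in out.index[~out["trait"].isin(known)]:
        problems.append(f"row {i + 2}: unknown trait code {df.at[i, 'trait']!r}")

    dup = out.duplicated(subset=["genotype", "treatment", "replicate", "trait"], keep=False)
    # report every row of each duplicated cell except the first occurrence
    first = out.duplicated(subset=["genotype", "treatment", "replicate", "trait"], keep="first")
    for i in out.index[dup & first & out["treatment"].notna()]:
        key = tuple(out.loc[i, ["genotype", "treatment", "replicate", "trait"]])
        problems.append(f"row {i + 2}: duplicate cell (genotype={key[0]!r}, treatment={key[1]!r}, "
                        f"replicate={key[2]:g}, trait={key[3]!r})")

    if problems:
        raise TraitTableError(problems)

    out["replicate"] = out["replicate"].astype(int)
    out["value"] = out["value"].astype(float)
    return out[list(REQUIRED_COLUMNS)]


def read_trait_table(source, registry: TraitRegistry | None = None) -> pd.DataFrame:
    """Read and validate a long-format trait CSV.

    Parameters
    ----------
    source
        Path or open text stream of an RFC-4180 CSV whose header names the
        columns ``genotype, treatment, replicate, trait, value``
        (case-insensitive, any order).
    registry
        Trait registry used to validate trait codes (default: the
        24-trait screening registry).

    Returns
    -------
    pandas.DataFrame
        Validated table with normalised treatment labels, original row
        order preserved.

    Raises
    ------
    TraitTableError
        Listing every offending row (unknown trait/treatment, non-numeric
        value, duplicate cell), with 1-based file line numbers.
    """
    registry = registry or default_registry()
    df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TraitTableError([f"missing required column(s): {missing}"])
    return _validate(df, registry)


def read_wide_table(source, registry: TraitRegistry | None = None) -> pd.DataFrame:
    """Read a wide CSV (columns: genotype, treatment, replicate, then one
    column per trait code) and normalise it to the canonical long form.
    Empty cells become missing (row omitted), not zero.
    """
    registry = registry or default_registry()
    df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    lower = {c.lower(): c for c in df.columns}
    id_cols = [lower.get(c) for c in ("genotype", "treatment", "replicate")]
    if any(c is None for c in id_cols):
        raise TraitTableError(["wide table must have genotype, treatment and replicate columns"])
    trait_cols = [c for c in df.columns if c not in id_cols]
    long = df.melt(id_vars=id_cols, value_vars=trait_cols,
                   var_name="trait", value_name="value")
    long.columns = ["genotype", "treatment", "replicate", "trait", "value"]
    long = long.dropna(subset=["value"]).reset_index(drop=True)
    return _validate(long, registry)


def write_trait_table(table: pd.DataFrame, target) -> None:
    """Write a long-format trait table as CSV (round-trips under
    :func:`read_trait_table`)."""
    table.to_csv(target, index=False)


@dataclass
class GenotypeMeans:
    """Replicate-averaged trait values per (genotype, treatment, trait).

    ``means`` has a (genotype, treatment, trait) MultiIndex and columns
    ``mean`` and ``n_reps``.  ``missing_cells`` lists every cell of the
    full genotype x treatment x trait grid with zero replicates.
    """

    means: pd.DataFrame
    missing_cells: list[tuple[str, str, str]] = field(default_factory=list)

    def value(self, genotype: str, treatment: str, trait: str) -> float:
        return float(self.means.loc[(genotype, treatment, trait), "mean"])

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.means.index.get_level_values("genotype").unique())

    @property
    def traits(self) -> list[str]:
        return sorted(self.means.index.get_level_values("trait").unique())

    def missing_cell_report(self) -> str:
        """JSON report of grid cells with no replicates."""
        return json.dumps(
            {"n_missing": len(self.missing_cells),
             "cells": [{"genotype": g, "treatment": s, "trait": t}
                       for g, s, t in self.missing_cells]},
            indent=2)


def aggregate_means(table: pd.DataFrame) -> GenotypeMeans:
    """Arithmetic mean over available replicates for every observed cell.

    The result is independent of input row order.  Cells of the full
    genotype x treatment x trait grid that have no replicates are absent
    from ``means`` and flagged in ``missing_cells``.
    """
    grouped = (table.groupby(["genotype", "treatment", "trait"], sort=True)["value"]
               .agg(mean="mean", n_reps="count"))
    grouped["n_reps"] = grouped["n_reps"].astype(int)

    genotypes = sorted(table["genotype"].unique())
    treatments = [s for s in TREATMENTS if s in set(table["treatment"])]
    traits = sorted(table["trait"].unique())
    full = pd.MultiIndex.from_product([genotypes, treatments, traits],
                                      names=["genotype", "treatment", "trait"])
    missing = [tuple(ix) for ix in full.difference(grouped.index)]
    return GenotypeMeans(means=grouped, missing_cells=missing)
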