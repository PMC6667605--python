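"""Salt stress response indices and SD-banded tolerance classification.

For a genotype and a trait with replicate-mean values ``Pc`` (control),
``Pm`` (moderate stress) and ``Ph`` (high stress), the individual
response indices are the retention ratios

    ISSRI_moderate = Pm / Pc        ISSRI_high = Ph / Pc

Summing the ratios over the index trait set gives the cumulative indices
CMSSRI (moderate) and CHSSRI (high), and their sum is the total index

    TSSRI = CMSSRI + CHSSRI

Higher TSSRI means less growth reduction under salinity, i.e. greater
tolerance.  Genotypes are then banded by the minimum TSSRI and the
sample standard deviation over genotypes:

    sensitive   TSSRI <= min + 0.5 SD
    low         min + 0.5 SD < TSSRI <= min + 1.5 SD
    moderate    min + 1.5 SD < TSSRI <= min + 2.5 SD
    high        TSSRI > min + 2.5 SD   (unbounded above)

Ratios are used as-is for every trait — no inversion for traits where a
decrease might be adaptive, and no clipping (ratios above 1 are real:
pigment traits can rise under moderate stress).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import TraitRegistry, default_registry, resolve_trait_set
from .traits import GenotypeMeans

TOLERANCE_CLASSES = ("sensitive", "low", "moderate", "high")


class IndexError_(ValueError):
    """Raised when response indices cannot be formed (missing or zero control)."""


def response_indices(means: GenotypeMeans,
                     traits: str | list[str] = "eq3-20") -> pd.DataFrame:
    """Per-genotype, per-trait retention ratios at both stress levels.

    Returns a tidy DataFrame with columns ``genotype, trait,
    issri_moderate, issri_high``.  Every requested trait must have a
    control, moderate and high mean for every genotype, and the control
    mean must be strictly positive; violations raise with the offending
    genotype and trait named (no silent substitution).
    """
    codes = resolve_trait_set(traits)
    wide = means.means["mean"].unstack("treatment")
    for level in ("control", "moderate", "high"):
        if level not in wide.columns:
            raise IndexError_(f"no {level!r} means present in the aggregated table")

    problems: list[str] = []
    rows = []
    for g in means.genotypes:
        for t in codes:
            try:
                pc = wide.loc[(g, t), "control"]
                pm = wide.loc[(g, t), "moderate"]
                ph = wide.loc[(g, t), "high"]
            except KeyError:
                problems.append(f"genotype {g!r}, trait {t!r}: missing mean cell")
                continue
            if pd.isna(pc) or pd.isna(pm) or pd.isna(ph):
                problems.append(f"genotype {g!r}, trait {t!r}: missing mean cell")
                continue
            if pc <= 0:
                problems.append(f"genotype {g!r}, trait {t!r}: control mean {pc:g} is not > 0")
                continue
            rows.append((g, t, pm / pc, ph / pc))
    if problems:
        preview = "; ".join(problems[:10])
        raise IndexError_(f"cannot form response indices ({len(problems)} cell(s)): {preview}")
    return pd.DataFrame(rows, columns=["genotype", "trait", "issri_moderate", "issri_high"])


def cumulative_indices(idx: pd.DataFrame,
                       traits: str | list[str] = "eq3-20",
                       registry: TraitRegistry | None = None) -> pd.DataFrame:
    """Sum the individual indices into CMSSRI, CHSSRI and TSSRI per genotype.

    Also returns per-category sub-sums (``<category>_moderate``,
    ``<category>_high``, ``<category>_total``) for every registry
    category present in the trait set; categories partition the trait
    set, so the sub-sums at each stress level add up to the cumulative
    index at that level.
    """
    registry = registry or default_registry()
    codes = resolve_trait_set(traits)
    unknown = [c for c in codes if c not in registry]
    if unknown:
        raise KeyError(f"trait set contains codes absent from the registry: {unknown}")

    have = idx.set_index(["genotype", "trait"])
    genotypes = sorted(idx["genotype"].unique())
    missing = [(g, t) for g in genotypes for t in codes if (g, t) not in have.index]
    if missing:
        raise IndexError_(
            f"response-index table lacks {len(missing)} (genotype, trait) cell(s) "
            f"required by the trait set, e.g. {missing[:5]}")

    sub = have.loc[[(g, t) for g in genotypes for t in codes]].reset_index()
    cats = {t: registry.category_of(t) for t in codes}
    sub["category"] = sub["trait"].map(cats)

    out = sub.groupby("genotype")[["issri_moderate", "issri_high"]].sum()
    out.columns = ["cmssri", "chssri"]
    out["tssri"] = out["cmssri"] + out["chssri"]

    by_cat = sub.groupby(["genotype", "category"])[["issri_moderate", "issri_high"]].sum()
    for cat in sorted(set(cats.values())):
        m = by_cat.xs(cat, level="category")["issri_moderate"].reindex(out.index, fill_value=0.0)
        h = by_cat.xs(cat, level="category")["issri_high"].reindex(out.index, fill_value=0.0)
        out[f"{cat}_moderate"] = m
        out[f"{cat}_high"] = h
        out[f"{cat}_total"] = m + h
    return out


def group_indices(scores: pd.DataFrame, which: str) -> pd.Series:
    """Per-genotype category sub-index (moderate + high levels combined)."""
    col = f"{which}_total"
    if col not in scores.columns:
        cats = sorted(c[:-len("_total")] for c in scores.columns if c.endswith("_total"))
        raise KeyError(f"unknown category {which!r}; available: {cats}")
    return scores[col]


@dataclass
class ToleranceClassification:
    """SD-banded classification of genotypes by TSSRI.

    Boundaries are ``b_k = min TSSRI + (k + 0.5) * SD`` for k = 0, 1, 2
    (sample SD over genotypes).  ``nominal_top = min + 3.5 SD`` is
    reported for reference only — the high class is unbounded above.
    """

    min_tssri: float
    sd_tssri: float
    b1: float
    b2: float
    b3: float
    nominal_top: float
    classes: pd.Series = field(repr=False)

    @property
    def counts(self) -> dict[str, int]:
        vc = self.classes.value_counts()
        return {c: int(vc.get(c, 0)) for c in TOLERANCE_CLASSES}

    def summary(self) -> dict:
        return {
            "min_tssri": self.min_tssri,
            "sd_tssri": self.sd_tssri,
            "boundaries": {"b1": self.b1, "b2": self.b2, "b3": self.b3,
                           "nominal_top": self.nominal_top},
            "counts": self.counts,
        }


def classify_by_boundaries(tssri: pd.Series, b1: float, b2: float, b3: float) -> pd.Series:
    """Apply the interval rule against explicit band edges.

    sensitive iff TSSRI <= b1; low iff b1 < TSSRI <= b2; moderate iff
    b2 < TSSRI <= b3; high iff TSSRI > b3.
    """
    v = tssri.to_numpy(dtype=float)
    cls = np.select([v <= b1, v <= b2, v <= b3],
                    ["sensitive", "low", "moderate"], default="high")
    return pd.Series(cls, index=tssri.index, name="tolerance_class")


def classify_tssri(scores: pd.DataFrame | pd.Series) -> ToleranceClassification:
    """Band genotypes into sensitive/low/moderate/high from their TSSRI.

    Accepts the DataFrame returned by :func:`cumulative_indices` (uses
    its ``tssri`` column) or a bare Series of TSSRI values indexed by
    genotype.  Needs at least two genotypes (the sample SD is undefined
    otherwise).  If SD is zero every boundary collapses onto the shared
    value and all genotypes are classified sensitive.
    """
    tssri = scores["tssri"] if isinstance(scores, pd.DataFrame) else scores
    if len(tssri) < 2:
        raise ValueError("classification needs at least 2 genotypes (sample SD undefined)")
    mn = float(tssri.min())
    sd = float(tssri.std(ddof=1))
    b1, b2, b3 = (mn + k * sd for k in (0.5, 1.5, 2.5))
    return ToleranceClassification(
        min_tssri=mn, sd_tssri=sd, b1=b1, b2=b2, b3=b3,
        nominal_top=mn + 3.5 * sd,
        classes=classify_by_boundaries(tssri, b1, b2, b3),
    )
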