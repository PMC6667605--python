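"""Trait registry: the measured variables of a seedling screening trial.

A :class:`TraitRegistry` declares which trait codes a trial may contain,
what each one measures, and which organ/category it belongs to.  The
default registry carries the 24 shoot, root and physiological variables
of a pot-culture rice salinity screen (plant height through nitrogen
balance index), and three named presets select the trait subsets used by
the downstream analyses:

``eq3-20``
    The 20 traits entering the cumulative stress-response indices
    (fluorescence parameters included, pigment indices excluded).
``pca-22``
    The 22 variables used for the correlation-matrix PCA (pigment
    indices included; variable fluorescence FV and lateral-root count RN
    excluded).
``all-24``
    Every trait in the default registry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import yaml

CATEGORIES = ("shoot", "root", "physiological", "biomass")


@dataclass(frozen=True)
class TraitDef:
    """One measured variable."""

    code: str
    name: str
    units: str
    category: str

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("trait code must be non-empty")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"trait {self.code!r}: category {self.category!r} not in {CATEGORIES}"
            )


@dataclass
class TraitRegistry:
    """An ordered collection of trait definitions with unique codes."""

    entries: list[TraitDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        codes = [t.code for t in self.entries]
        dupes = {c for c in codes if codes.count(c) > 1}
        if dupes:
            raise ValueError(f"duplicate trait codes in registry: {sorted(dupes)}")

    @property
    def codes(self) -> list[str]:
        return [t.code for t in self.entries]

    def __contains__(self, code: str) -> bool:
        return any(t.code == code for t in self.entries)

    def __getitem__(self, code: str) -> TraitDef:
        for t in self.entries:
            if t.code == code:
                return t
        raise KeyError(f"unknown trait code {code!r}")

    def category_of(self, code: str) -> str:
        return self[code].category

    def codes_in_category(self, category: str) -> list[str]:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
        return [t.code for t in self.entries if t.category == category]

    def subset(self, codes: Sequence[str]) -> "TraitRegistry":
        missing = [c for c in codes if c not in self]
        if missing:
            raise KeyError(f"trait codes not in registry: {missing}")
        return TraitRegistry([self[c] for c in codes])

    @classmethod
    def from_yaml(cls, source) -> "TraitRegistry":
        """Load a registry from a YAML mapping ``{code: {name, units, category}}``.

        ``source`` may be a path or an open text stream.
        """
        if hasattr(source, "read"):
            raw = yaml.safe_load(source)
        else:
            with open(source, "rt", encoding="utf-8") as fh:
                raw = yaml.safe_load(fh)
        entries = [
            TraitDef(code=str(code), name=str(spec.get("name", code)),
                     units=str(spec.get("units", "")), category=str(spec["category"]))
            for code, spec in raw.items()
        ]
        return cls(entries)


def default_registry() -> TraitRegistry:
    """The 24 measured variables of the pot-culture salinity screen.

    TW (total dry weight) is sometimes written TD in field protocols;
    the registry uses TW throughout.
    """
    e = [
        # shoot growth, development and biomass
        TraitDef("PH", "plant height", "cm", "shoot"),
        TraitDef("TN", "tiller number", "count", "shoot"),
        TraitDef("LA", "leaf area", "cm2", "shoot"),
        TraitDef("LW", "leaf dry weight", "g", "shoot"),
        TraitDef("SW", "stem dry weight", "g", "shoot"),
        TraitDef("TW", "total dry weight (alias TD)", "g", "shoot"),
        # root morphology and topology (image-analysis traits)
        TraitDef("RW", "root dry weight", "g", "root"),
        TraitDef("LRL", "longest root length", "cm", "root"),
        TraitDef("TRL", "total root length", "cm", "root"),
        TraitDef("SA", "root surface area", "cm2", "root"),
        TraitDef("AD", "average root diameter", "mm", "root"),
        TraitDef("RV", "root volume", "cm3", "root"),
        TraitDef("RN", "roots with laterals", "count", "root"),
        TraitDef("TP", "root tips", "count", "root"),
        TraitDef("FR", "root forks", "count", "root"),
        TraitDef("CR", "root crossings", "count", "root"),
        # chlorophyll fluorescence and pigment indices
        TraitDef("F0", "minimal fluorescence", "a.u.", "physiological"),
        TraitDef("FM", "maximal fluorescence", "a.u.", "physiological"),
        TraitDef("FV", "variable fluorescence", "a.u.", "physiological"),
        TraitDef("FvFm", "maximum quantum efficiency of PSII", "unitless", "physiological"),
        TraitDef("CH", "chlorophyll content", "ug cm-2", "physiological"),
        TraitDef("FLV", "flavonoids", "a.u.", "physiological"),
        TraitDef("ANT", "anthocyanins", "a.u.", "physiological"),
        TraitDef("NBI", "nitrogen balance index", "unitless", "physiological"),
    ]
    return TraitRegistry(e)


#: Trait-set presets selecting which variables enter each analysis.
TRAIT_SET_PRESETS: dict[str, tuple[str, ...]] = {
    "eq3-20": (
        "PH", "TN", "LA", "LW", "SW", "RW", "TW", "LRL", "F0", "FM",
        "FV", "FvFm", "TRL", "SA", "AD", "RV", "RN", "TP", "FR", "CR",
    ),
    "pca-22": (
        "PH", "LA", "TN", "LW", "SW", "RW", "TW", "LRL", "TRL", "SA",
        "AD", "RV", "TP", "FR", "CR", "F0", "FM", "FvFm", "CH", "FLV",
        "ANT", "NBI",
    ),
    "all-24": tuple(t.code for t in default_registry().entries),
}


def resolve_trait_set(preset_or_codes: str | Iterable[str]) -> tuple[str, ...]:
    """Resolve a preset name or an explicit code sequence to a code tuple."""
    if isinstance(preset_or_codes, str):
        try:
            return TRAIT_SET_PRESETS[preset_or_codes]
        except KeyError:
            raise KeyError(
                f"unknown trait-set preset {preset_or_codes!r}; "
                f"known presets: {sorted(TRAIT_SET_PRESETS)}"
            ) from None
    return tuple(preset_or_codes)
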