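"""Synthetic RCBD screening trials with a latent-tolerance generative model.

The generator emulates a 74-genotype x 3-salinity x 4-replicate
pot-culture screen.  Each observation is multiplicative:

    value(g, s, rep, t) = baseline_t * G_g * retention_t(s, tau_g)
                          * block_rep * noise

* ``G_g`` — a lognormal genotype size effect (mean 1): some genotypes
  are simply bigger plants.  It cancels out of every response ratio.
* ``tau_g`` in [0, 1] — the latent salinity tolerance of genotype g,
  sampled uniformly (or user-supplied).
* ``retention_t(s, tau)`` — the fraction of the control value kept under
  salinity level s.  Monotone-declining traits use
  ``1 - delta_t(s) * (1 - kappa * tau)``: a fully tolerant genotype
  (tau = 1) with leverage kappa = 1 escapes suppression entirely.
  Hump-shaped traits (chlorophyll, nitrogen balance, anthocyanins rise
  at moderate stress before falling at high stress) carry a uniform
  moderate-level boost, encoded as a negative ``delta_mod`` applied
  without tolerance modulation.
* ``block_rep`` — a shared multiplicative block (replicate) effect.
* ``noise`` — lognormal replicate noise with the trait's CV.

All lognormal factors have mean 1, so the population mean of a trait at
control equals its baseline.  Suppression fractions for traits with
published treatment-level means are set to the printed relative declines
(total root length 5968.3 -> 5286.3 -> 4817.8 cm, chlorophyll
21.4 -> 24.9 -> 19.7 ug/cm2, ...); the rest use field-realistic
assumptions documented in the methods note.

Reproducibility: one master seed spawns an independent child stream per
genotype (plus one for block effects), so enlarging the trial leaves
existing genotypes' data bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .registry import TRAIT_SET_PRESETS
from .traits import TREATMENTS

COUNT_TRAITS = ("TN", "TP", "FR", "CR")  # rounded to integers after noise


@dataclass(frozen=True)
class TraitSim:
    """Generative parameters for one trait.

    ``delta_mod``/``delta_high`` are suppression fractions in [0, 1);
    for hump-shaped traits ``delta_mod`` is negative (a moderate-stress
    boost).  ``cv`` is the replicate coefficient of variation.
    """

    baseline: float
    delta_mod: float
    delta_high: float
    cv: float
    shape: str = "monotone"  # or "hump"

    def validate(self, code: str) -> list[str]:
        errs = []
        if self.baseline <= 0:
            errs.append(f"trait {code}: baseline must be > 0, got {self.baseline}")
        if self.cv < 0:
            errs.append(f"trait {code}: cv must be >= 0, got {self.cv}")
        if self.shape not in ("monotone", "hump"):
            errs.append(f"trait {code}: shape must be monotone|hump, got {self.shape!r}")
        if not self.delta_high < 1:
            errs.append(f"trait {code}: delta_high must be < 1, got {self.delta_high}")
        if self.shape == "monotone":
            if self.delta_mod < 0:
                errs.append(f"trait {code}: monotone delta_mod must be >= 0, got {self.delta_mod}")
            if self.delta_high < self.delta_mod:
                errs.append(f"trait {code}: monotone trait needs delta_high >= delta_mod")
        else:
            if self.delta_mod >= 0:
                errs.append(f"trait {code}: hump trait needs a negative delta_mod (boost)")
            if self.delta_high < 0:
                errs.append(f"trait {code}: delta_high must be >= 0, got {self.delta_high}")
        return errs


def default_trait_sims() -> dict[str, TraitSim]:
    """Per-trait defaults calibrated to the published treatment means.

    Baselines are the control-level population means; suppression
    fractions are ``1 - stressed_mean / control_mean`` where both means
    are published, and stated assumptions otherwise.
    """
    def mono(c, m, h, cv):
        return TraitSim(baseline=c, delta_mod=1 - m / c, delta_high=1 - h / c, cv=cv)

    def hump(c, m, h, cv):
        return TraitSim(baseline=c, delta_mod=1 - m / c, delta_high=1 - h / c,
                        cv=cv, shape="hump")

    return {
        # shoot growth and biomass
        "PH": mono(20.0, 14.43, 12.0, 0.15),
        "TN": mono(12.0, 6.0, 4.0, 0.20),
        "LA": mono(721.1, 492.5, 174.5, 0.15),
        "LW": mono(2.4, 1.7, 1.0, 0.15),
        "SW": mono(3.6, 2.5, 1.5, 0.15),
        "TW": mono(6.0, 4.2, 2.5, 0.15),
        # root morphology / topology
        "RW": mono(1.8, 1.4, 0.9, 0.15),
        "LRL": mono(43.1, 41.2, 33.0, 0.15),
        "TRL": mono(5968.3, 5286.3, 4817.8, 0.15),
        "SA": mono(1246.7, 1025.6, 679.0, 0.15),
        "AD": mono(0.7, 0.6, 0.4, 0.10),
        "RV": mono(21.9, 15.0, 8.2, 0.20),
        "RN": mono(250.0, 225.0, 180.0, 0.20),
        "TP": mono(33308.0, 31800.0, 30282.8, 0.20),
        "FR": mono(108884.8, 90000.0, 72119.2, 0.20),
        "CR": mono(7759.8, 7000.0, 6239.3, 0.20),
        # fluorescence and pigments
        "F0": mono(9000.0, 8900.0, 8600.0, 0.10),
        "FM": mono(38000.0, 36500.0, 33000.0, 0.10),
        "FV": mono(29000.0, 27600.0, 24400.0, 0.10),
        "FvFm": mono(0.78, 0.76, 0.72, 0.05),
        "CH": hump(21.4, 24.9, 19.7, 0.10),
        "FLV": mono(1.30, 1.30, 1.27, 0.10),
        "ANT": hump(0.20, 0.22, 0.19, 0.10),
        "NBI": hump(20.2, 22.7, 18.3, 0.10),
    }


@dataclass
class SimConfig:
    """Full configuration of a synthetic screening trial."""

    n_genotypes: int = 74
    n_reps: int = 4
    seed: int = 0
    kappa: float = 0.8          # tolerance leverage on suppression
    sigma_genotype: float = 0.15  # lognormal sigma of the genotype size effect
    block_sd: float = 0.05      # lognormal sigma of the block effect
    traits: dict[str, TraitSim] = field(default_factory=default_trait_sims)
    tau: np.ndarray | None = None  # optional user-supplied latent tolerances

    def validate(self) -> None:
        errs: list[str] = []
        if self.n_genotypes < 1:
            errs.append(f"n_genotypes must be >= 1, got {self.n_genotypes}")
        if self.n_reps < 1:
            errs.append(f"n_reps must be >= 1, got {self.n_reps}")
        if not 0 <= self.kappa <= 1:
            errs.append(f"kappa must be in [0, 1], got {self.kappa}")
        if self.sigma_genotype < 0:
            errs.append(f"sigma_genotype must be >= 0, got {self.sigma_genotype}")
        if self.block_sd < 0:
            errs.append(f"block_sd must be >= 0, got {self.block_sd}")
        if not self.traits:
            errs.append("traits mapping is empty")
        for code, ts in self.traits.items():
            errs.extend(ts.validate(code))
        if self.tau is not None:
            tau = np.asarray(self.tau, dtype=float)
            if tau.shape != (self.n_genotypes,):
                errs.append(f"tau must have shape ({self.n_genotypes},), got {tau.shape}")
            elif ((tau < 0) | (tau > 1)).any():
                errs.append("tau values must lie in [0, 1]")
        if errs:
            raise ValueError("invalid SimConfig:\n  " + "\n  ".join(errs))

    def to_yaml(self, target) -> None:
        doc = {
            "n_genotypes": self.n_genotypes, "n_reps": self.n_reps, "seed": self.seed,
            "kappa": self.kappa, "sigma_genotype": self.sigma_genotype,
            "block_sd": self.block_sd,
            "traits": {c: {"baseline": t.baseline, "delta_mod": t.delta_mod,
                           "delta_high": t.delta_high, "cv": t.cv, "shape": t.shape}
                       for c, t in self.traits.items()},
        }
        if self.tau is not None:
            doc["tau"] = [float(v) for v in self.tau]
        text = yaml.safe_dump(doc, sort_keys=False)
        if hasattr(target, "write"):
            target.write(text)
        else:
            with open(target, "wt", encoding="utf-8") as fh:
                fh.write(text)

    @classmethod
    def from_yaml(cls, source) -> "SimConfig":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        else:
            with open(source, "rt", encoding="utf-8") as fh:
                doc = yaml.safe_load(fh)
        traits = default_trait_sims()
        for code, spec in (doc.get("traits") or {}).items():
            base = traits.get(code)
            merged = {**({"baseline": base.baseline, "delta_mod": base.delta_mod,
                          "delta_high": base.delta_high, "cv": base.cv,
                          "shape": base.shape} if base else {}), **spec}
            traits[code] = TraitSim(**merged)
        tau = doc.get("tau")
        return cls(
            n_genotypes=int(doc.get("n_genotypes", 74)),
            n_reps=int(doc.get("n_reps", 4)),
            seed=int(doc.get("seed", 0)),
            kappa=float(doc.get("kappa", 0.8)),
            sigma_genotype=float(doc.get("sigma_genotype", 0.15)),
            block_sd=float(doc.get("block_sd", 0.05)),
            traits=traits,
            tau=None if tau is None else np.asarray(tau, dtype=float),
        )


def _lognormal_mean1(rng: np.random.Generator, sigma: float, size=None):
    """Multiplicative factor with mean exactly 1 and lognormal sigma."""
    if sigma == 0:
        return np.ones(size) if size is not None else 1.0
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)


def _retention(ts: TraitSim, level: str, tau: float, kappa: float) -> float:
    delta = {"control": 0.0, "moderate": ts.delta_mod, "high": ts.delta_high}[level]
    if delta < 0:  # hump boost: uniform, not tolerance-modulated
        return 1.0 - delta
    return 1.0 - delta * (1.0 - kappa * tau)


def expected_tssri(cfg: SimConfig, tau: float,
                   trait_set: tuple[str, ...] = TRAIT_SET_PRESETS["eq3-20"]) -> float:
    """Noiseless TSSRI implied by the generative model for tolerance tau."""
    total = 0.0
    for code in trait_set:
        ts = cfg.traits[code]
        total += _retention(ts, "moderate", tau, cfg.kappa)
        total += _retention(ts, "high", tau, cfg.kappa)
    return total


def simulate_trial(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one complete trial.

    Returns ``(table, truth)``: a validated long-format trait table (one
    row per genotype x treatment x replicate x trait) and a truth table
    with columns ``genotype, tau, expected_tssri, quartile`` (quartile
    labels Q1 = least to Q4 = most tolerant).  Bit-reproducible from the
    seed; count traits are rounded to integers after noise.
    """
    cfg.validate()
    master = np.random.SeedSequence(cfg.seed)
    block_stream, *geno_streams = master.spawn(cfg.n_genotypes + 1)

    block_rng = np.random.default_rng(block_stream)
    blocks = _lognormal_mean1(block_rng, cfg.block_sd, size=cfg.n_reps)

    codes = list(cfg.traits)
    width = len(str(cfg.n_genotypes))
    records = []
    taus = np.empty(cfg.n_genotypes)
    for gi, stream in enumerate(geno_streams):
        rng = np.random.default_rng(stream)
        tau_draw = rng.uniform()  # always drawn, keeps streams aligned
        tau = float(cfg.tau[gi]) if cfg.tau is not None else tau_draw
        taus[gi] = tau
        G = _lognormal_mean1(rng, cfg.sigma_genotype)
        name = f"G{gi + 1:0{width}d}"
        for code in codes:
            ts = cfg.traits[code]
            noise = _lognormal_mean1(rng, np.sqrt(np.log1p(ts.cv ** 2)),
                                     size=(len(TREATMENTS), cfg.n_reps))
            for si, level in enumerate(TREATMENTS):
                ret = _retention(ts, level, tau, cfg.kappa)
                vals = ts.baseline * G * ret * blocks * noise[si]
                if code in COUNT_TRAITS:
                    vals = np.maximum(np.round(vals), 0.0)
                for rep in range(cfg.n_reps):
                    records.append((name, level, rep + 1, code, float(vals[rep])))

    table = pd.DataFrame(records,
                         columns=["genotype", "treatment", "replicate", "trait", "value"])

    eq3 = tuple(c for c in TRAIT_SET_PRESETS["eq3-20"] if c in cfg.traits)
    names = [f"G{i + 1:0{width}d}" for i in range(cfg.n_genotypes)]
    exp = [expected_tssri(cfg, t, eq3) for t in taus]
    truth = pd.DataFrame({"genotype": names, "tau": taus, "expected_tssri": exp})
    if cfg.n_genotypes >= 4:
        truth["quartile"] = pd.qcut(truth["tau"], 4, labels=["Q1", "Q2", "Q3", "Q4"])
    else:
        truth["quartile"] = pd.NA
    return table, truth


def config_with(cfg: SimConfig, **overrides) -> SimConfig:
    """Convenience: a copy of ``cfg`` with fields replaced."""
    return replace(cfg, **overrides)
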