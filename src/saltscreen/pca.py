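"""Correlation-matrix PCA on trait response indices and biplot quadrant
classification.

Each genotype is represented by one combined response value per trait
(moderate + high stress retention ratios summed), the genotype x trait
matrix is standardised column-wise (sample SD), and the correlation
matrix is eigendecomposed.  Genotypes are then grouped by the signs of
their first two component scores — the biplot-quadrant rule in which the
upper-right quadrant (both scores non-negative) holds the most tolerant
genotypes and the lower-left the most sensitive.

Component signs are not identified by the eigendecomposition, so they
are oriented deterministically: PC1 so that root-morphology traits load
positively (tolerant genotypes, with their larger root systems, then
score right of the origin), PC2 so that the anthocyanin index loads
positively; components without an anchor trait get their largest-magnitude
loading made positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import TraitRegistry, default_registry, resolve_trait_set
from .ssri import TOLERANCE_CLASSES

QUADRANT_CLASSES = TOLERANCE_CLASSES  # same 4-label vocabulary


def pca_index_matrix(idx: pd.DataFrame,
                     traits: str | list[str] = "pca-22",
                     combine: str = "sum") -> pd.DataFrame:
    """Genotype x trait matrix of combined response indices.

    ``combine='sum'`` (default) uses moderate + high ISSRI, mirroring the
    construction of the total index; ``combine='mean'`` halves that.
    Raises if any requested (genotype, trait) index cell is absent.
    """
    codes = resolve_trait_set(traits)
    if combine not in ("sum", "mean"):
        raise ValueError(f"combine must be 'sum' or 'mean', got {combine!r}")
    wide_m = idx.pivot(index="genotype", columns="trait", values="issri_moderate")
    wide_h = idx.pivot(index="genotype", columns="trait", values="issri_high")
    missing = [t for t in codes if t not in wide_m.columns]
    if missing:
        raise KeyError(f"trait(s) absent from the response-index table: {missing}")
    combined = wide_m[list(codes)] + wide_h[list(codes)]
    if combined.isna().any().any():
        bad = combined.columns[combined.isna().any()].tolist()
        raise KeyError(f"missing index cells for trait(s): {bad}")
    if combine == "mean":
        combined = combined / 2.0
    return combined


@dataclass
class PCAResult:
    """Correlation-matrix PCA with deterministic sign orientation.

    loadings: trait x component (orthonormal columns); scores: genotype x
    component (scores = standardised matrix @ loadings); eigenvalues sum
    to the trait count; variance fractions sum to 1.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    standardized: pd.DataFrame = field(repr=False)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def _orient_signs(loadings: np.ndarray, traits: list[str],
                  registry: TraitRegistry) -> np.ndarray:
    """Return a +/-1 vector fixing each component's sign.

    PC1: sum of root-category loadings > 0 (anchor to root vigour).
    PC2: ANT loading > 0 when ANT is present.
    Fallback (and any later component): entry of largest magnitude > 0,
    ties broken by trait order.
    """
    signs = np.ones(loadings.shape[1])
    root_ix = [i for i, t in enumerate(traits)
               if t in registry and registry.category_of(t) == "root"]
    ant_ix = traits.index("ANT") if "ANT" in traits else None
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        anchor = 0.0
        if j == 0 and root_ix:
            anchor = col[root_ix].sum()
        elif j == 1 and ant_ix is not None:
            anchor = col[ant_ix]
        if anchor == 0.0:
            k = int(np.argmax(np.abs(np.round(col, 12))))
            anchor = col[k]
        if anchor < 0:
            signs[j] = -1.0
    return signs


def fit_correlation_pca(matrix: pd.DataFrame,
                        registry: TraitRegistry | None = None) -> PCAResult:
    """Eigendecompose the trait correlation matrix of a genotype x trait table.

    Columns are standardised to mean 0 and sample SD 1 (a zero-variance
    column is an error naming the trait); the correlation matrix is the
    sample correlation of the columns.  Eigenvalues are sorted
    descending and component signs oriented as described in the module
    docstring, making results reproducible across eigensolvers.
    """
    registry = registry or default_registry()
    if matrix.shape[0] < 3:
        raise ValueError("correlation PCA needs at least 3 genotypes")
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    dead = matrix.columns[sd == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance trait column(s): {dead}")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (Z.shape[0] - 1)

    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    traits = list(matrix.columns)
    evecs = evecs * _orient_signs(evecs, traits, registry)

    comp = [f"PC{i + 1}" for i in range(len(evals))]
    loadings = pd.DataFrame(evecs, index=traits, columns=comp)
    scores = pd.DataFrame(Z @ evecs, index=matrix.index, columns=comp)
    return PCAResult(
        loadings=loadings,
        scores=scores,
        eigenvalues=evals,
        variance_fraction=evals / evals.sum(),
        standardized=pd.DataFrame(Z, index=matrix.index, columns=traits),
    )


def quadrant_classify(scores: pd.DataFrame, pc_a: int = 1, pc_b: int = 2) -> pd.Series:
    """Tolerance group from the signs of two component scores.

    (PC_a < 0, PC_b < 0) -> sensitive; (PC_a < 0, PC_b >= 0) -> low;
    (PC_a >= 0, PC_b < 0) -> moderate; (PC_a >= 0, PC_b >= 0) -> high.
    Zero scores fall on the non-negative (tolerant) side.
    """
    if scores.shape[1] < max(pc_a, pc_b):
        raise ValueError(
            f"scores have {scores.shape[1]} component(s); need at least {max(pc_a, pc_b)}")
    a = scores.iloc[:, pc_a - 1].to_numpy(dtype=float)
    b = scores.iloc[:, pc_b - 1].to_numpy(dtype=float)
    cls = np.select(
        [(a < 0) & (b < 0), (a < 0) & (b >= 0), (a >= 0) & (b < 0)],
        ["sensitive", "low", "moderate"], default="high")
    return pd.Series(cls, index=scores.index, name="pca_class")


@dataclass
class AgreementReport:
    """Confusion of SSRI-band classes against PCA-quadrant classes."""

    confusion: pd.DataFrame  # rows: SSRI class, cols: PCA class
    overall_agreement: float
    extreme_agreement: float  # among genotypes SSRI-classed sensitive or high

    def to_dict(self) -> dict:
        return {
            "confusion": {r: {c: int(self.confusion.loc[r, c]) for c in self.confusion.columns}
                          for r in self.confusion.index},
            "overall_agreement": self.overall_agreement,
            "extreme_agreement": self.extreme_agreement,
        }


def classification_agreement(ssri_classes: pd.Series,
                             pca_classes: pd.Series) -> AgreementReport:
    """4 x 4 confusion matrix and agreement fractions of the two methods.

    Both inputs must cover the same genotypes and use the shared label
    set.  ``extreme_agreement`` is the agreement fraction restricted to
    genotypes whose SSRI class is sensitive or high — the two extreme
    groups, where the methods are expected to concur most.
    """
    if set(ssri_classes.index) != set(pca_classes.index):
        raise ValueError("genotype sets of the two classifications differ")
    bad = (set(ssri_classes.unique()) | set(pca_classes.unique())) - set(QUADRANT_CLASSES)
    if bad:
        raise ValueError(f"labels outside the shared 4-class set: {sorted(bad)}")
    pca = pca_classes.reindex(ssri_classes.index)
    conf = pd.DataFrame(0, index=list(QUADRANT_CLASSES), columns=list(QUADRANT_CLASSES))
    for s, p in zip(ssri_classes, pca):
        conf.loc[s, p] += 1
    total = int(conf.to_numpy().sum())
    overall = float(np.trace(conf.to_numpy())) / total
    ext_mask = ssri_classes.isin(["sensitive", "high"])
    if ext_mask.any():
        extreme = float((ssri_classes[ext_mask] == pca[ext_mask]).mean())
    else:
        extreme = float("nan")
    return AgreementReport(confusion=conf, overall_agreement=overall,
                           extreme_agreement=extreme)
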