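"""Chemical-space embeddings and substructure enrichment.

PCA and UMAP embeddings of descriptor tables place a compound collection
relative to reference classes; substructure enrichment counts how often a
motif — by default the 3a-aryloctahydroindole (AOHI) core that defines the
mesembrine scaffold — occurs in each labeled class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .io import CompoundSet
from .descriptors import DescriptorTable

__all__ = ["AOHI_SMARTS", "Embedding", "EnrichmentRow", "pca_embed", "umap_embed", "enrichment"]

#: 3a-aryloctahydroindole: saturated 6-5 fused indoline core with an aryl
#: substituent on the ring-fusion quaternary carbon (the mesembrine scaffold).
#: Ring atoms are required to be non-aromatic but may be sp2 (ketones in the
#: carbocycle, as in mesembrine, still match).
AOHI_SMARTS = "[#7;!a]1[#6;!a][#6;!a][#6;!a]2([c])[#6;!a][#6;!a][#6;!a][#6;!a][#6;!a]12"


@dataclass
class Embedding:
    """2D (or k-D) coordinates of a table's rows plus method metadata."""

    coordinates: pd.DataFrame  # index: row ids, columns: dim_1..dim_k
    method: str  # "pca" | "umap"
    explained_variance_pct: list[float] | None = None  # pca only, per component
    params: dict = field(default_factory=dict)


def pca_embed(table: DescriptorTable | pd.DataFrame, k: int = 2) -> Embedding:
    """PCA of a standardized descriptor table.

    Columns are scaled to zero mean / unit variance first; constant columns
    are dropped with a warning. The sign of each component is fixed so that
    its largest-magnitude loading is positive, which makes the embedding
    deterministic. Explained variance is reported in percent per component.
    """
    df = table.values if isinstance(table, DescriptorTable) else table
    if df.isna().any().any():
        raise ValueError("descriptor table has missing values")
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant columns before PCA: {constant}", stacklevel=2)
        df = df.drop(columns=constant)
    if df.shape[0] < k + 1:
        raise ValueError(f"need at least {k + 1} rows for a {k}-component PCA")
    rank = np.linalg.matrix_rank(df.to_numpy() - df.to_numpy().mean(axis=0))
    if k > rank:
        raise ValueError(f"k={k} exceeds the data rank ({rank})")
    x = StandardScaler().fit_transform(df.to_numpy())
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(x)
    for j in range(k):
        i_max = int(np.argmax(np.abs(pca.components_[j])))
        if pca.components_[j, i_max] < 0:
            pca.components_[j] *= -1
            coords[:, j] *= -1
    frame = pd.DataFrame(coords, index=df.index, columns=[f"dim_{j + 1}" for j in range(k)])
    return Embedding(
        frame,
        method="pca",
        explained_variance_pct=[100.0 * v for v in pca.explained_variance_ratio_],
        params={"k": k, "dropped_constant": constant},
    )


def umap_embed(
    table: DescriptorTable | pd.DataFrame,
    n_neighbors: int = 10,
    seed: int = 42,
    normalize: bool = True,
    min_dist: float = 0.1,
) -> Embedding:
    """Seeded 2D UMAP embedding.

    ``normalize=True`` standardizes columns first (the convention for
    descriptor tables); ``normalize=False`` embeds raw values (the convention
    for z-score profiles, which are already on a common scale). Identical
    input and seed give identical coordinates.
    """
    import umap  # deferred: numba compilation makes this import expensive

    df = table.values if isinstance(table, DescriptorTable) else table
    if df.shape[0] <= n_neighbors:
        raise ValueError(
            f"UMAP needs more rows ({df.shape[0]}) than n_neighbors ({n_neighbors}); "
            "reduce n_neighbors or supply more rows"
        )
    x = df.to_numpy(dtype=float)
    if normalize:
        x = StandardScaler().fit_transform(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns that random_state disables parallelism
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            metric="euclidean",
            random_state=seed,
        )
        coords = reducer.fit_transform(x)
    frame = pd.DataFrame(np.asarray(coords), index=df.index, columns=["dim_1", "dim_2"])
    return Embedding(
        frame,
        method="umap",
        params={"n_neighbors": n_neighbors, "seed": seed, "normalize": normalize, "min_dist": min_dist},
    )


@dataclass(frozen=True)
class EnrichmentRow:
    """Substructure occurrence within one labeled compound class."""

    class_label: str
    n_total: int
    n_matching: int

    @property
    def fraction(self) -> float:
        return self.n_matching / self.n_total


def enrichment(compounds: CompoundSet, smarts: str = AOHI_SMARTS) -> list[EnrichmentRow]:
    """Count substructure matches per class label.

    Returns one row per label in first-appearance order; the fraction of each
    row is exactly n_matching / n_total.
    """
    pattern = Chem.MolFromSmarts(smarts)
    if pattern is None:
        raise ValueError(f"invalid SMARTS: {smarts!r}")
    rows = []
    for label in compounds.labels:
        members = compounds.subset(label)
        n_match = sum(1 for r in members if r.mol().HasSubstructMatch(pattern))
        rows.append(EnrichmentRow(label, len(members), n_match))
    return rows
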