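"""Subprofile analysis: cluster signatures and compound-to-cluster assignment.

A *subprofile* condenses a set of biosimilar reference profiles into the
features they change in the same direction, each carrying the per-feature
median z. Scoring a test profile against a subprofile (cluster biosimilarity,
100 x Pearson r on the subprofile's features) maps compounds into a space of
named bioactivity clusters — the mechanism-of-action readout of the pipeline.
The reference space mirrors a 13-cluster registry (MitoStress, L/CH, PYR,
BET, HDAC, HSP90, uncoupler, ...); membership is user-supplied or synthetic.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chemspace import Embedding, umap_embed
from .profiles import AnalysisConfig, MorphProfile, _pearson_biosim, biosimilarity

logger = logging.getLogger(__name__)

__all__ = [
    "Subprofile",
    "ClusterModel",
    "ClusterAssignment",
    "extract_subprofile",
    "cluster_biosim",
    "assign_clusters",
    "profile_umap",
    "assignments_to_frame",
]

SCHEMA_VERSION = 1


@dataclass
class Subprofile:
    """Reduced feature signature of one bioactivity cluster."""

    cluster_name: str
    feature_ids: list[str]
    values: np.ndarray  # median z per selected feature
    member_ids: list[str] = field(default_factory=list)
    consistency: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.feature_ids) == 0:
            raise ValueError("subprofile must select at least one feature")
        if len(self.feature_ids) != self.values.size:
            raise ValueError("feature_ids and values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("subprofile values must be finite")


@dataclass
class ClusterModel:
    """Ordered, uniquely named collection of subprofiles (default space: 13)."""

    subprofiles: list[Subprofile]

    def __post_init__(self) -> None:
        names = [s.cluster_name for s in self.subprofiles]
        if len(set(names)) != len(names):
            raise ValueError("cluster names must be unique")

    @property
    def names(self) -> list[str]:
        return [s.cluster_name for s in self.subprofiles]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "clusters": [
                {
                    "name": s.cluster_name,
                    "feature_ids": s.feature_ids,
                    "values": [float(v) for v in s.values],
                    "member_ids": s.member_ids,
                    "consistency": s.consistency,
                }
                for s in self.subprofiles
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported cluster model schema: {payload.get('schema_version')}")
        subs = [
            Subprofile(
                cluster_name=c["name"],
                feature_ids=list(c["feature_ids"]),
                values=np.asarray(c["values"], dtype=float),
                member_ids=list(c.get("member_ids", [])),
                consistency=float(c.get("consistency", 1.0)),
            )
            for c in payload["clusters"]
        ]
        return cls(subs)


@dataclass
class ClusterAssignment:
    """Per-profile cluster biosimilarities and the decision they imply.

    ``best_cluster`` is the argmax cluster if its biosimilarity clears the
    similarity threshold, else None. Unscorable cells are NaN, never zero.
    """

    profile_id: str
    biosimilarities: dict[str, float]
    best_cluster: str | None
    threshold: float


def extract_subprofile(
    members: list[MorphProfile],
    name: str,
    consistency: float = 1.0,
    min_abs_median: float = 1.0,
    config: AnalysisConfig | None = None,
) -> Subprofile:
    """Extract a cluster subprofile from reference member profiles.

    A feature is selected when (a) at least the ``consistency`` fraction of
    members shifts it in the direction of its median and (b) the median |z|
    reaches ``min_abs_median``. Members are expected to be pairwise biosimilar;
    violations warn but do not fail.
    """
    config = config or AnalysisConfig()
    if len(members) < 2:
        raise ValueError("need at least two member profiles")
    n_feat = members[0].n_features
    if any(m.n_features != n_feat for m in members):
        raise ValueError("member profiles have differing feature counts")
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            res = biosimilarity(members[i], members[j], config)
            if not res.similar:
                warnings.warn(
                    f"members {res.id_a} and {res.id_b} are not biosimilar "
                    f"({res.biosim:.1f}% < {config.similarity_threshold:g}%)",
                    stacklevel=2,
                )

    z = np.vstack([m.z for m in members])
    excluded = np.zeros(n_feat, dtype=bool)
    for m in members:
        excluded |= m.excluded
    med = np.median(z, axis=0)
    sign = np.sign(med)
    with np.errstate(invalid="ignore"):
        agree = (np.sign(z) == sign).mean(axis=0)
    selected = (agree >= consistency) & (np.abs(med) >= min_abs_median) & (sign != 0) & ~excluded
    if not selected.any():
        raise ValueError(
            "no consistent features selected; consider lowering consistency or min_abs_median"
        )
    idx = np.flatnonzero(selected)
    return Subprofile(
        cluster_name=name,
        feature_ids=[members[0].feature_ids[i] for i in idx],
        values=med[idx],
        member_ids=[m.key for m in members],
        consistency=consistency,
    )


def cluster_biosim(profile: MorphProfile, sub: Subprofile) -> float:
    """Cluster biosimilarity: 100 x Pearson r between the profile restricted
    to the subprofile's features and the subprofile values."""
    pos = {f: i for i, f in enumerate(profile.feature_ids)}
    shared = [i for i, f in enumerate(sub.feature_ids) if f in pos and not profile.excluded[pos[f]]]
    if len(shared) < 3:
        raise ValueError("subprofile too small for correlation (fewer than 3 shared features)")
    pz = np.array([profile.z[pos[sub.feature_ids[i]]] for i in shared])
    sv = sub.values[shared]
    return _pearson_biosim(pz, sv)


def assign_clusters(
    profiles: list[MorphProfile],
    model: ClusterModel,
    config: AnalysisConfig | None = None,
) -> list[ClusterAssignment]:
    """Score every profile against every cluster and apply the decision rule.

    Cells that cannot be scored propagate as NaN. Ties on the maximum are
    broken by model order (first declared cluster wins) and logged.
    """
    config = config or AnalysisConfig()
    if not model.subprofiles:
        raise ValueError("cluster model is empty")
    out = []
    for prof in profiles:
        sims: dict[str, float] = {}
        for sub in model.subprofiles:
            try:
                sims[sub.cluster_name] = cluster_biosim(prof, sub)
            except ValueError as exc:
                logger.warning("cannot score %s vs %s: %s", prof.key, sub.cluster_name, exc)
                sims[sub.cluster_name] = float("nan")
        finite = {k: v for k, v in sims.items() if np.isfinite(v)}
        best = None
        if finite:
            top = max(finite.values())
            winners = [n for n in model.names if n in finite and finite[n] == top]
            if len(winners) > 1:
                logger.info("tie between %s for %s; keeping %s", winners, prof.key, winners[0])
            if top >= config.similarity_threshold:
                best = winners[0]
        out.append(ClusterAssignment(prof.key, sims, best, config.similarity_threshold))
    return out


def assignments_to_frame(assignments: list[ClusterAssignment]) -> pd.DataFrame:
    """Heatmap-ready frame: profiles x clusters plus the best_cluster column."""
    rows = []
    for a in assignments:
        row = {"profile_id": a.profile_id, **a.biosimilarities, "best_cluster": a.best_cluster}
        rows.append(row)
    return pd.DataFrame(rows).set_index("profile_id")


def profile_umap(
    profiles: list[MorphProfile],
    references: list[MorphProfile] | None = None,
    n_neighbors: int = 10,
    seed: int = 42,
) -> Embedding:
    """Joint seeded UMAP of test + reference profiles on raw z vectors.

    Profiles are embedded without normalization (z-scores already share a
    scale). The returned coordinates carry ``induction`` and ``is_reference``
    columns so plots can size symbols by induction.
    """
    references = references or []
    combined = list(profiles) + list(references)
    if len(combined) <= n_neighbors:
        raise ValueError(
            f"need more than n_neighbors={n_neighbors} profiles, got {len(combined)}"
        )
    df = pd.DataFrame([p.z for p in combined], index=[p.key for p in combined])
    emb = umap_embed(df, n_neighbors=n_neighbors, seed=seed, normalize=False)
    emb.coordinates["induction"] = [p.induction for p in combined]
    emb.coordinates["is_reference"] = [False] * len(profiles) + [True] * len(references)
    emb.params["n_profiles"] = len(profiles)
    emb.params["n_references"] = len(references)
    return emb
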