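"""Cell-painting profile analytics: z-score profiles, induction, biosimilarity.

A plate's treatment wells are turned into per-(compound, concentration)
z-score profiles against the DMSO controls on the same plate using robust
statistics: per feature, center = control median and scale = 1.4826 x control
MAD (the Gaussian-consistent robust standard deviation). Two headline
statistics follow:

* **induction** — the percentage of features significantly altered
  (|z| >= theta, default 3) relative to controls; a treatment is *active*
  when induction >= 5%;
* **biosimilarity (BioSim)** — 100 x Pearson correlation between two z-score
  profiles, on a [-100, 100] percent scale; profiles are *similar* when
  BioSim >= 75%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FeatureTable
from .descriptors import SimilarityMatrix

__all__ = [
    "AnalysisConfig",
    "MorphProfile",
    "BioSimResult",
    "zscore_profiles",
    "induction",
    "biosimilarity",
    "biosim_matrix",
    "profiles_to_frame",
    "frame_to_profiles",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds of the profile analytics.

    feature_significance_threshold
        |z| cutoff above which a feature counts as significantly altered.
    activity_threshold
        induction percentage at and above which a treatment is active.
    similarity_threshold
        BioSim percentage at and above which two profiles are similar.
    robust_scale_constant
        multiplier turning a MAD into a Gaussian-consistent scale estimate.
    """

    feature_significance_threshold: float = 3.0
    activity_threshold: float = 5.0
    similarity_threshold: float = 75.0
    robust_scale_constant: float = 1.4826

    def __post_init__(self) -> None:
        if self.feature_significance_threshold <= 0 or self.robust_scale_constant <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.activity_threshold <= 100:
            raise ValueError("activity_threshold must be a percentage in (0, 100]")
        if not -100 <= self.similarity_threshold <= 100:
            raise ValueError("similarity_threshold must lie in [-100, 100]")


@dataclass
class MorphProfile:
    """One (compound, concentration) morphological z-score profile.

    ``excluded`` marks features that were constant across the whole plate
    (undefined z); they are left out of the induction denominator and of
    correlations. ``flagged_zero_mad`` marks features whose control MAD was
    zero and whose scale was substituted.
    """

    compound_id: str
    concentration_um: float
    z: np.ndarray
    feature_ids: list[str]
    induction: float = 0.0
    active: bool = False
    excluded: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    flagged_zero_mad: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.excluded.size == 0:
            self.excluded = np.zeros(self.z.size, dtype=bool)
        if self.flagged_zero_mad.size == 0:
            self.flagged_zero_mad = np.zeros(self.z.size, dtype=bool)
        if not (self.z.size == len(self.feature_ids) == self.excluded.size):
            raise ValueError("profile vectors and feature ids must have equal length")

    @property
    def n_features(self) -> int:
        return self.z.size

    @property
    def key(self) -> str:
        return f"{self.compound_id}@{self.concentration_um:g}uM"


@dataclass(frozen=True)
class BioSimResult:
    """Biosimilarity between two profiles on the [-100, 100] percent scale."""

    id_a: str
    id_b: str
    biosim: float
    similar: bool


def zscore_profiles(plate: FeatureTable, config: AnalysisConfig | None = None) -> list[MorphProfile]:
    """Robust z-score profiles for every (compound, concentration) on a plate.

    Replicate wells of the same treatment are aggregated by median before
    scaling. Features with zero control MAD get the smallest positive control
    MAD on the plate as a substitute scale (and are flagged); features that
    are constant across the entire plate are excluded from the induction
    denominator. Requires at least 4 control wells.
    """
    config = config or AnalysisConfig()
    ctrl_mask = plate.control_mask
    n_controls = int(ctrl_mask.sum())
    if n_controls < 4:
        raise ValueError(f"need at least 4 control wells, found {n_controls}")
    feats = plate.features.to_numpy(dtype=float)
    ctrl = feats[ctrl_mask]
    center = np.median(ctrl, axis=0)
    mad = np.median(np.abs(ctrl - center), axis=0)

    plate_constant = np.all(feats == feats[0], axis=0)  # z undefined everywhere
    zero_mad = (mad == 0) & ~plate_constant
    if zero_mad.any():
        positive = mad[mad > 0]
        if positive.size == 0:
            # every feature degenerate in controls; nothing to substitute
            plate_constant = plate_constant | zero_mad
            zero_mad = np.zeros_like(zero_mad)
        else:
            mad = np.where(zero_mad, positive.min(), mad)
    scale = config.robust_scale_constant * np.where(mad > 0, mad, 1.0)

    meta = plate.data.loc[~ctrl_mask, ["compound_id", "concentration_um"]]
    treat = feats[~ctrl_mask]
    profiles: list[MorphProfile] = []
    groups: dict[tuple[str, float], list[int]] = {}
    for pos, (_, row) in enumerate(meta.iterrows()):
        key = (str(row["compound_id"]), float(row["concentration_um"]))
        groups.setdefault(key, []).append(pos)
    for (cid, conc), rows in groups.items():
        tmed = np.median(treat[rows], axis=0)
        z = (tmed - center) / scale
        z[plate_constant] = 0.0
        prof = MorphProfile(
            compound_id=cid,
            concentration_um=conc,
            z=z,
            feature_ids=list(plate.feature_columns),
            excluded=plate_constant.copy(),
            flagged_zero_mad=zero_mad.copy(),
        )
        induction(prof, config)
        profiles.append(prof)
    return profiles


def induction(profile: MorphProfile, config: AnalysisConfig | None = None) -> float:
    """Induction: percentage of non-excluded features with |z| >= theta.

    Updates the profile's ``induction`` and ``active`` fields in place and
    returns the percentage.
    """
    config = config or AnalysisConfig()
    usable = ~profile.excluded
    denom = int(usable.sum())
    if denom == 0:
        raise ValueError("no usable features: every feature is excluded")
    theta = config.feature_significance_threshold
    hits = int((np.abs(profile.z[usable]) >= theta).sum())
    profile.induction = 100.0 * hits / denom
    profile.active = profile.induction >= config.activity_threshold
    return profile.induction


def _pearson_biosim(za: np.ndarray, zb: np.ndarray) -> float:
    if np.all(za == za[0]) or np.all(zb == zb[0]):
        raise ValueError("undefined correlation: constant z vector")
    return 100.0 * float(np.corrcoef(za, zb)[0, 1])


def biosimilarity(
    p: MorphProfile, q: MorphProfile, config: AnalysisConfig | None = None
) -> BioSimResult:
    """BioSim between two profiles: 100 x Pearson r over shared usable features."""
    config = config or AnalysisConfig()
    if p.n_features != q.n_features:
        raise ValueError("profiles have different feature counts")
    usable = ~(p.excluded | q.excluded)
    if usable.sum() < 3:
        raise ValueError("fewer than 3 shared usable features")
    biosim = _pearson_biosim(p.z[usable], q.z[usable])
    return BioSimResult(p.key, q.key, biosim, biosim >= config.similarity_threshold)


def biosim_matrix(
    profiles: list[MorphProfile], config: AnalysisConfig | None = None
) -> SimilarityMatrix:
    """Symmetric profile-by-profile BioSim matrix with diagonal 100."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    n = len(profiles)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            val = biosimilarity(profiles[i], profiles[j], config).biosim
            mat[i, j] = mat[j, i] = val
    ids = [p.key for p in profiles]
    return SimilarityMatrix(pd.DataFrame(mat, index=ids, columns=ids))


# ---------------------------------------------------------------------------
# tabular round trip (profile CSV convention)
# ---------------------------------------------------------------------------

def profiles_to_frame(profiles: list[MorphProfile]) -> pd.DataFrame:
    """Profiles as one row per treatment: metadata, induction, then z columns."""
    if not profiles:
        raise ValueError("no profiles to export")
    width = len(str(len(profiles[0].feature_ids)))
    zcols = [f"z_{i + 1:0{max(width, 4)}d}" for i in range(profiles[0].n_features)]
    rows = []
    for p in profiles:
        row = {
            "compound_id": p.compound_id,
            "concentration_um": p.concentration_um,
            "induction": p.induction,
            "active": p.active,
        }
        row.update(dict(zip(zcols, p.z)))
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_profiles(df: pd.DataFrame) -> list[MorphProfile]:
    """Inverse of :func:`profiles_to_frame` (excluded-feature flags are not kept)."""
    zcols = [c for c in df.columns if c.startswith("z_")]
    out = []
    for _, row in df.iterrows():
        out.append(
            MorphProfile(
                compound_id=str(row["compound_id"]),
                concentration_um=float(row["concentration_um"]),
                z=row[zcols].to_numpy(dtype=float),
                feature_ids=zcols,
                induction=float(row["induction"]),
                active=bool(row["active"]),
            )
        )
    return out
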