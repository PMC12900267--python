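"""Synthetic inputs with ground truth for every stage of the pipeline.

Three generators:

* :func:`gen_plate` — plate feature tables emulating cell-painting readouts:
  control wells drawn feature-wise from Normal(mu_f, sigma_f), treatment
  wells shifted on a planted cluster's effect features by
  ``amplitude x hill(conc) x sign x sigma_f``. Amplitudes are therefore in
  per-feature control-scale (sigma) units. Defaults mirror the study
  conditions the pipeline targets: 579 features, concentrations 2-50 uM,
  distinct bioactivity clusters with ~10% of features affected each.
* :func:`gen_toy_compound_classes` — a curated two-class compound set
  (stereocenter-rich fused polycyclic natural-product-like molecules vs flat
  aromatic drug-like molecules) for descriptor, enrichment and NP-likeness
  tests; exactly one member (mesembrine) carries the AOHI core.
* :func:`gen_ocr_trace` — MitoStress traces whose phase means reproduce
  target respiration parameters exactly before noise.

Features are generated independently; real morphological features are
correlated, so recovery results here bound the method's behaviour under the
generator's assumptions, not under real-plate covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bioenergetics import MITOSTRESS_LABELS, MitoParams, OCRTrace
from .io import CompoundRecord, CompoundSet, FeatureTable, METADATA_COLUMNS, canonicalize_smiles

__all__ = [
    "CompoundSpec",
    "SyntheticPlateSpec",
    "GroundTruth",
    "default_cluster_plate_spec",
    "gen_plate",
    "gen_toy_compound_classes",
    "gen_ocr_trace",
]


# ---------------------------------------------------------------------------
# plates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundSpec:
    """One synthetic compound: its planted cluster (None = inert), effect
    amplitude in control-sigma units, and tested concentrations (uM)."""

    compound_id: str
    cluster: int | None
    amplitude: float
    concentrations: tuple[float, ...] = (2.0, 10.0, 30.0, 50.0)


@dataclass
class SyntheticPlateSpec:
    """Generative parameters of a synthetic plate.

    ``n_features`` defaults to the 579-feature cell-painting convention;
    per-feature noise scales sigma_f are drawn log-uniformly over one decade
    so robust scaling is genuinely exercised. Cluster effect templates use
    disjoint feature subsets (hence exactly orthogonal directions) with
    random +/-1 signs. The dose response is a Hill curve,
    ``hill(c) = c^slope / (c50^slope + c^slope)``.
    """

    n_features: int = 579
    n_controls: int = 16
    k_clusters: int = 4
    features_per_cluster: int = 58
    compounds: list[CompoundSpec] = field(default_factory=list)
    n_replicates: int = 2
    c50_um: float = 10.0
    hill_slope: float = 1.0
    sigma_low: float = 0.5  # log-uniform sigma_f in [sigma_low, 10*sigma_low]
    seed: int = 0
    plate_id: str = "SYN1"

    def __post_init__(self) -> None:
        if self.n_controls < 8:
            raise ValueError("n_controls must be >= 8")
        if self.k_clusters * self.features_per_cluster > self.n_features:
            raise ValueError("cluster effect features exceed the feature count")
        if any(c.amplitude < 0 for c in self.compounds):
            raise ValueError("amplitudes must be non-negative")
        if self.sigma_low <= 0:
            raise ValueError("sigma_low must be positive")


@dataclass
class GroundTruth:
    """What was planted: per-compound cluster labels, per-cluster signed
    effect features, and the noise-free expected mean of every well."""

    compound_cluster: dict[str, int | None]
    cluster_features: dict[int, dict[int, int]]  # cluster -> {feature index: sign}
    templates: np.ndarray  # k x F unit-norm effect directions
    expected_means: pd.DataFrame  # well_id x features
    sigma: np.ndarray
    mu: np.ndarray


def default_cluster_plate_spec(
    n_per_cluster: int = 10,
    amplitude: float = 10.0,
    k_clusters: int = 4,
    n_inactive: int = 0,
    seed: int = 0,
    **kwargs,
) -> SyntheticPlateSpec:
    """Plate spec with ``n_per_cluster`` active compounds planted per cluster."""
    compounds = []
    for k in range(k_clusters):
        for i in range(n_per_cluster):
            compounds.append(CompoundSpec(f"cl{k}_cpd{i:02d}", k, amplitude))
    for i in range(n_inactive):
        compounds.append(CompoundSpec(f"inert_cpd{i:02d}", None, 0.0))
    return SyntheticPlateSpec(k_clusters=k_clusters, compounds=compounds, seed=seed, **kwargs)


def hill(conc: np.ndarray | float, c50: float, slope: float) -> np.ndarray | float:
    """Hill occupancy curve in [0, 1)."""
    c = np.asarray(conc, dtype=float)
    return c**slope / (c50**slope + c**slope)


def gen_plate(spec: SyntheticPlateSpec) -> tuple[FeatureTable, GroundTruth]:
    """Generate a plate feature table plus its ground truth, deterministically."""
    rng = np.random.default_rng(spec.seed)
    F = spec.n_features
    mu = rng.uniform(5.0, 15.0, size=F)
    sigma = spec.sigma_low * 10 ** rng.uniform(0.0, 1.0, size=F)

    # disjoint effect-feature subsets -> exactly orthogonal templates
    perm = rng.permutation(F)
    cluster_features: dict[int, dict[int, int]] = {}
    templates = np.zeros((spec.k_clusters, F))
    for k in range(spec.k_clusters):
        idx = perm[k * spec.features_per_cluster:(k + 1) * spec.features_per_cluster]
        signs = rng.choice([-1, 1], size=idx.size)
        cluster_features[k] = {int(i): int(s) for i, s in zip(idx, signs)}
        templates[k, idx] = signs / np.sqrt(idx.size)

    feature_cols = [f"f_{i + 1:04d}" for i in range(F)]
    rows, meta_rows, expected = [], [], []
    well = 0

    def add_well(cid: str | None, conc: float | None, mean_vec: np.ndarray, control: bool):
        nonlocal well
        well += 1
        rows.append(mean_vec + rng.normal(0.0, sigma))
        meta_rows.append(
            {
                "plate_id": spec.plate_id,
                "well_id": f"W{well:03d}",
                "compound_id": cid if cid is not None else "",
                "concentration_um": conc if conc is not None else np.nan,
                "is_control": control,
            }
        )
        expected.append(mean_vec)

    for _ in range(spec.n_controls):
        add_well(None, None, mu, control=True)
    for cpd in spec.compounds:
        for conc in cpd.concentrations:
            shift = np.zeros(F)
            if cpd.cluster is not None and cpd.amplitude > 0:
                frac = float(hill(conc, spec.c50_um, spec.hill_slope))
                for f_idx, sign in cluster_features[cpd.cluster].items():
                    shift[f_idx] = cpd.amplitude * frac * sign * sigma[f_idx]
            for _ in range(spec.n_replicates):
                add_well(cpd.compound_id, conc, mu + shift, control=False)

    meta = pd.DataFrame(meta_rows)
    data = pd.concat([meta, pd.DataFrame(rows, columns=feature_cols)], axis=1)
    table = FeatureTable(data[list(METADATA_COLUMNS) + feature_cols])
    truth = GroundTruth(
        compound_cluster={c.compound_id: c.cluster for c in spec.compounds},
        cluster_features=cluster_features,
        templates=templates,
        expected_means=pd.DataFrame(expected, index=meta["well_id"], columns=feature_cols),
        sigma=sigma,
        mu=mu,
    )
    return table, truth


# ---------------------------------------------------------------------------
# toy compound classes
# ---------------------------------------------------------------------------

# Stereocenter-rich, fused-polycyclic, mostly aliphatic scaffolds typical of
# alkaloid/terpenoid space. Mesembrine is the single AOHI-bearing member.
_NP_LIKE_SMILES = [
    ("mesembrine", "CN1CC[C@]2(c3ccc(OC)c(OC)c3)CC(=O)CC[C@@H]21"),
    ("decalinol", "O[C@H]1CC[C@H]2CCCC[C@@H]2C1"),
    ("camphor", "CC1(C)[C@@H]2CC[C@@]1(C)C(=O)C2"),
    ("borneol", "CC1(C)[C@@H]2CC[C@@]1(C)[C@H](O)C2"),
    ("sclareolide", "CC1(C)CCC[C@]2(C)[C@@H]1CC[C@@]1(C)OC(=O)C[C@H]21"),
    ("quinine", "COc1ccc2nccc([C@@H](O)[C@H]3C[C@@H]4CCN3C[C@@H]4C=C)c2c1"),
    ("menthol", "CC(C)[C@@H]1CC[C@@H](C)C[C@H]1O"),
    ("dihydrotestosterone", "C[C@]12CC[C@H]3[C@@H](CC[C@H]4CC(=O)CC[C@]34C)[C@@H]1CC[C@@H]2O"),
    ("glucopyranose", "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O"),
    ("alpha_pinene", "CC1=CC[C@@H]2C[C@H]1C2(C)C"),
    ("indolizidindiol", "O[C@H]1CCN2CCC[C@H](O)[C@H]12"),
    ("cis_bicyclononanone", "O=C1CC[C@H]2CCC[C@@H]2C1"),
]

# Flat, aromatic-ring-dominated drug-like molecules.
_DRUG_LIKE_SMILES = [
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("benzocaine", "CCOC(=O)c1ccc(N)cc1"),
    ("sulfamethoxazole", "Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1"),
    ("biphenyl_acid", "O=C(O)c1ccc(-c2ccccc2)cc1"),
    ("caffeine", "Cn1c(=O)c2c(ncn2C)n(C)c1=O"),
    ("nicotinamide", "NC(=O)c1cccnc1"),
    ("quinoline", "c1ccc2ncccc2c1"),
    ("indole", "c1ccc2[nH]ccc2c1"),
    ("triclosan", "Oc1cc(Cl)ccc1Oc1ccc(Cl)cc1Cl"),
    ("benzophenone", "O=C(c1ccccc1)c1ccccc1"),
    ("diflunisal", "O=C(O)c1cc(-c2ccc(F)cc2F)ccc1O"),
]


def gen_toy_compound_classes(seed: int = 0) -> CompoundSet:
    """Curated two-class toy compound set (labels ``np_like`` / ``drug_like``).

    The seed shuffles record order only (class membership is fixed by
    curation), so downstream train/test splits vary while the chemistry
    stays the same.
    """
    records = []
    for name, smi in _NP_LIKE_SMILES:
        canon = canonicalize_smiles(smi)
        assert canon is not None, name
        records.append(CompoundRecord(f"np_{name}", canon, "np_like", name))
    for name, smi in _DRUG_LIKE_SMILES:
        canon = canonicalize_smiles(smi)
        assert canon is not None, name
        records.append(CompoundRecord(f"drug_{name}", canon, "drug_like", name))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    return CompoundSet([records[i] for i in order], provenance=f"gen_toy_compound_classes(seed={seed})")


# ---------------------------------------------------------------------------
# Seahorse traces
# ---------------------------------------------------------------------------

def gen_ocr_trace(
    seed: int,
    targets: MitoParams,
    noise: float = 0.0,
    n_per_phase: int = 3,
    dt_min: float = 6.5,
    ecar_baseline: float = 20.0,
) -> OCRTrace:
    """MitoStress trace whose phase means equal the targets exactly pre-noise.

    The post-FCCP phase is generated flat so that the max-measurement
    definition of maximal respiration coincides with the phase mean and the
    zero-noise round trip through the parameter extraction is exact. Targets
    must satisfy the identities ``basal = atp_linked + proton_leak`` and
    ``spare_capacity = maximal - basal``.
    """
    if abs(targets.basal - (targets.atp_linked + targets.proton_leak)) > 1e-9:
        raise ValueError("inconsistent targets: basal != atp_linked + proton_leak")
    if abs(targets.spare_capacity - (targets.maximal - targets.basal)) > 1e-9:
        raise ValueError("inconsistent targets: spare_capacity != maximal - basal")
    rng = np.random.default_rng(seed)
    levels = [
        targets.basal + targets.non_mitochondrial,
        targets.proton_leak + targets.non_mitochondrial,
        targets.maximal + targets.non_mitochondrial,
        targets.non_mitochondrial,
    ]
    times, ocr, ecar = [], [], []
    t = 0.0
    for level in levels:
        for _ in range(n_per_phase):
            t += dt_min
            times.append(t)
            ocr.append(level + (rng.normal(0.0, noise) if noise > 0 else 0.0))
            ecar.append(ecar_baseline + (rng.normal(0.0, noise) if noise > 0 else 0.0))
    injections = [
        (label, times[(i + 1) * n_per_phase - 1] + dt_min / 2)
        for i, label in enumerate(MITOSTRESS_LABELS)
    ]
    return OCRTrace(
        timepoints=np.array(times),
        ocr=np.array(ocr),
        ecar=np.array(ecar),
        injections=injections,
    )
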