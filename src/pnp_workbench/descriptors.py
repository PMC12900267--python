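"""Per-molecule scores for compound-collection characterization.

Covers the descriptor panel used to compare a pseudo-natural-product (PNP)
collection against reference compound classes:

* a configurable 17-descriptor physicochemical table (the panel standard for
  natural-product vs drug chemspace comparisons);
* QED, the quantitative estimate of drug-likeness (weighted geometric mean of
  eight property desirabilities, in (0, 1]);
* NP-likeness, a circular-fragment log-odds score contrasting a natural-product
  reference set against a synthetic reference set, conventionally in [-5, 5];
* the spatial score SPS and its size-normalized form nSPS, a per-atom
  complexity descriptor combining hybridization, stereogenicity, non-aromatic
  ring membership and branching;
* principal-moments-of-inertia shape descriptors (NPR1, NPR2) locating a
  conformer in the rod-disc-sphere triangle;
* Morgan-fingerprint Tanimoto similarity matrices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import AllChem, Crippen, Descriptors, Lipinski, rdMolDescriptors, rdmolops
from rdkit.Chem import QED as _QED

from .io import CompoundSet

__all__ = [
    "DEFAULT_DESCRIPTORS",
    "DescriptorTable",
    "FragmentScoreTable",
    "ShapeDescriptor",
    "SimilarityMatrix",
    "descriptor_table",
    "qed",
    "train_np_likeness",
    "np_likeness",
    "sps",
    "nsps",
    "shape_descriptor",
    "tanimoto_matrix",
]


# ---------------------------------------------------------------------------
# descriptor registry
# ---------------------------------------------------------------------------

def _ring_system_count(mol: Chem.Mol) -> int:
    """Number of fused ring systems (rings sharing an atom count as one)."""
    rings = mol.GetRingInfo().AtomRings()
    systems: list[set[int]] = []
    for ring in rings:
        ring = set(ring)
        merged = [s for s in systems if s & ring]
        for s in merged:
            ring |= s
            systems.remove(s)
        systems.append(ring)
    return len(systems)


def _largest_ring_size(mol: Chem.Mol) -> int:
    rings = mol.GetRingInfo().AtomRings()
    return max((len(r) for r in rings), default=0)


#: Registry of supported named descriptors; the default panel is the 17 below.
DESCRIPTOR_REGISTRY: dict[str, callable] = {
    "molecular_weight": Descriptors.MolWt,
    "clogp": Crippen.MolLogP,
    "tpsa": rdMolDescriptors.CalcTPSA,
    "hbd_count": Lipinski.NumHDonors,
    "hba_count": Lipinski.NumHAcceptors,
    "rotatable_bonds": Lipinski.NumRotatableBonds,
    "ring_count": rdMolDescriptors.CalcNumRings,
    "aromatic_ring_count": rdMolDescriptors.CalcNumAromaticRings,
    "heavy_atom_count": lambda m: m.GetNumHeavyAtoms(),
    "fraction_csp3": rdMolDescriptors.CalcFractionCSP3,
    "stereocenter_count": lambda m: len(
        Chem.FindMolChiralCenters(m, includeUnassigned=True, useLegacyImplementation=False)
    ),
    "heteroatom_count": rdMolDescriptors.CalcNumHeteroatoms,
    "formal_charge": rdmolops.GetFormalCharge,
    "ring_system_count": _ring_system_count,
    "largest_ring_size": _largest_ring_size,
    "nitrogen_count": lambda m: sum(1 for a in m.GetAtoms() if a.GetAtomicNum() == 7),
    "oxygen_count": lambda m: sum(1 for a in m.GetAtoms() if a.GetAtomicNum() == 8),
}

DEFAULT_DESCRIPTORS: tuple[str, ...] = tuple(DESCRIPTOR_REGISTRY)
assert len(DEFAULT_DESCRIPTORS) == 17


@dataclass
class DescriptorTable:
    """Compound-by-descriptor table plus the list of compounds that failed."""

    values: pd.DataFrame  # index: compound_id, columns: descriptor names
    failures: list[str] = field(default_factory=list)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.values.columns)


def descriptor_table(compounds: CompoundSet, names: list[str] | None = None) -> DescriptorTable:
    """Compute named descriptors for every compound.

    Compounds whose computation fails are excluded from the table and listed
    in ``failures``; an unknown descriptor name is fatal.
    """
    names = list(names) if names is not None else list(DEFAULT_DESCRIPTORS)
    unknown = [n for n in names if n not in DESCRIPTOR_REGISTRY]
    if unknown:
        raise ValueError(
            f"unknown descriptors {unknown}; supported: {sorted(DESCRIPTOR_REGISTRY)}"
        )
    rows, index, failures = [], [], []
    for rec in compounds:
        try:
            mol = rec.mol()
            row = [float(DESCRIPTOR_REGISTRY[n](mol)) for n in names]
            if not all(math.isfinite(v) for v in row):
                raise ValueError("non-finite descriptor value")
        except Exception:
            failures.append(rec.compound_id)
            continue
        rows.append(row)
        index.append(rec.compound_id)
    return DescriptorTable(pd.DataFrame(rows, index=index, columns=names), failures)


# ---------------------------------------------------------------------------
# drug-likeness
# ---------------------------------------------------------------------------

def qed(structure: str) -> float:
    """Quantitative estimate of drug-likeness, in (0, 1].

    Weighted geometric mean of eight property desirability functions in the
    published parameterization.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparseable structure: {structure!r}")
    return float(_QED.qed(mol))


# ---------------------------------------------------------------------------
# NP-likeness
# ---------------------------------------------------------------------------

@dataclass
class FragmentScoreTable:
    """Circular-fragment log-odds contributions for NP-likeness scoring.

    Contribution of fragment *i* is ``log((p_np + eps_np) / (p_syn + eps_syn))``
    where ``p`` is the fraction of molecules in the respective reference set
    containing the fragment and ``eps = 1 / set size`` is the smoothing term.
    """

    contributions: dict[int, float]
    radius: int = 2
    n_np: int = 0
    n_synthetic: int = 0

    def to_json_dict(self) -> dict:
        return {
            "radius": self.radius,
            "n_np": self.n_np,
            "n_synthetic": self.n_synthetic,
            "contributions": {str(k): v for k, v in self.contributions.items()},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "FragmentScoreTable":
        return cls(
            contributions={int(k): float(v) for k, v in d["contributions"].items()},
            radius=int(d["radius"]),
            n_np=int(d["n_np"]),
            n_synthetic=int(d["n_synthetic"]),
        )


def _molecule_fragments(mol: Chem.Mol, radius: int) -> set[int]:
    """Hashed circular-environment identifiers up to the given radius."""
    gen = AllChem.GetMorganGenerator(radius=radius)
    return set(gen.GetSparseCountFingerprint(mol).GetNonzeroElements())


def train_np_likeness(
    np_set: CompoundSet, synthetic_set: CompoundSet, radius: int = 2
) -> FragmentScoreTable:
    """Train fragment contributions from a natural-product and a synthetic set.

    The two sets must be non-empty and disjoint by canonical structure.
    Swapping the sets negates every contribution exactly.
    """
    if len(np_set) == 0 or len(synthetic_set) == 0:
        raise ValueError("both training sets must be non-empty")
    np_structs = {r.structure for r in np_set}
    syn_structs = {r.structure for r in synthetic_set}
    overlap = np_structs & syn_structs
    if overlap:
        raise ValueError(f"training sets share {len(overlap)} canonical structures")

    def _doc_freq(cs: CompoundSet) -> dict[int, int]:
        counts: dict[int, int] = {}
        for rec in cs:
            for frag in _molecule_fragments(rec.mol(), radius):
                counts[frag] = counts.get(frag, 0) + 1
        return counts

    np_counts = _doc_freq(np_set)
    syn_counts = _doc_freq(synthetic_set)
    eps_np = 1.0 / len(np_set)
    eps_syn = 1.0 / len(synthetic_set)
    contributions = {}
    for frag in set(np_counts) | set(syn_counts):
        p_np = np_counts.get(frag, 0) / len(np_set)
        p_syn = syn_counts.get(frag, 0) / len(synthetic_set)
        contributions[frag] = math.log((p_np + eps_np) / (p_syn + eps_syn))
    return FragmentScoreTable(contributions, radius, len(np_set), len(synthetic_set))


def np_likeness(structure: str, table: FragmentScoreTable) -> float:
    """NP-likeness score: mean fragment contribution, clipped to [-5, 5].

    Fragments absent from the trained table contribute zero.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparseable structure: {structure!r}")
    frags = _molecule_fragments(mol, table.radius)
    if not frags:
        warnings.warn(f"no fragments for {structure!r}; NP-likeness set to 0", stacklevel=2)
        return 0.0
    mean = sum(table.contributions.get(f, 0.0) for f in frags) / len(frags)
    return float(np.clip(mean, -5.0, 5.0))


# ---------------------------------------------------------------------------
# spatial score
# ---------------------------------------------------------------------------

# Per-atom term constants of the spatial score: score(atom) = h * s * r * n^2.
SPS_HYBRIDIZATION_TERM = {
    Chem.HybridizationType.SP: 1,
    Chem.HybridizationType.SP2: 2,
    Chem.HybridizationType.SP3: 3,
}
SPS_HYBRIDIZATION_DEFAULT = 4  # unspecified / other hybridizations
SPS_STEREO_TERM = 2  # stereogenic atoms (tetrahedral centers or E/Z bond atoms)
SPS_RING_TERM = 2  # atoms in non-aromatic rings


def _stereogenic_atoms(mol: Chem.Mol) -> set[int]:
    """Indices of stereogenic atoms: (potential) tetrahedral centers plus atoms
    of (potential) E/Z double bonds."""
    mol = Chem.Mol(mol)
    rdmolops.FindPotentialStereoBonds(mol)
    idxs = {
        i
        for i, _ in Chem.FindMolChiralCenters(
            mol, includeUnassigned=True, includeCIP=False, useLegacyImplementation=False
        )
    }
    for bond in mol.GetBonds():
        if (
            bond.GetBondType() == Chem.BondType.DOUBLE
            and bond.GetStereo() != Chem.BondStereo.STEREONONE
        ):
            idxs.add(bond.GetBeginAtomIdx())
            idxs.add(bond.GetEndAtomIdx())
    return idxs


def sps(structure: str) -> float:
    """Spatial score: sum over heavy atoms of h * s * r * n^2.

    h rewards saturation (sp 1, sp2 2, sp3 3, other 4), s doubles stereogenic
    atoms, r doubles atoms in non-aromatic rings, and n^2 (heavy-neighbor
    count squared) rewards branching.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparseable structure: {structure!r}")
    if mol.GetNumHeavyAtoms() == 0:
        raise ValueError("structure has no heavy atoms")
    stereo = _stereogenic_atoms(mol)
    total = 0
    for atom in mol.GetAtoms():
        h = SPS_HYBRIDIZATION_TERM.get(atom.GetHybridization(), SPS_HYBRIDIZATION_DEFAULT)
        s = SPS_STEREO_TERM if atom.GetIdx() in stereo else 1
        r = SPS_RING_TERM if (atom.IsInRing() and not atom.GetIsAromatic()) else 1
        n = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1)
        total += h * s * r * n * n
    return float(total)


def nsps(structure: str) -> float:
    """Normalized spatial score: SPS / heavy-atom count (complexity density)."""
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparseable structure: {structure!r}")
    return sps(structure) / mol.GetNumHeavyAtoms()


# ---------------------------------------------------------------------------
# PMI shape
# ---------------------------------------------------------------------------

_SHAPE_VERTICES = {"rod": (0.0, 1.0), "disc": (0.5, 0.5), "sphere": (1.0, 1.0)}


@dataclass(frozen=True)
class ShapeDescriptor:
    """Normalized principal-moment ratios NPR1 = I1/I3, NPR2 = I2/I3.

    Valid descriptors satisfy 0 <= NPR1 <= NPR2 <= 1 and NPR1 + NPR2 >= 1;
    the shape class is the nearest vertex of the rod-disc-sphere triangle.
    """

    npr1: float
    npr2: float
    shape_class: str

    @classmethod
    def from_moments(cls, i1: float, i2: float, i3: float) -> "ShapeDescriptor":
        """Build from principal moments of inertia (any order; sorted here)."""
        i1, i2, i3 = sorted((i1, i2, i3))
        if i3 <= 0:
            raise ValueError("largest principal moment must be positive")
        npr1, npr2 = i1 / i3, i2 / i3
        shape = min(
            _SHAPE_VERTICES,
            key=lambda k: (npr1 - _SHAPE_VERTICES[k][0]) ** 2 + (npr2 - _SHAPE_VERTICES[k][1]) ** 2,
        )
        return cls(float(npr1), float(npr2), shape)


def shape_descriptor(structure: str, seed: int = 42, n_confs: int = 10) -> ShapeDescriptor:
    """PMI shape descriptor of the lowest-energy generated conformer.

    Conformers are embedded deterministically from the seed with hydrogens
    added; MMFF energies (UFF fallback) pick the conformer.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparseable structure: {structure!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_confs, params=params)
    if not conf_ids:
        raise ValueError(f"3D embedding failed for {structure!r}")
    energies = []
    try:
        props = AllChem.MMFFGetMoleculeProperties(mol)
        if props is None:
            raise ValueError
        for cid in conf_ids:
            ff = AllChem.MMFFGetMoleculeForceField(mol, props, confId=cid)
            energies.append(ff.CalcEnergy())
    except Exception:
        energies = []
        for cid in conf_ids:
            ff = AllChem.UFFGetMoleculeForceField(mol, confId=cid)
            energies.append(ff.CalcEnergy())
    best = conf_ids[int(np.argmin(energies))]
    moments = (
        rdMolDescriptors.CalcPMI1(mol, confId=best),
        rdMolDescriptors.CalcPMI2(mol, confId=best),
        rdMolDescriptors.CalcPMI3(mol, confId=best),
    )
    return ShapeDescriptor.from_moments(*moments)


# ---------------------------------------------------------------------------
# fingerprint similarity
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with row/column ids.

    Chemical (Tanimoto) similarities live in [0, 1] with unit diagonal;
    biological similarities (see the profile analytics) in [-100, 100] with
    diagonal 100.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.index) != list(self.values.columns):
            raise ValueError("similarity matrix ids must match on rows and columns")

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)


def tanimoto_matrix(compounds: CompoundSet, radius: int = 2, nbits: int = 2048) -> SimilarityMatrix:
    """Pairwise Tanimoto similarity of hashed Morgan fingerprints."""
    if len(compounds) < 2:
        raise ValueError("need at least two compounds for a similarity matrix")
    gen = AllChem.GetMorganGenerator(radius=radius, fpSize=nbits)
    fps = [gen.GetFingerprint(r.mol()) for r in compounds]
    ids = [r.compound_id for r in compounds]
    n = len(fps)
    mat = np.eye(n)
    for i in range(n):
        if i + 1 < n:
            sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1:])
            mat[i, i + 1:] = sims
            mat[i + 1:, i] = sims
    return SimilarityMatrix(pd.DataFrame(mat, index=ids, columns=ids))
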