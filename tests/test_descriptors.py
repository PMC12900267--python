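import math

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.SpacialScore import SPS as reference_sps

import pnp_workbench as w
from pnp_workbench.io import CompoundRecord, CompoundSet


# ---------------------------------------------------------------------------
# descriptor table
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "smiles,names,expected",
    [
        ("c1ccccc1", ["heavy_atom_count", "ring_count"], (6.0, 1.0)),
        ("CCO", ["hbd_count", "hba_count"], (1.0, 1.0)),
        ("C1CC2CCC1CC2", ["ring_system_count", "ring_count"], (1.0, 3.0)),
    ],
)
def test_descriptor_values_forced_by_structure(smiles, names, expected):
    cs = CompoundSet([CompoundRecord("x", w.canonicalize_smiles(smiles))])
    table = w.descriptor_table(cs, names)
    assert tuple(table.values.loc["x"]) == expected


def test_default_panel_is_17_finite_values(toy_compounds):
    table = w.descriptor_table(toy_compounds)
    assert table.values.shape[1] == 17
    assert not table.failures
    assert np.isfinite(table.values.to_numpy()).all()


def test_unknown_descriptor_name_is_fatal(toy_compounds):
    with pytest.raises(ValueError, match="unknown descriptors.*nope"):
        w.descriptor_table(toy_compounds, ["nope"])


# ---------------------------------------------------------------------------
# QED
# ---------------------------------------------------------------------------

def test_qed_range_and_determinism(toy_compounds):
    vals = [w.qed(r.structure) for r in toy_compounds]
    assert all(0 < v <= 1 for v in vals)
    assert w.qed("CCO") == w.qed("CCO")


def test_qed_reference_value_aspirin():
    # frozen from the published QED parameterization's reference implementation
    assert w.qed("CC(=O)Oc1ccccc1C(=O)O") == pytest.approx(0.5501218, abs=1e-3)


# ---------------------------------------------------------------------------
# NP-likeness
# ---------------------------------------------------------------------------

def _one_cpd(smi, cid):
    return CompoundSet([CompoundRecord(cid, w.canonicalize_smiles(smi))])


def test_np_likeness_hand_enumerable_contributions():
    # np = ethanol, syn = propane; eps = 1 per set. A fragment present only in
    # np contributes log((1+1)/(0+1)) = log 2; shared fragments (the terminal
    # CH3 environment) contribute log(2/2) = 0; syn-only fragments -log 2.
    table = w.train_np_likeness(_one_cpd("CCO", "np1"), _one_cpd("CCC", "s1"))
    allowed = {round(math.log(2), 10), 0.0, round(-math.log(2), 10)}
    assert {round(v, 10) for v in table.contributions.values()} <= allowed
    assert any(v > 0 for v in table.contributions.values())  # oxygen environments
    assert any(v < 0 for v in table.contributions.values())


def test_np_likeness_antisymmetry_under_set_swap(toy_compounds):
    np_set = toy_compounds.subset("np_like")
    dr_set = toy_compounds.subset("drug_like")
    fwd = w.train_np_likeness(np_set, dr_set)
    rev = w.train_np_likeness(dr_set, np_set)
    assert set(fwd.contributions) == set(rev.contributions)
    for k, v in fwd.contributions.items():
        assert rev.contributions[k] == pytest.approx(-v, abs=1e-12)


def test_np_likeness_zero_and_clip():
    table = w.FragmentScoreTable(contributions={}, radius=2, n_np=1, n_synthetic=1)
    assert w.np_likeness("CCO", table) == 0.0  # all fragments unknown -> 0
    mol = Chem.MolFromSmiles("C")
    frags = AllChem.GetMorganGenerator(radius=2).GetSparseCountFingerprint(mol)
    fid = next(iter(frags.GetNonzeroElements()))
    huge = w.FragmentScoreTable({fid: 1000.0}, radius=2, n_np=1, n_synthetic=1)
    assert w.np_likeness("C", huge) == 5.0  # clipped


def test_np_likeness_separates_generated_classes(toy_compounds):
    np_set = toy_compounds.subset("np_like")
    dr_set = toy_compounds.subset("drug_like")
    table = w.train_np_likeness(np_set, dr_set)
    np_scores = [w.np_likeness(r.structure, table) for r in np_set]
    dr_scores = [w.np_likeness(r.structure, table) for r in dr_set]
    assert np.mean(np_scores) > np.mean(dr_scores)


def test_np_likeness_training_rejects_overlap_and_empty(toy_compounds):
    np_set = toy_compounds.subset("np_like")
    with pytest.raises(ValueError, match="share"):
        w.train_np_likeness(np_set, np_set)
    with pytest.raises(ValueError, match="non-empty"):
        w.train_np_likeness(np_set, CompoundSet([]))


# ---------------------------------------------------------------------------
# spatial score
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "smiles,sps_val,nsps_val",
    [("CC", 6.0, 3.0), ("c1ccccc1", 48.0, 8.0), ("C1CCCCC1", 144.0, 24.0)],
)
def test_sps_hand_computed_anchors(smiles, sps_val, nsps_val):
    assert w.sps(smiles) == sps_val
    assert w.nsps(smiles) == nsps_val


def _random_molecules(n=120):
    rng = np.random.default_rng(0)
    frags = [
        "CC", "CCO", "c1ccccc1", "C1CCCCC1", "CC(C)C", "C1CCNCC1", "CC=CC",
        "C1CC1", "c1ccncc1", "CC(N)C(=O)O", "C1CCOC1", "CC(C)(C)C", "C/C=C/C",
        "N#CC", "O=S(=O)(N)c1ccccc1", "C[C@H](O)[C@@H](N)C",
        "OC1CCC2CCCCC2C1", "CC1=CC(=O)CC(C)(C)C1", "CN1CCC2(c3ccccc3)CCCC12",
    ]
    out = []
    while len(out) < n:
        a, b = rng.choice(frags, 2)
        smi = a if len(out) % 3 else f"{a}.{b}"
        canon = w.canonicalize_smiles(smi)
        if canon:
            out.append(canon)
    return out


def test_sps_matches_independent_reference_on_many_molecules():
    mols = _random_molecules(120)
    for smi in mols:
        ref = reference_sps(Chem.MolFromSmiles(smi), normalize=False)
        assert w.sps(smi) == ref, smi


def test_nsps_is_sps_over_heavy_atoms(toy_compounds):
    for r in toy_compounds:
        heavy = Chem.MolFromSmiles(r.structure).GetNumHeavyAtoms()
        assert w.nsps(r.structure) == pytest.approx(w.sps(r.structure) / heavy, abs=1e-12)


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def test_shape_limit_cases_from_moments():
    rod = w.ShapeDescriptor.from_moments(0.0, 1.0, 1.0)  # linear rotor: I1=0, I2=I3
    assert rod.npr1 == pytest.approx(0.0) and rod.npr2 == pytest.approx(1.0)
    assert rod.shape_class == "rod"
    disc = w.ShapeDescriptor.from_moments(1.0, 1.0, 2.0)  # flat ring: I3=I1+I2
    assert disc.npr1 == pytest.approx(0.5) and disc.npr2 == pytest.approx(0.5)
    assert disc.shape_class == "disc"
    sphere = w.ShapeDescriptor.from_moments(1.0, 1.0, 1.0)
    assert sphere.shape_class == "sphere"


def test_shape_invariants_hold_for_embedded_molecules():
    for smi in ["CCCCCCCC", "c1ccc2ccccc2c1", "CC(C)(C)C", "C1CCCCC1"]:
        sd = w.shape_descriptor(smi, seed=11)
        assert 0 <= sd.npr1 <= sd.npr2 <= 1
        assert sd.npr1 + sd.npr2 >= 1 - 1e-9


def test_shape_embedding_failure_is_reported():
    with pytest.raises(ValueError, match="unparseable"):
        w.shape_descriptor("notasmiles")


# ---------------------------------------------------------------------------
# Tanimoto
# ---------------------------------------------------------------------------

def test_tanimoto_matrix_identity_symmetry_and_bitset_oracle():
    cs = CompoundSet(
        [
            CompoundRecord("m", "C"),
            CompoundRecord("b", "c1ccccc1"),
            CompoundRecord("b2", "c1ccccc1C"),
        ]
    )
    mat = w.tanimoto_matrix(cs).values
    assert np.allclose(mat, mat.T)
    assert np.all(np.diag(mat) == 1.0)
    # explicit bit-set enumeration oracle
    gen = AllChem.GetMorganGenerator(radius=2, fpSize=2048)
    bits = [set(gen.GetFingerprint(Chem.MolFromSmiles(s)).GetOnBits()) for s in ["C", "c1ccccc1"]]
    expected = len(bits[0] & bits[1]) / len(bits[0] | bits[1]) if bits[0] | bits[1] else 0.0
    assert mat.loc["m", "b"] == pytest.approx(expected)
    assert expected == 0.0  # methane and benzene share no environment


def test_tanimoto_identical_structures_score_one():
    # same structure under two labels is allowed and must score 1.0
    cs = CompoundSet([CompoundRecord("a", "CCO", "np"), CompoundRecord("b", "CCO", "drug")])
    assert w.tanimoto_matrix(cs).values.loc["a", "b"] == 1.0
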