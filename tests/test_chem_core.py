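"""Structure parsing, fingerprints, descriptors, similarity and features."""

import numpy as np
import pytest
from rdkit import Chem

from augscreen.chem_core import (
    Fingerprint,
    FingerprintKind,
    InvalidStructureError,
    Molecule,
    build_feature_matrix,
    compute_descriptors,
    compute_fingerprint,
    parse_and_canonicalize,
    read_molecule_table,
    tanimoto,
)
from augscreen.synthetic_data import make_decoy_pool

# canonical SMILES frozen from the capsaicin structure (derived from its
# IUPAC name: (E)-N-[(4-hydroxy-3-methoxyphenyl)methyl]-8-methylnon-6-enamide)
CAPSAICIN_CANONICAL = "COc1cc(CNC(=O)CCCC/C=C/C(C)C)ccc1O"


class TestParseAndCanonicalize:
    def test_same_molecule_two_writings(self):
        assert parse_and_canonicalize("OCC") == parse_and_canonicalize("CCO")
        assert parse_and_canonicalize("OCC").smiles == parse_and_canonicalize("CCO").smiles

    def test_idempotent(self):
        m = parse_and_canonicalize("c1ccccc1CC(=O)O")
        assert parse_and_canonicalize(m.smiles).smiles == m.smiles

    @pytest.mark.parametrize("bad", ["C1CC", "C(C)(C)(C)(C)C", "", "not-a-smiles"])
    def test_invalid_structures_raise(self, bad):
        with pytest.raises(InvalidStructureError):
            parse_and_canonicalize(bad)

    def test_error_names_offending_input(self):
        with pytest.raises(InvalidStructureError, match="C1CC"):
            parse_and_canonicalize("C1CC")

    def test_capsaicin_canonical_is_stable(self):
        m = parse_and_canonicalize("O=C(NCc1ccc(O)c(OC)c1)CCCC/C=C/C(C)C")
        assert m.smiles == CAPSAICIN_CANONICAL

    def test_idempotence_over_generated_structures(self, family):
        pool = family + make_decoy_pool(family, n=1000 - len(family), rng_seed=9)
        assert len(pool) == 1000
        for m in pool:
            assert parse_and_canonicalize(m.smiles).smiles == m.smiles


class TestReadMoleculeTable:
    def test_smiles_file_order_preserving(self, tmp_path):
        p = tmp_path / "three.smi"
        p.write_text("CCO\tm1\nc1ccccc1\tm2\nCC(=O)O\tm3\n")
        mols = read_molecule_table(p)
        assert [m.id for m in mols] == ["m1", "m2", "m3"]

    def test_csv_with_one_bad_record(self, tmp_path, caplog):
        lines = ["id,smiles"] + [f"m{i},{'C' * (i + 1)}" for i in range(9)] + ["bad,C1CC"]
        p = tmp_path / "mols.csv"
        p.write_text("\n".join(lines) + "\n")
        with caplog.at_level("WARNING"):
            mols = read_molecule_table(p)
        assert len(mols) == 9
        assert any("C1CC" in rec.message for rec in caplog.records)

    def test_all_invalid_file_is_error(self, tmp_path):
        p = tmp_path / "bad.smi"
        p.write_text("C1CC\nxx\n")
        with pytest.raises(InvalidStructureError):
            read_molecule_table(p)

    def test_ten_compound_fixture(self, ten_compounds):
        assert len(ten_compounds) == 10
        names = [m.name for m in ten_compounds]
        assert names[0] == "Yakuchinone A"
        assert names[-1] == "Nonivamide"
        assert "Alpinoid D" in names and "Capsaicin" in names


class TestFingerprints:
    def test_deterministic(self):
        m = parse_and_canonicalize("CCO")
        assert compute_fingerprint(m) == compute_fingerprint(m)
        assert compute_fingerprint(m, "MACCS") == compute_fingerprint(m, "MACCS")

    def test_benzene_maccs_aromatic_no_halogen(self):
        benzene = compute_fingerprint(parse_and_canonicalize("c1ccccc1"), "MACCS")
        fluorobenzene = compute_fingerprint(parse_and_canonicalize("Fc1ccccc1"), "MACCS")
        # MACCS key 162 is the aromatic-atom key, 134 the halogen key
        # (stored indices are key-1 after dropping the unused bit 0)
        assert 162 - 1 in benzene.bits
        assert 134 - 1 not in benzene.bits
        assert 134 - 1 in fluorobenzene.bits

    def test_methane_ecfp_single_environment(self):
        fp = compute_fingerprint(parse_and_canonicalize("C"))
        assert len(fp.bits) <= 1

    def test_invariant_to_atom_order(self, ten_compounds, rng):
        for m in ten_compounds:
            ref_ecfp = compute_fingerprint(m)
            ref_maccs = compute_fingerprint(m, "MACCS")
            rdmol = m.to_rdkit()
            n = rdmol.GetNumAtoms()
            for _ in range(20):
                perm = rng.permutation(n).tolist()
                renum = Chem.RenumberAtoms(rdmol, perm)
                shuffled = Chem.MolToSmiles(renum, canonical=False)
                m2 = parse_and_canonicalize(shuffled)
                assert compute_fingerprint(m2) == ref_ecfp
                assert compute_fingerprint(m2, "MACCS") == ref_maccs

    def test_bit_index_bound_enforced(self):
        with pytest.raises(ValueError):
            Fingerprint(FingerprintKind.ECFP, frozenset({2048}), 2048)


class TestDescriptors:
    def test_water_conventions(self):
        d = compute_descriptors(parse_and_canonicalize("O"))
        assert d.mw == pytest.approx(18.02, abs=0.01)
        assert d.hbd == 1
        assert d.rotb == 0

    def test_ethane_terminal_bond_not_rotatable(self):
        assert compute_descriptors(parse_and_canonicalize("CC")).rotb == 0

    def test_capsaicin_mass(self):
        d = compute_descriptors(parse_and_canonicalize(CAPSAICIN_CANONICAL))
        assert d.mw == pytest.approx(305.4, abs=0.1)  # C18H27NO3


class TestTanimoto:
    def test_hand_example(self):
        a = Fingerprint(FingerprintKind.ECFP, frozenset({1, 2, 3}), 2048)
        b = Fingerprint(FingerprintKind.ECFP, frozenset({2, 3, 4}), 2048)
        assert tanimoto(a, b) == 0.5

    def test_identical_and_disjoint(self):
        a = Fingerprint(FingerprintKind.ECFP, frozenset({5, 9}), 2048)
        b = Fingerprint(FingerprintKind.ECFP, frozenset({7, 8}), 2048)
        assert tanimoto(a, a) == 1.0
        assert tanimoto(a, b) == 0.0

    def test_kind_mismatch_raises(self):
        a = Fingerprint(FingerprintKind.ECFP, frozenset({1}), 2048)
        b = Fingerprint(FingerprintKind.MACCS, frozenset({1}), 166)
        with pytest.raises(ValueError):
            tanimoto(a, b)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(100):
            xa = frozenset(rng.choice(256, size=rng.integers(0, 60), replace=False).tolist())
            xb = frozenset(rng.choice(256, size=rng.integers(1, 60), replace=False).tolist())
            a = Fingerprint(FingerprintKind.ECFP, xa, 256)
            b = Fingerprint(FingerprintKind.ECFP, xb, 256)
            inter = sum(1 for i in range(256) if i in xa and i in xb)
            union = sum(1 for i in range(256) if i in xa or i in xb)
            expected = inter / union if union else 1.0
            assert tanimoto(a, b) == expected


class TestFeatureMatrix:
    def test_standardization_and_roundtrip(self, family):
        mols = family[:100]
        fm = build_feature_matrix(mols)
        nonconst = fm.raw.std(axis=0) > 0
        assert np.abs(fm.X[:, nonconst].mean(axis=0)).max() < 1e-9
        assert np.abs(fm.X[:, nonconst].std(axis=0) - 1).max() < 1e-9
        # constant columns map to zero, no division failure
        assert np.abs(fm.X[:, ~nonconst]).max() == 0
        # stored scaler transforms held-out rows without refitting; inverse recovers raw
        held_out = family[100:110]
        fm2 = build_feature_matrix(held_out, scaler=fm.scaler)
        back = fm.scaler.inverse_transform(fm2.X)
        assert np.abs(back - fm2.raw).max() < 1e-9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_feature_matrix([])

    def test_layout_mismatch_rejected(self, family):
        fm = build_feature_matrix(family[:5], ecfp_nbits=2048)
        with pytest.raises(ValueError, match="column-layout"):
            build_feature_matrix(family[5:8], scaler=fm.scaler, ecfp_nbits=1024)
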