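"""Analog growth, curation, decoy construction and training-set assembly."""

import numpy as np
import pytest
from rdkit import Chem

from augscreen.augmentation import (
    AugmentationConfig,
    CurationPolicy,
    DecoyConfig,
    DecoyPool,
    DecoyPoolExhaustedError,
    Fragment,
    LabeledDataset,
    assemble_training_set,
    curate_generated,
    generate_decoys,
    grow_analogs,
    load_fragment_library,
)
from augscreen.chem_core import (
    Molecule,
    compute_descriptors,
    compute_fingerprint,
    parse_and_canonicalize,
    tanimoto,
)
from augscreen.synthetic_data import make_decoy_pool


@pytest.fixture(scope="module")
def seed_molecule(family):
    return Molecule(id="seed1", smiles=family[0].smiles, source="seed")


@pytest.fixture(scope="module")
def grown_analogs(seed_molecule):
    cfg = AugmentationConfig(n_per_seed_min=60, n_per_seed_max=80, runs=30, rng_seed=7)
    return grow_analogs(seed_molecule, cfg)


class TestFragmentLibrary:
    def test_builtin_loads_with_attachment_points(self):
        frags = load_fragment_library()
        assert len(frags) >= 200
        for f in frags[:20]:
            mol = f.to_rdkit()
            assert sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0) == 1

    def test_malformed_fragment_rejected(self, tmp_path):
        p = tmp_path / "frags.smi"
        p.write_text("CC\tno_attachment\n")
        with pytest.raises(ValueError, match="attachment"):
            load_fragment_library(p)


class TestGrowAnalogs:
    def test_phenol_with_single_methyl_fragment(self):
        phenol = parse_and_canonicalize("Oc1ccccc1", id="phenol", source="seed")
        lib = [Fragment(smiles="[*]C", name="methyl")]
        cfg = AugmentationConfig(
            n_per_seed_min=1, n_per_seed_max=50, optimization_steps=50, runs=10,
            similarity_window=(0.05, 1.0), fragment_library=lib, rng_seed=0,
        )
        analogs = grow_analogs(phenol, cfg)
        query = Chem.MolFromSmiles("Oc1ccccc1")
        assert analogs  # at least one methylated product
        for a in analogs:
            assert a.to_rdkit().HasSubstructMatch(query)

    def test_analogs_are_valid_distinct_and_contain_seed(self, seed_molecule, grown_analogs):
        smiles = [a.smiles for a in grown_analogs]
        assert len(set(smiles)) == len(smiles)
        query = Chem.MolFromSmiles(seed_molecule.smiles)
        for a in grown_analogs:
            mol = a.to_rdkit()
            assert mol is not None
            assert mol.HasSubstructMatch(query)

    def test_count_within_configured_bounds(self, seed_molecule):
        cfg = AugmentationConfig(rng_seed=3)  # defaults: 200-300 per seed
        analogs = grow_analogs(seed_molecule, cfg)
        assert 200 <= len(analogs) <= 300

    def test_deterministic_under_seed(self, seed_molecule):
        cfg = AugmentationConfig(n_per_seed_min=20, n_per_seed_max=30, runs=10, rng_seed=11)
        a = [m.smiles for m in grow_analogs(seed_molecule, cfg)]
        b = [m.smiles for m in grow_analogs(seed_molecule, cfg)]
        assert a == b

    def test_empty_fragment_library_rejected(self, seed_molecule):
        with pytest.raises(ValueError):
            grow_analogs(seed_molecule, AugmentationConfig(fragment_library=[]))

    def test_mw_cap_respected(self, seed_molecule, grown_analogs):
        from rdkit.Chem import Descriptors

        for a in grown_analogs:
            assert Descriptors.MolWt(a.to_rdkit()) <= 600.0


class TestCuration:
    def test_duplicates_collapse(self, seed_molecule, grown_analogs):
        doubled = list(grown_analogs) + list(grown_analogs)
        policy = CurationPolicy(seed_similarity_window=(0.0, 1.0))
        result = curate_generated(doubled, policy, seed_molecule)
        assert len(result) == len(grown_analogs)
        assert result.report["duplicate"] == len(grown_analogs)

    def test_near_duplicate_rejected_by_similarity_window(self, seed_molecule):
        near_dup = Molecule(id="dup", smiles=seed_molecule.smiles, source="generated")
        policy = CurationPolicy(seed_similarity_window=(0.4, 0.95))
        result = curate_generated([near_dup], policy, seed_molecule)
        assert len(result) == 0
        assert result.report["similarity_window"] == 1

    def test_planted_alert_rejections_counted_exactly(self, seed_molecule, grown_analogs):
        clean = list(grown_analogs)[:50]
        # plant 10 nitroaromatic offenders (distinct chain lengths)
        offenders = []
        for i in range(10):
            mol = Chem.MolFromSmiles("O=[N+]([O-])c1ccc(" + "C" * (i + 2) + ")cc1")
            assert mol is not None
            offenders.append(Molecule(id=f"nitro{i}", smiles=Chem.MolToSmiles(mol), source="generated"))
        policy = CurationPolicy(
            alert_smarts=[("a[N+](=O)[O-]", "nitroaromatic")],
            seed_similarity_window=(0.0, 1.0),
        )
        result = curate_generated(clean + offenders, policy, seed_molecule)
        assert result.report["alert"] == 10
        assert len(result) == 50

    def test_monotone_under_nested_policies(self, seed_molecule, grown_analogs):
        windows = [(0.5, 0.8), (0.45, 0.9), (0.4, 0.95)]
        sizes = []
        for w in windows:
            policy = CurationPolicy(seed_similarity_window=w)
            sizes.append(len(curate_generated(grown_analogs, policy, seed_molecule)))
        assert sizes == sorted(sizes)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            CurationPolicy(seed_similarity_window=(0.9, 0.4))


class TestDecoys:
    @pytest.fixture(scope="class")
    def pool_and_active(self, family):
        active = family[0]
        pool_mols = make_decoy_pool(family[:30], n=1000, rng_seed=5)
        return DecoyPool(pool_mols), active

    def test_exactly_k_decoys(self, pool_and_active):
        pool, active = pool_and_active
        cfg = DecoyConfig(k_per_active=50, rng_seed=0)
        decoys = generate_decoys(active, cfg, pool=pool)
        assert len(decoys) == 50
        assert all(d.source == "decoy" for d in decoys)

    def test_active_itself_never_selected(self, family):
        active = family[0]
        pool_mols = make_decoy_pool(family[:30], n=200, rng_seed=5) + [active]
        pool = DecoyPool(pool_mols)
        decoys = pool.select(active, DecoyConfig(k_per_active=20))
        assert active.smiles not in {d.smiles for d in decoys}

    def test_constraints_verified_by_brute_force(self, pool_and_active):
        pool, active = pool_and_active
        cfg = DecoyConfig(k_per_active=50, rng_seed=0)
        decoys = generate_decoys(active, cfg, pool=pool)
        # independent re-check of both constraints over the pool
        desc = np.array([compute_descriptors(m).to_array() for m in pool.pool])
        mu, sd = desc.mean(axis=0), desc.std(axis=0)
        sd[sd == 0] = 1.0
        a_z = (compute_descriptors(active).to_array() - mu) / sd
        a_fp = compute_fingerprint(active)
        for d in decoys:
            d_z = (compute_descriptors(d).to_array() - mu) / sd
            assert np.linalg.norm(d_z - a_z) <= cfg.property_tolerance + 1e-9
            assert tanimoto(a_fp, compute_fingerprint(d)) < cfg.max_similarity

    def test_pool_exhaustion_reports_counts(self, pool_and_active):
        pool, active = pool_and_active
        with pytest.raises(DecoyPoolExhaustedError, match="satisfy"):
            pool.select(active, DecoyConfig(k_per_active=50, property_tolerance=1e-6))

    def test_deterministic(self, pool_and_active):
        pool, active = pool_and_active
        cfg = DecoyConfig(k_per_active=25, rng_seed=3)
        assert [d.id for d in pool.select(active, cfg)] == [d.id for d in pool.select(active, cfg)]


class TestAssembly:
    def _decoy_sets(self, actives, pool_mols, k=5):
        pool = DecoyPool(pool_mols)
        cfg = DecoyConfig(k_per_active=k, property_tolerance=50.0, max_similarity=0.9)
        return {a.id: pool.select(a, cfg) for a in actives}

    def test_single_active_gives_two_rows(self, family):
        actives = [family[0]]
        pool_mols = make_decoy_pool(family[:30], n=50, rng_seed=2)
        ds = assemble_training_set(actives, self._decoy_sets(actives, pool_mols), rng_seed=0)
        assert len(ds) == 2
        assert ds.class_counts == (1, 1)

    def test_balance_and_no_duplicates(self, family):
        actives = family[:40]
        pool_mols = make_decoy_pool(actives, n=400, rng_seed=2)
        ds = assemble_training_set(actives, self._decoy_sets(actives, pool_mols, k=10), rng_seed=1)
        n0, n1 = ds.class_counts
        assert n0 == n1 == 40
        assert len({m.smiles for m in ds.molecules}) == len(ds)

    def test_reproducible_and_seed_sensitive(self, family):
        actives = family[:20]
        pool_mols = make_decoy_pool(actives, n=300, rng_seed=2)
        sets_ = self._decoy_sets(actives, pool_mols, k=10)
        a = [m.id for m in assemble_training_set(actives, sets_, rng_seed=5).molecules]
        b = [m.id for m in assemble_training_set(actives, sets_, rng_seed=5).molecules]
        c = [m.id for m in assemble_training_set(actives, sets_, rng_seed=6).molecules]
        assert a == b
        assert a != c

    def test_missing_decoy_set_raises(self, family):
        with pytest.raises(KeyError, match="missing decoy set"):
            assemble_training_set([family[0]], {}, rng_seed=0)
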