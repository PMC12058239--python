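"""Active-set augmentation: fragment growth from seeds, curation, decoys.

The training problem starts from a handful of seed activators — far too few
to train a classifier.  This module enlarges the active class by *growing*
structural analogs of each seed (attaching library fragments at hydrogen
positions, accepting moves that keep the analog inside a Tanimoto window
around the seed), curates the generated pool (validity, duplicates,
structural alerts, property and similarity windows), builds per-active
property-matched/topology-dissimilar decoy sets, and assembles the balanced
1:1 labeled training set.
"""

from __future__ import annotations

import logging
import random
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors
from sklearn.preprocessing import StandardScaler

from .chem_core import (
    FingerprintKind,
    Molecule,
    compute_descriptors,
    compute_fingerprint,
    parse_and_canonicalize,
    tanimoto,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Fragment library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fragment:
    """A growth fragment: a structure with exactly one attachment point ``[*]``."""

    smiles: str
    name: str

    def to_rdkit(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


def load_fragment_library(path: str | Path | None = None) -> list[Fragment]:
    """Load a fragment library (built-in if ``path`` is None).

    Format: ``smiles_with_[*]<TAB>name`` per line; '#' comments allowed.
    """
    if path is None:
        text = resources.files("augscreen.data").joinpath("fragments.smi").read_text()
    else:
        text = Path(path).read_text()
    frags: list[Fragment] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smi = parts[0]
        name = parts[1] if len(parts) > 1 else smi
        mol = Chem.MolFromSmiles(smi)
        if mol is None or sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0) != 1:
            raise ValueError(f"malformed fragment (needs exactly one [*]): {line!r}")
        frags.append(Fragment(smiles=smi, name=name))
    if not frags:
        raise ValueError("empty fragment library")
    return frags


def _attach(host: Chem.Mol, atom_idx: int, fragment: Chem.Mol) -> Chem.Mol | None:
    """Bond a fragment's attachment neighbor to ``host`` atom ``atom_idx``.

    Returns the sanitized product, or None if the attachment is chemically
    invalid (no spare hydrogen, hetero-hetero single bond, sanitize failure).
    """
    host_atom = host.GetAtomWithIdx(atom_idx)
    if host_atom.GetTotalNumHs() < 1:
        return None
    dummy_idx = next(a.GetIdx() for a in fragment.GetAtoms() if a.GetAtomicNum() == 0)
    frag_attach = fragment.GetAtomWithIdx(dummy_idx).GetNeighbors()[0]
    # avoid creating O-O / N-N / O-N etc. single bonds (alert-prone)
    if host_atom.GetAtomicNum() not in (6,) and frag_attach.GetAtomicNum() not in (6,):
        return None
    combined = Chem.RWMol(Chem.CombineMols(host, fragment))
    offset = host.GetNumAtoms()
    combined.AddBond(atom_idx, offset + frag_attach.GetIdx(), Chem.BondType.SINGLE)
    combined.RemoveAtom(offset + dummy_idx)
    try:
        product = combined.GetMol()
        Chem.SanitizeMol(product)
    except Exception:
        return None
    return product


# ---------------------------------------------------------------------------
# Analog growth
# ---------------------------------------------------------------------------

@dataclass
class AugmentationConfig:
    """Controls the per-seed analog generator.

    ``runs`` independent growth chains are started from the seed; each chain
    performs ``optimization_steps`` accept/reject moves (attach a random
    fragment at a random hydrogen position; accept when the analog's
    Tanimoto to the seed stays inside ``similarity_window``).  Every accepted
    state is a candidate analog; growth stops once the per-seed target
    (drawn uniformly from [n_per_seed_min, n_per_seed_max]) is reached.
    ``context_radius`` is the Morgan radius of the environment fingerprint
    used to judge whether a grown analog still complies with the seed — a
    conservative radius of 3 makes acceptance sensitive to three-bond
    contexts around every atom.
    """

    n_per_seed_min: int = 200
    n_per_seed_max: int = 300
    optimization_steps: int = 200
    runs: int = 100
    context_radius: int = 3
    similarity_window: tuple[float, float] = (0.4, 0.95)
    max_mw: float = 600.0  # growth moves never exceed this molecular weight
    fragment_library: list[Fragment] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_seed_min > self.n_per_seed_max:
            raise ValueError("n_per_seed_min must be <= n_per_seed_max")
        if self.context_radius < 0:
            raise ValueError("context_radius must be >= 0")


def _eligible_positions(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1 and a.GetAtomicNum() > 1]


def grow_analogs(seed: Molecule, cfg: AugmentationConfig) -> list[Molecule]:
    """Generate structural analogs of ``seed`` by iterative fragment growth.

    Every returned molecule is valid, distinct after canonicalization,
    contains the seed structure as a substructure, and lies inside the
    configured similarity window.  Deterministic under ``cfg.rng_seed``.
    """
    fragments = cfg.fragment_library if cfg.fragment_library is not None else load_fragment_library()
    if not fragments:
        raise ValueError("empty fragment library")
    seed_mol = seed.to_rdkit()
    if not _eligible_positions(seed_mol):
        raise ValueError(f"seed {seed.id} has no growth points (no spare hydrogens)")
    frag_mols = [(f, f.to_rdkit()) for f in fragments]
    # acceptance similarity uses Morgan environments of radius context_radius
    from rdkit.Chem import rdFingerprintGenerator

    ctx_gen = rdFingerprintGenerator.GetMorganGenerator(radius=cfg.context_radius, fpSize=2048)

    def ctx_fp(mol: Chem.Mol) -> frozenset[int]:
        return frozenset(ctx_gen.GetFingerprint(mol).GetOnBits())

    def ctx_tanimoto(a: frozenset[int], b: frozenset[int]) -> float:
        union = len(a | b)
        return len(a & b) / union if union else 1.0

    seed_fp = ctx_fp(seed_mol)
    seed_query = Chem.MolFromSmiles(seed.smiles)
    lo, hi = cfg.similarity_window

    rng = random.Random(cfg.rng_seed)
    target = rng.randint(cfg.n_per_seed_min, cfg.n_per_seed_max)
    analogs: dict[str, Molecule] = {}

    for run in range(cfg.runs):
        current = seed_mol
        for _ in range(cfg.optimization_steps):
            if len(analogs) >= target:
                break
            positions = _eligible_positions(current)
            if not positions:
                break
            pos = rng.choice(positions)
            _, frag = frag_mols[rng.randrange(len(frag_mols))]
            candidate = _attach(current, pos, frag)
            if candidate is None:
                continue
            if Descriptors.MolWt(candidate) > cfg.max_mw:
                continue  # keep analogs in a lead-like mass range
            sim = ctx_tanimoto(seed_fp, ctx_fp(candidate))
            if not (lo <= sim <= hi):
                continue  # reject: outside the seed-similarity window
            current = candidate
            smi = Chem.MolToSmiles(candidate)
            if smi not in analogs and candidate.HasSubstructMatch(seed_query):
                analogs[smi] = Molecule(
                    id=f"{seed.id}:a{len(analogs) + 1}", smiles=smi,
                    name=None, source="generated",
                )
        if len(analogs) >= target:
            break

    if len(analogs) < cfg.n_per_seed_min:
        logger.warning(
            "seed %s: combinatorial space yielded %d analogs (< %d requested)",
            seed.id, len(analogs), cfg.n_per_seed_min,
        )
    return list(analogs.values())


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

@dataclass
class CurationPolicy:
    """Filters applied to generated analogs before they become training actives."""

    alert_smarts: list[tuple[str, str]] = field(default_factory=list)  # (pattern, name)
    seed_similarity_window: tuple[float, float] = (0.4, 0.95)
    property_window: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.seed_similarity_window
        if not (0 <= lo < hi <= 1):
            raise ValueError("seed_similarity_window must satisfy 0 <= low < high <= 1")


@dataclass
class CurationResult:
    """Curation survivors plus a tally of rejection reasons."""

    molecules: list[Molecule]
    report: Counter

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self):
        return iter(self.molecules)


def curate_generated(mols: Sequence[Molecule], policy: CurationPolicy, seed: Molecule) -> CurationResult:
    """Apply validity, duplicate, alert, property-window and similarity-window
    filters; survivors are a subset of the input, duplicate-free."""
    seed_fp = compute_fingerprint(seed, FingerprintKind.ECFP)
    alert_patterns = [(Chem.MolFromSmarts(p), name) for p, name in policy.alert_smarts]
    for pat, name in alert_patterns:
        if pat is None:
            raise ValueError(f"malformed alert SMARTS: {name}")
    lo, hi = policy.seed_similarity_window
    survivors: list[Molecule] = []
    seen: set[str] = set()
    report: Counter = Counter()
    for m in mols:
        rdmol = Chem.MolFromSmiles(m.smiles)
        if rdmol is None:
            report["invalid"] += 1
            continue
        if m.smiles in seen:
            report["duplicate"] += 1
            continue
        seen.add(m.smiles)
        if any(rdmol.HasSubstructMatch(pat) for pat, _ in alert_patterns):
            report["alert"] += 1
            continue
        if policy.property_window:
            desc = compute_descriptors(rdmol)
            values = dict(zip(
                ("mw", "clogp", "tpsa", "hbd", "hba", "rotb", "aromatic_rings"), desc.to_array()
            ))
            violated = False
            for key, (pl, ph) in policy.property_window.items():
                if not (pl <= values[key] <= ph):
                    violated = True
                    break
            if violated:
                report["property_window"] += 1
                continue
        sim = tanimoto(seed_fp, compute_fingerprint(rdmol, FingerprintKind.ECFP))
        if not (lo <= sim <= hi):
            report["similarity_window"] += 1
            continue
        survivors.append(m)
        report["kept"] += 1
    return CurationResult(molecules=survivors, report=report)


# ---------------------------------------------------------------------------
# Decoys
# ---------------------------------------------------------------------------

class DecoyPoolExhaustedError(RuntimeError):
    """Raised when fewer candidates satisfy the decoy constraints than requested."""


@dataclass
class DecoyConfig:
    """Decoy selection: property-matched, topology-dissimilar pool members.

    ``property_tolerance`` is a Euclidean distance over the seven Z-scored
    descriptors (standardized on the candidate pool); ``max_similarity`` is a
    strict ECFP Tanimoto ceiling against the active.
    """

    k_per_active: int = 50
    property_tolerance: float = 3.0
    max_similarity: float = 0.30
    candidate_pool: list[Molecule] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k_per_active < 1:
            raise ValueError("k_per_active must be >= 1")
        if not (0 < self.max_similarity < 1):
            raise ValueError("max_similarity must lie in (0, 1)")


class DecoyPool:
    """A candidate pool with precomputed descriptors and fingerprints.

    Reuse one instance across many actives: featurization of the pool is the
    dominant cost and is done once.
    """

    def __init__(self, pool: Sequence[Molecule]):
        if not pool:
            raise ValueError("empty decoy candidate pool")
        self.pool = list(pool)
        self._desc = np.array([compute_descriptors(m).to_array() for m in self.pool])
        self.scaler = StandardScaler().fit(self._desc)
        self._z = self.scaler.transform(self._desc)
        self._fps = [compute_fingerprint(m, FingerprintKind.ECFP) for m in self.pool]

    def select(self, active: Molecule, cfg: DecoyConfig) -> list[Molecule]:
        active_z = self.scaler.transform(compute_descriptors(active).to_array()[None, :])[0]
        active_fp = compute_fingerprint(active, FingerprintKind.ECFP)
        dist = np.linalg.norm(self._z - active_z, axis=1)
        candidates = []
        for i, m in enumerate(self.pool):
            if m.smiles == active.smiles:
                continue
            if dist[i] > cfg.property_tolerance:
                continue
            if tanimoto(active_fp, self._fps[i]) >= cfg.max_similarity:
                continue
            candidates.append((dist[i], m.id, i))
        if len(candidates) < cfg.k_per_active:
            raise DecoyPoolExhaustedError(
                f"active {active.id}: only {len(candidates)} of {len(self.pool)} pool candidates "
                f"satisfy the decoy constraints (need {cfg.k_per_active})"
            )
        candidates.sort()  # by property closeness, then id for determinism
        out = []
        for rank, (_, _, i) in enumerate(candidates[: cfg.k_per_active], start=1):
            src = self.pool[i]
            out.append(Molecule(id=src.id, smiles=src.smiles, name=src.name, source="decoy"))
        return out


def generate_decoys(active: Molecule, cfg: DecoyConfig, pool: DecoyPool | None = None) -> list[Molecule]:
    """Select exactly ``cfg.k_per_active`` decoys for one active.

    Each decoy satisfies the standardized-descriptor-distance and Tanimoto
    constraints; results are ranked by property closeness and deterministic.
    """
    if pool is None:
        if cfg.candidate_pool is None:
            raise ValueError("no candidate pool provided")
        pool = DecoyPool(cfg.candidate_pool)
    return pool.select(active, cfg)


# ---------------------------------------------------------------------------
# Training-set assembly
# ---------------------------------------------------------------------------

@dataclass
class LabeledDataset:
    """Molecules with binary labels (1 = activator, 0 = decoy/inactive)."""

    molecules: list[Molecule]
    labels: np.ndarray
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.molecules) != len(self.labels):
            raise ValueError("molecules and labels length mismatch")

    def __len__(self) -> int:
        return len(self.molecules)

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            molecules=[self.molecules[i] for i in indices],
            labels=self.labels[list(indices)],
            provenance=[self.provenance[i] for i in indices] if self.provenance else [],
        )

    @property
    def class_counts(self) -> tuple[int, int]:
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))


def assemble_training_set(
    actives: Sequence[Molecule],
    decoy_sets: dict[str, Sequence[Molecule]],
    rng_seed: int = 0,
) -> LabeledDataset:
    """Pair each active with one randomly chosen decoy from its decoy set.

    The result is exactly balanced: 2 x len(actives) rows, one decoy sampled
    per active, no duplicate structure across both classes.  Reproducible
    under ``rng_seed``.
    """
    rng = random.Random(rng_seed)
    mols: list[Molecule] = []
    labels: list[int] = []
    prov: list[dict] = []
    used: set[str] = set()
    for a in actives:
        if a.id not in decoy_sets:
            raise KeyError(f"missing decoy set for active {a.id}")
        if a.smiles in used:
            raise ValueError(f"duplicate active structure in assembly: {a.id}")
        used.add(a.smiles)
        mols.append(a)
        labels.append(1)
        prov.append({"role": "active", "seed": a.id.split(":")[0]})
    assigned: dict[str, Molecule] = {}  # active id -> decoy
    owner: dict[str, str] = {}  # decoy smiles -> active id
    for a in actives:
        choices = list(decoy_sets[a.id])
        rng.shuffle(choices)
        pick = next((d for d in choices if d.smiles not in used and d.smiles not in owner), None)
        if pick is None:
            # all of this active's decoys are taken: free one by moving its
            # current owner to an unused alternative (one-level repair)
            for d in choices:
                holder = owner.get(d.smiles)
                if holder is None:
                    continue
                alt = next(
                    (x for x in decoy_sets[holder]
                     if x.smiles not in used and x.smiles not in owner and x.smiles != d.smiles),
                    None,
                )
                if alt is not None:
                    assigned[holder] = alt
                    owner[alt.smiles] = holder
                    del owner[d.smiles]
                    pick = d
                    break
        if pick is None:
            raise ValueError(f"all decoys for active {a.id} duplicate existing rows")
        assigned[a.id] = pick
        owner[pick.smiles] = a.id
    for a in actives:
        d = assigned[a.id]
        mols.append(d)
        labels.append(0)
        prov.append({"role": "decoy", "decoy_of": a.id})
    return LabeledDataset(molecules=mols, labels=np.array(labels), provenance=prov)
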