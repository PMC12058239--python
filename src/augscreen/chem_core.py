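"""Molecular data model, structure I/O, fingerprints, descriptors and features.

Everything downstream of this module works with :class:`Molecule` objects
(canonical-SMILES value objects), bit-set :class:`Fingerprint` objects and
the seven-descriptor :class:`DescriptorVector`.  Feature matrices concatenate
the MACCS block, the ECFP block and the descriptor block in that fixed order
and are Z-score standardized with a scaler fitted on training rows only.

Conventions
-----------
* Canonicalization is RDKit's canonical SMILES (isomeric).
* MACCS keys: the 166 informative keys (RDKit's 167-bit vector with the
  unused bit 0 dropped, so stored indices run 0..165 for keys 1..166).
* ECFP: Morgan fingerprint of radius 2 hashed to ``nbits`` (default 2048).
* Descriptors: MW (Da), Crippen cLogP, TPSA (A^2), H-bond donors, H-bond
  acceptors, rotatable bonds (RDKit strict convention: single, non-ring,
  non-amide bonds between non-terminal heavy atoms), aromatic rings.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, MACCSkeys, rdFingerprintGenerator
from rdkit.Chem import Lipinski
from rdkit.Chem.rdMolDescriptors import (
    CalcNumAromaticRings,
    CalcNumRotatableBonds,
    CalcTPSA,
)
from sklearn.preprocessing import StandardScaler

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

DESCRIPTOR_NAMES = ("mw", "clogp", "tpsa", "hbd", "hba", "rotb", "aromatic_rings")


class InvalidStructureError(ValueError):
    """Raised when a SMILES string cannot be parsed into a valid structure."""


class FingerprintKind(str, Enum):
    MACCS = "MACCS"
    ECFP = "ECFP"


@dataclass(frozen=True)
class Molecule:
    """A canonicalized molecule with identity and provenance.

    Two molecules compare equal iff their canonical SMILES are equal; the id,
    name and source tag are carried metadata and do not affect equality.
    """

    id: str
    smiles: str
    name: str | None = None
    source: str = "library"  # seed | generated | decoy | library | fixture

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Molecule):
            return NotImplemented
        return self.smiles == other.smiles

    def __hash__(self) -> int:
        return hash(self.smiles)

    def to_rdkit(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:  # pragma: no cover - smiles is canonical by construction
            raise InvalidStructureError(f"stored SMILES no longer parses: {self.smiles!r}")
        return mol


@dataclass(frozen=True)
class Fingerprint:
    """A fingerprint as an ordered, duplicate-free set of set-bit indices."""

    kind: FingerprintKind
    bits: frozenset[int]
    nbits: int

    def __post_init__(self) -> None:
        if self.bits and max(self.bits) >= self.nbits:
            raise ValueError("bit index exceeds fingerprint length")

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.nbits, dtype=np.uint8)
        if self.bits:
            arr[sorted(self.bits)] = 1
        return arr


@dataclass(frozen=True)
class DescriptorVector:
    """The seven physicochemical properties used throughout the pipeline."""

    mw: float
    clogp: float
    tpsa: float
    hbd: int
    hba: int
    rotb: int
    aromatic_rings: int

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.mw, self.clogp, self.tpsa, self.hbd, self.hba, self.rotb, self.aromatic_rings],
            dtype=float,
        )


def parse_and_canonicalize(
    raw: str, *, id: str | None = None, name: str | None = None, source: str = "library"
) -> Molecule:
    """Parse a SMILES string and return a :class:`Molecule` with canonical SMILES.

    Raises
    ------
    InvalidStructureError
        if the string does not parse or violates valence rules; the message
        names the offending input.
    """
    if not raw or not raw.strip():
        raise InvalidStructureError("empty SMILES string")
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise InvalidStructureError(f"invalid structure: {raw!r}")
    canonical = Chem.MolToSmiles(mol)
    return Molecule(id=id if id is not None else canonical, smiles=canonical, name=name, source=source)


def _read_smiles_lines(path: Path, source: str) -> tuple[list[Molecule], list[tuple[int, str, str]]]:
    mols: list[Molecule] = []
    failures: list[tuple[int, str, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smi = parts[0].strip()
        mol_id = parts[1].strip() if len(parts) > 1 else f"{path.stem}:{lineno}"
        name = parts[2].strip() if len(parts) > 2 else (parts[1].strip() if len(parts) > 1 else None)
        try:
            mols.append(parse_and_canonicalize(smi, id=mol_id, name=name, source=source))
        except InvalidStructureError as exc:
            failures.append((lineno, smi, str(exc)))
    return mols, failures


def _read_csv(path: Path, source: str) -> tuple[list[Molecule], list[tuple[int, str, str]]]:
    mols: list[Molecule] = []
    failures: list[tuple[int, str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "smiles" not in [f.lower() for f in reader.fieldnames]:
            raise ValueError(f"{path}: CSV must declare a 'smiles' column (columns: id,smiles,name,label)")
        cols = {f.lower(): f for f in reader.fieldnames}
        for lineno, row in enumerate(reader, start=2):
            smi = (row.get(cols["smiles"]) or "").strip()
            mol_id = (row.get(cols.get("id", ""), "") or "").strip() or f"{path.stem}:{lineno}"
            name = (row.get(cols.get("name", ""), "") or "").strip() or None
            try:
                mols.append(parse_and_canonicalize(smi, id=mol_id, name=name, source=source))
            except InvalidStructureError as exc:
                failures.append((lineno, smi, str(exc)))
    return mols, failures


def _read_sdf(path: Path, source: str) -> tuple[list[Molecule], list[tuple[int, str, str]]]:
    mols: list[Molecule] = []
    failures: list[tuple[int, str, str]] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for idx, mol in enumerate(supplier):
        if mol is None:
            failures.append((idx + 1, "<record>", "unparseable SDF record"))
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"{path.stem}:{idx + 1}"
        mols.append(Molecule(id=mol_id, smiles=Chem.MolToSmiles(mol), name=mol_id, source=source))
    return mols, failures


def read_molecule_table(path: str | Path, format: str | None = None, *, source: str = "library") -> list[Molecule]:
    """Read molecules from a SMILES (.smi), CSV or SDF file, order-preserving.

    Per-record parse failures are logged with line numbers and skipped; a file
    in which every record fails raises :class:`InvalidStructureError`.
    Duplicate canonical SMILES are retained but flagged in the log.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("smi", "smiles", "txt"):
        mols, failures = _read_smiles_lines(path, source)
    elif fmt == "csv":
        mols, failures = _read_csv(path, source)
    elif fmt == "sdf":
        mols, failures = _read_sdf(path, source)
    else:
        raise ValueError(f"unsupported molecule table format: {fmt!r}")
    for lineno, smi, msg in failures:
        logger.warning("%s line %d: rejected %r (%s)", path, lineno, smi, msg)
    if not mols:
        raise InvalidStructureError(f"{path}: no valid structures (all {len(failures)} records failed)")
    seen: set[str] = set()
    for m in mols:
        if m.smiles in seen:
            logger.info("%s: duplicate structure retained: %s (%s)", path, m.id, m.smiles)
        seen.add(m.smiles)
    return mols


def write_molecule_table(path: str | Path, mols: Sequence[Molecule], labels: Sequence[int] | None = None) -> None:
    """Write molecules as CSV with columns id,smiles,name,source[,label]."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["id", "smiles", "name", "source"] + (["label"] if labels is not None else [])
        writer.writerow(header)
        for i, m in enumerate(mols):
            row = [m.id, m.smiles, m.name or "", m.source]
            if labels is not None:
                row.append(labels[i])
            writer.writerow(row)


_MORGAN_GENERATORS: dict[int, rdFingerprintGenerator.FingerprintGenerator64] = {}


def _morgan_generator(nbits: int) -> rdFingerprintGenerator.FingerprintGenerator64:
    if nbits not in _MORGAN_GENERATORS:
        _MORGAN_GENERATORS[nbits] = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=nbits)
    return _MORGAN_GENERATORS[nbits]


def compute_fingerprint(
    mol: Molecule | Chem.Mol, kind: FingerprintKind | str = FingerprintKind.ECFP, nbits: int = 2048
) -> Fingerprint:
    """Compute a MACCS (166 keys) or ECFP (radius 2, hashed) fingerprint.

    Deterministic per (canonical SMILES, kind, nbits) and invariant to the
    atom ordering of the input SMILES.
    """
    kind = FingerprintKind(kind)
    rdmol = mol.to_rdkit() if isinstance(mol, Molecule) else mol
    if kind is FingerprintKind.MACCS:
        bv = MACCSkeys.GenMACCSKeys(rdmol)  # 167 bits, bit 0 unused
        bits = frozenset(b - 1 for b in bv.GetOnBits() if b >= 1)
        return Fingerprint(kind=kind, bits=bits, nbits=166)
    bv = _morgan_generator(nbits).GetFingerprint(rdmol)
    return Fingerprint(kind=kind, bits=frozenset(bv.GetOnBits()), nbits=nbits)


# donor convention: any N/O/S heavy atom bearing at least one hydrogen
_HBD_QUERY = Chem.MolFromSmarts("[#7,#8,#16;!H0]")


def compute_descriptors(mol: Molecule | Chem.Mol) -> DescriptorVector:
    """Compute the seven-descriptor vector (MW, cLogP, TPSA, HBD, HBA, rotB, aromatic rings)."""
    rdmol = mol.to_rdkit() if isinstance(mol, Molecule) else mol
    return DescriptorVector(
        mw=Descriptors.MolWt(rdmol),
        clogp=Crippen.MolLogP(rdmol),
        tpsa=CalcTPSA(rdmol),
        hbd=len(rdmol.GetSubstructMatches(_HBD_QUERY)),
        hba=Lipinski.NumHAcceptors(rdmol),
        rotb=CalcNumRotatableBonds(rdmol, strict=True),
        aromatic_rings=CalcNumAromaticRings(rdmol),
    )


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| of two same-kind, same-length fingerprints.

    Two empty fingerprints are defined to have similarity 1.0 (identical sets).
    """
    if a.kind != b.kind or a.nbits != b.nbits:
        raise ValueError(f"fingerprint mismatch: {a.kind}/{a.nbits} vs {b.kind}/{b.nbits}")
    if not a.bits and not b.bits:
        return 1.0
    inter = len(a.bits & b.bits)
    union = len(a.bits | b.bits)
    return inter / union


@dataclass
class FeatureMatrix:
    """Concatenated MACCS | ECFP | descriptor feature matrix with scaler state.

    Column layout is fixed: 166 MACCS columns, then ``ecfp_nbits`` ECFP
    columns, then the 7 descriptors in :data:`DESCRIPTOR_NAMES` order.
    ``scaler`` is a fitted :class:`sklearn.preprocessing.StandardScaler`;
    constant columns transform to zero (sklearn's zero-variance convention).
    """

    ids: list[str]
    X: np.ndarray  # standardized
    raw: np.ndarray
    scaler: StandardScaler
    ecfp_nbits: int = 2048

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def featurize(mols: Iterable[Molecule], ecfp_nbits: int = 2048) -> np.ndarray:
    """Raw (unscaled) feature rows for a molecule list, in input order."""
    rows = []
    for m in mols:
        rdmol = m.to_rdkit()
        maccs = compute_fingerprint(rdmol, FingerprintKind.MACCS).to_array()
        ecfp = compute_fingerprint(rdmol, FingerprintKind.ECFP, nbits=ecfp_nbits).to_array()
        desc = compute_descriptors(rdmol).to_array()
        rows.append(np.concatenate([maccs, ecfp, desc]))
    return np.asarray(rows, dtype=float)


def build_feature_matrix(
    mols: Sequence[Molecule], scaler: StandardScaler | None = None, ecfp_nbits: int = 2048
) -> FeatureMatrix:
    """Assemble the standardized feature matrix for ``mols``.

    Without ``scaler`` a new one is fitted on these rows (training use); with
    a stored scaler the rows are transformed only, never refitted.
    """
    if len(mols) == 0:
        raise ValueError("empty molecule list")
    raw = featurize(mols, ecfp_nbits=ecfp_nbits)
    if scaler is None:
        scaler = StandardScaler()
        X = scaler.fit_transform(raw)
    else:
        if scaler.n_features_in_ != raw.shape[1]:
            raise ValueError(
                f"column-layout mismatch: scaler expects {scaler.n_features_in_} features, got {raw.shape[1]}"
            )
        X = scaler.transform(raw)
    return FeatureMatrix(ids=[m.id for m in mols], X=X, raw=raw, scaler=scaler, ecfp_nbits=ecfp_nbits)
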