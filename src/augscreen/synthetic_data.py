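"""Synthetic study inputs: chemotype families, planted screening libraries
and simulated concentration-response data.

The generators emulate the structure of the real screening problem — a
scarce, structurally coherent family of activator-chemotype molecules
(guaiacol-bearing phenolics with variable lipophilic chains, the vanilloid
motif) hidden inside a much larger background library — without requiring
any external compound collection.  Background molecules are property-matched
to the planted family on molecular weight and cLogP, so recovering the
planted actives exercises the fingerprint/SAR signal rather than trivial
property differences.  Dose-response simulation reproduces the nine-point
0.1-50 uM assay design with multiplicative replicate noise.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

from .assay_analysis import biphasic_response, four_param_logistic
from .augmentation import Fragment, _attach, load_fragment_library
from .chem_core import Molecule, parse_and_canonicalize

GUAIACOL_CORE_SMARTS = "[OX2H]c1ccc(*)cc1OC"  # 2-methoxy-4-substituted phenol

# Series templates for the activator chemotype: a guaiacol head group joined
# through a ketone / amide / alcohol / ester linker to a lipophilic chain.
SERIES_TEMPLATES = (
    "O=C(CCc1ccc(O)c(OC)c1){R}",   # alkyl aryl ketone (paradol/shogaol-like)
    "O=C(NCc1ccc(O)c(OC)c1){R}",   # vanillylamide (capsaicinoid-like)
    "OC(CCc1ccc(O)c(OC)c1){R}",    # secondary alcohol (oxyphyllacinol-like)
    "O=C(OCc1ccc(O)c(OC)c1){R}",   # vanillyl ester
)
FURAN_TEMPLATE = "COc1cc(Cc2ccc({R})o2)ccc1O"  # furan-bridged (alpinoid-like)


def _chain_vocabulary(chain_range: tuple[int, int]) -> list[str]:
    lo, hi = chain_range
    chains: list[str] = []
    for n in range(lo, hi + 1):
        chains.append("C" * n)                      # plain alkyl
    for n in range(lo, max(lo, hi - 3) + 1):
        chains.append("/C=C/" + "C" * n)            # trans-enone chain
        chains.append("CC(O)" + "C" * n)            # beta-hydroxy chain
    for n in range(lo, max(lo, hi - 4) + 1):
        chains.append("C" * n + "c1ccccc1")         # phenyl-terminated chain
    return chains


@dataclass
class ChemotypeSpec:
    """Defines the planted activator family.

    ``scaffold_smarts`` is the substructure every family member must contain;
    the vocabulary is the cross-product of linker series templates and
    lipophilic chains of lengths ``chain_range``.
    """

    scaffold_smarts: str = GUAIACOL_CORE_SMARTS
    series_templates: tuple[str, ...] = SERIES_TEMPLATES
    furan_template: str | None = FURAN_TEMPLATE
    chain_range: tuple[int, int] = (1, 12)
    n_actives: int = 150
    rng_seed: int = 0


def make_chemotype_family(spec: ChemotypeSpec | None = None) -> list[Molecule]:
    """Emit exactly ``spec.n_actives`` distinct, valid, scaffold-containing
    molecules, deterministically under ``spec.rng_seed``."""
    spec = spec or ChemotypeSpec()
    scaffold = Chem.MolFromSmarts(spec.scaffold_smarts)
    if scaffold is None:
        raise ValueError(f"invalid scaffold SMARTS: {spec.scaffold_smarts!r}")
    chains = _chain_vocabulary(spec.chain_range)
    if not chains:
        raise ValueError("empty chain vocabulary")
    candidates: list[str] = []
    for tmpl in spec.series_templates:
        for r in chains:
            candidates.append(tmpl.format(R=r))
    if spec.furan_template:
        for r in chains:
            if len(r) <= 8:  # keep the furan series short-chained
                candidates.append(spec.furan_template.format(R=r))
    seen: set[str] = set()
    family: list[Molecule] = []
    for smi in candidates:
        mol = Chem.MolFromSmiles(smi)
        if mol is None or not mol.HasSubstructMatch(scaffold):
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen:
            continue
        seen.add(can)
        family.append(Molecule(id=f"fam{len(family) + 1:04d}", smiles=can, source="fixture"))
    if len(family) < spec.n_actives:
        raise ValueError(
            f"combinatorial space ({len(family)}) smaller than n_actives ({spec.n_actives})"
        )
    rng = random.Random(spec.rng_seed)
    rng.shuffle(family)
    return family[: spec.n_actives]


# ---------------------------------------------------------------------------
# Screening library with planted actives
# ---------------------------------------------------------------------------

_BACKGROUND_CORES = (
    "c1ccccc1", "c1ccncc1", "c1ccc2ccccc2c1", "c1ccoc1", "c1ccsc1",
    "C1CCCCC1", "C1CCCC1", "C1CCNCC1", "C1CCOCC1", "c1cnc2ccccc2c1",
    "c1cc[nH]c1", "C1CCCCCC1",
)


@dataclass
class PlantedLibrary:
    """A screening library with ground-truth planted/background labels."""

    molecules: list[Molecule]
    truth: dict[str, bool]  # id -> planted?
    composition: dict = field(default_factory=dict)

    @property
    def planted_ids(self) -> set[str]:
        return {i for i, v in self.truth.items() if v}

    def __len__(self) -> int:
        return len(self.molecules)


def _generate_background(
    target_mws: Sequence[float],
    logp_range: tuple[float, float],
    forbidden: Chem.Mol,
    fragments: list[Fragment],
    rng: random.Random,
    n: int,
    max_attempts_factor: int = 30,
) -> list[Molecule]:
    frag_mols = [f.to_rdkit() for f in fragments]
    cores = [Chem.MolFromSmiles(s) for s in _BACKGROUND_CORES]
    out: list[Molecule] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = max_attempts_factor * n
    lo_logp, hi_logp = logp_range
    while len(out) < n and attempts < max_attempts:
        attempts += 1
        target = rng.choice(target_mws) + rng.gauss(0, 15)
        mol = cores[rng.randrange(len(cores))]
        for _ in range(8):
            if Descriptors.MolWt(mol) >= target - 25:
                break
            positions = [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1]
            if not positions:
                break
            grown = _attach(mol, rng.choice(positions), frag_mols[rng.randrange(len(frag_mols))])
            if grown is not None:
                mol = grown
        mw = Descriptors.MolWt(mol)
        if abs(mw - target) > 40:
            continue
        if not (lo_logp <= Crippen.MolLogP(mol) <= hi_logp):
            continue
        if mol.HasSubstructMatch(forbidden):
            continue  # background must not carry the planted chemotype core
        can = Chem.MolToSmiles(mol)
        if can in seen:
            continue
        seen.add(can)
        out.append(Molecule(id=f"bg{len(out) + 1:05d}", smiles=can, source="library"))
    if len(out) < n:
        raise RuntimeError(f"background generation exhausted: {len(out)}/{n} after {attempts} attempts")
    return out


def make_screening_library(
    family: Sequence[Molecule],
    n_background: int = 5000,
    rng_seed: int = 0,
    scaffold_smarts: str = GUAIACOL_CORE_SMARTS,
) -> PlantedLibrary:
    """Plant the family inside a property-matched background library.

    Background molecules are grown from assorted ring cores to match the
    family's molecular-weight distribution (targets resampled from family
    MWs with Gaussian jitter) and constrained to the family's cLogP range
    (padded by 1 log unit), but never contain the family scaffold.
    """
    if n_background <= 0:
        raise ValueError("n_background must be positive")
    rng = random.Random(rng_seed)
    forbidden = Chem.MolFromSmarts(scaffold_smarts)
    fam_rd = [m.to_rdkit() for m in family]
    fam_mws = [Descriptors.MolWt(m) for m in fam_rd]
    fam_logps = [Crippen.MolLogP(m) for m in fam_rd]
    logp_range = (min(fam_logps) - 1.0, max(fam_logps) + 1.0)
    background = _generate_background(
        fam_mws, logp_range, forbidden, load_fragment_library(), rng, n_background
    )
    planted = [
        Molecule(id=f"planted{k + 1:03d}", smiles=m.smiles, name=m.name, source="fixture")
        for k, m in enumerate(family)
    ]
    molecules = planted + background
    rng.shuffle(molecules)
    truth = {m.id: m.id.startswith("planted") for m in molecules}
    composition = {
        "n_planted": len(planted),
        "n_background": len(background),
        "n_total": len(molecules),
    }
    return PlantedLibrary(molecules=molecules, truth=truth, composition=composition)


def make_decoy_pool(
    actives: Sequence[Molecule],
    n: int = 3000,
    rng_seed: int = 0,
    scaffold_smarts: str = GUAIACOL_CORE_SMARTS,
) -> list[Molecule]:
    """Generate a decoy candidate pool property-matched to ``actives``.

    Like the screening background, pool members match the actives' MW
    distribution and cLogP range but never contain the activator scaffold,
    so selected decoys are property-matched yet topologically dissimilar.
    """
    rng = random.Random(rng_seed)
    forbidden = Chem.MolFromSmarts(scaffold_smarts)
    rd = [m.to_rdkit() for m in actives]
    mws = [Descriptors.MolWt(m) for m in rd]
    logps = [Crippen.MolLogP(m) for m in rd]
    return _generate_background(
        mws, (min(logps) - 1.0, max(logps) + 1.0), forbidden, load_fragment_library(), rng, n
    )


# ---------------------------------------------------------------------------
# Dose-response simulation
# ---------------------------------------------------------------------------

NINE_POINT_DESIGN = (0.1, 0.25, 0.5, 1.0, 2.5, 5.0, 10.0, 25.0, 50.0)


@dataclass
class DRSimConfig:
    """Ground truth and noise model for simulated concentration-response data.

    Defaults reproduce the assay design: nine concentrations spanning
    0.1-50 uM, triplicate wells, 5 % multiplicative noise, a monotone
    activator with EC50 9.3 uM rising from 100 % to a 127 % plateau.
    Setting ``ic50`` produces a bell-shaped (biphasic) truth curve.
    """

    ec50: float = 9.3
    hill: float = 1.0
    bottom: float = 100.0
    top: float = 127.0
    ic50: float | None = None
    hill2: float = 1.0
    concentrations: tuple[float, ...] = NINE_POINT_DESIGN
    noise_sd: float = 0.05
    replicates: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if (conc <= 0).any() or len(np.unique(conc)) != len(conc):
            raise ValueError("concentrations must be positive and distinct")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def truth(self, c: np.ndarray) -> np.ndarray:
        if self.ic50 is None:
            return four_param_logistic(c, self.bottom, self.top, np.log10(self.ec50), self.hill)
        return biphasic_response(
            c, self.bottom, self.top - self.bottom,
            np.log10(self.ec50), self.hill, np.log10(self.ic50), self.hill2,
        )


# a bell-shaped truth emulating observed biphasic activators: activity rises
# to ~+35 % near 10 uM and falls back to ~+11 % at 50 uM
BELL_EXAMPLE = dict(ec50=5.0, hill=1.0, bottom=100.0, top=160.0, ic50=25.0, hill2=2.0)


def simulate_dose_response_replicates(cfg: DRSimConfig | None = None) -> list[tuple[float, float]]:
    """Simulate replicate-level (concentration, response %) points.

    Replicate responses are ``truth(c) * (1 + eps)`` with
    ``eps ~ Normal(0, noise_sd)``; deterministic under ``rng_seed``.
    """
    cfg = cfg or DRSimConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    conc = np.asarray(cfg.concentrations, dtype=float)
    model = cfg.truth(conc)
    points = []
    for ci, mi in zip(conc, model):
        reps = mi * (1.0 + rng.normal(0.0, cfg.noise_sd, size=cfg.replicates))
        points.extend((float(ci), float(r)) for r in reps)
    return points


def simulate_dose_response(cfg: DRSimConfig | None = None) -> list[tuple[float, float, float, int]]:
    """Simulate (concentration, mean %, SEM %, N) rows.

    Aggregates :func:`simulate_dose_response_replicates` per concentration;
    deterministic under ``rng_seed``.
    """
    cfg = cfg or DRSimConfig()
    points = simulate_dose_response_replicates(cfg)
    rows = []
    for i in range(0, len(points), cfg.replicates):
        block = np.array([r for _, r in points[i : i + cfg.replicates]])
        ci = points[i][0]
        sem = float(block.std(ddof=1) / np.sqrt(cfg.replicates)) if cfg.replicates > 1 else 0.0
        rows.append((ci, float(block.mean()), sem, cfg.replicates))
    return rows
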