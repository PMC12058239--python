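"""Consensus drug-likeness, physicochemical cutoffs and structural alerts.

Five literature rule sets (Lipinski, Ghose, Veber, Egan, Muegge) are
evaluated as pure threshold functions of computed descriptors.  "Consensus"
drug-likeness defaults to passing at least 3 of the 5 rule sets; strict
all-five consensus under standard descriptor conventions rejects long-chain
phenolics that are legitimate hits in this chemotype, so majority consensus
is the default (configurable).  Toxicity screening matches a SMARTS alert
library (a curated Brenk-style built-in list; user-replaceable).  The final
hit filter keeps a molecule iff rotatable bonds <= 10, cLogP < 5, consensus
drug-likeness passes and no alert matches — and reports *all* failed checks
for every dropped molecule, not just the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen

from .chem_core import DescriptorVector, Molecule, compute_descriptors

RULE_IDS = ("lipinski", "ghose", "veber", "egan", "muegge")


@dataclass(frozen=True)
class Violation:
    name: str
    observed: float
    bound: str


@dataclass
class RuleResult:
    rule_id: str
    passed: bool
    violations: list[Violation]


@dataclass
class AlertMatch:
    pattern_id: str
    category: str
    atom_indices: tuple[int, ...]


@dataclass
class AlertLibrary:
    """Named SMARTS substructure patterns with categories."""

    patterns: list[tuple[str, str, str]]  # (smarts, name, category)
    _compiled: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self._compiled = []
        for smarts, name, category in self.patterns:
            query = Chem.MolFromSmarts(smarts)
            if query is None:
                raise ValueError(f"malformed alert pattern {name!r}: {smarts!r}")
            self._compiled.append((query, name, category))

    @staticmethod
    def load(path: str | Path | None = None) -> "AlertLibrary":
        """Load from a tab-separated file (pattern, name, category); built-in if None."""
        if path is None:
            text = resources.files("augscreen.data").joinpath("alerts.smarts").read_text()
        else:
            text = Path(path).read_text()
        patterns = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed alert line (need pattern<TAB>name): {line!r}")
            patterns.append((parts[0], parts[1], parts[2] if len(parts) > 2 else "unspecified"))
        return AlertLibrary(patterns=patterns)


def toxicity_alerts(mol: Molecule | Chem.Mol, alert_library: AlertLibrary) -> list[AlertMatch]:
    """All alert-library substructure matches; an empty list means clean."""
    rdmol = mol.to_rdkit() if isinstance(mol, Molecule) else mol
    matches = []
    for query, name, category in alert_library._compiled:
        hit = rdmol.GetSubstructMatch(query)
        if hit:
            matches.append(AlertMatch(pattern_id=name, category=category, atom_indices=tuple(hit)))
    return matches


# ---------------------------------------------------------------------------
# Rule sets
# ---------------------------------------------------------------------------

def _extended_properties(rdmol: Chem.Mol) -> dict[str, float]:
    """Descriptors beyond the core seven needed by Ghose and Muegge."""
    with_h = Chem.AddHs(rdmol)
    return {
        "molar_refractivity": Crippen.MolMR(rdmol),
        "n_atoms": with_h.GetNumAtoms(),  # all atoms including hydrogens
        "n_carbons": sum(1 for a in rdmol.GetAtoms() if a.GetAtomicNum() == 6),
        "n_heteroatoms": sum(1 for a in rdmol.GetAtoms() if a.GetAtomicNum() not in (1, 6)),
        "n_rings": rdmol.GetRingInfo().NumRings(),
    }


def _check(violations: list[Violation], name: str, value: float, ok: bool, bound: str) -> None:
    if not ok:
        violations.append(Violation(name=name, observed=value, bound=bound))


def evaluate_druglikeness(mol: Molecule | Chem.Mol, desc: DescriptorVector | None = None) -> list[RuleResult]:
    """Evaluate all five drug-likeness rule sets with their literature bounds."""
    rdmol = mol.to_rdkit() if isinstance(mol, Molecule) else mol
    d = desc or compute_descriptors(rdmol)
    ext = _extended_properties(rdmol)
    results = []

    v: list[Violation] = []
    _check(v, "mw", d.mw, d.mw <= 500, "MW <= 500")
    _check(v, "clogp", d.clogp, d.clogp <= 5, "LogP <= 5")
    _check(v, "hbd", d.hbd, d.hbd <= 5, "HBD <= 5")
    _check(v, "hba", d.hba, d.hba <= 10, "HBA <= 10")
    results.append(RuleResult("lipinski", not v, v))

    v = []
    _check(v, "mw", d.mw, 160 <= d.mw <= 480, "160 <= MW <= 480")
    _check(v, "clogp", d.clogp, -0.4 <= d.clogp <= 5.6, "-0.4 <= LogP <= 5.6")
    _check(v, "n_atoms", ext["n_atoms"], 20 <= ext["n_atoms"] <= 70, "20 <= atoms <= 70")
    _check(v, "molar_refractivity", ext["molar_refractivity"],
           40 <= ext["molar_refractivity"] <= 130, "40 <= MR <= 130")
    results.append(RuleResult("ghose", not v, v))

    v = []
    _check(v, "rotb", d.rotb, d.rotb <= 10, "rotB <= 10")
    _check(v, "tpsa", d.tpsa, d.tpsa <= 140, "TPSA <= 140")
    results.append(RuleResult("veber", not v, v))

    v = []
    _check(v, "clogp", d.clogp, d.clogp <= 5.88, "LogP <= 5.88")
    _check(v, "tpsa", d.tpsa, d.tpsa <= 131.6, "TPSA <= 131.6")
    results.append(RuleResult("egan", not v, v))

    v = []
    _check(v, "mw", d.mw, 200 <= d.mw <= 600, "200 <= MW <= 600")
    _check(v, "clogp", d.clogp, -2 <= d.clogp <= 5, "-2 <= LogP <= 5")
    _check(v, "tpsa", d.tpsa, d.tpsa <= 150, "TPSA <= 150")
    _check(v, "n_rings", ext["n_rings"], ext["n_rings"] <= 7, "rings <= 7")
    _check(v, "n_carbons", ext["n_carbons"], ext["n_carbons"] > 4, "carbons > 4")
    _check(v, "n_heteroatoms", ext["n_heteroatoms"], ext["n_heteroatoms"] > 1, "heteroatoms > 1")
    _check(v, "rotb", d.rotb, d.rotb <= 15, "rotB <= 15")
    _check(v, "hbd", d.hbd, d.hbd <= 5, "HBD <= 5")
    _check(v, "hba", d.hba, d.hba <= 10, "HBA <= 10")
    results.append(RuleResult("muegge", not v, v))
    return results


def consensus_pass(rule_results: Sequence[RuleResult], min_rules: int = 3) -> bool:
    """Consensus drug-likeness: at least ``min_rules`` of the five rule sets pass."""
    return sum(1 for r in rule_results if r.passed) >= min_rules


# ---------------------------------------------------------------------------
# Hit filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    max_rotb: float = 10
    max_logp: float = 5.0  # exclusive: keep requires cLogP < max_logp
    consensus_min_rules: int = 3
    alert_library: AlertLibrary | None = None  # None -> built-in

    def resolved_alerts(self) -> AlertLibrary:
        return self.alert_library if self.alert_library is not None else AlertLibrary.load()


@dataclass
class FilterReport:
    """Per-molecule verdicts: keep/drop with every failed check named."""

    table: pd.DataFrame  # id, smiles, keep, reasons, rotb, clogp, consensus_n_pass, n_alerts
    rule_results: dict[str, list[RuleResult]]
    alert_matches: dict[str, list[AlertMatch]]
    config: FilterConfig

    @property
    def kept(self) -> list[str]:
        return self.table.loc[self.table["keep"], "id"].tolist()

    @property
    def dropped(self) -> list[str]:
        return self.table.loc[~self.table["keep"], "id"].tolist()


def apply_hit_filters(mols, config: FilterConfig | None = None) -> FilterReport:
    """Keep iff rotB <= max_rotb AND cLogP < max_logp AND consensus passes AND
    zero toxicity alerts.  Every drop lists all failed checks.

    ``mols`` is a sequence of molecules or a :class:`~augscreen.screening.HitTable`.
    """
    if hasattr(mols, "table"):  # HitTable
        mols = [
            Molecule(id=r.id, smiles=r.smiles, source="library")
            for r in mols.table.itertuples()
        ]
    config = config or FilterConfig()
    alerts = config.resolved_alerts()
    rows = []
    rule_results: dict[str, list[RuleResult]] = {}
    alert_matches: dict[str, list[AlertMatch]] = {}
    for m in mols:
        rdmol = m.to_rdkit()
        d = compute_descriptors(rdmol)
        rules = evaluate_druglikeness(rdmol, desc=d)
        hits = toxicity_alerts(rdmol, alerts)
        rule_results[m.id] = rules
        alert_matches[m.id] = hits
        n_pass = sum(1 for r in rules if r.passed)
        reasons = []
        if not d.rotb <= config.max_rotb:
            reasons.append(f"rotatable_bonds: {d.rotb} > {config.max_rotb}")
        if not d.clogp < config.max_logp:
            reasons.append(f"clogp: {d.clogp:.2f} >= {config.max_logp}")
        if n_pass < config.consensus_min_rules:
            failed = ",".join(r.rule_id for r in rules if not r.passed)
            reasons.append(f"consensus_druglikeness: {n_pass}/5 passed (failed: {failed})")
        if hits:
            reasons.append("toxicity_alerts: " + ",".join(h.pattern_id for h in hits))
        rows.append(
            {
                "id": m.id,
                "smiles": m.smiles,
                "keep": not reasons,
                "reasons": "; ".join(reasons),
                "rotb": d.rotb,
                "clogp": d.clogp,
                "consensus_n_pass": n_pass,
                "n_alerts": len(hits),
            }
        )
    return FilterReport(
        table=pd.DataFrame(rows),
        rule_results=rule_results,
        alert_matches=alert_matches,
        config=config,
    )
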