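"""Configuration and orchestration: augment -> train -> screen -> select ->
filter -> assay as composable stages under one master seed.

Every stochastic stage receives a seed derived from the master seed as
``(master * 1_000_003 + crc32(stage_name)) % 2**31``, so a single integer
reproduces the whole run bit-for-bit.  Each stage writes CSV/JSON artifacts
into the run directory and records row counts, durations and content hashes
in a :class:`RunManifest`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import admet_filters, assay_analysis, augmentation, classifier, screening, synthetic_data
from .augmentation import (
    AugmentationConfig,
    CurationPolicy,
    DecoyConfig,
    DecoyPool,
    LabeledDataset,
    assemble_training_set,
    curate_generated,
    grow_analogs,
)
from .chem_core import Molecule, parse_and_canonicalize
from .classifier import SMALL_GRID, SplitConfig, TrainedClassifier, evaluate, stratified_split, train

logger = logging.getLogger(__name__)

STAGES = ("fixtures", "augment", "train", "screen", "select", "filter", "assay")


def stage_seed(master: int, stage: str) -> int:
    """Fan one master seed out to a per-stage seed (documented derivation)."""
    return (master * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


# ---------------------------------------------------------------------------
# Config schema
# ---------------------------------------------------------------------------

class ConfigError(ValueError):
    pass


@dataclass
class SyntheticSection:
    n_family: int = 150
    n_seeds: int = 6
    n_planted: int = 50
    n_background: int = 5000
    decoy_pool_size: int = 3000


@dataclass
class AugmentSection:
    n_per_seed_min: int = 200
    n_per_seed_max: int = 300
    optimization_steps: int = 200
    runs: int = 100
    context_radius: int = 3
    similarity_window: tuple[float, float] = (0.4, 0.95)
    max_mw: float = 600.0
    target_actives: int = 575


@dataclass
class DecoySection:
    k_per_active: int = 50
    property_tolerance: float = 3.0
    max_similarity: float = 0.30


@dataclass
class TrainSection:
    train_fraction: float = 0.75
    cv_folds: int = 10
    grid: str | dict = "small"  # "small" | "default" | explicit mapping

    def resolved_grid(self) -> dict:
        if isinstance(self.grid, dict):
            return self.grid
        if self.grid == "small":
            return SMALL_GRID
        if self.grid == "default":
            return classifier.DEFAULT_GRID
        raise ConfigError(f"train.grid must be 'small', 'default' or a mapping (got {self.grid!r})")


@dataclass
class ScreenSection:
    edge_threshold: float = 0.6
    prob_min: float = 0.7
    prob_max: float = 1.0
    min_degree: int = 3
    cliff_delta: float = 0.5


@dataclass
class FilterSection:
    max_rotb: float = 10
    max_logp: float = 5.0
    consensus_min_rules: int = 3


@dataclass
class AssaySection:
    margin: float = 5.0
    concentrations: tuple[float, float] = (1.0, 10.0)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "runs/default"
    synthetic: SyntheticSection = field(default_factory=SyntheticSection)
    augment: AugmentSection = field(default_factory=AugmentSection)
    decoys: DecoySection = field(default_factory=DecoySection)
    train: TrainSection = field(default_factory=TrainSection)
    screen: ScreenSection = field(default_factory=ScreenSection)
    filters: FilterSection = field(default_factory=FilterSection)
    assay: AssaySection = field(default_factory=AssaySection)
    provenance: dict = field(default_factory=dict, repr=False)  # field path -> default|user

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("provenance", None)
        return d


def _build_section(cls, data: dict, path: str, provenance: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown config key: {path}.{sorted(unknown)[0]}")
    kwargs = {}
    for name, f in fields.items():
        key = f"{path}.{name}" if path else name
        if name in data:
            value = data[name]
            if f.type in ("int",) and not isinstance(value, int):
                raise ConfigError(f"{key}: expected integer, got {value!r}")
            if isinstance(value, list):
                value = tuple(value)
            kwargs[name] = value
            provenance[key] = "user"
        else:
            provenance[key] = "default"
    return cls(**kwargs)


_SECTION_TYPES = {
    "synthetic": SyntheticSection,
    "augment": AugmentSection,
    "decoys": DecoySection,
    "train": TrainSection,
    "screen": ScreenSection,
    "filters": FilterSection,
    "assay": AssaySection,
}


def config_from_dict(data: dict | None) -> PipelineConfig:
    data = dict(data or {})
    provenance: dict[str, str] = {}
    unknown = set(data) - set(_SECTION_TYPES) - {"seed", "outdir"}
    if unknown:
        raise ConfigError(f"unknown config key: {sorted(unknown)[0]}")
    kwargs: dict[str, Any] = {}
    for scalar in ("seed", "outdir"):
        if scalar in data:
            kwargs[scalar] = data[scalar]
            provenance[scalar] = "user"
        else:
            provenance[scalar] = "default"
    for name, cls in _SECTION_TYPES.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"{name}: expected a mapping")
        kwargs[name] = _build_section(cls, section, name, provenance)
    cfg = PipelineConfig(**kwargs, provenance=provenance)
    _validate(cfg)
    return cfg


def _validate(cfg: PipelineConfig) -> None:
    t = cfg.train
    if not (0 < t.train_fraction < 1):
        raise ConfigError(f"train.train_fraction: must lie in (0, 1), got {t.train_fraction}")
    if not (0 < cfg.screen.edge_threshold < 1):
        raise ConfigError("screen.edge_threshold: must lie in (0, 1)")
    if not (0 < cfg.decoys.max_similarity < 1):
        raise ConfigError("decoys.max_similarity: must lie in (0, 1)")
    if cfg.augment.n_per_seed_min > cfg.augment.n_per_seed_max:
        raise ConfigError("augment.n_per_seed_min must be <= augment.n_per_seed_max")
    t.resolved_grid()


def validate_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML config; an empty/missing file means all defaults.

    The returned config records per-field provenance (default vs user).
    """
    data = None
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if data is not None and not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
    return config_from_dict(data)


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, seed: int | None, duration: float, outputs: dict[str, Path], counts: dict) -> None:
        self.stages[stage] = {
            "seed": seed,
            "duration_s": round(duration, 3),
            "outputs": {str(p): _sha256(p) for p in outputs.values()},
            "counts": counts,
        }

    def write(self, path: Path) -> None:
        path.write_text(json.dumps({"config": self.config, "stages": self.stages}, indent=2, default=str))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class MissingInputError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Pipeline runner
# ---------------------------------------------------------------------------

def _write_mols(path: Path, mols: Sequence[Molecule], extra: dict[str, list] | None = None) -> None:
    df = pd.DataFrame(
        {
            "id": [m.id for m in mols],
            "smiles": [m.smiles for m in mols],
            "name": [m.name or "" for m in mols],
            "source": [m.source for m in mols],
        }
    )
    for k, v in (extra or {}).items():
        df[k] = v
    df.to_csv(path, index=False)


def _read_mols(path: Path) -> tuple[list[Molecule], pd.DataFrame]:
    df = pd.read_csv(path, keep_default_na=False)
    mols = [
        Molecule(id=str(r.id), smiles=r.smiles, name=(r.name or None), source=r.source)
        for r in df.itertuples()
    ]
    return mols, df


class PipelineRunner:
    """Executes the pipeline stages in dependency order against a run directory."""

    def __init__(self, config: PipelineConfig, outdir: str | Path | None = None):
        self.cfg = config
        self.outdir = Path(outdir or config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest = RunManifest(config=config.to_dict())
        # in-memory state shared between stages
        self.state: dict[str, Any] = {}

    # -- fixtures ----------------------------------------------------------
    def stage_fixtures(self) -> dict:
        cfg, s = self.cfg, stage_seed(self.cfg.seed, "fixtures")
        syn = cfg.synthetic
        spec = synthetic_data.ChemotypeSpec(n_actives=syn.n_family, rng_seed=s)
        family = synthetic_data.make_chemotype_family(spec)
        if syn.n_seeds + syn.n_planted > len(family):
            raise ConfigError("n_seeds + n_planted exceeds family size")
        seeds = [Molecule(id=f"seed{i+1}", smiles=m.smiles, source="seed") for i, m in enumerate(family[: syn.n_seeds])]
        planted = family[syn.n_seeds : syn.n_seeds + syn.n_planted]
        library = synthetic_data.make_screening_library(planted, n_background=syn.n_background, rng_seed=s + 1)
        self.state.update(seeds=seeds, library=library)
        out = {
            "seeds": self.outdir / "seeds.csv",
            "library": self.outdir / "library.csv",
        }
        _write_mols(out["seeds"], seeds)
        _write_mols(out["library"], library.molecules, {"planted": [int(library.truth[m.id]) for m in library.molecules]})
        return {
            "seed": s,
            "outputs": out,
            "counts": {"seeds": len(seeds), "library": len(library)},
        }

    def _load_fixtures(self) -> None:
        if "seeds" in self.state:
            return
        for name in ("seeds", "library"):
            path = self.outdir / f"{name}.csv"
            if not path.exists():
                raise MissingInputError(f"stage requires output of 'fixtures' (missing {path})")
        seeds, _ = _read_mols(self.outdir / "seeds.csv")
        lib_mols, lib_df = _read_mols(self.outdir / "library.csv")
        truth = {m.id: bool(p) for m, p in zip(lib_mols, lib_df["planted"])}
        self.state.update(
            seeds=seeds,
            library=synthetic_data.PlantedLibrary(molecules=lib_mols, truth=truth),
        )

    # -- augment -----------------------------------------------------------
    def stage_augment(self) -> dict:
        self._load_fixtures()
        cfg, s = self.cfg, stage_seed(self.cfg.seed, "augment")
        a = cfg.augment
        alert_lib = admet_filters.AlertLibrary.load()
        policy = CurationPolicy(
            alert_smarts=[(p, n) for p, n, _ in alert_lib.patterns],
            seed_similarity_window=a.similarity_window,
            property_window={"mw": (100.0, 600.0), "rotb": (0, 15), "clogp": (-3.0, 7.5)},
        )
        # grow in passes until curation yields the target (+ buffer for the
        # decoy-outlier drop below) — per-seed yield varies, and the study
        # design is to generate until the curated set is large enough
        reports = []
        unique: dict[str, Molecule] = {}
        buffer = a.target_actives + 25
        for attempt in range(5):
            if len(unique) >= buffer:
                break
            for k, seed_mol in enumerate(self.state["seeds"]):
                gcfg = AugmentationConfig(
                    n_per_seed_min=a.n_per_seed_min,
                    n_per_seed_max=a.n_per_seed_max,
                    optimization_steps=a.optimization_steps,
                    runs=a.runs,
                    context_radius=a.context_radius,
                    similarity_window=a.similarity_window,
                    max_mw=a.max_mw,
                    rng_seed=s + k + 1000 * attempt,
                )
                analogs = grow_analogs(seed_mol, gcfg)
                result = curate_generated(analogs, policy, seed_mol)
                for m in result.molecules:
                    unique.setdefault(m.smiles, m)
                reports.append({"seed": seed_mol.id, "pass": attempt, **dict(result.report)})
        candidates = list(unique.values())
        # decoy candidates are property-matched to the curated actives;
        # an active whose property neighborhood cannot supply a full decoy
        # complement is itself an outlier and is excluded (logged)
        decoy_pool = synthetic_data.make_decoy_pool(
            candidates, n=cfg.synthetic.decoy_pool_size, rng_seed=s + 7
        )
        pool = DecoyPool(decoy_pool)
        dcfg = DecoyConfig(
            k_per_active=cfg.decoys.k_per_active,
            property_tolerance=cfg.decoys.property_tolerance,
            max_similarity=cfg.decoys.max_similarity,
            rng_seed=s,
        )
        decoy_sets = {}
        actives = []
        n_outliers = 0
        for m in candidates:
            try:
                decoy_sets[m.id] = pool.select(m, dcfg)
                actives.append(m)
            except augmentation.DecoyPoolExhaustedError as exc:
                n_outliers += 1
                logger.info("dropping property-outlier active %s: %s", m.id, exc)
        # fix the curated-set size deterministically
        rng = np.random.default_rng(s)
        if len(actives) > a.target_actives:
            keep = rng.choice(len(actives), size=a.target_actives, replace=False)
            actives = [actives[i] for i in sorted(keep)]
            decoy_sets = {m.id: decoy_sets[m.id] for m in actives}
        elif len(actives) < a.target_actives:
            logger.warning("curation produced %d actives (< target %d)", len(actives), a.target_actives)
        dataset = assemble_training_set(actives, decoy_sets, rng_seed=s)
        self.state["dataset"] = dataset
        out = {
            "training_set": self.outdir / "training_set.csv",
            "curation_report": self.outdir / "curation_report.csv",
            "decoy_pool": self.outdir / "decoy_pool.csv",
        }
        _write_mols(out["training_set"], dataset.molecules, {"label": dataset.labels.tolist()})
        _write_mols(out["decoy_pool"], decoy_pool)
        pd.DataFrame(reports).fillna(0).to_csv(out["curation_report"], index=False)
        n0, n1 = dataset.class_counts
        return {
            "seed": s,
            "outputs": out,
            "counts": {
                "curated_actives": len(actives),
                "decoy_outliers_dropped": n_outliers,
                "rows": len(dataset),
                "actives": n1,
                "decoys": n0,
            },
        }

    def _load_dataset(self) -> LabeledDataset:
        if "dataset" not in self.state:
            path = self.outdir / "training_set.csv"
            if not path.exists():
                raise MissingInputError(f"stage requires output of 'augment' (missing {path})")
            mols, df = _read_mols(path)
            self.state["dataset"] = LabeledDataset(molecules=mols, labels=df["label"].to_numpy())
        return self.state["dataset"]

    # -- train -------------------------------------------------------------
    def stage_train(self) -> dict:
        ds = self._load_dataset()
        cfg, s = self.cfg, stage_seed(self.cfg.seed, "train")
        split = SplitConfig(train_fraction=cfg.train.train_fraction, random_state=s)
        train_ds, test_ds = stratified_split(ds, split)
        clf = train(train_ds, grid=cfg.train.resolved_grid(), cv_folds=cfg.train.cv_folds, random_state=s)
        report = evaluate(clf, test_ds)
        train_report = evaluate(clf, train_ds)
        self.state.update(clf=clf, eval_report=report, train_report=train_report)
        out = {
            "model": self.outdir / "model.pkl",
            "evaluation": self.outdir / "evaluation.json",
            "roc": self.outdir / "roc.csv",
        }
        clf.save(out["model"])
        payload = report.to_dict()
        payload.update(
            {
                "train_accuracy": train_report.accuracy,
                "train_test_gap": abs(train_report.accuracy - report.accuracy),
                "best_params": clf.best_params,
                "train_rows": len(train_ds),
                "test_rows": len(test_ds),
            }
        )
        out["evaluation"].write_text(json.dumps(payload, indent=2))
        pd.DataFrame({"fpr": report.fpr, "tpr": report.tpr, "threshold": report.thresholds}).to_csv(
            out["roc"], index=False
        )
        return {
            "seed": s,
            "outputs": out,
            "counts": {"train_rows": len(train_ds), "test_rows": len(test_ds)},
        }

    def _load_classifier(self) -> TrainedClassifier:
        if "clf" not in self.state:
            path = self.outdir / "model.pkl"
            if not path.exists():
                raise MissingInputError(f"stage requires output of 'train' (missing {path})")
            self.state["clf"] = TrainedClassifier.load(path)
        return self.state["clf"]

    # -- screen ------------------------------------------------------------
    def stage_screen(self) -> dict:
        self._load_fixtures()
        clf = self._load_classifier()
        cfg, s = self.cfg, stage_seed(self.cfg.seed, "screen")
        library = self.state["library"]
        result = screening.screen_library(clf, library.molecules, library_id="synthetic")
        net = screening.build_similarity_network(
            library.molecules, dict(zip(result.ids, result.probs)), edge_threshold=cfg.screen.edge_threshold
        )
        cliffs = screening.detect_activity_cliffs(net, cliff_delta=cfg.screen.cliff_delta)
        self.state.update(screen_result=result, network=net, cliffs=cliffs)
        out = {
            "probs": self.outdir / "screen_probs.csv",
            "edges": self.outdir / "network_edges.csv",
            "nodes": self.outdir / "network_nodes.csv",
            "cliffs": self.outdir / "cliffs.csv",
        }
        result.to_frame().to_csv(out["probs"], index=False)
        net.edge_frame().to_csv(out["edges"], index=False)
        net.node_frame().to_csv(out["nodes"], index=False)
        pd.DataFrame([dataclasses.asdict(c) for c in cliffs]).to_csv(out["cliffs"], index=False)
        return {
            "seed": s,
            "outputs": out,
            "counts": {"scored": len(result.ids), "edges": net.graph.number_of_edges(), "cliffs": len(cliffs)},
        }

    # -- select ------------------------------------------------------------
    def stage_select(self) -> dict:
        if "screen_result" not in self.state:
            raise MissingInputError("stage requires output of 'screen' (run screen first)")
        cfg = self.cfg
        hits = screening.select_hits(
            self.state["screen_result"],
            self.state["network"],
            prob_min=cfg.screen.prob_min,
            prob_max=cfg.screen.prob_max,
            min_degree=cfg.screen.min_degree,
        )
        self.state["hits"] = hits
        out = {"hits": self.outdir / "hits.csv"}
        hits.table.to_csv(out["hits"], index=False)
        (self.outdir / "hit_criteria.json").write_text(json.dumps(hits.criteria, indent=2))
        out["criteria"] = self.outdir / "hit_criteria.json"
        return {"seed": None, "outputs": out, "counts": {"hits": len(hits)}}

    # -- filter ------------------------------------------------------------
    def stage_filter(self) -> dict:
        if "hits" not in self.state:
            path = self.outdir / "hits.csv"
            if not path.exists():
                raise MissingInputError(f"stage requires output of 'select' (missing {path})")
            df = pd.read_csv(path)
            hits = screening.HitTable(table=df)
            self.state["hits"] = hits
        cfg = self.cfg
        fcfg = admet_filters.FilterConfig(
            max_rotb=cfg.filters.max_rotb,
            max_logp=cfg.filters.max_logp,
            consensus_min_rules=cfg.filters.consensus_min_rules,
        )
        report = admet_filters.apply_hit_filters(self.state["hits"], fcfg)
        self.state["filter_report"] = report
        out = {"filter_report": self.outdir / "filter_report.csv"}
        report.table.to_csv(out["filter_report"], index=False)
        return {
            "seed": None,
            "outputs": out,
            "counts": {"kept": len(report.kept), "dropped": len(report.dropped)},
        }

    # -- assay -------------------------------------------------------------
    def stage_assay(self) -> dict:
        cfg, s = self.cfg, stage_seed(self.cfg.seed, "assay")
        tbl = assay_analysis.load_atpase_reference_table()
        calls = {}
        for conc in cfg.assay.concentrations:
            c = assay_analysis.classify_modulation(tbl, conc, margin=cfg.assay.margin)
            calls[conc] = {
                "calls": [dataclasses.asdict(x) for x in c],
                "summary": assay_analysis.modulation_summary(c),
            }
        # dose-response demonstration on the simulated nine-point design
        sim = synthetic_data.simulate_dose_response(synthetic_data.DRSimConfig(rng_seed=s))
        fit = assay_analysis.fit_dose_response([(c, m) for c, m, _, _ in sim])
        payload = {
            "margin": cfg.assay.margin,
            "modulation": {str(k): v for k, v in calls.items()},
            "simulated_fit": fit.to_dict(),
        }
        out = {"assay": self.outdir / "assay_analysis.json"}
        out["assay"].write_text(json.dumps(payload, indent=2))
        counts = {f"activators_at_{k}uM": v["summary"]["activator"] for k, v in calls.items()}
        self.state["assay"] = payload
        return {"seed": s, "outputs": out, "counts": counts}

    # -- driver ------------------------------------------------------------
    def run(self, stages: Sequence[str] | None = None) -> RunManifest:
        requested = list(stages) if stages else list(STAGES)
        unknown = set(requested) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
        ordered = [s for s in STAGES if s in requested]
        for name in ordered:
            fn = getattr(self, f"stage_{name}")
            t0 = time.time()
            info = fn()
            self.manifest.record(name, info["seed"], time.time() - t0, info["outputs"], info["counts"])
            logger.info("stage %s done in %.1fs: %s", name, time.time() - t0, info["counts"])
            self.manifest.write(self.outdir / "manifest.json")
        return self.manifest


def run_pipeline(
    config: PipelineConfig, stages: Sequence[str] | None = None, outdir: str | Path | None = None
) -> RunManifest:
    """Run the requested stages (all by default) and return the manifest."""
    return PipelineRunner(config, outdir=outdir).run(stages)
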