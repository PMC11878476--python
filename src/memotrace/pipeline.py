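"""End-to-end orchestration: generate -> expand -> train -> extract ->
normalize -> phenotype -> analyze -> evaluate.

A run is driven by a :class:`RunConfig` (YAML-loadable), executes the
enabled stages in dependency order in a single process, and writes a
:class:`RunManifest` recording per-stage output hashes and timing — even
when a stage fails, so partial runs are auditable.  All randomness flows
through named per-stage seeds derived from the run seed; deterministic
stages reproduce identical hashes under identical config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import evaluation, expansion, linker, normalize, phenotype, synthetic
from . import tagger as tagger_mod
from . import trajectory
from .ontology import to_bio, write_standoff
from .text import tokenize

logger = logging.getLogger(__name__)

STAGES = ("generate", "expand_query", "train", "extract", "normalize",
          "phenotype", "analyze", "evaluate")


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 42
    n_patients: int = 500
    n_training_notes: int = 200
    stages: Dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES})
    tagger: Dict[str, object] = field(default_factory=dict)
    generator: Dict[str, object] = field(default_factory=dict)
    expansion_k: int = 20
    expansion_min_sim: float = 0.4
    f1_threshold: float = 0.8

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)

    def stage_seed(self, stage: str) -> int:
        # Stable per-stage stream, independent of stage toggles.
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    config: dict
    stages: List[dict] = field(default_factory=list)
    status: str = "ok"
    error: Optional[str] = None

    def record(self, stage: str, seed: Optional[int], outputs: Dict[str, str],
               seconds: float) -> None:
        self.stages.append({"stage": stage, "seed": seed,
                            "outputs": outputs,
                            "seconds": round(seconds, 3)})

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_outputs(paths: List[Path]) -> Dict[str, str]:
    return {p.name: _sha256(p) for p in paths if p.is_file()}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run(config: RunConfig) -> RunManifest:
    """Execute the enabled stages; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())
    with open(out / "run_config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)

    state: Dict[str, object] = {}
    try:
        for stage in STAGES:
            if not config.stages.get(stage, False):
                continue
            seed = config.stage_seed(stage)
            t0 = time.time()
            logger.info("stage %s (seed %d)", stage, seed)
            outputs = _STAGE_FNS[stage](config, state, out, seed)
            manifest.record(stage, seed, outputs, time.time() - t0)
    except Exception as exc:  # noqa: BLE001 - manifest must still be written
        manifest.status = "failed"
        manifest.error = str(exc)
        manifest.write(out / "manifest.json")
        raise StageError(stage, exc) from exc
    manifest.write(out / "manifest.json")
    return manifest


# -- stage implementations ---------------------------------------------------

def _stage_generate(config: RunConfig, state, out: Path, seed: int):
    gen_cfg = synthetic.GeneratorConfig(
        n_patients=config.n_patients, seed=seed, **config.generator)
    dataset = synthetic.generate(gen_cfg)
    data_dir = dataset.write(out / "data")
    state["dataset"] = dataset
    return _hash_outputs(sorted(data_dir.glob("*.csv"))
                         + [data_dir / "ground_truth.json"])


def _stage_expand_query(config: RunConfig, state, out: Path, seed: int):
    dataset: synthetic.SyntheticDataset = state["dataset"]
    corpus = [[t.text.lower() for t in tokenize(n.text)]
              for n in dataset.notes]
    merged, phrases = expansion.detect_bigrams(corpus, min_count=5,
                                               threshold=10.0, delta=5.0)
    emb_cfg = expansion.EmbeddingConfig(seed=seed)
    model = expansion.train_embeddings(merged, emb_cfg)
    seeds = expansion.SeedLexicon()
    candidates = expansion.expand_terms(model, seeds, k=config.expansion_k,
                                        min_sim=config.expansion_min_sim)
    path = out / "expansion_candidates.csv"
    expansion.write_candidates(path, candidates)
    state["expansion"] = candidates
    return _hash_outputs([path])


def _stage_train(config: RunConfig, state, out: Path, seed: int):
    dataset: synthetic.SyntheticDataset = state["dataset"]
    notes = dataset.notes[:config.n_training_notes]
    corpus = [to_bio(n) for n in notes]
    cfg = tagger_mod.TaggerConfig(seed=seed, **config.tagger)
    batch = max(1, len(corpus) // 4)
    batches = [corpus[i:i + batch] for i in range(0, len(corpus), batch)]
    trained = tagger_mod.train_until(batches, cfg,
                                     f1_threshold=config.f1_threshold)
    path = out / "tagger.zip"
    trained.save(path)
    state["tagger"] = trained
    return _hash_outputs([path])


def _stage_extract(config: RunConfig, state, out: Path, seed: int):
    dataset: synthetic.SyntheticDataset = state["dataset"]
    trained: tagger_mod.TrainedTagger = state["tagger"]
    texts = [n.text for n in dataset.notes]
    entity_lists = trained.predict_many(texts)
    pred_notes = []
    pred_dir = out / "pred"
    pred_dir.mkdir(exist_ok=True)
    for note, ents in zip(dataset.notes, entity_lists):
        pred = note.with_entities(ents)
        pred = pred.with_entities(ents, linker.link_relations(pred))
        pred_notes.append(pred)
    for note in pred_notes:
        _, ann = write_standoff(note)
        (pred_dir / f"{note.doc_id}.ann").write_text(ann, encoding="utf-8")
    state["pred_notes"] = pred_notes
    return {"n_documents": str(len(pred_notes))}


def _stage_normalize(config: RunConfig, state, out: Path, seed: int):
    pred_notes = state["pred_notes"]
    table = normalize.build_extraction_table(pred_notes)
    path = out / "extractions.csv"
    table.to_csv(path, index=False)
    state["extractions"] = table
    return _hash_outputs([path])


def _stage_phenotype(config: RunConfig, state, out: Path, seed: int):
    dataset: synthetic.SyntheticDataset = state["dataset"]
    result = phenotype.select_cohort(dataset.patients, state["extractions"])
    result.write_attrition(out / "attrition.json")
    rows = ["patient_id,first_complaint_date,first_dx_date,analysis"]
    for pid in result.included:
        c, d = result.index_dates[pid]
        rows.append(f"{pid},{c.isoformat()},{d.isoformat()},"
                    f"{int(pid in set(result.analysis))}")
    (out / "cohort.csv").write_text("\n".join(rows) + "\n", encoding="utf-8")
    state["cohort"] = result
    return _hash_outputs([out / "attrition.json", out / "cohort.csv"])


def _stage_analyze(config: RunConfig, state, out: Path, seed: int):
    dataset: synthetic.SyntheticDataset = state["dataset"]
    records = trajectory.build_trajectories(
        state["cohort"], state["extractions"], dataset.patients)
    trajectory.write_trajectories_csv(records, out / "trajectories.csv")
    trajectory.write_report(records, out / "report")
    state["records"] = records
    return _hash_outputs([out / "trajectories.csv",
                          out / "report" / "results.json"])


def _stage_evaluate(config: RunConfig, state, out: Path, seed: int):
    dataset: synthetic.SyntheticDataset = state["dataset"]
    pred_notes = state["pred_notes"]
    report = evaluation.score_documents(
        [n.entities for n in dataset.notes],
        [n.entities for n in pred_notes], mode="exact")
    path = out / "metrics.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    return _hash_outputs([path])


_STAGE_FNS = {
    "generate": _stage_generate,
    "expand_query": _stage_expand_query,
    "train": _stage_train,
    "extract": _stage_extract,
    "normalize": _stage_normalize,
    "phenotype": _stage_phenotype,
    "analyze": _stage_analyze,
    "evaluate": _stage_evaluate,
}
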