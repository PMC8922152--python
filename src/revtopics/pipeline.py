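"""End-to-end orchestration: data -> filters -> DTM -> per-drug LDA ->
stratified tables and tests -> reproducible report bundle.

One topic model is fitted per drug label, never pooled. All randomness
flows from the single global seed through named substreams (stage name ->
child seed), so any stage can be re-run in isolation and two runs from
the same config produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .corpus_io import filter_reviews, read_reviews, write_filter_log, write_reviews
from .lda import (TopicModelParams, fit_lda, primary_topics, select_num_topics)
from .preprocess import PreprocessConfig, preprocess_corpus, save_dtm
from .records import AGE_GROUPS, TIME_GROUPS, ReviewRecord
from .report import demographics_table, topic_report
from .stats import fisher_exact, rating_summary, share_table, welch_t
from .synthetic import SyntheticConfig, generate_ground_truth, render_corpus

log = logging.getLogger("revtopics")


def substream_seed(base_seed: int, name: str) -> int:
    """Deterministic named child seed (< 2^31) for a pipeline stage."""
    digest = hashlib.sha256(f"{base_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Exactly one of ``synthetic`` / ``input_path`` must be set."""

    out_dir: str = "revtopics_out"
    seed: int = 0
    synthetic: Optional[SyntheticConfig] = None
    input_path: Optional[str] = None
    input_format: Optional[str] = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    lda: TopicModelParams = field(default_factory=TopicModelParams)
    k_candidates: Optional[list[int]] = None
    top_n_words: int = 30
    mc_reps: int = 20_000
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_path is None):
            raise ValueError("exactly one of synthetic / input_path must be set")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if raw.get("synthetic") is not None:
            syn = dict(raw["synthetic"])
            syn.setdefault("seed", raw.get("seed", 0))
            raw["synthetic"] = SyntheticConfig(**syn)
        if raw.get("preprocess") is not None:
            pp = dict(raw["preprocess"])
            if pp.get("bigrams") is not None:
                pp["bigrams"] = tuple(tuple(b) for b in pp["bigrams"])
            if pp.get("stopwords") is not None:
                pp["stopwords"] = frozenset(pp["stopwords"])
            raw["preprocess"] = PreprocessConfig(**pp)
        if raw.get("lda") is not None:
            raw["lda"] = TopicModelParams(**dict(raw["lda"]))
        inp = raw.pop("input", None)
        if inp:
            raw["input_path"] = inp.get("path")
            raw["input_format"] = inp.get("format")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (frozenset, set)):
                return sorted(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: list[str]
    checksums: dict[str, str]
    filter_summary: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis and write the report bundle to
    ``config.out_dir``. On any stage failure, partial outputs are removed
    and a ``PipelineError`` naming the stage is raised."""
    out = Path(config.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    try:
        return _run(config, out, stages)
    except Exception:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for p in out.iterdir():
                if p.is_file():
                    p.unlink()
                else:
                    shutil.rmtree(p, ignore_errors=True)
        raise


def _run(config: PipelineConfig, out: Path, stages: list[str]) -> RunManifest:
    logging.basicConfig(level=config.log_level,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")

    @_stage("acquire")
    def acquire() -> list[ReviewRecord]:
        if config.synthetic is not None:
            syn = dataclasses.replace(
                config.synthetic, seed=substream_seed(config.seed, "synthetic"))
            gt = generate_ground_truth(syn)
            records, genlog = render_corpus(gt, syn)
            gt.to_json(out / "ground_truth.json")
            (out / "generator_log.json").write_text(
                json.dumps(genlog.to_dict(), indent=2, sort_keys=True) + "\n")
            write_reviews(records, out / "corpus.csv", "csv")
            return records
        return read_reviews(config.input_path, config.input_format)

    records = acquire()
    stages.append("acquire")

    @_stage("filter")
    def filt():
        survivors, flog = filter_reviews(records)
        write_filter_log(flog, out / "filter_log.json")
        return survivors, flog

    survivors, flog = filt()
    stages.append("filter")
    if not survivors:
        raise PipelineError(
            "stage preprocess: all documents empty (no eligible reviews "
            "survived filtering)")

    demographics_table(survivors).to_csv(out / "demographics.csv", index=False)

    drugs = sorted({r.drug for r in survivors})
    report_md = ["# Patient review topic report", "",
                 f"Eligible reviews: {len(survivors)} of {flog.n_input} "
                 f"({json.dumps(flog.removed_counts)})", "",
                 "No multiple-testing correction is applied; "
                 "alpha = .05 per test.", ""]
    per_drug: dict[str, dict] = {}

    for drug in drugs:
        recs = [r for r in survivors if r.drug == drug]

        @_stage(f"preprocess[{drug}]")
        def preprocess_stage(recs=recs, drug=drug):
            dtm = preprocess_corpus([r.comment or "" for r in recs],
                                    [r.record_id for r in recs],
                                    config.preprocess)
            save_dtm(dtm, out / f"dtm_{drug}")
            return dtm

        dtm = preprocess_stage()
        stages.append(f"preprocess[{drug}]")

        @_stage(f"lda[{drug}]")
        def lda_stage(dtm=dtm, drug=drug):
            params = dataclasses.replace(
                config.lda, seed=substream_seed(config.seed, f"lda:{drug}"))
            if config.k_candidates:
                sel = select_num_topics(dtm, config.k_candidates, params)
                pd.Series(sel.scores, name="density").rename_axis("K").to_csv(
                    out / f"k_selection_{drug}.csv")
                params = dataclasses.replace(params, n_topics=sel.chosen_k,
                                             alpha=None)
            model = fit_lda(dtm, params)
            np.savetxt(out / f"phi_{drug}.csv", model.phi, delimiter=",")
            np.savetxt(out / f"theta_{drug}.csv", model.theta, delimiter=",")
            return model

        model = lda_stage()
        stages.append(f"lda[{drug}]")

        assignments = primary_topics(model)
        rep = topic_report(model, assignments, drug=drug,
                           n_words=config.top_n_words)
        (out / f"topics_{drug}.json").write_text(
            json.dumps(rep.to_dict(), indent=2, sort_keys=True) + "\n")
        report_md.append(rep.to_markdown())

        by_id = {r.record_id: r for r in recs}
        age_of = {r.record_id: r.age_group for r in recs}
        time_of = {r.record_id: (r.time_on_med if r.time_on_med != "missing"
                                 else None) for r in recs}
        ratings = {r.record_id: r.rating for r in recs}

        @_stage(f"stats[{drug}]")
        def stats_stage():
            shares_age = share_table(assignments, age_of, list(AGE_GROUPS),
                                     model.n_topics)
            shares_time = share_table(assignments, time_of, list(TIME_GROUPS),
                                      model.n_topics)
            shares_age.to_csv(out / f"shares_by_age_{drug}.csv")
            shares_time.to_csv(out / f"shares_by_time_{drug}.csv")
            rs_age = rating_summary(assignments, ratings, age_of,
                                    list(AGE_GROUPS), model.n_topics)
            rs_time = rating_summary(assignments, ratings, time_of,
                                     list(TIME_GROUPS), model.n_topics)
            rs_age.to_csv(out / f"ratings_by_age_{drug}.csv")
            rs_time.to_csv(out / f"ratings_by_time_{drug}.csv")
            # long-format export for share plots
            long = shares_age.counts.drop(columns="total").reset_index().melt(
                id_vars="topic", var_name="stratum", value_name="n")
            long.to_csv(out / f"shares_long_{drug}.csv", index=False)
            return shares_age

        shares_age = stats_stage()
        stages.append(f"stats[{drug}]")
        per_drug[drug] = {
            "model": model, "assignments": assignments,
            "ratings": [float(r.rating) for r in recs if r.rating is not None
                        and by_id[r.record_id] is not None],
            "topic_counts": shares_age.counts["total"].tolist(),
        }

    tests: dict[str, dict] = {}
    if len(drugs) == 2:
        @_stage("between_drug_tests")
        def between():
            a, b = drugs
            ka = len(per_drug[a]["topic_counts"])
            kb = len(per_drug[b]["topic_counts"])
            if ka == kb:
                table = np.array([per_drug[a]["topic_counts"],
                                  per_drug[b]["topic_counts"]]).T
                table = table[~np.all(table == 0, axis=1)]
                tests["fisher_topic_by_drug"] = fisher_exact(
                    table.T, mc_reps=config.mc_reps,
                    seed=substream_seed(config.seed, "fisher")).to_dict()
            tests["welch_rating_by_drug"] = welch_t(
                per_drug[a]["ratings"], per_drug[b]["ratings"]).to_dict()

        between()
        stages.append("between_drug_tests")
    (out / "tests.json").write_text(
        json.dumps(tests, indent=2, sort_keys=True) + "\n")

    (out / "report.md").write_text("\n".join(report_md), encoding="utf-8")

    checksums = {p.name: _sha256(p) for p in sorted(out.iterdir())
                 if p.is_file() and p.name != "manifest.json"}
    manifest = RunManifest(config_hash=config.config_hash(), version=__version__,
                           stages=stages, checksums=checksums,
                           filter_summary=flog.to_dict())
    (out / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True) + "\n")
    return manifest
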