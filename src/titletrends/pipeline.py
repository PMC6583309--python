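"""End-to-end pipeline: simulate -> parse -> count -> trend -> classify -> report.

A single YAML config drives all stages; every run writes a manifest
(config hash, stoplist/ruleset versions, seed, input digests, tool version)
so outputs are traceable to the exact configuration that produced them.
Stage outputs are plain TSV/JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .classify import (
    classify_title,
    load_default_ruleset,
    title_length_contrast,
    two_proportion_z,
    wilson_interval,
)
from .ngrams import STOPWORDS_VERSION, TokenizerConfig, build_frequency_table
from .records import (
    default_clinical_trial_filter,
    select_clinical_trials,
    write_records_jsonl,
)
from .synth import SyntheticSpec, TermSpec, generate_corpus, read_corpus, write_corpus
from .trends import TrendScreenModel

__all__ = ["ConfigError", "MissingInputError", "run_pipeline", "cohort_report", "load_config"]

log = logging.getLogger("titletrends")

_TOP_KEYS = {"seed", "stages", "simulate", "trend", "classify"}
_ALL_STAGES = ["simulate", "parse", "count", "trend", "classify", "contrast", "report"]


class ConfigError(ValueError):
    """Config fails schema validation (unknown key, bad type/value)."""


class MissingInputError(FileNotFoundError):
    """A stage input file is absent."""


def _check_keys(d: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}")


def load_config(path: str | Path) -> dict:
    """Load and validate the pipeline YAML config."""
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"config file not found: {path}")
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    _check_keys(cfg, _TOP_KEYS, "top level")
    if "seed" not in cfg or not isinstance(cfg["seed"], int):
        raise ConfigError("config requires an integer 'seed'")
    stages = cfg.get("stages", _ALL_STAGES)
    bad = [s for s in stages if s not in _ALL_STAGES]
    if bad:
        raise ConfigError(f"unknown stage(s) {bad}; allowed: {_ALL_STAGES}")
    _check_keys(cfg.get("simulate", {}), {
        "years", "articles_per_year", "vocabulary", "injected_bigrams",
        "pub_type_mix", "patient_centric_fraction_by_era", "journal",
        "n_filler_terms", "title_length_range",
    }, "simulate")
    _check_keys(cfg.get("trend", {}), {"fdr_threshold", "top_k", "orders", "low_freq_threshold"},
                "trend")
    _check_keys(cfg.get("classify", {}), {"early_era", "late_era"}, "classify")
    return cfg


def _spec_from_config(cfg: dict) -> SyntheticSpec:
    sim = cfg.get("simulate", {})
    vocab = tuple(TermSpec(v["term"], float(v["baseline"]), float(v["slope"]))
                  for v in sim.get("vocabulary", []))
    bigrams = tuple(TermSpec(v["term"], float(v["baseline"]), float(v["slope"]))
                    for v in sim.get("injected_bigrams", []))
    kwargs: dict[str, Any] = {}
    if "pub_type_mix" in sim:
        kwargs["pub_type_mix"] = tuple(
            (tuple(types), float(p)) for types, p in sim["pub_type_mix"]
        )
    if "patient_centric_fraction_by_era" in sim:
        kwargs["patient_centric_fraction_by_era"] = tuple(
            ((int(e[0]), int(e[1])), float(f))
            for e, f in sim["patient_centric_fraction_by_era"]
        )
    for key in ("journal", "n_filler_terms"):
        if key in sim:
            kwargs[key] = sim[key]
    if "title_length_range" in sim:
        kwargs["title_length_range"] = tuple(sim["title_length_range"])
    return SyntheticSpec(
        years=tuple(sim.get("years", (1976, 2015))),
        articles_per_year=sim.get("articles_per_year", 50),
        vocabulary=vocab,
        injected_bigrams=bigrams,
        seed=int(cfg["seed"]),
        **kwargs,
    )


def cohort_report(per_journal: Mapping[str, int]) -> dict:
    """Cohort accounting: per-journal included-title counts and their total."""
    counts = {j: int(n) for j, n in per_journal.items()}
    return {"per_journal": counts, "total": sum(counts.values())}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    stoplist_version: str
    ruleset_version: str
    seed: int
    tool_version: str
    timestamp: str
    input_digests: dict[str, str]
    outputs: dict[str, str]

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2) + "\n")


def run_pipeline(config_path: str | Path, out_dir: str | Path) -> Path:
    """Execute the configured stages in order; returns the output directory.

    Any stage failure raises with a diagnostic naming the stage. Outputs
    and the run manifest are written under *out_dir*.
    """
    config_path = Path(config_path)
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages", _ALL_STAGES)
    seed = int(cfg["seed"])
    rules = load_default_ruleset()
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_path.read_bytes()).hexdigest(),
        stoplist_version=STOPWORDS_VERSION,
        ruleset_version=rules.version,
        seed=seed,
        tool_version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        input_digests={str(config_path): _digest(config_path)},
        outputs={},
    )

    def _out(name: str) -> Path:
        p = out / name
        manifest.outputs[name] = ""
        return p

    records = None
    truth = None
    report_blob: dict[str, Any] = {}
    try:
        if "simulate" in stages:
            log.info("stage simulate")
            spec = _spec_from_config(cfg)
            truth, records = generate_corpus(spec)
            write_corpus(records, _out("corpus"))
            _out("truth.json").write_text(json.dumps(
                {"true_slopes": truth.true_slopes,
                 "true_labels": truth.true_labels}, indent=2) + "\n")
        if "parse" in stages:
            log.info("stage parse")
            corpus_dir = out / "corpus"
            if not corpus_dir.exists():
                raise MissingInputError(f"parse: corpus directory missing: {corpus_dir}")
            records = read_corpus(corpus_dir)
            write_records_jsonl(records, _out("records.jsonl"))
            report_blob["n_records"] = len(records)
        if records is None:
            raise MissingInputError("no records available; include simulate/parse stages")

        tcfg = TokenizerConfig()
        tr = cfg.get("trend", {})
        if "count" in stages or "trend" in stages:
            log.info("stage count")
            tables = {
                order: build_frequency_table(records, order=order, cfg=tcfg)
                for order in tr.get("orders", [1, 2])
            }
            for order, tab in tables.items():
                tab.to_tsv(_out(f"{'monograms' if order == 1 else 'bigrams'}.tsv"))
        if "trend" in stages:
            log.info("stage trend")
            for order, tab in tables.items():
                model = TrendScreenModel(
                    tab,
                    fdr_threshold=tr.get("fdr_threshold", 0.01),
                    low_freq_threshold=tr.get("low_freq_threshold", 1e-4),
                )
                res = model.fit(k=tr.get("top_k", 20))
                tag = "monogram" if order == 1 else "bigram"
                res.report.to_tsv(_out(f"trend_{tag}.tsv"))
                _out(f"top_{tag}.json").write_text(res.report.top_lists_json() + "\n")
                weights = res.cloud_weights()
                with open(_out(f"cloud_{tag}.tsv"), "w") as fh:
                    fh.write("term\tweight\n")
                    for t, w in sorted(weights.items(), key=lambda kv: -kv[1]):
                        fh.write(f"{t}\t{w:.6g}\n")
                report_blob[f"significant_{tag}s"] = res.report.n_significant

        cl = cfg.get("classify", {})
        early = tuple(cl.get("early_era", (1976, 1980)))
        late = tuple(cl.get("late_era", (2011, 2015)))
        if "classify" in stages or "contrast" in stages:
            log.info("stage classify")
            f = default_clinical_trial_filter()
            trials, acc = select_clinical_trials(records, f)
            labels = {r.pmid: classify_title(r.title, rules) for r in trials}
            with open(_out("labels.tsv"), "w") as fh:
                fh.write("pmid\tyear\tlabel\tevidence\trules_version\n")
                for r in trials:
                    c = labels[r.pmid]
                    fh.write(
                        f"{r.pmid}\t{r.year}\t{int(c.patient_centric)}\t"
                        f"{'|'.join(c.matched_nouns)}\t{c.rules_version}\n"
                    )
            report_blob["n_trials"] = len(trials)
            report_blob["trial_selection"] = {
                "n_input": acc.n_input,
                "n_passing_inclusion": acc.n_passing_inclusion,
                "n_selected": acc.n_selected,
                "removed_by_exclusion": acc.removed_by_exclusion,
            }
        if "contrast" in stages:
            log.info("stage contrast")
            def era_records(era):
                return [r for r in trials if era[0] <= r.year <= era[1]]
            er, lr = era_records(early), era_records(late)
            if not er or not lr:
                raise MissingInputError("contrast: an era holds no clinical-trial records")
            xe = sum(labels[r.pmid].patient_centric for r in er)
            xl = sum(labels[r.pmid].patient_centric for r in lr)
            pc = two_proportion_z(xe, len(er), xl, len(lr))
            lc = title_length_contrast([r.title for r in er], [r.title for r in lr])
            contrast = {
                "early_era": list(early), "late_era": list(late),
                "patient_centric": {
                    "x_early": pc.x_early, "n_early": pc.n_early,
                    "x_late": pc.x_late, "n_late": pc.n_late,
                    "p_early": pc.p_early, "p_late": pc.p_late,
                    "wilson_early": wilson_interval(pc.x_early, pc.n_early),
                    "wilson_late": wilson_interval(pc.x_late, pc.n_late),
                    "z": pc.z, "p_value": pc.p_value, "ci_diff": list(pc.ci_diff),
                },
                "title_length": {
                    "mean_early": lc.mean_early, "mean_late": lc.mean_late,
                    "diff": lc.diff, "p_value": lc.p_value,
                },
            }
            _out("contrast.json").write_text(json.dumps(contrast, indent=2) + "\n")
            report_blob["contrast"] = contrast
        if "report" in stages:
            log.info("stage report")
            if "n_trials" in report_blob:
                per_journal: dict[str, int] = {}
                for r in trials:
                    per_journal[r.journal] = per_journal.get(r.journal, 0) + 1
                report_blob["cohort"] = cohort_report(per_journal)
            _out("report.json").write_text(json.dumps(report_blob, indent=2) + "\n")
    except (ConfigError, MissingInputError):
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    for name in list(manifest.outputs):
        p = out / name
        manifest.outputs[name] = "directory" if p.is_dir() else _digest(p)
    manifest.write(out / "manifest.json")
    return out
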