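"""End-to-end orchestration: read -> filter -> dedup -> classify -> stats.

The pipeline mirrors the study's flow: read the corpus, keep keyword-matching
posts, eliminate near-duplicates by word-level Levenshtein leader clustering,
flag (optionally drop) non-human clusters, enforce one post per author,
build the consensus seed set from the two-rater labels, classify every
remaining post by nearest seed, and compute the quarterly/gender statistics.
All artifacts are written to the output directory and a machine-readable
run report is returned; identical config and inputs yield an identical
report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import date
from pathlib import Path

import yaml

from . import __version__
from .classify import CATEGORIES, assignments_table, build_seed_set, classify_corpus
from .corpus_io import (
    STUDY_WINDOW,
    KeywordSet,
    filter_by_keywords,
    read_corpus,
    read_labels,
    write_corpus,
    write_table,
)
from .dedup import cluster_report, enforce_unique_authors, flag_nonhuman, leader_cluster
from .stats import (
    build_quarter_series,
    describe_counts,
    gender_breakdown,
    gender_chi_square,
    hashtag_frequencies,
    runs_test,
    term_frequencies,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("fluortweets")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything one run needs; serialisable to/from YAML."""

    corpus_path: str
    labels_path: str
    out_dir: str = "out"
    corpus_format: str | None = None
    keywords: list[str] | None = None
    window_start: date = STUDY_WINDOW[0]
    window_end: date = STUDY_WINDOW[1]
    dedup_threshold: float = 0.8
    dedup_min_cluster_size: int = 3
    dedup_drop_nonhuman_leaders: bool = False
    classify_confidence_floor: float = 0.1
    classify_aggregation: str = "max"
    classify_top_k: int = 3
    chi_square_yates_2x2: bool = True
    top_n_terms: int = 50
    rng_seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("window_start", "window_end"):
            if key in raw and isinstance(raw[key], str):
                raw[key] = date.fromisoformat(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window_start"] = self.window_start.isoformat()
        d["window_end"] = self.window_end.isoformat()
        return d


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run report (also written as JSON)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        report = _run(config, out_dir, written)
    except Exception:
        for p in written:  # do not leave partial outputs behind
            p.unlink(missing_ok=True)
        raise
    return report


def _run(config: PipelineConfig, out_dir: Path, written: list[Path]) -> dict:
    kw = KeywordSet(tuple(config.keywords)) if config.keywords else KeywordSet()

    records = _stage("read_corpus")(read_corpus)(config.corpus_path, config.corpus_format)
    n_collected = len(records)
    log.info("read %d records", n_collected)

    kept = _stage("keyword_filter")(filter_by_keywords)(records, kw)
    n_keyword = len(kept)
    log.info("keyword filter kept %d records", n_keyword)

    dd = _stage("dedup")(leader_cluster)(kept, threshold=config.dedup_threshold)
    dd = _stage("flag_nonhuman")(flag_nonhuman)(
        dd,
        min_cluster_size=config.dedup_min_cluster_size,
        drop_nonhuman_leaders=config.dedup_drop_nonhuman_leaders,
    )
    n_eliminated = dd.n_eliminated
    log.info("dedup eliminated %d records (%d clusters flagged non-human)",
             n_eliminated, len(dd.flagged_nonhuman))

    unique = _stage("unique_authors")(enforce_unique_authors)(dd.retained)
    n_removed_author = len(dd.retained) - len(unique)
    log.info("unique-author rule removed %d records; %d remain", n_removed_author, len(unique))

    labels = _stage("read_labels")(read_labels)(config.labels_path)
    retained_ids = {r.id for r in unique}
    usable = labels[labels["tweet_id"].isin(retained_ids)]
    n_labels_dropped = labels["tweet_id"].nunique() - usable["tweet_id"].nunique()
    if n_labels_dropped:
        log.info("dropped labels for %d tweets eliminated upstream", n_labels_dropped)
    seeds, agreement = _stage("build_seed_set")(build_seed_set)(usable, unique)

    assignments, summary = _stage("classify")(classify_corpus)(
        unique,
        seeds,
        confidence_floor=config.classify_confidence_floor,
        aggregation=config.classify_aggregation,
        top_k=config.classify_top_k,
    )
    n_classified = len(assignments)

    series = _stage("quarter_series")(build_quarter_series)(
        assignments, unique, config.window_start, config.window_end
    )
    descriptives = describe_counts(series.totals)
    runs = {}
    for cat in CATEGORIES:
        try:
            r = runs_test(series.counts[cat])
            runs[cat] = {
                "n_runs": r.n_runs, "n_above": r.n_above, "n_below": r.n_below,
                "p_value": r.p_value, "method": r.method,
            }
        except ValueError as exc:
            runs[cat] = {"error": str(exc)}
    # a sparse corpus can leave a category column empty; record the
    # degeneracy in the report rather than aborting the whole run
    try:
        omnibus = gender_chi_square(unique, assignments, mode="omnibus")
        omnibus_report = {
            "statistic": omnibus.statistic, "df": omnibus.df, "p_value": omnibus.p_value,
        }
    except ValueError as exc:
        omnibus_report = {"error": str(exc)}
    try:
        per_cat = gender_chi_square(
            unique, assignments, mode="per_category",
            yates_2x2=config.chi_square_yates_2x2,
        )
        per_cat_report = {
            c: {
                "statistic": entry["result"].statistic,
                "df": entry["result"].df,
                "p_value": entry["result"].p_value,
                "p_bonferroni": entry["p_bonferroni"],
            }
            for c, entry in per_cat.items()
        }
    except ValueError as exc:
        per_cat_report = {"error": str(exc)}
    genders = gender_breakdown(unique, assignments)
    top_terms = term_frequencies((r.text for r in unique), config.top_n_terms)
    top_tags = hashtag_frequencies((r.text for r in unique), config.top_n_terms)

    report = {
        "software": {"name": "fluortweets", "version": __version__},
        "config": config.to_dict(),
        "stage_counts": {
            "collected": n_collected,
            "keyword_filtered": n_keyword,
            "eliminated_by_dedup": n_eliminated,
            "removed_by_unique_author": n_removed_author,
            "classified": n_classified,
        },
        "category_counts": summary["counts"],
        "category_percentages": summary["percentages"],
        "agreement": {
            "n_rated": agreement.n_rated,
            "n_consensus": agreement.n_consensus,
            "per_category": agreement.per_category,
        },
        "quarterly_descriptives": descriptives,
        "runs_tests": runs,
        "chi_square": {
            "omnibus": omnibus_report,
            "per_category": per_cat_report,
        },
        "gender_breakdown": genders,
        "top_terms": [[t, c] for t, c in top_terms],
        "top_hashtags": [[t, c] for t, c in top_tags],
    }
    # stage arithmetic audit: filtered - eliminated - removed = classified
    assert n_keyword - n_eliminated - n_removed_author == n_classified

    def _out(name: str) -> Path:
        p = out_dir / name
        written.append(p)
        return p

    write_corpus(unique, _out("corpus_retained.jsonl"), "jsonl")
    write_table(cluster_report(dd), _out("clusters.csv"), "csv")
    write_table(assignments_table(assignments), _out("assignments.csv"), "csv")
    write_table(
        [
            {
                "quarter": q.label,
                **{c: series.counts[c][i] for c in CATEGORIES},
                "total": series.totals[i],
            }
            for i, q in enumerate(series.quarters)
        ],
        _out("quarter_series.csv"),
        "csv",
    )
    stats_payload = {k: report[k] for k in (
        "quarterly_descriptives", "runs_tests", "chi_square", "gender_breakdown",
        "top_terms", "top_hashtags",
    )}
    _out("stats_report.json").write_text(
        json.dumps(stats_payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    _out("run_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report
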