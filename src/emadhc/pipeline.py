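"""End-to-end pipeline: ingest -> lexicon -> DHC -> profiles -> association.

One :func:`run_pipeline` call reads a corpus, applies the filter cascade,
builds the lexical table, runs the descending hierarchical classification,
prunes small clusters, profiles the kept clusters, tests cluster x
satisfaction independence, and writes every artifact plus a machine-readable
run report into an output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from emadhc.association import (
    DegenerateTableError,
    build_contingency,
    chi2_independence,
    residual_heatmap_table,
)
from emadhc.ingest import FilterConfig, export_iramuteq_corpus, filter_corpus, read_records
from emadhc.lexicon import ACTIVE_POS, build_lexical_table, load_lemma_dictionary
from emadhc.profiles import build_profiles, profiles_to_frame, texts_to_frame
from emadhc.records import EMARecord
from emadhc.reinert import prune_small_clusters, run_dhc

logger = logging.getLogger("emadhc")


@dataclass
class RunConfig:
    """Settings of one pipeline run; the defaults reproduce the published
    analysis settings (20 terminal clusters, 30,000-form cap, minimum form
    frequency 3, 20-character minimum text length)."""

    input_path: str | None = None
    input_format: str = "jsonl"
    out_dir: str | None = None
    # filter settings
    min_chars: int = 20
    allowed_countries: Sequence[str] | None = None
    # lexicon settings
    min_frequency: int = 3
    max_forms: int = 30_000
    keep_pos: Sequence[str] = tuple(sorted(ACTIVE_POS))
    lemma_dictionary_path: str | None = None
    use_bundled_dictionary: bool = True
    # clustering settings
    n_terminal_clusters: int = 20
    min_split_size: int = 2
    # profiling settings
    profile_top_k: int = 20
    top_texts: int = 3
    # misc
    seed: int = 0
    verbosity: str = "info"

    def __post_init__(self) -> None:
        self.keep_pos = tuple(self.keep_pos)
        if self.allowed_countries is not None:
            self.allowed_countries = tuple(self.allowed_countries)

    def filter_config(self) -> FilterConfig:
        kwargs: dict = {"min_chars": self.min_chars}
        if self.allowed_countries is not None:
            kwargs["allowed_countries"] = tuple(self.allowed_countries)
        return FilterConfig(**kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["keep_pos"] = list(self.keep_pos)
        if self.allowed_countries is not None:
            out["allowed_countries"] = list(self.allowed_countries)
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")


@dataclass
class RunReport:
    """Headline numbers and artifact paths of one pipeline run."""

    n_input: int
    n_corpus_texts: int
    n_classified: int
    classification_rate: float
    n_kept_clusters: int
    cluster_percents: dict[int, float]
    chi2_statistic: float | None
    chi2_df: int | None
    chi2_p_value: float | None
    degenerate: bool = False
    degenerate_reason: str | None = None
    artifacts: dict[str, str] = field(default_factory=dict)
    filter_counts: tuple[int, int, int, int, int] | None = None

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["cluster_percents"] = {str(k): v for k, v in self.cluster_percents.items()}
        if self.filter_counts is not None:
            out["filter_counts"] = list(self.filter_counts)
        return out


@dataclass
class PipelineResult:
    """Full in-memory outcome of a run (report plus intermediate objects)."""

    report: RunReport
    records: list[EMARecord]
    filter_report: object
    table: object | None
    tree: object | None
    assignment: dict[str, int]
    profiles: dict
    contingency: object | None


def run_pipeline(config: RunConfig, records: Sequence[EMARecord] | None = None) -> PipelineResult:
    """Run the full pipeline.

    ``records`` may be passed directly (e.g. from the synthetic generator);
    otherwise ``config.input_path`` is read.  When ``config.out_dir`` is
    set, all artifacts are written there.
    """
    level = getattr(logging, config.verbosity.upper(), logging.INFO)
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")

    if records is None:
        if config.input_path is None:
            raise ValueError("either records or config.input_path is required")
        read = read_records(config.input_path, config.input_format)
        if read.failures:
            logger.warning("%d unparseable input rows reported", len(read.failures))
        records = read.records
    records = list(records)
    n_input = len(records)
    logger.info("ingest: %d input records", n_input)

    corpus, filter_report = filter_corpus(records, config.filter_config())
    logger.info("filter cascade counts: %s", filter_report.counts)

    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "config.yaml")

    def fail(reason: str) -> PipelineResult:
        report = RunReport(
            n_input=n_input,
            n_corpus_texts=len(corpus),
            n_classified=0,
            classification_rate=0.0,
            n_kept_clusters=0,
            cluster_percents={},
            chi2_statistic=None,
            chi2_df=None,
            chi2_p_value=None,
            degenerate=True,
            degenerate_reason=reason,
            filter_counts=filter_report.counts,
        )
        _write_common(out_dir, report, filter_report, corpus)
        return PipelineResult(report, list(corpus), filter_report, None, None, {}, {}, None)

    if not corpus:
        return fail("no records survive the filter cascade")

    lemma_dictionary = (
        load_lemma_dictionary(config.lemma_dictionary_path)
        if config.lemma_dictionary_path
        else None
    )
    try:
        table = build_lexical_table(
            corpus,
            min_frequency=config.min_frequency,
            keep_pos=frozenset(config.keep_pos),
            max_forms=config.max_forms,
            lemma_dictionary=lemma_dictionary,
            use_bundled_dictionary=config.use_bundled_dictionary,
        )
    except ValueError as exc:
        return fail(f"lexicon stage: {exc}")
    logger.info(
        "lexical table: %d units x %d forms (%d unclassifiable)",
        table.n_units,
        table.n_forms,
        len(table.unclassifiable_units),
    )

    tree = run_dhc(
        table,
        n_terminal=config.n_terminal_clusters,
        min_split_size=config.min_split_size,
        n_corpus_texts=len(corpus),
    )
    prune_small_clusters(tree, len(corpus), config.n_terminal_clusters)
    assignment = tree.assignment()
    kept = tree.kept_leaves()
    logger.info(
        "DHC: %d kept clusters, classification rate %.1f%%",
        len(kept),
        100 * tree.classification_rate,
    )

    if len(kept) < 2:
        result = fail("clustering produced fewer than 2 kept clusters")
        result.table = table
        result.tree = tree
        if out_dir:
            _write_tree(out_dir, tree, result.report)
        return result

    profiles = build_profiles(
        table, assignment, top_k=config.profile_top_k, top_texts=config.top_texts
    )

    ratings = {r.record_id: r.satisfaction for r in corpus}
    contingency = None
    chi2_stat = chi2_df = chi2_p = None
    try:
        cont_table = build_contingency(assignment, ratings)
        contingency = chi2_independence(cont_table)
        chi2_stat = contingency.chi2_statistic
        chi2_df = contingency.df
        chi2_p = contingency.p_value
        logger.info("chi2(%d) = %.3f, p = %.3f", chi2_df, chi2_stat, chi2_p)
    except (DegenerateTableError, ValueError) as exc:
        logger.warning("association stage skipped: %s", exc)

    report = RunReport(
        n_input=n_input,
        n_corpus_texts=len(corpus),
        n_classified=len(assignment),
        classification_rate=tree.classification_rate,
        n_kept_clusters=len(kept),
        cluster_percents={p.cluster_id: p.percent_of_classified for p in profiles.values()},
        chi2_statistic=chi2_stat,
        chi2_df=chi2_df,
        chi2_p_value=chi2_p,
        filter_counts=filter_report.counts,
    )

    if out_dir:
        _write_common(out_dir, report, filter_report, corpus)
        _write_tree(out_dir, tree, report)
        assignment_frame = pd.DataFrame(
            [
                {"record_id": r.record_id, "cluster_id": assignment.get(r.record_id, "unclassified")}
                for r in corpus
            ]
        )
        assignment_frame.to_csv(out_dir / "assignments.csv", index=False)
        profiles_to_frame(profiles).to_csv(out_dir / "profiles.csv", index=False)
        texts_to_frame(profiles).to_csv(out_dir / "characteristic_texts.csv", index=False)
        if contingency is not None:
            (out_dir / "contingency.json").write_text(
                json.dumps(contingency.to_dict(), indent=2), encoding="utf-8"
            )
            residual_heatmap_table(contingency).to_csv(out_dir / "heatmap.csv", index=False)
        report.artifacts = {
            name: str(out_dir / name)
            for name in (
                "config.yaml",
                "filter_report.json",
                "run_report.json",
                "corpus_iramuteq.txt",
                "tree.json",
                "tree.nwk",
                "assignments.csv",
                "profiles.csv",
                "characteristic_texts.csv",
            )
        }
        (out_dir / "run_report.json").write_text(
            json.dumps(report.to_dict(), indent=2), encoding="utf-8"
        )

    return PipelineResult(
        report=report,
        records=list(corpus),
        filter_report=filter_report,
        table=table,
        tree=tree,
        assignment=assignment,
        profiles=profiles,
        contingency=contingency,
    )


def _write_common(out_dir: Path | None, report: RunReport, filter_report, corpus) -> None:
    if not out_dir:
        return
    (out_dir / "filter_report.json").write_text(
        json.dumps(filter_report.to_dict(), indent=2), encoding="utf-8"
    )
    (out_dir / "run_report.json").write_text(
        json.dumps(report.to_dict(), indent=2), encoding="utf-8"
    )
    if corpus:
        export_iramuteq_corpus(corpus, path=out_dir / "corpus_iramuteq.txt")


def _write_tree(out_dir: Path | None, tree, report: RunReport) -> None:
    if not out_dir:
        return
    (out_dir / "tree.json").write_text(tree.to_json(), encoding="utf-8")
    (out_dir / "tree.nwk").write_text(tree.to_newick() + "\n", encoding="utf-8")
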