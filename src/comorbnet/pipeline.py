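"""End-to-end pipeline: generate/ingest → aggregate → network → trends.

:func:`run_pipeline` executes the whole analysis from a single
:class:`PipelineConfig`, writing every artifact (cohort summary,
co-occurrence matrices, edge tests, network files, trend and disruption
reports, run log) under one output directory together with a manifest that
records the resolved configuration, its hash, the seed, library versions and
per-artifact checksums.  Two runs with the same config and seed produce
identical checksums, layout coordinates included.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from pathlib import Path
from typing import IO, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .claims_io import ClaimsDialect, ClaimsTable, parse_claims, summarize_cohort
from .cooccurrence import aggregate_patient_windows, count_cooccurrence, pair_counts_by_year
from .network import (
    CODE_LABELS,
    FOCAL_CODES,
    build_network,
    compute_layout,
    export_network,
    node_centrality,
    pairwise_associations,
)
from .synthetic import SyntheticCohortConfig, generate_cohort
from .trends import TrendSeries, annualize_partial, detect_disruption

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("comorbnet")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class PipelineConfig:
    """Fully resolved parameters for one pipeline run.

    Exactly one of ``claims_path`` or ``synthetic`` supplies the input.
    ``trend_pairs`` defaults to the five pairs with the highest pooled
    co-occurrence counts.  ``coverage`` marks partially observed years
    (fraction of the year with data); ``partial_year_mode`` is ``"flag"`` or
    ``"scale"``.
    """

    claims_path: str | None = None
    synthetic: SyntheticCohortConfig | None = None
    vocabulary: tuple[str, ...] = FOCAL_CODES
    labels: dict[str, str] = dataclasses.field(default_factory=lambda: dict(CODE_LABELS))
    window: int | str = "pooled"
    alpha: float = 0.05
    use_adjusted: bool = False
    trend_pairs: tuple[tuple[str, str], ...] | None = None
    n_trend_pairs: int = 5
    drop_threshold: float = 0.2
    rise_threshold: float = 0.2
    coverage: dict[int, float] = dataclasses.field(default_factory=dict)
    partial_year_mode: str = "flag"
    layout_seed: int = 0
    out_dir: str = "comorbnet-run"

    def validate(self) -> None:
        if (self.claims_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of claims_path or synthetic must be set")
        if self.claims_path is not None and not Path(self.claims_path).exists():
            raise ValueError(f"claims file does not exist: {self.claims_path}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1): {self.alpha}")
        if len(self.vocabulary) < 2:
            raise ValueError("vocabulary needs at least 2 codes")
        if self.partial_year_mode not in ("flag", "scale"):
            raise ValueError(f"unknown partial_year_mode: {self.partial_year_mode!r}")
        if self.drop_threshold <= 0 or self.rise_threshold <= 0:
            raise ValueError("trend thresholds must be positive")
        for y, f in self.coverage.items():
            if not 0 < f <= 1:
                raise ValueError(f"coverage for {y} must be in (0, 1]")

    # --- text round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        if self.synthetic is not None:
            syn = doc["synthetic"]
            syn["years"] = list(syn["years"])
            syn["associations"] = [dict(a) for a in syn["associations"]]
        doc["vocabulary"] = list(self.vocabulary)
        doc["trend_pairs"] = (
            None if self.trend_pairs is None else [list(p) for p in self.trend_pairs]
        )
        return doc

    @classmethod
    def from_dict(cls, doc: Mapping) -> "PipelineConfig":
        doc = dict(doc)
        if doc.get("synthetic") is not None:
            doc["synthetic"] = SyntheticCohortConfig(**doc["synthetic"])
        if doc.get("vocabulary") is not None:
            doc["vocabulary"] = tuple(doc["vocabulary"])
        if doc.get("trend_pairs") is not None:
            doc["trend_pairs"] = tuple(tuple(p) for p in doc["trend_pairs"])
        if doc.get("coverage"):
            doc["coverage"] = {int(y): float(f) for y, f in doc["coverage"].items()}
        return cls(**doc)

    def to_yaml(self, target: str | IO[str]) -> None:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if hasattr(target, "write"):
            target.write(text)
        else:
            Path(target).write_text(text)

    @classmethod
    def from_yaml(cls, source: str | IO[str]) -> "PipelineConfig":
        text = source.read() if hasattr(source, "read") else Path(source).read_text()
        return cls.from_dict(yaml.safe_load(text))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write all artifacts under ``config.out_dir``.

    Stages: input (load or generate claims) → cohort summary → patient-year
    aggregation → co-occurrence matrices → pairwise Spearman tests → network
    (build, centrality, layout, export) → trends and disruption reports →
    manifest.  Any stage failure raises :class:`PipelineError` naming the
    stage.  Returns the manifest dictionary.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    artifacts: dict[str, str] = {}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        # --- input -------------------------------------------------------
        stage("input")
        try:
            if config.synthetic is not None:
                claims, _ = generate_cohort(config.synthetic)
                logger.info("generated %d synthetic claims", len(claims))
            else:
                claims, report = parse_claims(config.claims_path)
                for line in report.log_lines():
                    logger.info(line)
        except Exception as e:
            raise PipelineError("input", e) from e

        # --- cohort summary ----------------------------------------------
        stage("cohort_summary")
        try:
            summary = summarize_cohort(claims)
            path = out / "cohort_summary.json"
            path.write_text(json.dumps(dataclasses.asdict(summary), indent=2, sort_keys=True))
            artifacts["cohort_summary"] = path.name
        except Exception as e:
            raise PipelineError("cohort_summary", e) from e

        # --- aggregation + co-occurrence ----------------------------------
        stage("cooccurrence")
        try:
            sets = aggregate_patient_windows(claims)
            matrix = count_cooccurrence(sets, window=config.window,
                                        vocabulary=config.vocabulary)
            matrix.to_frame().to_csv(out / "cooccurrence_matrix.csv")
            matrix.to_long().to_csv(out / "cooccurrence_long.csv", index=False)
            artifacts["cooccurrence_matrix"] = "cooccurrence_matrix.csv"
        except Exception as e:
            raise PipelineError("cooccurrence", e) from e

        # --- association tests --------------------------------------------
        stage("associations")
        try:
            n_universe = None
            if config.synthetic is not None:
                # Enrollment denominator is known by design for synthetic
                # cohorts: every patient is enrolled in every cohort year.
                years = (
                    len(config.synthetic.years)
                    if config.window == "pooled"
                    else int(config.window in config.synthetic.years)
                )
                n_universe = config.synthetic.n_patients * years
            tests = pairwise_associations(
                sets, config.vocabulary, window=config.window,
                alpha=config.alpha, use_adjusted=config.use_adjusted,
                n_universe=n_universe,
            )
            df = pd.DataFrame(
                [
                    (t.code_a, t.code_b, t.rho, t.p_value, t.p_adjusted, t.n,
                     t.significant, t.degenerate)
                    for t in tests
                ],
                columns=["code_a", "code_b", "rho", "p", "p_adjusted", "n",
                         "significant", "degenerate"],
            )
            df.to_csv(out / "edge_tests.csv", index=False)
            artifacts["edge_tests"] = "edge_tests.csv"
            n_deg = sum(t.degenerate for t in tests)
            if n_deg:
                logger.info("degenerate (constant) pairs excluded: %d", n_deg)
            logger.info("alpha=%s use_adjusted=%s window=%s",
                        config.alpha, config.use_adjusted, config.window)
        except Exception as e:
            raise PipelineError("associations", e) from e

        # --- network -------------------------------------------------------
        stage("network")
        try:
            G = build_network(tests, alpha=config.alpha,
                              use_adjusted=config.use_adjusted, labels=config.labels)
            if G.number_of_nodes() > 0:
                compute_layout(G, seed=config.layout_seed)
                export_network(G, str(out / "network.graphml"), fmt="graphml")
            else:
                (out / "network.graphml").write_text("")
            export_network(G, str(out / "network_edges.csv"), fmt="edge-list")
            node_centrality(G).to_csv(out / "centrality.csv", index=False)
            artifacts["network"] = "network.graphml"
            artifacts["centrality"] = "centrality.csv"
            logger.info("network: %d nodes, %d edges",
                        G.number_of_nodes(), G.number_of_edges())
        except Exception as e:
            raise PipelineError("network", e) from e

        # --- trends --------------------------------------------------------
        stage("trends")
        try:
            pairs = config.trend_pairs
            if pairs is None:
                long = matrix.to_long().sort_values(
                    ["count", "code_a", "code_b"], ascending=[False, True, True],
                    kind="mergesort",
                )
                pairs = tuple(
                    (r.code_a, r.code_b)
                    for r in long.head(config.n_trend_pairs).itertuples(index=False)
                )
            trend_table = pair_counts_by_year(sets, pairs)
            trend_table.to_csv(out / "trend_counts.csv")
            artifacts["trends"] = "trend_counts.csv"

            reports = []
            for pair, row in trend_table.iterrows():
                series = TrendSeries(pair=pair, counts={int(y): int(c) for y, c in row.items()},
                                     coverage=dict(config.coverage))
                series = annualize_partial(series, mode=config.partial_year_mode)
                try:
                    rep = detect_disruption(series, config.drop_threshold,
                                            config.rise_threshold)
                except ValueError as err:
                    logger.info("disruption skipped for %s: %s", pair, err)
                    continue
                reports.append(
                    (pair[0], pair[1],
                     ";".join(map(str, rep.dip_years)),
                     ";".join(map(str, rep.rebound_years)),
                     json.dumps({str(y): round(c, 6) for y, c in
                                 sorted(rep.relative_changes.items())}))
                )
            pd.DataFrame(
                reports,
                columns=["code_a", "code_b", "dip_years", "rebound_years",
                         "relative_changes"],
            ).to_csv(out / "disruption_report.csv", index=False)
            artifacts["disruption"] = "disruption_report.csv"
        except Exception as e:
            raise PipelineError("trends", e) from e

        # --- manifest ------------------------------------------------------
        stage("manifest")
        resolved = out / "config_resolved.yaml"
        config.to_yaml(str(resolved))
        # Hash the analysis parameters only: where artifacts land does not
        # change what was computed.
        hashed = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
        config_hash = hashlib.sha256(
            yaml.safe_dump(hashed, sort_keys=True).encode()
        ).hexdigest()
        seed = config.synthetic.seed if config.synthetic is not None else None
        manifest = {
            "config_file": resolved.name,
            "config_sha256": config_hash,
            "seed": seed,
            "layout_seed": config.layout_seed,
            "versions": {
                "comorbnet": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "networkx": nx.__version__,
            },
            "artifacts": artifacts,
            "checksums": {name: _sha256(out / fname) for name, fname in artifacts.items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()
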