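"""End-to-end orchestration: simulate -> audit -> weights -> prioritize ->
sensitivity -> report.

Every artifact is written to a single output directory together with a
frozen YAML echo of the configuration and a manifest of SHA-256 checksums;
identical configuration + seed reproduces identical checksums.  A stage
failure aborts the run with the failing stage named and removes the partial
artifacts it had written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ahp, audit, mcda, reference, simulate
from .catalog import catalog_to_records, get_parameter, stampc_ids
from .dataset import (
    CohortDataset,
    read_registry_csv,
    read_reports_csv,
    write_registry_csv,
    write_reports_csv,
)

log = logging.getLogger("stampc")

STAMPC_ORDER = ("S", "T", "A", "M", "P", "C")
STAMPC_HEADINGS = {
    "S": "Size (defect width)",
    "T": "Tanaka index",
    "A": "Anatomical location (EHS)",
    "M": "Mesh (presence of prior mesh)",
    "P": "Plane (old mesh plane)",
    "C": "Concurrent hernia (inguinal / parastomal or stomal)",
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    out_dir: Path = Path("results/pipeline")
    seed: int = 0
    generator: simulate.GeneratorConfig = field(
        default_factory=simulate.GeneratorConfig
    )
    n_raters: int = reference.SURVEY_N_RATERS
    survey_targets: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(reference.SURVEY_MEAN_SD)
    )
    mcda_config: mcda.MCDAConfig = field(default_factory=mcda.MCDAConfig)
    pairwise_matrix: list[list[float]] | None = None  # optional: derive weights
    reference_scores: dict[str, float] | None = None  # published final scores
    sensitivity_draws: int = 500
    sensitivity_concentration: float = 100.0

    def echo(self) -> dict:
        # out_dir is deliberately not echoed: the provenance record must be
        # identical wherever the same configuration + seed is rerun
        d = {
            "seed": self.seed,
            "generator": asdict(self.generator),
            "n_raters": self.n_raters,
            "survey_targets": {k: list(v) for k, v in self.survey_targets.items()},
            "mcda": asdict(self.mcda_config),
            "pairwise_matrix": self.pairwise_matrix,
            "reference_scores": self.reference_scores,
            "sensitivity": {
                "n_draws": self.sensitivity_draws,
                "concentration": self.sensitivity_concentration,
            },
        }
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; return the artifact manifest (name -> checksum)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    gen_cfg = config.generator.with_seed(config.seed)
    stage = "setup"

    def emit(name: str) -> Path:
        p = out / name
        written.append(p)
        return p

    try:
        stage = "config-echo"
        t0 = time.perf_counter()
        with open(emit("config.yaml"), "w", encoding="utf-8") as fh:
            yaml.safe_dump(config.echo(), fh, sort_keys=True)
        _dump_json(catalog_to_records(), emit("catalog.json"))

        stage = "simulate"
        registry = simulate.generate_registry(gen_cfg)
        reports = simulate.generate_report_abstractions(registry, gen_cfg)
        write_registry_csv(registry, emit("registry.csv"))
        write_reports_csv(reports, emit("reports.csv"))
        survey = simulate.generate_survey(
            config.n_raters, config.survey_targets, seed=config.seed
        )
        survey.ratings.to_csv(emit("survey.csv"), index_label="rater_id")
        sources = simulate.generate_source_scores(
            survey, reference.EXPERT_AUDIT_RANKS, reference.LITERATURE_FREQ
        )
        sources.to_csv(emit("sources.csv"))
        log.info("simulate: %d patients, %d raters (%.2fs)",
                 gen_cfg.n_patients, config.n_raters, time.perf_counter() - t0)

        stage = "audit"
        rates = audit.audit_rates(reports, registry)
        summaries = audit.summarize(rates)
        with open(emit("rates.csv"), "w", encoding="utf-8") as fh:
            fh.write("parameter,category,numerator,denominator,rate_pct\n")
            for r in rates:
                fh.write(
                    f"{r.parameter_id},{r.category.value},{r.numerator},"
                    f"{r.denominator},{audit.format_pct(r.rate_pct)}\n"
                )
        _dump_json(
            {
                scope: {
                    "median_pct": s.median_pct,
                    "min_pct": s.min_pct,
                    "max_pct": s.max_pct,
                }
                for scope, s in summaries.items()
            },
            emit("summary.json"),
        )
        log.info("audit: overall median %.1f%%", summaries["overall"].median_pct)

        stage = "weights"
        cfg = config.mcda_config
        if config.pairwise_matrix is not None:
            ahp_result = ahp.consistency_ratio(np.asarray(config.pairwise_matrix))
            from dataclasses import replace

            cfg = replace(cfg, weights=tuple(ahp_result.weights))
            _dump_json(
                {
                    "weights": list(ahp_result.weights),
                    "lambda_max": ahp_result.lambda_max,
                    "consistency_index": ahp_result.consistency_index,
                    "consistency_ratio": ahp_result.consistency_ratio,
                    "acceptable": ahp_result.acceptable,
                },
                emit("ahp.json"),
            )

        stage = "prioritize"
        if config.reference_scores is not None:
            import pandas as pd

            final = pd.Series(config.reference_scores, name="final_score")
            final = final.reindex([p for p in sources.index if p in final.index])
        else:
            final = mcda.aggregate(sources, cfg)
        result = mcda.rank_and_tier(final, cfg)
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            panel = mcda.stampc_panel(result)
        result.table.to_csv(emit("mcda.csv"))
        _dump_json(
            {"panel": panel, "warnings": result.warnings}, emit("stampc.json")
        )

        stage = "sensitivity"
        sens = mcda.weight_sensitivity(
            sources,
            cfg,
            n_draws=config.sensitivity_draws,
            concentration=config.sensitivity_concentration,
            seed=config.seed,
        )
        _dump_json(
            {
                "n_draws": sens.n_draws,
                "concentration": sens.concentration,
                "seed": sens.seed,
                "top_k": sens.top_k,
                "top_k_stability": sens.top_k_stability,
                "mean_rank_correlation": sens.mean_rank_correlation,
            },
            emit("sensitivity.json"),
        )
        log.info("sensitivity: top-%d stability %.3f", sens.top_k, sens.top_k_stability)

        stage = "report"
        _write_report(emit("report.md"), summaries, result, panel, sens)

        stage = "manifest"
        manifest = {p.name: _sha256(p) for p in written}
        _dump_json(manifest, out / "manifest.json")
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def _write_report(path: Path, summaries, result, panel, sens) -> None:
    lines = ["# STAMP-C structured CT summary", ""]
    lines += [
        "Documentation completeness (median, synthetic cohort): "
        f"overall {summaries['overall'].median_pct:.1f}%, "
        f"generalizable {summaries['generalizable'].median_pct:.1f}%, "
        f"patient-specific {summaries['patient_specific'].median_pct:.1f}%.",
        "",
    ]
    canonical = {}
    for pid in stampc_ids():
        canonical.setdefault(get_parameter(pid).stampc_letter, []).append(pid)
    table = result.table
    for letter in STAMPC_ORDER:
        lines.append(f"## {letter} — {STAMPC_HEADINGS[letter]}")
        for pid in panel.get(letter, canonical.get(letter, [])):
            if pid in table.index:
                row = table.loc[pid]
                status = "in panel" if pid in panel.get(letter, []) else "below Tier 1"
                lines.append(
                    f"- {get_parameter(pid).name}: score "
                    f"{row['final_score']:.2f}, rank {int(row['rank'])}, "
                    f"tier {int(row['tier'])} ({status})"
                )
        lines.append("")
    lines.append("## Full prioritization")
    lines.append("")
    lines.append("| rank | parameter | score | tier | recommendation |")
    lines.append("|------|-----------|-------|------|----------------|")
    for pid, row in table.sort_values("rank").iterrows():
        lines.append(
            f"| {int(row['rank'])} | {get_parameter(pid).name} | "
            f"{row['final_score']:.2f} | {int(row['tier'])} | "
            f"{row['recommendation']} |"
        )
    lines += [
        "",
        f"Weight sensitivity: top-{sens.top_k} stability "
        f"{sens.top_k_stability:.3f}, mean Kendall tau "
        f"{sens.mean_rank_correlation:.3f} over {sens.n_draws} Dirichlet "
        f"draws (concentration {sens.concentration:g}).",
        "",
    ]
    path.write_text("\n".join(lines), encoding="utf-8")


def load_cohort(registry_path: Path, reports_path: Path) -> CohortDataset:
    return CohortDataset(
        registry=read_registry_csv(registry_path),
        reports=read_reports_csv(reports_path),
    )
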