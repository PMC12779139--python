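"""End-to-end pipeline orchestration and comparative reporting.

``run_pipeline`` drives the full analysis — record generation (or loading),
cohort selection and exclusion, event-log construction, process-map mining
and rendering, waiting-time statistics, cost tables, and the cross-hospital
comparison tables — writing every artifact into one output directory with a
content-hash manifest.  With a fixed seed the manifest hashes are identical
across reruns.

Hospitals are anonymized at report time (H1..Hn, by decreasing case volume)
with a sidecar mapping file.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cohort as cb
from . import costs as ca
from . import discovery as pd_
from . import stats as ps
from .catalog import CATEGORIES, TariffCatalog, build_default_catalog
from .eventlog import EventLog, export_xes, write_log_csv
from .records import (
    read_inpatient_csv,
    read_outpatient_csv,
    write_inpatient_csv,
    write_outpatient_csv,
)
from .synthetic import GeneratorConfig, generate_labeled_cohort


class PipelineError(RuntimeError):
    """Failure of a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Exactly one of ``generator`` or (``inpatient_path``,
    ``outpatient_path``) must be supplied."""

    out_dir: str | Path
    generator: GeneratorConfig | None = None
    inpatient_path: str | Path | None = None
    outpatient_path: str | Path | None = None
    catalog: TariffCatalog | None = None
    view: pd_.ViewConfig = field(default_factory=pd_.ViewConfig)
    scale: float = 1.0
    seed: int | None = None
    anonymize: bool = True
    plots: bool = False

    def validate(self) -> None:
        has_gen = self.generator is not None
        has_paths = self.inpatient_path is not None and self.outpatient_path is not None
        if has_gen == has_paths:
            raise ValueError(
                "supply exactly one of a generator config or input record paths"
            )


def compare_hospitals(
    summaries: dict[str, ca.CostSummary],
) -> dict[str, pd.DataFrame]:
    """Long-format comparison tables (hospital, category, metric, value) for
    per-category frequency, per-category mean cost, and mean total cost."""
    if len(summaries) < 2:
        raise ValueError("comparison requires at least two hospital summaries")
    freq_rows, cost_rows, total_rows = [], [], []
    for hosp in sorted(summaries):
        s = summaries[hosp]
        for category in CATEGORIES:
            st = s.categories[category]
            freq_rows.append((hosp, category, "frequency", st.frequency))
            cost_rows.append((hosp, category, "mean_cost", st.mean_cost))
        total_rows.append((hosp, "all", "mean_total_cost", s.mean_total_cost))
    cols = ["hospital", "category", "metric", "value"]
    return {
        "frequency": pd.DataFrame(freq_rows, columns=cols),
        "mean_cost": pd.DataFrame(cost_rows, columns=cols),
        "mean_total_cost": pd.DataFrame(total_rows, columns=cols),
    }


def _anonymize_hospitals(cases: list[cb.SurgeryCase]) -> dict[str, str]:
    """H1..Hn by decreasing kept-case volume (ties by original id)."""
    volume: dict[str, int] = {}
    for c in cases:
        volume[c.hospital_id] = volume.get(c.hospital_id, 0) + 1
    ranked = sorted(volume, key=lambda h: (-volume[h], h))
    return {h: f"H{i + 1}" for i, h in enumerate(ranked)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_cost_csv(summaries: dict[str, ca.CostSummary], path: Path) -> None:
    """One block per hospital, columns exactly Median, Mean, S.D., Frequency,
    Types."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["hospital", "category", "Median", "Mean", "S.D.", "Frequency", "Types"])
        for hosp in sorted(summaries):
            s = summaries[hosp]
            for category in CATEGORIES:
                st = s.categories[category]
                w.writerow(
                    [
                        hosp,
                        category,
                        f"{st.median_cost:.2f}",
                        f"{st.mean_cost:.2f}",
                        f"{st.sd_cost:.2f}",
                        f"{st.frequency:.2f}",
                        st.types,
                    ]
                )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; return the artifact manifest (also written as
    ``manifest.json``).  Partial failures raise :class:`PipelineError` naming
    the stage."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = config.catalog or (
        config.generator.catalog if config.generator else build_default_catalog()
    )

    stage = "load_records"
    try:
        if config.generator is not None:
            stage = "generate_records"
            gen = config.generator
            if config.seed is not None:
                from dataclasses import replace

                gen = replace(gen, seed=config.seed)
            cohort = generate_labeled_cohort(gen)
            inpatient, outpatient = cohort.inpatient, cohort.outpatient
            write_inpatient_csv(inpatient, out / "inpatient.csv")
            write_outpatient_csv(outpatient, out / "outpatient.csv")
            with open(out / "injections.csv", "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["patient_id", "rule"])
                for pid in sorted(cohort.injections):
                    w.writerow([pid, cohort.injections[pid]])
        else:
            inpatient = read_inpatient_csv(config.inpatient_path)
            outpatient = read_outpatient_csv(config.outpatient_path)

        stage = "select_cases"
        cases = cb.select_cases(inpatient)
        stage = "apply_exclusions"
        kept, report = cb.apply_exclusions(cases, inpatient, outpatient, catalog)
        (out / "exclusion_report.json").write_text(
            json.dumps(report.as_dict(), indent=1)
        )

        mapping = _anonymize_hospitals(kept) if config.anonymize else {}
        with open(out / "hospital_mapping.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["hospital_id", "anonymized_id"])
            for h in sorted(mapping):
                w.writerow([h, mapping[h]])
        if mapping:
            from dataclasses import replace

            kept = [replace(c, hospital_id=mapping[c.hospital_id]) for c in kept]

        stage = "build_event_log"
        log = cb.build_event_log(kept, outpatient, catalog)
        cb.write_cases_csv(kept, out / "cases.csv")

        stage = "discover_maps"
        for hosp, sublog in sorted(log.by_hospital().items()):
            write_log_csv(sublog, out / f"event_log_{hosp}.csv")
            export_xes(sublog, out / f"event_log_{hosp}.xes")
            pmap = pd_.mine_map(sublog)
            zoomed = pd_.zoom(pmap, config.view.path_zoom, config.view.activity_zoom)
            (out / f"map_{hosp}.json").write_text(pd_.map_to_json(pmap))
            for name, vw in (
                ("frequency", pd_.ViewConfig(primary_view="frequency", mixed=False)),
                ("performance", pd_.ViewConfig(primary_view="performance", mixed=False)),
                ("mixed", pd_.ViewConfig(primary_view="frequency", mixed=True)),
            ):
                vw.performance_statistic = config.view.performance_statistic
                (out / f"map_{hosp}_{name}.dot").write_text(pd_.render_dot(zoomed, vw))

        stage = "performance_stats"
        summaries = ps.hospital_summary(log, kept)
        with open(out / "hospital_summary.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                [
                    "hospital_id",
                    "n_patients",
                    "n_events",
                    "avg_events_per_patient",
                    "median_case_duration_days",
                    "share_of_total_cases",
                ]
            )
            for s in summaries:
                w.writerow(
                    [
                        s.hospital_id,
                        s.n_patients,
                        s.n_events,
                        s.avg_events_per_patient,
                        s.median_case_duration_days,
                        f"{s.share_of_total_cases:.2f}",
                    ]
                )
        with open(out / "durations.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["hospital_id", "mode", "n", "median", "q1", "q3"])
            for mode in ps.MODES:
                for h, dist in ps.case_durations(kept, mode).items():
                    q1, q3 = dist.iqr
                    w.writerow([h, mode, len(dist.values), dist.median, q1, q3])
        with open(out / "adherence_30d.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["hospital_id", "adherence_30d"])
            for h, frac in ps.adherence_30d(kept).items():
                w.writerow([h, f"{frac:.4f}"])

        stage = "cost_analysis"
        cost_summaries = ca.cost_summary(log, catalog, scale=config.scale)
        _write_cost_csv(cost_summaries, out / "cost_summary.csv")

        stage = "comparison_tables"
        if len(cost_summaries) >= 2:
            tables = compare_hospitals(cost_summaries)
            for name, df in tables.items():
                df.to_csv(out / f"comparison_{name}.csv", index=False)
            if config.plots:
                _plot_comparisons(tables, out)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    manifest = {
        "seed": config.seed
        if config.seed is not None
        else (config.generator.seed if config.generator else None),
        "n_cases": len(kept),
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _plot_comparisons(tables: dict[str, pd.DataFrame], out: Path) -> None:
    """Grouped bar charts backing the three comparison tables."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for name, df in tables.items():
        fig, ax = plt.subplots(figsize=(6, 4))
        pivot = df.pivot_table(index="category", columns="hospital", values="value")
        pivot.plot.bar(ax=ax)
        ax.set_ylabel(name.replace("_", " "))
        fig.tight_layout()
        fig.savefig(out / f"comparison_{name}.png", dpi=120)
        plt.close(fig)
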