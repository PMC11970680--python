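"""Config-driven orchestration: score -> detect -> measures -> agree /
gridsearch -> compare, with reproducible file outputs and a run manifest."""

from __future__ import annotations

import hashlib
import json
import shutil
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .agreement_optimization import (
    GridSpec,
    cohort_agreement,
    grid_search,
    minute_agreement,
)
from .comparison_stats import (
    apply_missing_strategy,
    build_paired_daily_table,
    extended_bland_altman,
    missed_night_report,
    participant_means,
    wilcoxon_signed_rank,
)
from .core_io import CsvDialect, ParticipantDataset, read_epoch_csv, read_sleep_log
from .sleep_measures import MEASURE_NAMES, aggregate_daily, assign_day, compute_measures
from .sleep_wake_scoring import ScorerConfig, score_cole_kripke
from .tudor_locke import TLParameters, detect_sleep_periods, periods_from_log

__all__ = ["PipelineConfig", "run_pipeline", "daily_measures_table", "load_datasets"]

#: Named Tudor-Locke parameter presets.
TL_PRESETS = {
    "tl-default": TLParameters(),
    "tl-chronic-pain": TLParameters(5, 25, 160, 5, 1440),
}


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs.

    ``tl_params`` maps method label -> TLParameters; the comparison stage
    pairs each label against the diary ("SL") and against the other labels.
    Grid mode (``grid`` set) and single-parameter mode are mutually
    exclusive per run.
    """

    epoch_files: list[str] = field(default_factory=list)
    sleep_log: str | None = None
    output_dir: str = "actisleep_out"
    scorer: ScorerConfig = field(default_factory=ScorerConfig)
    tl_params: dict[str, TLParameters] = field(
        default_factory=lambda: {"TLD": TL_PRESETS["tl-default"]}
    )
    grid: GridSpec | None = None
    missing_strategy: str = "complete_case"
    min_nights: int = 5
    quiet: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        cfg.epoch_files = [str(p) for p in raw.get("epoch_files", [])]
        cfg.sleep_log = raw.get("sleep_log")
        cfg.output_dir = raw.get("output_dir", cfg.output_dir)
        cfg.missing_strategy = raw.get("missing_strategy", cfg.missing_strategy)
        cfg.min_nights = int(raw.get("min_nights", cfg.min_nights))
        if "scorer" in raw:
            s = raw["scorer"]
            cfg.scorer = ScorerConfig(
                weights=tuple(s.get("weights", ScorerConfig().weights)),
                offsets=tuple(s.get("offsets", ScorerConfig().offsets)),
                scale=float(s.get("scale", ScorerConfig().scale)),
                threshold=float(s.get("threshold", ScorerConfig().threshold)),
                count_divisor=s.get("count_divisor"),
                count_cap=s.get("count_cap"),
            )
        if "tudor_locke" in raw:
            cfg.tl_params = {
                label: (TL_PRESETS[p] if isinstance(p, str) else TLParameters(**p))
                for label, p in raw["tudor_locke"].items()
            }
        if "grid" in raw:
            g = raw["grid"]
            cfg.grid = GridSpec(
                bedtime_def=tuple(g.get("bedtime_def", GridSpec().bedtime_def)),
                waketime_def=tuple(g.get("waketime_def", GridSpec().waketime_def)),
                min_period_len=tuple(g.get("min_period_len", GridSpec().min_period_len)),
                min_nonzero_epochs=tuple(
                    g.get("min_nonzero_epochs", GridSpec().min_nonzero_epochs)
                ),
                max_period_len=int(g.get("max_period_len", GridSpec().max_period_len)),
            )
        return cfg


def load_datasets(config: PipelineConfig) -> list[ParticipantDataset]:
    entries = read_sleep_log(config.sleep_log) if config.sleep_log else []
    by_pid: dict[str, list] = {}
    for e in entries:
        by_pid.setdefault(e.participant_id, []).append(e)
    datasets = []
    for path in config.epoch_files:
        series = read_epoch_csv(path)
        datasets.append(
            ParticipantDataset(series, by_pid.get(series.participant_id, []))
        )
    return datasets


def daily_measures_table(datasets, periods_by_pid, sw_by_pid) -> pd.DataFrame:
    """Flat per-(participant, day) measures table for one detection method."""
    rows = []
    for ds in datasets:
        pid = ds.participant_id
        periods = periods_by_pid[pid]
        sw = sw_by_pid[pid]
        pms = [(p, compute_measures(p, sw, ds.epochs)) for p in periods]
        for dm in aggregate_daily(pms, ds.epochs):
            row = {"participant_id": pid, "day": dm.calendar_day,
                   "n_periods": dm.n_periods}
            row.update(dm.measures.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def _log(config: PipelineConfig, msg: str) -> None:
    if not config.quiet:
        print(msg, file=sys.stderr)


def run_pipeline(config: PipelineConfig, datasets=None) -> dict:
    """Run the full analysis and write outputs under ``config.output_dir``.

    Returns a dict of the in-memory artifacts (periods, daily tables,
    agreement or grid table, comparison tables). File outputs are removed
    if any stage fails, so partial runs leave no stale artifacts.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    try:
        if datasets is None:
            datasets = load_datasets(config)
        if not datasets:
            raise ValueError("no input datasets")
        _log(config, f"[load] {len(datasets)} participants")

        sw_by_pid = {
            d.participant_id: score_cole_kripke(d.epochs, config.scorer)
            for d in datasets
        }
        _log(config, f"[score] done in {time.time() - t0:.1f}s")

        artifacts: dict = {}
        log_periods = {
            d.participant_id: periods_from_log(d.log, d.epochs) for d in datasets
        }

        if config.grid is not None:
            result = grid_search(datasets, config.grid, config.scorer)
            result.table.to_csv(out / "grid_results.csv", index=False)
            artifacts["grid"] = result
            _log(config, f"[gridsearch] {len(result.table)} parameter sets; "
                         f"best mean agreement {result.best_agreement:.3f}")
        else:
            period_rows = []
            daily_by_method = {}
            agreements = {}
            for label, params in config.tl_params.items():
                det = {
                    d.participant_id: detect_sleep_periods(
                        sw_by_pid[d.participant_id], d.epochs, params
                    )
                    for d in datasets
                }
                daily_by_method[label] = det
                per_part = [
                    minute_agreement(det[d.participant_id],
                                     log_periods[d.participant_id])
                    for d in datasets
                ]
                agreements[label] = cohort_agreement(per_part)
                for pid, periods in det.items():
                    for p in periods:
                        period_rows.append(
                            {"participant_id": pid, "onset": p.onset_epoch,
                             "end": p.end_epoch, "duration_min": p.duration_min,
                             "source": label}
                        )
            pd.DataFrame(period_rows).to_csv(out / "periods.csv", index=False)

            tables = {"SL": daily_measures_table(datasets, log_periods, sw_by_pid)}
            for label, det in daily_by_method.items():
                tables[label] = daily_measures_table(datasets, det, sw_by_pid)
            combined = pd.concat(
                [t.assign(method=m) for m, t in tables.items()], ignore_index=True
            )
            combined.to_csv(out / "daily_measures.csv", index=False)

            pd.DataFrame(
                [{"method": m, "mean_agreement": v} for m, v in agreements.items()]
            ).to_csv(out / "agreement.csv", index=False)
            artifacts["agreement"] = agreements
            artifacts["daily_tables"] = tables
            _log(config, f"[agree] {agreements}")

            # comparison stage: pairwise stats on the paired daily table
            from .sleep_measures import DailyMeasures, SleepMeasures

            daily_struct = {}
            for m, t in tables.items():
                dms = []
                for r in t.itertuples():
                    dms.append(
                        DailyMeasures(
                            participant_id=r.participant_id,
                            calendar_day=r.day,
                            measures=SleepMeasures(
                                latency=r.latency, efficiency=r.efficiency,
                                total_minutes_in_bed=r.total_minutes_in_bed,
                                total_sleep_time=r.total_sleep_time, waso=r.waso,
                                n_awakenings=int(r.n_awakenings),
                                avg_awakening_len=r.avg_awakening_len,
                                movement_index=r.movement_index,
                                fragmentation_index=r.fragmentation_index,
                                sleep_fragmentation_index=r.sleep_fragmentation_index,
                            ),
                            n_periods=int(r.n_periods),
                        )
                    )
                daily_struct[m] = dms
            log_days = {
                d.participant_id: [
                    assign_day(p, d.epochs) for p in log_periods[d.participant_id]
                ]
                for d in datasets
            }
            paired = build_paired_daily_table(daily_struct, log_days)
            artifacts["paired_daily"] = paired

            methods = list(tables)
            missed = [missed_night_report(paired, m) for m in methods if m != "SL"]
            pd.DataFrame([vars(r) for r in missed]).to_csv(
                out / "missed_nights.csv", index=False
            )
            artifacts["missed_nights"] = missed

            filtered = apply_missing_strategy(paired, config.missing_strategy)
            ba_rows, wx_rows = [], []
            pairs = [(a, b) for i, a in enumerate(methods) for b in methods[i + 1:]]
            for a, b in pairs:
                for measure in MEASURE_NAMES:
                    try:
                        ba = extended_bland_altman(filtered, measure, b, a)
                        ba_rows.append(vars(ba))
                    except ValueError:
                        pass
                    ma = participant_means(filtered, measure, a)
                    mb = participant_means(filtered, measure, b)
                    common = ma.index.intersection(mb.index)
                    if len(common) >= 2:
                        wx = wilcoxon_signed_rank(ma[common], mb[common])
                        wx_rows.append(
                            {"method_a": a, "method_b": b, "measure": measure,
                             **vars(wx)}
                        )
            pd.DataFrame(ba_rows).to_csv(out / "bland_altman.csv", index=False)
            pd.DataFrame(wx_rows).to_csv(out / "wilcoxon.csv", index=False)
            artifacts["bland_altman"] = ba_rows
            artifacts["wilcoxon"] = wx_rows
            _log(config, f"[compare] {len(ba_rows)} BA rows, {len(wx_rows)} tests")

        manifest = {
            "version": __version__,
            "config_hash": hashlib.sha256(
                repr(config).encode()
            ).hexdigest(),
            "inputs": {
                str(p): hashlib.sha256(Path(p).read_bytes()).hexdigest()
                for p in config.epoch_files
                if Path(p).exists()
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        _log(config, f"[done] {time.time() - t0:.1f}s -> {out}")
        return artifacts
    except Exception:
        shutil.rmtree(out, ignore_errors=True)
        raise
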