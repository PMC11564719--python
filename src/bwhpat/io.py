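"""Readers/writers, run configuration and the end-to-end pipeline driver.

The pipeline mirrors the four-phase design: per (channel, case) a feature
matrix is built from the segmented recordings, INCA selects the minimum-loss
feature subset, the 1-NN/L1 classifier produces a cross-validated outcome,
and the per-channel accuracies of the three cases feed the cortex map.
All artifacts are written under the output directory with a manifest; under
a fixed seed every result file is reproduced byte-identically (wall-clock
timings live only in the manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classification import ChannelOutcome, KnnConfig, knn_cv
from .cortex_map import CortexMap, build_cortex_map
from .features import build_feature_matrix
from .selection import IncaConfig, inca_select
from .synthetic_data import (EegDataset, SynthConfig, generate_dataset,
                             read_dataset, segment_record)
from .tqwt import TqwtParams

__all__ = ["RunConfig", "PipelineResult", "read_recording", "run_pipeline"]

logger = logging.getLogger("bwhpat")

DEFAULT_CASE_DURATIONS = (60.0, 30.0, 15.0)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Exactly one of ``synth`` (generator conditions) or ``dataset_manifest``
    (path to a written dataset) must be set.
    """

    synth: SynthConfig | None = None
    dataset_manifest: str | Path | None = None
    case_durations: tuple[float, ...] = DEFAULT_CASE_DURATIONS
    tqwt: TqwtParams = field(default_factory=TqwtParams)
    inca: IncaConfig = field(default_factory=IncaConfig)
    knn: KnnConfig = field(default_factory=KnnConfig)
    out_dir: str | Path | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.synth is None) == (self.dataset_manifest is None):
            raise ValueError(
                "exactly one of synth config or dataset_manifest must be given"
            )
        if self.seed is not None:
            if self.synth is not None:
                self.synth = dataclasses.replace(self.synth, seed=self.seed)
            self.inca = dataclasses.replace(self.inca, rng_seed=self.seed)
            self.knn = dataclasses.replace(self.knn, rng_seed=self.seed)


@dataclass
class PipelineResult:
    outcomes: list[ChannelOutcome]
    cortex: CortexMap
    losses: dict[tuple[int, int], np.ndarray]
    selected_sizes: dict[tuple[int, int], int]
    config: RunConfig


def read_recording(path: str | Path, fmt: str | None = None
                   ) -> tuple[np.ndarray, dict]:
    """Read one channel-by-sample recording from CSV or EDF.

    CSV rows are channels (first column: channel name); EDF reading goes
    through :mod:`mne`.  Returns the matrix and metadata (channel names and,
    for EDF, the sampling rate).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        try:
            df = pd.read_csv(path, header=None, index_col=0,
                             float_precision="round_trip")
            data = df.to_numpy(dtype=float)
        except Exception as exc:
            raise ValueError(f"malformed CSV recording {path}: {exc}") from exc
        if np.isnan(data).any():
            bad = int(np.where(np.isnan(data).any(axis=1))[0][0])
            raise ValueError(f"NaN values in {path}, first bad record row {bad}")
        return data, {"channel_names": [str(i) for i in df.index], "fs": None}
    if fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        return raw.get_data(), {"channel_names": list(raw.ch_names),
                                "fs": float(raw.info["sfreq"])}
    raise ValueError(f"unsupported recording format: {fmt!r}")


def _case_segments(dataset: EegDataset, channel0: int,
                   duration_s: float) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    segs, labels, subjects = [], [], []
    for rec, lab, sid in zip(dataset.records, dataset.labels, dataset.subject_ids):
        for s in segment_record(rec[channel0], dataset.fs, duration_s):
            segs.append(s)
            labels.append(lab)
            subjects.append(sid)
    return segs, np.asarray(labels), np.asarray(subjects)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Features -> INCA -> kNN per (channel, case), then the cortex map."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    if cfg.synth is not None:
        dataset = generate_dataset(cfg.synth)
    else:
        dataset = read_dataset(cfg.dataset_manifest)
    timings["dataset"] = time.perf_counter() - t0
    n_channels = dataset.records[0].shape[0]

    outcomes: list[ChannelOutcome] = []
    losses: dict[tuple[int, int], np.ndarray] = {}
    sizes: dict[tuple[int, int], int] = {}
    knn_cfg = dataclasses.replace(cfg.knn, folds=cfg.inca.cv_folds,
                                  rng_seed=cfg.inca.rng_seed)
    t0 = time.perf_counter()
    for case_id, duration in enumerate(cfg.case_durations, start=1):
        for ch in range(1, n_channels + 1):
            stage = f"case {case_id} channel {ch}"
            try:
                segs, y, _sub = _case_segments(dataset, ch - 1, duration)
                fm = build_feature_matrix(segs, y, cfg.tqwt,
                                          channel=ch, case=case_id)
                res = inca_select(fm.X, fm.y, cfg.inca)
                oc = knn_cv(fm.X[:, res.sfeat_indices], fm.y, knn_cfg,
                            channel=ch, case=case_id)
            except Exception as exc:
                raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc
            outcomes.append(oc)
            losses[(ch, case_id)] = res.loss
            sizes[(ch, case_id)] = int(res.sfeat_indices.size)
            logger.info("%s: acc=%.4f F1=%.4f selected=%d",
                        stage, oc.accuracy, oc.f1, res.sfeat_indices.size)
    timings["channel_runs"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cortex = build_cortex_map(outcomes, channel_names=dataset.channel_names,
                              n_cases=len(cfg.case_durations))
    timings["cortex_map"] = time.perf_counter() - t0

    result = PipelineResult(outcomes=outcomes, cortex=cortex, losses=losses,
                            selected_sizes=sizes, config=cfg)
    if cfg.out_dir is not None:
        _write_results(result, Path(cfg.out_dir), timings)
    return result


def _config_dict(cfg: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return {k: enc(v) for k, v in dataclasses.asdict(cfg).items()
            if k != "out_dir"}


def _write_results(result: PipelineResult, out_dir: Path,
                   timings: dict[str, float]) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    per_channel = []
    for oc in result.outcomes:
        key = (oc.channel, oc.case)
        per_channel.append({
            "channel": oc.channel,
            "case": oc.case,
            "accuracy": oc.accuracy,
            "f1": oc.f1,
            "confusion": oc.confusion.tolist(),
            "selected_size": result.selected_sizes[key],
        })
        name = f"channel{oc.channel:02d}_case{oc.case}.json"
        _dump_json(out_dir / name, {
            **per_channel[-1],
            "loss_curve": result.losses[key].tolist(),
        })
    cx = result.cortex
    _dump_json(out_dir / "cortex_map.json", {
        "cac": cx.cac.tolist(),
        "medians": cx.medval.tolist(),
        "meaningful_channels": [sorted(s) for s in cx.mch],
        "intersection": cx.umc,
        "intersection_names": cx.umc_names,
        "channel_names": list(cx.channel_names),
    })
    pd.DataFrame(per_channel).to_csv(out_dir / "summary.tsv", sep="\t",
                                     index=False, float_format="%.6f")
    from . import __version__

    cfg_json = json.dumps(_config_dict(result.config), sort_keys=True)
    _dump_json(out_dir / "manifest.json", {
        "bwhpat_version": __version__,
        "config": _config_dict(result.config),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stage_seconds": timings,          # informational; not deterministic
        "n_outcomes": len(result.outcomes),
    })


def _dump_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
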