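"""End-to-end orchestration: simulate -> segment -> preprocess -> train ->
relevance -> overlap -> profile, with seeded determinism and a run manifest.

Every stage persists its artifact under the run directory; the manifest
records configuration, derived seeds, cycle counts, accuracies, stage
timings and a SHA-256 checksum per file, so a rerun with the same
configuration reproduces every numeric output bit for bit (timings and
timestamps aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .errors import GaitprintError, InvalidConfigError
from .gait_events import EventConfig, detect_events, process_trial, touchdown_error_ms
from .layout import VariableLayout
from .network import (
    NetworkConfig,
    accuracy_by_participant,
    classify,
    sample_training_indices,
    train,
)
from .overlap import OverlapConfig, overlap_curve, profile_variables
from .preprocess import DataMatrix, OutlierConfig, assemble_matrix, filter_outliers, scale_matrix
from .relevance import (
    LrpConfig,
    aggregate_relevance,
    relevance_for_cycles,
    smooth_pattern_matrix,
)

STAGES = ("simulate", "segment", "preprocess", "train", "relevance",
          "overlap", "profile")


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Nested configuration of a full pipeline run.

    ``scale='reduced'`` shrinks the timepoint grid (25 instead of 100
    points per cycle), coarsens the overlap schedule and lowers the
    Monte-Carlo budget, keeping the run desk-sized; ``'full'`` keeps the
    canonical 5400-variable layout and the step-of-five schedule.
    """

    outdir: str = "gaitprint_run"
    seed: int = 0
    scale: str = "full"
    train_cycles_per_participant: int = 10
    n_timepoints: int | None = None
    cohort: synthetic.CohortConfig | None = None
    event: EventConfig = field(default_factory=EventConfig)
    outlier: OutlierConfig = field(default_factory=OutlierConfig)
    lrp: LrpConfig = field(default_factory=LrpConfig)
    overlap: OverlapConfig | None = None
    network_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in ("full", "reduced"):
            raise InvalidConfigError("scale must be 'full' or 'reduced'")

    def resolved_timepoints(self) -> int:
        if self.n_timepoints is not None:
            return self.n_timepoints
        return 100 if self.scale == "full" else 30

    def resolved_cohort(self) -> synthetic.CohortConfig:
        if self.cohort is not None:
            return self.cohort
        return synthetic.CohortConfig(seed=derive_seed(self.seed, "cohort"))

    def resolved_overlap(self, n_variables: int) -> OverlapConfig:
        if self.overlap is not None:
            return self.overlap
        if self.scale == "full":
            return OverlapConfig(seed=derive_seed(self.seed, "overlap"))
        return OverlapConfig(step=150, mc_samples=20_000,
                             seed=derive_seed(self.seed, "overlap"))

    def to_yaml(self, path) -> None:
        blob = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(blob, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            blob = yaml.safe_load(fh) or {}
        return cls.from_dict(blob)

    @classmethod
    def from_dict(cls, blob: dict) -> "RunConfig":
        kwargs = dict(blob)
        if kwargs.get("cohort") is not None:
            cohort = dict(kwargs["cohort"])
            for key in ("signature_windows",):
                if key in cohort:
                    cohort[key] = tuple(tuple(w) for w in cohort[key])
            for key in ("signature_joints", "signature_planes"):
                if key in cohort:
                    cohort[key] = tuple(cohort[key])
            kwargs["cohort"] = synthetic.CohortConfig(**cohort)
        for key, klass in (("event", EventConfig), ("outlier", OutlierConfig),
                           ("lrp", LrpConfig), ("overlap", OverlapConfig)):
            if kwargs.get(key) is not None and isinstance(kwargs[key], dict):
                sub = dict(kwargs[key])
                if key == "lrp" and "smoothing_weights" in sub:
                    sub["smoothing_weights"] = tuple(sub["smoothing_weights"])
                kwargs[key] = klass(**sub)
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and return the run manifest.

    On a stage failure the manifest (with the failing stage recorded) is
    still written before the exception propagates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "scale": config.scale,
        "stage_seeds": {s: derive_seed(config.seed, s) for s in STAGES},
        "counts": {},
        "results": {},
        "files": {},
        "timings_s": {},
        "completed_stages": [],
        "failed_stage": None,
    }
    try:
        _run_stages(config, outdir, manifest)
    except Exception as exc:
        manifest["failed_stage"] = manifest.get("_current_stage")
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest.pop("_current_stage", None)
        _write_manifest(outdir, manifest)
        raise
    manifest.pop("_current_stage", None)
    _write_manifest(outdir, manifest)
    return manifest


def _write_manifest(outdir: Path, manifest: dict) -> None:
    manifest["created"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)


def _register(outdir: Path, manifest: dict, name: str) -> None:
    manifest["files"][name] = _sha256(outdir / name)


def _run_stages(config: RunConfig, outdir: Path, manifest: dict) -> None:
    timer = time.perf_counter
    n_t = config.resolved_timepoints()
    layout = VariableLayout(n_t)

    # --- simulate ---------------------------------------------------------
    manifest["_current_stage"] = "simulate"
    t0 = timer()
    cohort_cfg = config.resolved_cohort()
    profiles, trials = synthetic.synthesize_cohort(cohort_cfg)
    manifest["counts"]["participants"] = cohort_cfg.n_participants
    manifest["counts"]["trials"] = sum(len(v) for v in trials.values())
    manifest["timings_s"]["simulate"] = round(timer() - t0, 3)

    # --- segment ----------------------------------------------------------
    manifest["_current_stage"] = "segment"
    t0 = timer()
    cycles = []
    touchdown_errors = []
    for pid, per_trial in trials.items():
        for label, trial in per_trial.items():
            events = detect_events(trial, config.event)
            touchdown_errors.append(touchdown_error_ms(trial, events))
            cycles.extend(process_trial(trial, config.event, n_t))
    manifest["counts"]["cycles_segmented"] = len(cycles)
    manifest["results"]["mean_touchdown_error_ms"] = round(
        float(np.mean(touchdown_errors)), 4
    )
    manifest["timings_s"]["segment"] = round(timer() - t0, 3)

    # --- preprocess -------------------------------------------------------
    manifest["_current_stage"] = "preprocess"
    t0 = timer()
    raw = assemble_matrix(cycles, layout, scale=False)
    keep, report = filter_outliers(raw.values, raw.index["participant"].to_numpy(),
                                   config.outlier)
    matrix = DataMatrix(
        values=scale_matrix(raw.values[keep]),
        index=raw.index.loc[keep].reset_index(drop=True),
        layout=layout,
    )
    matrix.save(outdir / "matrix.npz", outdir / "matrix_index.csv")
    report.to_csv(outdir / "outlier_report.csv", index=False)
    manifest["counts"]["cycles_removed_as_outliers"] = int((~keep).sum())
    manifest["counts"]["cycles_retained"] = matrix.n_cycles
    _register(outdir, manifest, "matrix.npz")
    _register(outdir, manifest, "matrix_index.csv")
    _register(outdir, manifest, "outlier_report.csv")
    manifest["timings_s"]["preprocess"] = round(timer() - t0, 3)

    # --- train ------------------------------------------------------------
    manifest["_current_stage"] = "train"
    t0 = timer()
    train_pool = matrix.restrict(["CR", "WR"])
    test_set = matrix.restrict(["TR"])
    pool_labels = train_pool.index["participant"].to_numpy()
    chosen = sample_training_indices(
        pool_labels, config.train_cycles_per_participant,
        derive_seed(config.seed, "train-sampling"),
    )
    net_kwargs = dict(
        input_nodes=layout.n_variables,
        output_nodes=int(pd.unique(pool_labels).size),
        seed=derive_seed(config.seed, "train"),
    )
    net_kwargs.update(config.network_overrides)
    net_cfg = NetworkConfig(**net_kwargs)
    weights, log = train(train_pool.values[chosen], pool_labels[chosen], net_cfg)
    weights.save(outdir / "weights.npz")
    with open(outdir / "training_log.json", "w") as fh:
        json.dump(log, fh, indent=1)
    predictions, _ = classify(weights, test_set.values)
    test_labels = test_set.index["participant"].to_numpy()
    acc = accuracy_by_participant(predictions, test_labels)
    acc.per_participant.to_csv(outdir / "accuracy.csv", index=False)
    manifest["counts"]["training_cycles"] = int(chosen.size)
    manifest["counts"]["test_cycles"] = test_set.n_cycles
    manifest["results"]["test_accuracy_percent"] = round(acc.overall, 4)
    manifest["results"]["epochs_run"] = log["epochs_run"]
    _register(outdir, manifest, "weights.npz")
    _register(outdir, manifest, "training_log.json")
    _register(outdir, manifest, "accuracy.csv")
    manifest["timings_s"]["train"] = round(timer() - t0, 3)

    # --- relevance --------------------------------------------------------
    manifest["_current_stage"] = "relevance"
    t0 = timer()
    patterns, correct = relevance_for_cycles(weights, test_set.values,
                                             test_labels, config.lrp)
    smoothed = smooth_pattern_matrix(patterns, layout, config.lrp)
    per_part, overall, ranked = aggregate_relevance(
        smoothed, test_labels[correct], layout
    )
    ranked.to_frame().to_csv(outdir / "ranking.csv", index=False,
                             float_format="%.10g")
    rel = layout.descriptor_frame()
    rel["relevance"] = overall
    rel.to_csv(outdir / "overall_relevance.csv", index=False,
               float_format="%.10g")
    manifest["counts"]["cycles_explained"] = int(correct.sum())
    _register(outdir, manifest, "ranking.csv")
    _register(outdir, manifest, "overall_relevance.csv")
    manifest["timings_s"]["relevance"] = round(timer() - t0, 3)

    # --- overlap ----------------------------------------------------------
    manifest["_current_stage"] = "overlap"
    t0 = timer()
    ov_cfg = config.resolved_overlap(layout.n_variables)
    curves = [
        overlap_curve(test_set.values, test_labels, ranked, ov_cfg, direction)
        for direction in ("most_relevant", "least_relevant")
    ]
    pd.concat([c.to_frame() for c in curves]).to_csv(
        outdir / "overlap_curves.csv", index=False, float_format="%.6g"
    )
    for c in curves:
        finite = np.isfinite(c.mean_overlap)
        key = f"mean_overlap_first_size_{c.direction}"
        if finite.any():
            manifest["results"][key] = round(float(c.mean_overlap[finite][0]), 3)
    _register(outdir, manifest, "overlap_curves.csv")
    manifest["timings_s"]["overlap"] = round(timer() - t0, 3)

    # --- profile ----------------------------------------------------------
    manifest["_current_stage"] = "profile"
    t0 = timer()
    profiles_by_dir = profile_variables(ranked)
    frames = []
    for direction, prof in profiles_by_dir.items():
        frames.append(pd.DataFrame({
            "direction": direction,
            "stratification": "movement",
            "category": prof.by_movement.index,
            "value": prof.by_movement.to_numpy(),
        }))
        frames.append(pd.DataFrame({
            "direction": direction,
            "stratification": "group",
            "category": prof.by_group.index,
            "value": prof.by_group.to_numpy(),
        }))
        frames.append(pd.DataFrame({
            "direction": direction,
            "stratification": "timepoint",
            "category": np.arange(1, layout.n_timepoints + 1).astype(str),
            "value": prof.by_time,
        }))
    pd.concat(frames).to_csv(outdir / "variable_profiles.csv", index=False,
                             float_format="%.6g")
    _register(outdir, manifest, "variable_profiles.csv")
    manifest["timings_s"]["profile"] = round(timer() - t0, 3)
    manifest["completed_stages"] = list(STAGES)


# ---------------------------------------------------------------------------
# Artifact round-trip validation


def validate_io_roundtrip(outdir) -> pd.DataFrame:
    """Check that every artifact of a completed run reloads faithfully.

    Each file listed in the manifest is re-hashed and re-parsed; parseable
    files are additionally round-tripped (load, re-serialize, re-load,
    compare). Returns one row per file with a pass/fail status.
    """
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise GaitprintError(f"no manifest.json under {outdir}; not a completed run")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if not manifest.get("files"):
        raise GaitprintError("manifest lists no artifacts")
    rows = []
    for name, digest in sorted(manifest["files"].items()):
        path = outdir / name
        if not path.exists():
            rows.append((name, False, "missing"))
            continue
        if _sha256(path) != digest:
            rows.append((name, False, "checksum mismatch"))
            continue
        ok, detail = _roundtrip_file(path)
        rows.append((name, ok, detail))
    return pd.DataFrame(rows, columns=["file", "passed", "detail"])


def _roundtrip_file(path: Path) -> tuple[bool, str]:
    import io

    try:
        if path.suffix == ".npz":
            with np.load(path) as data:
                arrays = {k: data[k] for k in data.files}
            buf = io.BytesIO()
            np.savez_compressed(buf, **arrays)
            buf.seek(0)
            with np.load(buf) as again:
                same = all(np.array_equal(arrays[k], again[k]) for k in arrays)
            return same, "npz round trip"
        if path.suffix == ".csv":
            frame = pd.read_csv(path)
            buf = io.StringIO()
            frame.to_csv(buf, index=False)
            buf.seek(0)
            return frame.equals(pd.read_csv(buf)), "csv round trip"
        if path.suffix == ".json":
            with open(path) as fh:
                blob = json.load(fh)
            return json.loads(json.dumps(blob)) == blob, "json round trip"
        return True, "checksum only"
    except Exception as exc:  # any parse failure means the artifact is corrupt
        return False, f"{type(exc).__name__}: {exc}"
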