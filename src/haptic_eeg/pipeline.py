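"""End-to-end orchestration: simulate -> preprocess -> features -> classify ->
stats -> spectral, as cached, seeded stages under one run directory.

Each stage writes its outputs (and a ``.done`` marker) into its own
subdirectory and is skipped on rerun when the marker exists, so deleting a
downstream stage and rerunning reproduces it from the cached upstream
outputs.  A single global seed fans out to per-stage substreams through a
stable name-keyed hash, making the derived seeds independent of execution
order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as heio
from .bands import BAND_NAMES
from .classify import AccuracyTable, evaluate_grid
from .features import (FeatureDataset, FeatureTensor, assemble_dataset, dasm,
                       dcau, de_features, psd_features)
from .montage import dasm_pairs, dcau_pairs, standard_montage
from .preprocess import SessionSegment, band_decompose, preprocess_recording
from .simulate import GeneratorConfig, SessionAnnotation, generate_experiment
from .spectral import tf_wavelet, topo_de
from .stats import growth_grid, render_tables, stats_grid

__all__ = ["RunConfig", "run_pipeline", "stage_seed",
           "stage_simulate", "stage_preprocess", "stage_classify",
           "stage_report", "stage_spectral",
           "extract_subject_features", "subject_datasets",
           "save_segments", "load_segments"]

log = logging.getLogger("haptic_eeg")

FEATURE_KINDS = ("PSD", "DE", "DASM", "DCAU")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage substream seed (< 2**31) from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    out_dir: str | Path = "run"
    fs_out: float = 200.0
    run_ica: bool = True
    feature_kinds: tuple[str, ...] = FEATURE_KINDS
    band_rows: tuple[str, ...] = BAND_NAMES + ("total",)
    folds: int = 4
    svm_c: float = 1.0
    alpha: float = 0.05
    average_windows: bool = False
    io_format: str = "brainvision"
    run_spectral: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.feature_kinds) - set(FEATURE_KINDS)
        if unknown:
            raise ValueError(f"unknown feature kinds {sorted(unknown)}")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        # the global seed drives the generator unless one was set explicitly
        if self.generator.seed == 0 and self.seed != 0:
            self.generator = dataclasses.replace(
                self.generator, seed=stage_seed(self.seed, "simulate"))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        prof = d["generator"]["profile"]
        prof["gains"] = {emo: {f"{grp}|{band}": v for (grp, band), v in g.items()}
                         for emo, g in self.generator.profile.gains.items()}
        d["out_dir"] = str(self.out_dir)
        return d


# --------------------------------------------------------------- feature step

def extract_subject_features(segments: list[SessionSegment],
                             montage=None) -> dict:
    """Per (pattern, condition): feature tensors for every session.

    Returns ``{(pattern, condition): {kind: [(tensor, session, emotion), ...]}}``.
    PSD/DE tensors are restricted to the montage's 63 usable channels; the
    recovered FCz reference participates only through the caudality pairs.
    """
    montage = montage or standard_montage()
    usable = [c for c in montage.usable_channels if c in segments[0].channel_names]
    pairs_a = dasm_pairs(montage, available=segments[0].channel_names)
    pairs_c = dcau_pairs(montage, available=segments[0].channel_names,
                         warn=lambda msg: log.warning(msg))
    out: dict = {}
    for seg in segments:
        band_segs = band_decompose(seg)
        de_full = de_features(band_segs)
        tensors = {
            "PSD": psd_features(seg).select_units(usable),
            "DE": de_full.select_units(usable),
            "DASM": dasm(de_full, pairs_a),
            "DCAU": dcau(de_full, pairs_c),
            "DE_baseline": de_features(band_segs, use_baseline=True).select_units(usable),
        }
        bucket = out.setdefault((seg.pattern, seg.condition), {})
        for kind, t in tensors.items():
            bucket.setdefault(kind, []).append((t, seg.session, seg.emotion))
    return out


def subject_datasets(feats: dict, subject: int,
                     feature_kinds=FEATURE_KINDS,
                     band_rows=BAND_NAMES + ("total",),
                     average_windows: bool = False) -> list[FeatureDataset]:
    datasets = []
    for (pattern, condition), by_kind in sorted(feats.items()):
        for kind in feature_kinds:
            for band in band_rows:
                datasets.append(assemble_dataset(
                    by_kind[kind], band_selection=band, subject=subject,
                    condition=condition, pattern=pattern,
                    average_windows=average_windows))
    return datasets


# -------------------------------------------------------------------- staging

def _marker(stage_dir: Path) -> Path:
    return stage_dir / ".done"


def _stage_fresh(stage_dir: Path) -> bool:
    return not _marker(stage_dir).exists()


def _finish(stage_dir: Path) -> None:
    _marker(stage_dir).write_text("ok\n")


def _annotations_from_manifest(manifest: pd.DataFrame) -> dict[int, list[SessionAnnotation]]:
    per_subject: dict[int, list[SessionAnnotation]] = {}
    for _, r in manifest.iterrows():
        per_subject.setdefault(int(r.subject), []).append(SessionAnnotation(
            int(r.subject), int(r.session), r.emotion, r.pattern,
            float(r.cue_onset_s), float(r.clip_onset_s),
            float(r.haptic_onset_s), float(r.clip_end_s)))
    return per_subject


def save_segments(path: Path, segments: list[SessionSegment]) -> None:
    arrays, meta = {}, []
    for i, s in enumerate(segments):
        arrays[f"samples_{i}"] = s.samples
        arrays[f"baseline_{i}"] = s.baseline if s.baseline is not None else np.empty((0, 0))
        meta.append({"fs": s.fs, "channel_names": list(s.channel_names),
                     "subject": s.subject, "session": s.session,
                     "emotion": s.emotion, "pattern": s.pattern,
                     "condition": s.condition})
    np.savez(path, **arrays)
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_segments(path: Path) -> list[SessionSegment]:
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path)
    out = []
    for i, m in enumerate(meta):
        baseline = data[f"baseline_{i}"]
        out.append(SessionSegment(
            data[f"samples_{i}"], m["fs"], tuple(m["channel_names"]),
            m["subject"], m["session"], m["emotion"], m["pattern"],
            m["condition"], baseline=baseline if baseline.size else None))
    return out


def _annotations_for_run(out: Path) -> dict[int, list[SessionAnnotation]]:
    manifest = heio.read_manifest(out / "recordings" / "manifest.csv")
    return _annotations_from_manifest(manifest)


def stage_simulate(cfg: RunConfig, out: Path) -> Path:
    """Generate and write recordings + manifest under ``out/recordings``."""
    rec_dir = out / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    if _stage_fresh(rec_dir):
        log.info("stage simulate: generating %d subjects", cfg.generator.n_subjects)
        recordings, _, manifest = generate_experiment(cfg.generator)
        for rec in recordings:
            heio.write_recording(rec, rec_dir / f"subject{rec.meta['subject']:02d}",
                                 format=cfg.io_format)
        heio.write_manifest(manifest, rec_dir / "manifest.csv")
        _finish(rec_dir)
    return rec_dir


def stage_preprocess(cfg: RunConfig, out: Path) -> Path:
    """Preprocess every recording into condition segments under ``out/segments``."""
    rec_dir = out / "recordings"
    seg_dir = out / "segments"
    seg_dir.mkdir(exist_ok=True)
    if _stage_fresh(seg_dir):
        ext = ".vhdr" if cfg.io_format == "brainvision" else ".edf"
        for subject, anns in sorted(_annotations_for_run(out).items()):
            log.info("stage preprocess: subject %d", subject)
            rec = heio.read_recording(rec_dir / f"subject{subject:02d}{ext}")
            segs = preprocess_recording(
                rec, anns, fs_out=cfg.fs_out, run_ica=cfg.run_ica,
                ica_seed=stage_seed(cfg.seed, f"ica/{subject}"),
                line_freq=cfg.generator.line_freq)
            save_segments(seg_dir / f"subject{subject:02d}.npz", segs)
        _finish(seg_dir)
    return seg_dir


def stage_classify(cfg: RunConfig, out: Path) -> Path:
    """Extract features and evaluate the SVM grid; writes ``out/accuracy.csv``."""
    seg_dir = out / "segments"
    acc_path = out / "accuracy.csv"
    if not acc_path.exists():
        montage = standard_montage()
        tables = []
        for subject in sorted(_annotations_for_run(out)):
            log.info("stage features/classify: subject %d", subject)
            segs = load_segments(seg_dir / f"subject{subject:02d}.npz")
            feats = extract_subject_features(segs, montage)
            datasets = subject_datasets(
                feats, subject, cfg.feature_kinds, cfg.band_rows,
                cfg.average_windows)
            tables.append(evaluate_grid(
                datasets, k=cfg.folds,
                seed=stage_seed(cfg.seed, "classify"), C=cfg.svm_c).table)
        AccuracyTable(pd.concat(tables, ignore_index=True)).to_csv(acc_path)
    return acc_path


def stage_report(cfg: RunConfig, out: Path) -> Path:
    """Paired statistics + growth rates rendered under ``out/report``."""
    acc = AccuracyTable(pd.read_csv(out / "accuracy.csv"))
    report_dir = out / "report"
    if _stage_fresh(report_dir):
        stats = stats_grid(acc, alpha=cfg.alpha)
        growth = growth_grid(acc)
        render_tables(acc, stats, growth, report_dir, alpha=cfg.alpha)
        stats.to_csv(report_dir / "stats_long.csv", index=False)
        growth.to_csv(report_dir / "growth_long.csv", index=False)
        _finish(report_dir)
    return report_dir


def stage_spectral(cfg: RunConfig, out: Path) -> Path:
    """Time-frequency and topographic summary tables under ``out/spectral``."""
    spec_dir = out / "spectral"
    if _stage_fresh(spec_dir):
        spec_dir.mkdir(exist_ok=True)
        _spectral_stage(cfg, out / "segments", spec_dir,
                        sorted(_annotations_for_run(out)))
        _finish(spec_dir)
    return spec_dir


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage under ``cfg.out_dir``; returns the run directory.

    Completed stages (``.done`` marker) are skipped, so a rerun rebuilds
    only deleted downstream outputs, bit-identically.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(name)s %(message)s")
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    try:
        stage_simulate(cfg, out)
        stage_preprocess(cfg, out)
        stage_classify(cfg, out)
        stage_report(cfg, out)
        if cfg.run_spectral:
            stage_spectral(cfg, out)
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def _spectral_stage(cfg: RunConfig, seg_dir: Path, spec_dir: Path,
                    subjects: list[int]) -> None:
    """Subject-mean TF maps per condition and baseline-subtracted DE maps."""
    montage = standard_montage()
    usable = list(montage.usable_channels)
    tf_acc: dict = {}
    de_acc: dict = {}
    for subject in subjects:
        segs = load_segments(seg_dir / f"subject{subject:02d}.npz")
        feats = extract_subject_features(segs, montage)
        for seg in segs:
            try:
                tfm = tf_wavelet(seg)
            except ValueError:
                continue  # clip half shorter than one 5-s window
            key = (seg.pattern, seg.condition, seg.emotion)
            tf_acc.setdefault(key, []).append(tfm.energy)
        for (pattern, condition), by_kind in feats.items():
            for (t, sess, emo) in by_kind["DE"]:
                de_acc.setdefault((pattern, condition, emo, "de"), []).append(t)
            for (t, sess, emo) in by_kind["DE_baseline"]:
                de_acc.setdefault((pattern, condition, emo, "base"), []).append(t)
    for (pattern, condition, emotion), maps in sorted(tf_acc.items()):
        mean_map = np.mean(maps, axis=0)
        pd.DataFrame(mean_map).to_csv(
            spec_dir / f"tf_{pattern}_{condition}_{emotion}.csv", index=False)
    for key in {k[:3] for k in de_acc}:
        pattern, condition, emotion = key
        des = de_acc.get(key + ("de",), [])
        bases = de_acc.get(key + ("base",), [])
        if not des or not bases:
            continue
        de_stack = FeatureTensor("DE", np.concatenate([t.values for t in des]),
                                 des[0].units_axis, des[0].band_axis)
        base_stack = FeatureTensor("DE", np.concatenate([t.values for t in bases]),
                                   bases[0].units_axis, bases[0].band_axis)
        tv = topo_de(de_stack, base_stack)
        pd.DataFrame(tv.values, index=list(tv.channel_names),
                     columns=list(tv.band_axis)).to_csv(
            spec_dir / f"topo_{pattern}_{condition}_{emotion}.csv")
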