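"""End-to-end analysis pipeline.

Chains the stages: input (CSV table or synthetic generation) -> preprocessing
-> replicate-dispersion outlier screen -> per-channel normalization (inside
the cross-validation, so healthy-reference statistics never see test folds)
-> per-channel feature extraction + classification -> decision fusion ->
evaluation.  The whole run is a pure function of (input, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .channels import ALL_CHANNELS, Channel, channel_from_key
from .classify import ClassifierSpec, CvConfig, FeatureSpec, crossvalidate_channel, make_fold_plan
from .datamodel import ConfigError, Dataset, SkinSite, validate_dataset
from .evaluate import PerformanceReport, performance_report
from .fusion import FusionResult, FusionSpec, fuse
from .io import read_spectra_table
from .normalize import NORMALIZATION_MODES, build_context, normalize_spectrum
from .outlier import DEFAULT_THRESHOLD, QcReport, screen_dataset
from .preprocess import PreprocessConfig, preprocess_dataset
from .synthetic import SynthConfig, generate_dataset
from .datamodel import Spectrum

#: Built-in classification tasks.  Values map a task class to the base tokens
#: that select sites: histology labels, the invasiveness regroupings CI/CNI,
#: and KC (= BCC + SCC).
TASK_PRESETS = {
    "H_AK_BCC_SCC": {"H": ["H"], "AK": ["AK"], "BCC": ["BCC"], "SCC": ["SCC"]},
    "H_AK_KC": {"H": ["H"], "AK": ["AK"], "KC": ["KC"]},
    "AK_BCC_SCC": {"AK": ["AK"], "BCC": ["BCC"], "SCC": ["SCC"]},
    "AK_CNI_CI": {"AK": ["AK"], "CNI": ["CNI"], "CI": ["CI"]},
    "H_AK_CNI_CI": {"H": ["H"], "AK": ["AK"], "CNI": ["CNI"], "CI": ["CI"]},
    "H_BCC": {"H": ["H"], "BCC": ["BCC"]},
    "H_SCC": {"H": ["H"], "SCC": ["SCC"]},
    "H_KC": {"H": ["H"], "KC": ["KC"]},
    "H_AK": {"H": ["H"], "AK": ["AK"]},
}

_VALID_TOKENS = {"H", "AK", "BCC", "SCC", "CI", "CNI", "KC"}


def resolve_task(task) -> dict[str, list[str]]:
    """Resolve a preset name or explicit {class: [tokens]} mapping."""
    if isinstance(task, str):
        if task not in TASK_PRESETS:
            raise ConfigError(
                f"unknown task {task!r}; presets: {sorted(TASK_PRESETS)}"
            )
        return TASK_PRESETS[task]
    mapping = {k: list(v) for k, v in dict(task).items()}
    for cls, tokens in mapping.items():
        bad = set(tokens) - _VALID_TOKENS
        if bad:
            raise ConfigError(
                f"task class {cls!r} uses unknown labels {sorted(bad)}; "
                f"valid labels: {sorted(_VALID_TOKENS)}"
            )
    return mapping


def site_label(site: SkinSite, task: dict[str, list[str]]) -> str | None:
    """Task class of a site, or None when the site is outside the task."""
    tokens = {site.histology}
    if site.histology in ("BCC", "SCC"):
        tokens.add("KC")
        if site.invasiveness != "NA":
            tokens.add(site.invasiveness)
    hits = [cls for cls, toks in task.items() if tokens & set(toks)]
    if len(hits) > 1:
        raise ConfigError(f"site {site.site_id} matches several task classes {hits}")
    return hits[0] if hits else None


@dataclass
class PipelineConfig:
    """Full configuration of one pipeline run (YAML-serializable, version 1)."""

    synth: SynthConfig | None = field(default_factory=SynthConfig)
    input_path: str | None = None
    channels: list[str] | None = None  # channel keys; None = all 24
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    screen_threshold: float = DEFAULT_THRESHOLD
    #: normalization mode per modality group; the defaults are the
    #: best-performing configuration (baseline for AF, none for DR).
    normalization: dict = field(default_factory=lambda: {"AF": "baseline", "DR": "none"})
    task: str | dict = "H_AK_BCC_SCC"
    cv: CvConfig = field(default_factory=CvConfig)
    fusion: list[FusionSpec] = field(
        default_factory=lambda: [
            FusionSpec(method="majority", level="all"),
            FusionSpec(method="weighted", level="all"),
        ]
    )
    seed: int = 0
    schema_version: int = 1

    def __post_init__(self) -> None:
        for mode in self.normalization.values():
            if mode not in NORMALIZATION_MODES:
                raise ConfigError(
                    f"unknown normalization mode {mode!r}; choose from {NORMALIZATION_MODES}"
                )
        resolve_task(self.task)

    def resolved_channels(self) -> list[Channel]:
        if self.channels is None:
            return list(ALL_CHANNELS)
        return [channel_from_key(k) for k in self.channels]

    def mode_for(self, channel: Channel) -> str:
        m = self.normalization
        for key in (channel.key, channel.modality.value, "AF" if channel.is_af else "DR"):
            if key in m:
                return m[key]
        return "none"

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fusion"] = [dataclasses.asdict(f) for f in self.fusion]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synth") is not None:
            d["synth"] = SynthConfig(**d["synth"])
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        if "cv" in d and isinstance(d["cv"], dict):
            cv = dict(d["cv"])
            if isinstance(cv.get("feature"), dict):
                cv["feature"] = FeatureSpec(**cv["feature"])
            elif isinstance(cv.get("feature"), list):
                cv["feature"] = [FeatureSpec(**f) for f in cv["feature"]]
            if isinstance(cv.get("classifier"), dict):
                cv["classifier"] = ClassifierSpec(**cv["classifier"])
            elif isinstance(cv.get("classifier"), list):
                cv["classifier"] = [ClassifierSpec(**c) for c in cv["classifier"]]
            d["cv"] = CvConfig(**cv)
        if "fusion" in d:
            d["fusion"] = [
                f if isinstance(f, FusionSpec) else FusionSpec(**f) for f in d["fusion"]
            ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        Path(path).write_text(
            yaml.safe_dump(clean(self.to_dict()), sort_keys=False), encoding="utf-8"
        )


@dataclass
class ChannelResult:
    channel: str
    report: PerformanceReport
    accuracy_mean_pct: float
    accuracy_sd_pct: float
    n_samples: int


@dataclass
class ReportBundle:
    config: PipelineConfig
    qc: QcReport
    channel_results: dict[str, ChannelResult]
    decisions: pd.DataFrame
    fusion_results: dict[str, FusionResult]
    validation: dict
    skipped_channels: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def channel_accuracy_table(self) -> pd.DataFrame:
        rows = [
            {
                "channel": k,
                "accuracy_mean_pct": v.accuracy_mean_pct,
                "accuracy_sd_pct": v.accuracy_sd_pct,
                "n_samples": v.n_samples,
            }
            for k, v in self.channel_results.items()
        ]
        return pd.DataFrame(rows)

    def to_json_dir(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "qc.json").write_text(json.dumps(self.qc.to_dict(), indent=2))
        channels = {
            k: {
                "accuracy_mean_pct": v.accuracy_mean_pct,
                "accuracy_sd_pct": v.accuracy_sd_pct,
                "n_samples": v.n_samples,
                **v.report.to_dict(),
            }
            for k, v in self.channel_results.items()
        }
        (out / "channels.json").write_text(json.dumps(channels, indent=2))
        fused = {
            key: {
                "n_unfusable": res.n_unfusable,
                "groups": {g: r.to_dict() for g, r in res.reports.items()},
            }
            for key, res in self.fusion_results.items()
        }
        (out / "fused.json").write_text(json.dumps(fused, indent=2))
        (out / "validation.json").write_text(json.dumps(self.validation, indent=2))
        self.decisions.to_csv(out / "decisions.csv", index=False)


def load_input(config: PipelineConfig) -> Dataset:
    if config.input_path is not None:
        return read_spectra_table(config.input_path)
    if config.synth is None:
        raise ConfigError("config must provide input_path or a synthetic spec")
    synth = replace(config.synth, seed=config.seed)
    return generate_dataset(synth, channels=tuple(config.resolved_channels()))


def _channel_matrix(averaged: dict, sites: dict, channel: Channel, site_ids: list[str]):
    grid = None
    keep_ids, rows = [], []
    for sid in site_ids:
        spec = averaged.get((sid, channel))
        if spec is None:
            continue
        if grid is None:
            grid = spec.wavelengths_nm
        elif spec.wavelengths_nm.size != grid.size:
            raise ConfigError(
                f"inconsistent grids on channel {channel.key}; resample first"
            )
        keep_ids.append(sid)
        rows.append(spec.intensities)
    if not rows:
        return None, [], None
    return np.vstack(rows), keep_ids, grid


def _make_normalizer(mode, channel, grid, sub_ds, all_channel_sites, lesion_of):
    """Fold-aware normalization hook for :func:`crossvalidate_channel`."""
    if mode == "none":
        return None

    def normalizer(Xtr, Xte, tr_ids, te_ids):
        ctx = None
        if mode in ("ratio", "baseline"):
            training = set(all_channel_sites) - set(te_ids)
            ctx = build_context(sub_ds, training_site_ids=training, channels=[channel])

        def apply(X, ids):
            out = np.empty_like(X)
            for i, sid in enumerate(ids):
                s = Spectrum(channel=channel, wavelengths_nm=grid, intensities=X[i])
                out[i] = normalize_spectrum(
                    s, mode, ctx=ctx, lesion_id=lesion_of.get(sid)
                ).intensities
            return out

        return apply(Xtr, tr_ids), apply(Xte, te_ids)

    return normalizer


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage and return the full report bundle."""
    raw = load_input(config)
    channels = [c for c in config.resolved_channels() if c in raw.channels()]
    validation = validate_dataset(raw, channels).to_dict()

    pre = preprocess_dataset(raw, config.preprocess)
    screened, qc = screen_dataset(pre, config.screen_threshold)

    task = resolve_task(config.task)
    classes = sorted(task)
    labels = {
        sid: lab
        for sid, site in screened.sites.items()
        if (lab := site_label(site, task)) is not None
    }
    master_ids = np.array(sorted(labels))
    if master_ids.size == 0:
        raise ConfigError("no sites match the requested task classes")
    y_master = np.array([labels[s] for s in master_ids])
    lesion_of = {sid: screened.sites[sid].lesion_id for sid in screened.sites}

    cv = replace(config.cv, seed=config.seed + 1000)
    master_plan = make_fold_plan(y_master, cv)

    decisions = []
    channel_results: dict[str, ChannelResult] = {}
    skipped: list[str] = []

    for ch in channels:
        X, ch_ids, grid = _channel_matrix(
            screened.averaged, screened.sites, ch, list(master_ids)
        )
        if X is None:
            skipped.append(ch.key)
            continue
        mode = config.mode_for(ch)
        sub_ds = Dataset(
            sites=dict(screened.sites),
            averaged={k: v for k, v in screened.averaged.items() if k[1] == ch},
        )
        if mode in ("ratio", "baseline"):
            # sites whose lesion has no surviving healthy reference must abstain
            ctx_probe = build_context(sub_ds, training_site_ids=(), channels=[ch])
            usable = {
                sid
                for sid in ch_ids
                if (lesion_of[sid], ch.key) in ctx_probe.lesion_mean
            }
            keep = [i for i, sid in enumerate(ch_ids) if sid in usable]
            X, ch_ids = X[keep], [ch_ids[i] for i in keep]
        all_channel_sites = {k[0] for k in sub_ds.averaged}

        # remap the master fold plan onto this channel's available samples
        pos_of = {sid: i for i, sid in enumerate(ch_ids)}
        plan = []
        ok = True
        for sub, folds in master_plan:
            keep = [j for j, m_idx in enumerate(sub) if master_ids[m_idx] in pos_of]
            local = np.array([pos_of[master_ids[sub[j]]] for j in keep], dtype=int)
            plan.append((local, folds[keep]))
            for f in np.unique(folds[keep]):
                tr = local[folds[keep] != f]
                if np.unique(np.array([labels[ch_ids[i]] for i in tr])).size < len(classes):
                    ok = False
        if not ok or not plan:
            skipped.append(ch.key)
            continue

        y_ch = np.array([labels[sid] for sid in ch_ids])
        normalizer = _make_normalizer(mode, ch, grid, sub_ds, all_channel_sites, lesion_of)
        try:
            table, metrics = crossvalidate_channel(
                X,
                y_ch,
                cv,
                sample_ids=np.array(ch_ids),
                normalizer=normalizer,
                fold_plan=plan,
            )
        except ConfigError:
            skipped.append(ch.key)
            continue
        table.insert(1, "channel", ch.key)
        decisions.append(table)
        report = performance_report(
            table["truth"], table["pred"], classes, repeats=table["repeat"]
        )
        channel_results[ch.key] = ChannelResult(
            channel=ch.key,
            report=report,
            accuracy_mean_pct=100.0 * metrics["accuracy_mean"],
            accuracy_sd_pct=100.0 * float(np.std(metrics["per_repeat_accuracy"], ddof=0)),
            n_samples=metrics["n_samples"],
        )

    if not decisions:
        raise ConfigError("no channel produced decisions; nothing to fuse")
    all_decisions = pd.concat(decisions, ignore_index=True)

    fusion_results: dict[str, FusionResult] = {}
    for i, fspec in enumerate(config.fusion):
        fspec = replace(fspec, seed=config.seed + 2000 + i)
        fusion_results[f"{fspec.method}:{fspec.level}"] = fuse(all_decisions, fspec)

    return ReportBundle(
        config=config,
        qc=qc,
        channel_results=channel_results,
        decisions=all_decisions,
        fusion_results=fusion_results,
        validation=validation,
        skipped_channels=skipped,
        provenance={
            "seed": config.seed,
            "task": task,
            "classes": classes,
            "n_sites": int(master_ids.size),
            "input": config.input_path or "synthetic",
            "generator": raw.provenance.get("config"),
            "injected_outliers": raw.provenance.get("injected_outliers", []),
        },
    )
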