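"""End-to-end orchestration: preprocess, segment, featurize, evaluate.

This is the programmatic surface the command-line interface wraps. A
recording moves through resampling to 2 kHz, peak normalization, wavelet
denoising, segmentation into cycles, and feature extraction; a cohort of
recordings becomes a feature matrix evaluated by the jack-knife classifier.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier, features, segmentation
from .denoise import WaveletDenoiseConfig, denoise_signal
from .features import FEATURE_NAMES, FeatureVector
from .segmentation import Segmentation, SegmentationConfig, segment_pcg
from .signal import CANONICAL_RATE, PCGSignal, normalize_amplitude, read_wav, resample_to_rate


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable constants of the pipeline, file-loadable.

    Defaults are the published operating point; any override is the
    caller's responsibility to log.
    """

    denoise: WaveletDenoiseConfig = field(default_factory=WaveletDenoiseConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    train: classifier.TrainConfig = field(default_factory=classifier.TrainConfig)
    target_rate: float = CANONICAL_RATE
    welch_segment: int = features.WELCH_SEGMENT

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        kwargs: dict = {}
        if "denoise" in payload:
            kwargs["denoise"] = WaveletDenoiseConfig(**payload["denoise"])
        if "segmentation" in payload:
            seg = dict(payload["segmentation"])
            kwargs["segmentation"] = SegmentationConfig(**seg)
        if "train" in payload:
            kwargs["train"] = classifier.TrainConfig(**payload["train"])
        for key in ("target_rate", "welch_segment"):
            if key in payload:
                kwargs[key] = payload[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def preprocess(signal: PCGSignal, config: PipelineConfig | None = None) -> PCGSignal:
    """Resample to the canonical rate, peak-normalize, and denoise."""
    config = config or PipelineConfig()
    if signal.rate > config.target_rate:
        signal = resample_to_rate(signal, config.target_rate)
    elif signal.rate != config.target_rate:
        raise ValueError(
            f"recording at {signal.rate} Hz below canonical "
            f"{config.target_rate} Hz; cannot upsample"
        )
    signal = normalize_amplitude(signal)
    return denoise_signal(signal, config.denoise)


def process_recording(
    signal: PCGSignal, config: PipelineConfig | None = None
) -> tuple[PCGSignal, Segmentation, FeatureVector]:
    """Preprocess, segment and featurize one recording.

    Returns the denoised 2 kHz signal (whose samples the CAV/CSV features
    are read from), the segmentation, and the 10-feature vector.
    """
    config = config or PipelineConfig()
    denoised = preprocess(signal, config)
    seg = segment_pcg(denoised, config.segmentation)
    vector = features.extract_feature_vector(denoised, seg.cycles)
    return denoised, seg, vector


def annotations_frame(subject_id: str, seg: Segmentation) -> pd.DataFrame:
    """Cycle annotations as one row per cycle (times in seconds)."""
    rows = []
    for k, cyc in enumerate(seg.cycles):
        rows.append(
            {
                "subject_id": subject_id,
                "cycle_index": k,
                "s1_start": round(cyc.s1_interval[0], 4),
                "s1_end": round(cyc.s1_interval[1], 4),
                "s2_start": round(cyc.s2_interval[0], 4),
                "s2_end": round(cyc.s2_interval[1], 4),
                "cav_start": round(cyc.cav_interval[0], 4),
                "cav_end": round(cyc.cav_interval[1], 4),
                "csv_start": round(cyc.csv_interval[0], 4),
                "csv_end": round(cyc.csv_interval[1], 4),
                "heart_rate": round(cyc.heart_rate, 2),
            }
        )
    return pd.DataFrame(rows)


def feature_frame(
    entries: list[tuple[str, int, FeatureVector]]
) -> pd.DataFrame:
    """Feature table: subject_id, label, then the 10 named feature columns."""
    rows = []
    for subject_id, label, vec in entries:
        row = {"subject_id": subject_id, "label": label}
        row.update(dict(zip(FEATURE_NAMES, vec.as_array())))
        rows.append(row)
    return pd.DataFrame(rows)


def extract_cohort_features(
    signals: list[PCGSignal],
    labels: list[int] | np.ndarray,
    config: PipelineConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str], list[tuple[str, str]]]:
    """Feature matrix for a cohort; failures are collected, not fatal.

    Returns (X, y, subject_ids, failures) where failures is a list of
    (subject_id, error message) for recordings that could not be segmented.
    """
    config = config or PipelineConfig()
    rows, kept_labels, ids, failures = [], [], [], []
    for signal, label in zip(signals, labels):
        try:
            _, _, vec = process_recording(signal, config)
        except (ValueError, segmentation.SegmentationError) as exc:
            failures.append((signal.subject_id, str(exc)))
            continue
        rows.append(vec.as_array())
        kept_labels.append(int(label))
        ids.append(signal.subject_id)
    if not rows:
        raise RuntimeError("no recording could be processed")
    return np.vstack(rows), np.array(kept_labels), ids, failures


def evaluate_cohort(
    signals: list[PCGSignal],
    labels: list[int] | np.ndarray,
    config: PipelineConfig | None = None,
) -> tuple[classifier.EvaluationReport, list[tuple[str, str]]]:
    """Full study replication on a cohort: features then jack-knife."""
    config = config or PipelineConfig()
    x, y, _, failures = extract_cohort_features(signals, labels, config)
    report = classifier.jackknife_evaluate(x, y, config.train)
    return report, failures


def load_manifest(manifest_path: str | Path) -> tuple[list[PCGSignal], np.ndarray]:
    """Read a cohort manifest CSV (filename, label) and its WAV files."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    signals, labels = [], []
    for _, row in table.iterrows():
        signals.append(read_wav(manifest_path.parent / row["filename"]))
        labels.append(int(row["label"]))
    return signals, np.array(labels)
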