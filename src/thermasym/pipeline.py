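"""End-to-end orchestration: files in, classification report out.

A :class:`RunManifest` lists, per patient, the face-view and mouth-view
temperature-matrix files and (for evaluation) the class label.  The pipeline
reads each pair, runs the averaged feature extraction, assembles the labeled
dataset, evaluates the repeated-split protocol, and writes the feature
matrix, the report and the ROC points as plain text.  All randomness derives
from ``config.rng_seed``, so a rerun with the same manifest is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .classify import ClassificationReport, LabeledDataset, evaluate, feature_ttest
from .config import PipelineConfig
from .exceptions import ProtocolError, ThermasymError
from .features import FEATURE_NAMES, FeatureVector, averaged_features
from .io import read_thermogram

__all__ = [
    "PatientEntry",
    "RunManifest",
    "run_pipeline",
    "extract_cohort_features",
    "evaluate_phantom_cohort",
    "features_to_frame",
    "frame_to_dataset",
    "write_report",
]

logger = logging.getLogger("thermasym")

_CSV_FLOAT_FMT = "%.9g"


@dataclasses.dataclass(frozen=True)
class PatientEntry:
    id: str
    face_path: Path
    mouth_path: Path
    label: Optional[int] = None  # 0 = NT, 1 = T, None = unlabeled


@dataclasses.dataclass
class RunManifest:
    patients: list[PatientEntry]
    output_dir: Path
    config: PipelineConfig = dataclasses.field(default_factory=PipelineConfig)

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if not self.patients:
            raise ProtocolError("manifest lists no patients")
        for p in self.patients:
            for path in (p.face_path, p.mouth_path):
                if not Path(path).is_file():
                    raise ProtocolError(f"input file missing before run: {path}")

    @classmethod
    def from_cohort_dir(
        cls, cohort_dir: str | Path, output_dir: str | Path, config: PipelineConfig | None = None
    ) -> "RunManifest":
        """Build a manifest from a phantom-cohort directory (truth.csv + matrices)."""
        cohort_dir = Path(cohort_dir)
        truth = pd.read_csv(cohort_dir / "truth.csv")
        patients = [
            PatientEntry(
                id=str(row["id"]),
                face_path=cohort_dir / f"face_{row['id']}.csv",
                mouth_path=cohort_dir / f"mouth_{row['id']}.csv",
                label=int(row["class_label"]),
            )
            for _, row in truth.iterrows()
        ]
        return cls(patients=patients, output_dir=Path(output_dir),
                   config=config or PipelineConfig())


def _patient_seed(rng_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([int(rng_seed), int(index)]).generate_state(1)[0] % 2**31)


def extract_cohort_features(
    manifest: RunManifest,
) -> tuple[list[FeatureVector], list[Optional[int]], list[str]]:
    """Run read -> edges -> axis -> split -> averaged features for every patient.

    Per-patient failures are logged and the patient excluded; the returned
    exclusion list records their ids.
    """
    config = manifest.config
    vectors: list[FeatureVector] = []
    labels: list[Optional[int]] = []
    excluded: list[str] = []
    for idx, patient in enumerate(manifest.patients):
        try:
            face = read_thermogram(patient.face_path, view="face", config=config)
            mouth = read_thermogram(patient.mouth_path, view="mouth", config=config)
            fv = averaged_features(
                face, mouth, config,
                seed=_patient_seed(config.rng_seed, idx),
                patient_id=patient.id,
            )
        except ThermasymError as exc:
            logger.warning("patient %s excluded: %s", patient.id, exc)
            excluded.append(patient.id)
            continue
        vectors.append(fv)
        labels.append(patient.label)
        logger.info("patient %s: features extracted", patient.id)
    return vectors, labels, excluded


def features_to_frame(
    vectors: list[FeatureVector], labels: list[Optional[int]] | None = None
) -> pd.DataFrame:
    df = pd.DataFrame(
        [[v.patient_id, *v.as_array()] for v in vectors],
        columns=["patient_id", *FEATURE_NAMES],
    )
    if labels is not None and any(l is not None for l in labels):
        df["label"] = labels
    return df


def frame_to_dataset(df: pd.DataFrame) -> LabeledDataset:
    if "label" not in df.columns:
        raise ProtocolError("feature table has no label column")
    vectors = [
        FeatureVector(**{n: float(row[n]) for n in FEATURE_NAMES},
                      patient_id=str(row["patient_id"]))
        for _, row in df.iterrows()
    ]
    return LabeledDataset(vectors=vectors, labels=df["label"].to_numpy(dtype=int))


def write_report(
    report: ClassificationReport,
    path: Path,
    config: PipelineConfig,
    excluded: list[str],
    ttests: dict[str, tuple[float, float, bool]] | None = None,
) -> None:
    cm = report.confusion
    lines = [
        "# thermasym classification report",
        f"n_repeats: {report.n_repeats}",
        f"n_train_per_class: {config.n_train_per_class}",
        f"rng_seed: {config.rng_seed}",
        f"standardize_features: {config.standardize_features}",
        f"excluded_patients: {','.join(excluded) if excluded else 'none'}",
        f"tp: {cm.tp}",
        f"tn: {cm.tn}",
        f"fp: {cm.fp}",
        f"fn: {cm.fn}",
        f"sensitivity: {report.sensitivity:.6f}",
        f"specificity: {report.specificity:.6f}",
        f"accuracy: {report.accuracy:.6f}",
        f"auc: {report.auc:.6f}",
    ]
    if ttests:
        lines.append("# Welch t-tests per feature (t, two-sided p, significant at 0.05)")
        for name, (t, p, sig) in ttests.items():
            lines.append(f"ttest_{name}: t={t:.6f} p={p:.6g} significant={sig}")
    path.write_text("\n".join(lines) + "\n")


def evaluate_phantom_cohort(
    n_nt: int = 23,
    n_t: int = 23,
    lesion_amp_c: float = 1.0,
    lesion_radius_px: float = 8.0,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> tuple[ClassificationReport, LabeledDataset]:
    """Generate a phantom cohort in memory and run the full protocol on it.

    Class labels are the nominal group assignments, so a null cohort
    (``lesion_amp_c = 0``, both groups lesion-free) measures chance-level
    performance of the whole chain.  All randomness — phantom noise, lesion
    placement, contour jitter, and train/test splits — derives from ``seed``.
    """
    from .phantom import make_cohort

    config = config or PipelineConfig()
    members = make_cohort(
        n_nt, n_t, lesion_amp_c=lesion_amp_c,
        lesion_radius_px=lesion_radius_px, seed=seed,
    )
    vectors = [
        averaged_features(
            m.face, m.mouth, config,
            seed=_patient_seed(seed + 1, i), patient_id=m.id,
        )
        for i, m in enumerate(members)
    ]
    labels = np.array([1 if m.group == "T" else 0 for m in members])
    dataset = LabeledDataset(vectors=vectors, labels=labels)
    report = evaluate(dataset, config, seed=seed + 2)
    return report, dataset


def run_pipeline(manifest: RunManifest) -> ClassificationReport:
    """Full run: features for every patient, repeated-split evaluation, outputs.

    Writes ``features.csv``, ``report.txt`` and ``roc.csv`` into the
    manifest's output directory.  Deterministic given ``config.rng_seed``:
    a rerun produces byte-identical files.
    """
    config = manifest.config
    manifest.output_dir.mkdir(parents=True, exist_ok=True)
    vectors, labels, excluded = extract_cohort_features(manifest)
    if any(l is None for l in labels):
        raise ProtocolError("evaluation requires a class label for every patient")
    df = features_to_frame(vectors, labels)
    df.to_csv(manifest.output_dir / "features.csv", index=False, float_format=_CSV_FLOAT_FMT)

    dataset = LabeledDataset(vectors=vectors, labels=np.array(labels, dtype=int))
    report = evaluate(dataset, config, seed=config.rng_seed)

    matrix = dataset.matrix()
    ttests = {}
    for j, name in enumerate(FEATURE_NAMES):
        try:
            ttests[name] = feature_ttest(
                matrix[dataset.labels == 0, j], matrix[dataset.labels == 1, j]
            )
        except ThermasymError:
            ttests[name] = (float("nan"), float("nan"), False)
    write_report(report, manifest.output_dir / "report.txt", config, excluded, ttests)
    roc_df = pd.DataFrame(report.roc_points, columns=["fpr", "tpr"])
    roc_df.to_csv(manifest.output_dir / "roc.csv", index=False, float_format=_CSV_FLOAT_FMT)
    return report
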