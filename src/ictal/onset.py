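"""Seizure **onset** detection on multichannel records with channel voting.

Every record is cut into consecutive 1-second epochs; each channel of each
epoch yields a 20-value feature vector (18 wavelet features plus raw IQR and
MAD).  A pooled binary linear model — trained on channel-epochs from the
chronologically first >= 60% of the patient's seizures plus an equal number
of seizure-remote normal epochs — labels every channel 0 (normal) or
1 (seizure).  An epoch is declared ictal when at least 60% of its channels
vote 1.  Per test seizure, detection latency is the delay from the annotated
onset to the first declared epoch inside the seizure; sensitivity and the
false-detection percentage over non-seizure test epochs complete the report.

Exposed as a model/results pair:

>>> det = OnsetDetector(records, patient_id="p01")
>>> res = det.fit()
>>> res.sensitivity_pct, res.mean_latency_s, res.false_detection_pct
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import classify
from .classify import LinearModel
from .features import ONSET_FEATURE_NAMES, onset_feature_matrix
from .io import EegRecord

__all__ = [
    "OnsetConfig",
    "EpochDecision",
    "SeizureEvaluation",
    "OnsetDetector",
    "OnsetResults",
    "PatientReport",
    "epoch_matrix",
    "vote",
    "detect_onset",
    "evaluate_patient",
    "train_test_split_counts",
]


@dataclass(frozen=True)
class OnsetConfig:
    """Epoching, voting, split and training settings of the onset detector."""

    epoch_s: float = 1.0
    vote_threshold: float = 0.6
    train_fraction: float = 0.6
    n_train_seizures: int | None = None  # explicit override of the 60% rule
    normal_guard_s: float = 60.0
    trainer: str = "lda"
    dwt_config: tuple[tuple[str, object], ...] = (
        ("levels", 4),
        ("extension_mode", "symmetric"),
    )
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "epoch_s": self.epoch_s,
            "vote_threshold": self.vote_threshold,
            "train_fraction": self.train_fraction,
            "n_train_seizures": self.n_train_seizures,
            "normal_guard_s": self.normal_guard_s,
            "trainer": self.trainer,
            "dwt_config": dict(self.dwt_config),
            "seed": self.seed,
        }


def train_test_split_counts(n_seizures: int, fraction: float = 0.6) -> tuple[int, int]:
    """(n_train, n_test) under the "at least ``fraction`` for training" rule.

    ``n_train = ceil(fraction * n)``, so 16 seizures split 10/6 and 3 split
    2/1; at least one seizure must remain for testing.
    """
    if n_seizures < 2:
        raise ValueError("need at least 2 seizures (1 train, 1 test)")
    n_train = math.ceil(fraction * n_seizures)
    n_train = min(n_train, n_seizures - 1)
    return n_train, n_seizures - n_train


def vote(channel_votes, threshold_fraction: float = 0.6) -> bool:
    """True iff the fraction of positive channel votes reaches the threshold."""
    v = np.asarray(channel_votes)
    if v.size == 0:
        raise ValueError("cannot vote over zero channels")
    return bool(np.mean(v != 0) >= threshold_fraction)


@dataclass
class EpochDecision:
    """Per-epoch channel votes and the resulting declaration."""

    epoch_index: int
    channel_votes: np.ndarray
    declared_seizure: bool = field(init=False)
    threshold_fraction: float = 0.6

    def __post_init__(self) -> None:
        self.channel_votes = np.asarray(self.channel_votes).astype(bool)
        self.declared_seizure = vote(self.channel_votes, self.threshold_fraction)


@dataclass
class SeizureEvaluation:
    """Detection outcome for one annotated seizure."""

    seizure_id: str
    annotated_onset_s: float
    detected_onset_s: float | None
    detected: bool

    @property
    def latency_s(self) -> float | None:
        if not self.detected:
            return None
        return self.detected_onset_s - self.annotated_onset_s


def epoch_matrix(
    record: EegRecord, feature_config: dict | None = None, epoch_s: float = 1.0
) -> np.ndarray:
    """Per-epoch per-channel features, shape (n_epochs, n_channels, 20).

    Epoch ``k`` covers ``[k * epoch_s, (k + 1) * epoch_s)`` seconds; a
    trailing partial epoch is discarded.
    """
    spe = int(round(record.sampling_rate_hz * epoch_s))
    n_epochs = record.n_samples // spe
    if n_epochs == 0:
        raise ValueError(
            f"record of {record.duration_s:.2f} s is shorter than one epoch"
        )
    c = record.n_channels
    x = record.samples[:, : n_epochs * spe].reshape(c, n_epochs, spe)
    stacked = x.transpose(1, 0, 2).reshape(n_epochs * c, spe)
    feats = onset_feature_matrix(stacked, feature_config)
    return feats.reshape(n_epochs, c, feats.shape[-1])


def detect_onset(
    decisions: list[EpochDecision],
    annotated_onset_s: float,
    search_window: tuple[float, float],
    epoch_s: float = 1.0,
    seizure_id: str = "",
) -> SeizureEvaluation:
    """Locate the first declared epoch at or after the annotated onset.

    The detected onset is the start time of the first declared epoch whose
    start lies in ``[annotated_onset_s, search_window_end)``, so latency is
    never negative; declarations before the onset are the business of
    false-detection scoring, not of latency.
    """
    lo, hi = search_window
    n = len(decisions)
    if not 0 <= annotated_onset_s <= n * epoch_s:
        raise ValueError(
            f"annotated onset {annotated_onset_s} s outside the {n * epoch_s:.0f}-s record"
        )
    first = math.ceil(max(annotated_onset_s, lo) / epoch_s)
    last = min(n, math.ceil(hi / epoch_s))
    for k in range(first, last):
        if decisions[k].declared_seizure:
            return SeizureEvaluation(
                seizure_id=seizure_id,
                annotated_onset_s=annotated_onset_s,
                detected_onset_s=k * epoch_s,
                detected=True,
            )
    return SeizureEvaluation(
        seizure_id=seizure_id,
        annotated_onset_s=annotated_onset_s,
        detected_onset_s=None,
        detected=False,
    )


@dataclass
class OnsetResults:
    """Per-patient onset-detection report."""

    patient_id: str
    n_train_seizures: int
    n_test_seizures: int
    evaluations: list[SeizureEvaluation]
    false_detections: int
    normal_epochs_evaluated: int
    model: LinearModel
    config: OnsetConfig

    @property
    def sensitivity_pct(self) -> float:
        detected = sum(e.detected for e in self.evaluations)
        return 100.0 * detected / len(self.evaluations)

    @property
    def mean_latency_s(self) -> float | None:
        latencies = [e.latency_s for e in self.evaluations if e.detected]
        return float(np.mean(latencies)) if latencies else None

    @property
    def false_detection_pct(self) -> float:
        if self.normal_epochs_evaluated == 0:
            return 0.0
        return 100.0 * self.false_detections / self.normal_epochs_evaluated

    def summary(self) -> str:
        lat = self.mean_latency_s
        lines = [
            f"Seizure onset detection - patient {self.patient_id}",
            "=" * 60,
            f"Seizures: {self.n_train_seizures} train / {self.n_test_seizures} test",
            f"Vote threshold: {self.config.vote_threshold:.0%} of channels",
            "",
            f"{'seizure':>16} {'onset (s)':>10} {'detected (s)':>13} {'latency (s)':>12}",
        ]
        for e in self.evaluations:
            det = f"{e.detected_onset_s:.0f}" if e.detected else "missed"
            latency = f"{e.latency_s:.1f}" if e.detected else "-"
            lines.append(
                f"{e.seizure_id:>16} {e.annotated_onset_s:>10.1f} {det:>13} {latency:>12}"
            )
        lines += [
            "",
            f"Sensitivity:        {self.sensitivity_pct:6.1f} %",
            f"Mean latency:       {'-' if lat is None else format(lat, '6.2f')} s",
            f"False detections:   {self.false_detection_pct:6.2f} % "
            f"({self.false_detections}/{self.normal_epochs_evaluated} normal epochs)",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "n_train_seizures": self.n_train_seizures,
            "n_test_seizures": self.n_test_seizures,
            "sensitivity_pct": self.sensitivity_pct,
            "mean_latency_s": self.mean_latency_s,
            "false_detection_pct": self.false_detection_pct,
            "false_detections": self.false_detections,
            "normal_epochs_evaluated": self.normal_epochs_evaluated,
            "seizures": [
                {
                    "seizure_id": e.seizure_id,
                    "annotated_onset_s": e.annotated_onset_s,
                    "detected_onset_s": e.detected_onset_s,
                    "latency_s": e.latency_s,
                    "detected": e.detected,
                }
                for e in self.evaluations
            ],
            "config": self.config.to_dict(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


# Backwards-friendly alias: the report type of evaluate_patient.
PatientReport = OnsetResults


class OnsetDetector:
    """Patient-level onset-detection experiment.

    Parameters
    ----------
    records
        The patient's records in chronological order; annotated seizure
        intervals travel on each :class:`~ictal.io.EegRecord`.
    patient_id
        Identifier echoed in the report.
    config
        :class:`OnsetConfig`.
    """

    def __init__(
        self,
        records: list[EegRecord],
        patient_id: str = "",
        config: OnsetConfig | None = None,
    ):
        if not records:
            raise ValueError("no records supplied")
        channels = {r.n_channels for r in records}
        if len(channels) > 1:
            raise ValueError(f"records disagree on channel count: {sorted(channels)}")
        self.records = list(records)
        self.patient_id = patient_id or (records[0].record_id.split("_")[0] or "patient")
        self.config = config or OnsetConfig()

    # -- helpers -----------------------------------------------------------

    def _seizures(self) -> list[tuple[int, float, float]]:
        out = []
        for ri, rec in enumerate(self.records):
            for start, end in rec.annotations:
                out.append((ri, start, end))
        return out

    @staticmethod
    def _seizure_epoch_range(start: float, end: float, epoch_s: float) -> range:
        """Epochs fully inside the annotated interval."""
        return range(math.ceil(start / epoch_s), math.floor(end / epoch_s))

    def _normal_epoch_pool(
        self, record_indices: set[int], epoch_counts: dict[int, int]
    ) -> list[tuple[int, int]]:
        guard = self.config.normal_guard_s
        epoch_s = self.config.epoch_s
        pool = []
        for ri in sorted(record_indices):
            rec = self.records[ri]
            for k in range(epoch_counts[ri]):
                t0, t1 = k * epoch_s, (k + 1) * epoch_s
                if all(
                    t1 <= s - guard or t0 >= e + guard for s, e in rec.annotations
                ):
                    pool.append((ri, k))
        return pool

    # -- fitting -----------------------------------------------------------

    def fit(self) -> OnsetResults:
        cfg = self.config
        dwt_cfg = dict(cfg.dwt_config)
        seizures = self._seizures()
        if len(seizures) < 2:
            raise ValueError("need at least 2 annotated seizures (1 train, 1 test)")
        if cfg.n_train_seizures is not None:
            n_train = cfg.n_train_seizures
            if not 1 <= n_train <= len(seizures) - 1:
                raise ValueError("n_train_seizures leaves no train or no test seizure")
        else:
            n_train, _ = train_test_split_counts(len(seizures), cfg.train_fraction)
        train_seizures = seizures[:n_train]
        test_seizures = seizures[n_train:]

        feats: dict[int, np.ndarray] = {}

        def features_of(ri: int) -> np.ndarray:
            if ri not in feats:
                feats[ri] = epoch_matrix(self.records[ri], dwt_cfg, cfg.epoch_s)
            return feats[ri]

        # positive channel-epochs from training seizures
        pos_blocks = []
        n_pos_epochs = 0
        for ri, start, end in train_seizures:
            f = features_of(ri)
            ks = [k for k in self._seizure_epoch_range(start, end, cfg.epoch_s)
                  if k < f.shape[0]]
            if not ks:
                raise ValueError(
                    f"training seizure ({start}, {end}) in record "
                    f"{self.records[ri].record_id} spans no full epoch"
                )
            pos_blocks.append(f[ks].reshape(-1, f.shape[-1]))
            n_pos_epochs += len(ks)

        # matched normal epochs, seizure-remote, from records without test seizures
        test_records = {ri for ri, _, _ in test_seizures}
        candidate_records = set(range(len(self.records))) - test_records
        epoch_counts = {
            ri: self.records[ri].n_samples
            // int(round(self.records[ri].sampling_rate_hz * cfg.epoch_s))
            for ri in candidate_records
        }
        pool = self._normal_epoch_pool(candidate_records, epoch_counts)
        if not pool:
            raise ValueError(
                "no seizure-remote normal epochs available for training; "
                "add seizure-free records or shrink normal_guard_s"
            )
        rng = np.random.default_rng([cfg.seed, 211])
        take = min(n_pos_epochs, len(pool))
        chosen = rng.choice(len(pool), size=take, replace=False)
        neg_blocks = [
            features_of(pool[i][0])[pool[i][1]] for i in sorted(chosen.tolist())
        ]

        X_pos = np.vstack(pos_blocks)
        X_neg = np.vstack(neg_blocks)
        X = np.vstack([X_neg, X_pos])
        y = np.concatenate([np.zeros(len(X_neg), int), np.ones(len(X_pos), int)])
        model = classify.train(
            X, y, trainer=cfg.trainer, feature_names=ONSET_FEATURE_NAMES
        )

        # evaluate test records: epoch decisions by channel voting
        decisions: dict[int, list[EpochDecision]] = {}
        for ri in sorted(test_records):
            f = features_of(ri)
            n_ep, n_ch, n_feat = f.shape
            preds = model.predict(f.reshape(-1, n_feat)).reshape(n_ep, n_ch)
            decisions[ri] = [
                EpochDecision(k, preds[k] == 1, threshold_fraction=cfg.vote_threshold)
                for k in range(n_ep)
            ]

        evaluations = []
        for idx, (ri, start, end) in enumerate(test_seizures):
            evaluations.append(
                detect_onset(
                    decisions[ri],
                    annotated_onset_s=start,
                    search_window=(start, end),
                    epoch_s=cfg.epoch_s,
                    seizure_id=f"{self.records[ri].record_id}#{idx}",
                )
            )

        # false detections over non-seizure epochs of the test records
        false_det = 0
        normal_eval = 0
        for ri in sorted(test_records):
            rec = self.records[ri]
            for dec in decisions[ri]:
                t0 = dec.epoch_index * cfg.epoch_s
                t1 = t0 + cfg.epoch_s
                in_seizure = any(t1 > s and t0 < e for s, e in rec.annotations)
                if not in_seizure:
                    normal_eval += 1
                    false_det += bool(dec.declared_seizure)

        return OnsetResults(
            patient_id=self.patient_id,
            n_train_seizures=len(train_seizures),
            n_test_seizures=len(test_seizures),
            evaluations=evaluations,
            false_detections=false_det,
            normal_epochs_evaluated=normal_eval,
            model=model,
            config=cfg,
        )


def evaluate_patient(
    records: list[EegRecord],
    seizure_annotations: dict[str, list[tuple[float, float]]] | None = None,
    patient_id: str = "",
    config: OnsetConfig | None = None,
) -> OnsetResults:
    """Convenience wrapper around :class:`OnsetDetector`.

    ``seizure_annotations`` (record id -> intervals) may be supplied from a
    CSV sidecar; intervals already attached to the records are kept.
    """
    if seizure_annotations:
        patched = []
        for rec in records:
            iv = seizure_annotations.get(rec.record_id)
            if iv and not rec.annotations:
                rec = EegRecord(
                    samples=rec.samples,
                    sampling_rate_hz=rec.sampling_rate_hz,
                    channel_labels=rec.channel_labels,
                    record_id=rec.record_id,
                    annotations=list(iv),
                )
            patched.append(rec)
        records = patched
    return OnsetDetector(records, patient_id=patient_id, config=config).fit()
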