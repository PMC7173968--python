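"""Five-state vigilance scoring: data-driven threshold estimation, the base
wake/NREM/REM rules, and the contextual cataplexy and DT-sleep detectors.

Epoch rules (4-s epochs):

* **W** — EMG integral at or above the wake threshold.
* **R** — not W, θ-fraction > 0.5 (θ power over total 1–30 Hz power).
* **NR** — not W, not R (low tone with δ-dominant or mixed EEG).
* **C** (cataplexy) — a maximal run (≥ 3 epochs, i.e. > 10 s) of non-wake
  epochs with EMG below the atonia threshold and θ-fraction > 0.5,
  immediately preceded by ≥ 10 consecutive W epochs (40 s of wakefulness).
* **D** (DT sleep) — a maximal run of non-wake, non-cataplexy epochs with
  atonia, δ power ≥ 60% of the NREM δ reference *and* θ power ≥ 60% of the
  REM θ reference, immediately preceded by ≥ 10 W epochs and immediately
  followed by a return to W.

Cataplexy takes precedence over DT sleep; a run satisfying both is scored C
(cataplexy carries the stricter θ-dominance requirement). The antecedent
wake run must consist strictly of W epochs. A DT-like run cut off by the end
of the recording cannot show its return to wakefulness and is conservatively
left unlabeled (kept NR/R and flagged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Recording, STATES, bandpass, epoch_segment, EEG_BAND, EMG_BAND
from .spectral import EpochFeatures, compute_features

logger = logging.getLogger(__name__)


class ReferenceEstimationError(RuntimeError):
    """Raised when scoring references cannot be derived from a recording."""


@dataclass
class ScoringReferences:
    """Data-driven thresholds the state rules are evaluated against."""

    emg_wake_thresh: float        # µV·s; at/above => muscle-active (wake)
    emg_atonia_thresh: float      # µV·s; below => atonia
    nrem_delta_ref: float         # µV²; central δ power of provisional NREM
    dt_theta_ref: float           # µV²; central θ power of provisional REM
    theta_thresh: float = 0.5     # θ-fraction cut for REM/cataplexy
    dt_delta_ratio: float = 0.6   # DT δ criterion: fraction of nrem_delta_ref
    dt_theta_ratio: float = 0.6   # DT θ criterion: fraction of dt_theta_ref
    min_wake_epochs: int = 10     # 40 s of antecedent wakefulness
    min_cataplexy_epochs: int = 3  # smallest run > 10 s on the 4-s grid

    def __post_init__(self):
        if not (0 < self.emg_atonia_thresh <= self.emg_wake_thresh):
            raise ValueError("need 0 < atonia threshold <= wake threshold")
        if not (0 < self.dt_delta_ratio <= 1):
            raise ValueError("dt_delta_ratio must be in (0, 1]")
        if self.min_wake_epochs * 4.0 < 40.0:
            raise ValueError("antecedent wake must cover >= 40 s")


@dataclass
class Hypnogram:
    """Per-epoch state labels with provenance and the references used."""

    labels: np.ndarray
    provenance: str = "auto"      # auto | truth | corrected
    references: ScoringReferences | None = None
    epoch_len: float = 4.0
    start_clock: float = 72000.0
    lights_on: float = 28800.0
    lights_off: float = 72000.0
    unscorable: np.ndarray | None = None
    truncated_dt_at_end: bool = False

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype="<U2")
        bad = set(self.labels.tolist()) - set(STATES)
        if bad:
            raise ValueError(f"unknown state tokens {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return self.labels.shape[0]

    def validate_structure(self) -> None:
        refs = self.references or ScoringReferences(1, 1, 1, 1)
        _assert_structure(self.labels, refs.min_wake_epochs, refs.min_cataplexy_epochs)


def _assert_structure(labels, min_wake: int, min_c: int) -> None:
    n = len(labels)
    for s, i, j in iter_runs(labels):
        if s == "C" and j - i < min_c:
            raise AssertionError(f"C run [{i},{j}) shorter than {min_c} epochs")
        if s in ("C", "D") and (i < min_wake or not np.all(labels[i - min_wake : i] == "W")):
            raise AssertionError(f"{s} run at {i} lacks {min_wake} antecedent W epochs")
        if s == "D" and j < n and labels[j] != "W":
            raise AssertionError(f"D run [{i},{j}) not followed by W")


def iter_runs(labels):
    """Yield (state, start, stop) for maximal same-label runs, in order."""
    labels = np.asarray(labels)
    n = len(labels)
    i = 0
    while i < n:
        j = i + 1
        while j < n and labels[j] == labels[i]:
            j += 1
        yield str(labels[i]), i, j
        i = j


def _two_means_1d(x: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Optimal two-class 1-D clustering (exhaustive split on sorted values).

    Returns (low center, high center, boolean high-class membership).
    Exact and deterministic, unlike iterative k-means.
    """
    xs = np.sort(x)
    n = len(xs)
    csum = np.cumsum(xs)
    total = csum[-1]
    k = np.arange(1, n)  # split: low class = xs[:k]
    m1 = csum[:-1] / k
    m2 = (total - csum[:-1]) / (n - k)
    # within-class sum of squares, up to a constant
    css = np.cumsum(xs**2)
    wss = (css[:-1] - k * m1**2) + ((css[-1] - css[:-1]) - (n - k) * m2**2)
    kbest = int(np.argmin(wss)) + 1
    cut = xs[kbest - 1]
    high = x > cut
    return float(np.mean(x[~high])), float(np.mean(x[high])), high


def estimate_references(
    features: EpochFeatures,
    theta_thresh: float = 0.5,
    dt_delta_ratio: float = 0.6,
    dt_theta_ratio: float = 0.6,
    min_epochs: int = 500,
    atonia_quantile: float = 0.9,
) -> ScoringReferences:
    """Derive scoring thresholds from the recording itself.

    EMG thresholds come from two-class clustering of log EMG integrals: the
    wake threshold is the midpoint of the cluster centers (log domain) and
    the atonia threshold is the 90th percentile of the low cluster. The δ
    reference is the median δ power of provisional NREM epochs (low EMG,
    δ-dominant); the θ reference is the median θ power of provisional REM
    epochs (low EMG, θ-fraction above threshold), falling back to NREM
    epochs when no REM is present. Thresholds scale with the input channels
    (scale equivariance), so re-gained recordings score identically.
    """
    if features.n_epochs < min_epochs:
        raise ValueError(f"need at least {min_epochs} epochs to estimate references")
    emg = np.asarray(features.emg_integral, dtype=float)
    pos = emg[emg > 0]
    if pos.size < min_epochs // 2:
        raise ReferenceEstimationError("too few epochs with nonzero EMG")
    logs = np.log(np.clip(emg, pos.min() * 1e-3, None))
    c_lo, c_hi, _high = _two_means_1d(logs)
    # bimodality check: fraction of variance the 2-class split explains.
    # An optimal split of a *unimodal* Gaussian explains exactly 2/π ≈ 0.64;
    # genuinely bimodal wake/sleep EMG explains >= ~0.8.
    tss = np.var(logs) * len(logs)
    wss = np.sum((logs[_high] - c_hi) ** 2) + np.sum((logs[~_high] - c_lo) ** 2)
    explained = 1.0 - wss / max(tss, 1e-12)
    if explained < 0.72:
        raise ReferenceEstimationError(
            "EMG integral distribution looks unimodal (no sleep detected?); "
            "set thresholds manually"
        )
    wake_thresh = float(np.exp((c_lo + c_hi) / 2.0))
    low_members = emg[~_high]
    atonia_thresh = float(np.quantile(low_members, atonia_quantile))

    low_emg = emg < wake_thresh
    bf = features.band_fraction
    delta_dominant = np.ones(features.n_epochs, dtype=bool)
    for b in features.bands:
        if b != "delta":
            delta_dominant &= np.nan_to_num(bf["delta"]) >= np.nan_to_num(bf[b])
    tf = np.nan_to_num(features.theta_fraction)
    prov_nr = low_emg & delta_dominant & (tf <= theta_thresh)
    prov_r = low_emg & (tf > theta_thresh)
    if not prov_nr.any():
        raise ReferenceEstimationError("no provisional NREM epochs; δ reference undefined")
    nrem_delta_ref = float(np.median(features.band_power["delta"][prov_nr]))
    theta_pool = prov_r if prov_r.any() else prov_nr
    dt_theta_ref = float(np.median(features.band_power["theta"][theta_pool]))
    logger.info(
        "references: wake %.3g, atonia %.3g µV·s; δ ref %.3g, θ ref %.3g µV²",
        wake_thresh, atonia_thresh, nrem_delta_ref, dt_theta_ref,
    )
    return ScoringReferences(
        emg_wake_thresh=wake_thresh,
        emg_atonia_thresh=atonia_thresh,
        nrem_delta_ref=nrem_delta_ref,
        dt_theta_ref=dt_theta_ref,
        theta_thresh=theta_thresh,
        dt_delta_ratio=dt_delta_ratio,
        dt_theta_ratio=dt_theta_ratio,
    )


def classify_base(features: EpochFeatures, refs: ScoringReferences):
    """Provisional W/NR/R labels; returns (labels, unscorable mask)."""
    emg = np.asarray(features.emg_integral, dtype=float)
    tf = np.asarray(features.theta_fraction, dtype=float)
    unscorable = ~np.isfinite(tf)
    labels = np.full(features.n_epochs, "NR", dtype="<U2")
    labels[(~unscorable) & (tf > refs.theta_thresh)] = "R"
    labels[emg >= refs.emg_wake_thresh] = "W"  # wake rule takes precedence
    if unscorable.any():
        logger.info("%d unscorable epochs (no spectral power)", int(unscorable.sum()))
    return labels, unscorable


def _candidate_runs(candidate: np.ndarray):
    """Maximal runs of True in a boolean array, as (start, stop) pairs."""
    idx = np.flatnonzero(candidate)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    return list(zip(starts.tolist(), stops.tolist()))


def _has_antecedent_wake(labels, start: int, min_wake: int) -> bool:
    return start >= min_wake and bool(np.all(labels[start - min_wake : start] == "W"))


def detect_cataplexy(labels, features: EpochFeatures, refs: ScoringReferences):
    """Relabel qualifying atonia/θ-dominant runs after sustained wake as C."""
    labels = np.asarray(labels, dtype="<U2").copy()
    emg = np.asarray(features.emg_integral, dtype=float)
    tf = np.nan_to_num(np.asarray(features.theta_fraction, dtype=float))
    candidate = (labels != "W") & (emg < refs.emg_atonia_thresh) & (tf > refs.theta_thresh)
    for start, stop in _candidate_runs(candidate):
        if stop - start < refs.min_cataplexy_epochs:
            continue
        if _has_antecedent_wake(labels, start, refs.min_wake_epochs):
            labels[start:stop] = "C"
    return labels


def detect_dt_sleep(labels, features: EpochFeatures, refs: ScoringReferences):
    """Relabel qualifying high-δ/high-θ atonia arrests as D (DT sleep).

    Must run after cataplexy detection (C has precedence). Returns
    (labels, n_truncated_at_end).
    """
    labels = np.asarray(labels, dtype="<U2").copy()
    if not np.isfinite(refs.nrem_delta_ref) or refs.nrem_delta_ref <= 0:
        raise ReferenceEstimationError("NREM δ reference missing; cannot score DT sleep")
    emg = np.asarray(features.emg_integral, dtype=float)
    delta = np.asarray(features.band_power["delta"], dtype=float)
    theta = np.asarray(features.band_power["theta"], dtype=float)
    candidate = (
        (labels != "W")
        & (labels != "C")
        & (emg < refs.emg_atonia_thresh)
        & (delta >= refs.dt_delta_ratio * refs.nrem_delta_ref)
        & (theta >= refs.dt_theta_ratio * refs.dt_theta_ref)
    )
    n = len(labels)
    truncated = 0
    for start, stop in _candidate_runs(candidate):
        if not _has_antecedent_wake(labels, start, refs.min_wake_epochs):
            continue
        if stop >= n:
            truncated += 1  # no following epoch: return to wake unverifiable
            logger.info("DT-like run at recording end left unlabeled")
            continue
        if labels[stop] != "W":
            continue
        labels[start:stop] = "D"
    return labels, truncated


def score_recording(
    rec: Recording,
    refs: ScoringReferences | None = None,
    epoch_len: float = 4.0,
    bands: dict | None = None,
    context: bool = True,
    **ref_overrides,
) -> Hypnogram:
    """Full pipeline: filter → epoch → features → references → W/NR/R → C → D.

    ``refs`` may be supplied to skip estimation (e.g. manual thresholds);
    ``context=False`` stops after the base rules (no C/D detection).
    The resulting hypnogram carries the features table used for scoring in
    ``.features`` for downstream spectral comparisons.
    """
    filtered = Recording(
        eeg=bandpass(rec.eeg, rec.fs, *EEG_BAND),
        emg=bandpass(rec.emg, rec.fs, *EMG_BAND),
        fs=rec.fs,
        start_clock=rec.start_clock,
        lights_on=rec.lights_on,
        lights_off=rec.lights_off,
    )
    es = epoch_segment(filtered, epoch_len)
    features = compute_features(es, bands)
    if refs is None:
        refs = estimate_references(features, **ref_overrides)
    labels, unscorable = classify_base(features, refs)
    truncated = 0
    if context:
        labels = detect_cataplexy(labels, features, refs)
        labels, truncated = detect_dt_sleep(labels, features, refs)
    hyp = Hypnogram(
        labels=labels,
        provenance="auto",
        references=refs,
        epoch_len=epoch_len,
        start_clock=rec.start_clock,
        lights_on=rec.lights_on,
        lights_off=rec.lights_off,
        unscorable=unscorable,
        truncated_dt_at_end=bool(truncated),
    )
    hyp.features = features  # type: ignore[attr-defined]
    hyp.validate_structure()
    return hyp


@dataclass
class ScoringEvaluation:
    confusion: pd.DataFrame       # rows = truth, columns = prediction
    recall: pd.Series
    precision: pd.Series
    accuracy: float


def evaluate_scoring(pred, truth) -> ScoringEvaluation:
    """Confusion matrix and per-state recall/precision against ground truth."""
    p = pred.labels if isinstance(pred, Hypnogram) else np.asarray(pred, dtype=str)
    t = truth.labels if hasattr(truth, "labels") else np.asarray(truth, dtype=str)
    if len(p) != len(t):
        raise ValueError(f"length mismatch: {len(p)} predicted vs {len(t)} true epochs")
    cm = pd.DataFrame(0, index=list(STATES), columns=list(STATES), dtype=int)
    for ti, pi in zip(t, p):
        cm.loc[ti, pi] += 1
    row_sums = cm.sum(axis=1)
    col_sums = cm.sum(axis=0)
    diag = pd.Series(np.diag(cm.values), index=cm.index)
    with np.errstate(invalid="ignore"):
        recall = diag / row_sums.replace(0, np.nan)
        precision = diag / col_sums.replace(0, np.nan)
    accuracy = float(diag.sum() / max(len(t), 1))
    return ScoringEvaluation(cm, recall, precision, accuracy)
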