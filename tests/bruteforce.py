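"""Independent oracles used by the test suite.

These deliberately avoid the library's run-scanning code paths: the context
detector oracle enumerates every candidate interval naively, and the
occupancy oracle solves the embedded Markov chain with plain linear algebra.
"""

from __future__ import annotations

import numpy as np

from dtsleep.scoring import ScoringReferences
from dtsleep.spectral import EpochFeatures


def make_features(emg, delta, theta, theta_fraction, epoch_len: float = 4.0) -> EpochFeatures:
    """Minimal feature table for driving the state rules directly."""
    emg = np.asarray(emg, dtype=float)
    n = len(emg)
    zeros = np.zeros(n)
    bands = {"delta": (1, 6), "theta": (6, 11), "alpha": (11, 16), "beta": (16, 31)}
    return EpochFeatures(
        psd_1hz=np.zeros((n, 31)),
        freqs=np.arange(31, dtype=float),
        band_power={
            "delta": np.asarray(delta, dtype=float),
            "theta": np.asarray(theta, dtype=float),
            "alpha": zeros,
            "beta": zeros,
        },
        band_fraction={b: zeros for b in bands},
        theta_fraction=np.asarray(theta_fraction, dtype=float),
        emg_integral=emg,
        epoch_len=epoch_len,
        bands=bands,
    )


def brute_force_context(base_labels, features: EpochFeatures, refs: ScoringReferences):
    """Exhaustive interval enumeration of the cataplexy and DT-sleep rules.

    Every interval [i, j) is tested against the written criteria; maximality
    is checked against the per-epoch candidate predicates; cataplexy is
    applied first (precedence), then DT sleep on the updated labels.
    """
    lab = list(np.asarray(base_labels, dtype=str))
    n = len(lab)
    emg = features.emg_integral
    tf = np.nan_to_num(features.theta_fraction)
    delta = features.band_power["delta"]
    theta = features.band_power["theta"]

    def wake_before(i):
        k = refs.min_wake_epochs
        return i >= k and all(lab[m] == "W" for m in range(i - k, i))

    c_cand = [
        lab[k] != "W" and emg[k] < refs.emg_atonia_thresh and tf[k] > refs.theta_thresh
        for k in range(n)
    ]
    c_intervals = []
    for i in range(n):
        for j in range(i + 1, n + 1):
            if not all(c_cand[i:j]):
                continue
            if i > 0 and c_cand[i - 1]:
                continue
            if j < n and c_cand[j]:
                continue
            if j - i >= refs.min_cataplexy_epochs and wake_before(i):
                c_intervals.append((i, j))
    for i, j in c_intervals:
        for k in range(i, j):
            lab[k] = "C"

    d_cand = [
        lab[k] not in ("W", "C")
        and emg[k] < refs.emg_atonia_thresh
        and delta[k] >= refs.dt_delta_ratio * refs.nrem_delta_ref
        and theta[k] >= refs.dt_theta_ratio * refs.dt_theta_ref
        for k in range(n)
    ]
    d_intervals = []
    for i in range(n):
        for j in range(i + 1, n + 1):
            if not all(d_cand[i:j]):
                continue
            if i > 0 and d_cand[i - 1]:
                continue
            if j < n and d_cand[j]:
                continue
            if j < n and lab[j] == "W" and wake_before(i):
                d_intervals.append((i, j))
    for i, j in d_intervals:
        for k in range(i, j):
            lab[k] = "D"
    return np.asarray(lab, dtype="<U2")


def semi_markov_occupancy(config) -> dict[str, float]:
    """Stationary state occupancy of a semi-Markov chain without C/D states:
    embedded-chain stationary distribution (solved by linear algebra) weighted
    by the expected discretized dwell length of each state."""
    states = list(config.profiles)
    assert not ({"C", "D"} & set(states)), "oracle assumes no wake-length coupling"
    k = len(states)
    P = np.zeros((k, k))
    for (a, b), w in config.transition_weights.items():
        P[states.index(a), states.index(b)] = w
    P /= P.sum(axis=1, keepdims=True)
    # stationary distribution of the embedded jump chain
    A = np.vstack([P.T - np.eye(k), np.ones(k)])
    nu = np.linalg.lstsq(A, np.concatenate([np.zeros(k), [1.0]]), rcond=None)[0]
    mean_ep = np.array(
        [config.profiles[s].dwell.mean_epochs(config.epoch_len) for s in states]
    )
    occ = nu * mean_ep
    occ /= occ.sum()
    return dict(zip(states, occ))
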