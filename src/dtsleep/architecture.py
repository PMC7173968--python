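"""Sleep-architecture statistics from hypnograms: maximal-run bouts, per-phase
and hourly summaries, fold differences between groups, NREM→REM transition
windows, DT-vs-transition spectral comparison, and the standard group tests
(paired/unpaired t, one-way ANOVA with Bonferroni post hoc).

Conventions: a *bout* is a maximal run of consecutive epochs with one label.
Phase totals are epoch-accurate (each epoch counts toward the phase its start
clock falls in); bout counts and mean bout durations assign a bout to the
phase of its start epoch. The two conventions only differ for bouts spanning
a light/dark boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import STATES, is_light
from .scoring import Hypnogram, iter_runs
from .spectral import EpochFeatures

logger = logging.getLogger(__name__)


def _hyp_meta(hyp, epoch_len, start_clock, lights_on, lights_off):
    if isinstance(hyp, Hypnogram):
        return (
            hyp.labels,
            hyp.epoch_len,
            hyp.start_clock,
            hyp.lights_on,
            hyp.lights_off,
        )
    return np.asarray(hyp, dtype=str), epoch_len, start_clock, lights_on, lights_off


def extract_bouts(
    hyp,
    epoch_len: float = 4.0,
    start_clock: float = 72000.0,
    lights_on: float = 28800.0,
    lights_off: float = 72000.0,
) -> pd.DataFrame:
    """Maximal same-state runs, in order; together they partition the hypnogram.

    Columns: state, start_epoch, n_epochs, duration_s, phase (of the start
    epoch), antecedent_wake (length in epochs of the immediately preceding
    wake run, 0 if the previous epoch is not W).
    """
    labels, epoch_len, start_clock, lights_on, lights_off = _hyp_meta(
        hyp, epoch_len, start_clock, lights_on, lights_off
    )
    if len(labels) == 0:
        raise ValueError("empty hypnogram")
    rows = []
    prev_state, prev_len = None, 0
    for s, i, j in iter_runs(labels):
        clock = (start_clock + i * epoch_len) % 86400.0
        rows.append(
            {
                "state": s,
                "start_epoch": i,
                "n_epochs": j - i,
                "duration_s": (j - i) * epoch_len,
                "phase": "light" if is_light(clock, lights_on, lights_off) else "dark",
                "antecedent_wake": prev_len if prev_state == "W" else 0,
            }
        )
        prev_state, prev_len = s, j - i
    df = pd.DataFrame(rows)
    df.attrs.update(
        epoch_len=epoch_len, start_clock=start_clock,
        lights_on=lights_on, lights_off=lights_off,
    )
    return df


def phase_summary(
    bouts: pd.DataFrame,
    lights_on: float | None = None,
    lights_off: float | None = None,
) -> pd.DataFrame:
    """Totals, bout counts and mean bout durations per (state, phase).

    ``total_min`` is epoch-accurate (bouts spanning the light/dark boundary
    are split); ``n_bouts`` and ``mean_bout_s`` use the start-epoch phase
    convention, with ``mean_bout_s = total bout seconds / n_bouts`` over the
    bouts assigned to the phase.
    """
    lights_on = bouts.attrs["lights_on"] if lights_on is None else lights_on
    lights_off = bouts.attrs["lights_off"] if lights_off is None else lights_off
    epoch_len = bouts.attrs.get("epoch_len", 4.0)
    start_clock = bouts.attrs.get("start_clock", 72000.0)

    acc: dict[tuple[str, str], dict] = {}
    for row in bouts.itertuples():
        # epoch-accurate split of the bout across phases
        epochs = row.start_epoch + np.arange(row.n_epochs)
        clocks = (start_clock + epochs * epoch_len) % 86400.0
        in_light = is_light(clocks, lights_on, lights_off)
        for phase, n_ep in (("light", int(in_light.sum())), ("dark", int((~in_light).sum()))):
            if n_ep == 0:
                continue
            a = acc.setdefault((row.state, phase), {"total_s": 0.0, "n_bouts": 0, "bout_s": 0.0})
            a["total_s"] += n_ep * epoch_len
        a = acc.setdefault((row.state, row.phase), {"total_s": 0.0, "n_bouts": 0, "bout_s": 0.0})
        a["n_bouts"] += 1
        a["bout_s"] += row.duration_s

    rows = []
    for (state, phase), a in sorted(acc.items()):
        mean = a["bout_s"] / a["n_bouts"] if a["n_bouts"] else np.nan
        rows.append(
            {
                "state": state,
                "phase": phase,
                "total_min": a["total_s"] / 60.0,
                "n_bouts": a["n_bouts"],
                "mean_bout_s": mean,
            }
        )
    return pd.DataFrame(rows).set_index(["state", "phase"]).sort_index()


def fold_difference(summary_a, summary_b, metric=None, state=None, phase=None) -> float:
    """Ratio of group B over group A for one metric (e.g. OXMC over OX).

    Accepts two phase summaries plus (metric, state, phase), or two plain
    numbers. Full precision is returned; round to 2 decimals for reports.
    """
    if np.isscalar(summary_a) and np.isscalar(summary_b):
        a, b = float(summary_a), float(summary_b)
    else:
        if metric is None or state is None or phase is None:
            raise ValueError("metric, state and phase are required with summaries")
        a = float(summary_a.loc[(state, phase), metric])
        b = float(summary_b.loc[(state, phase), metric])
    if a == 0:
        raise ZeroDivisionError("fold difference undefined: denominator is zero")
    return b / a


def hourly_summary(
    bouts: pd.DataFrame,
    window_start: float = 0.0,
    n_hours: int = 6,
) -> pd.DataFrame:
    """Per-hour totals, bout counts and mean durations per state.

    ``window_start`` is in seconds from the start of the hypnogram. Totals
    split bouts at hour boundaries; a bout spanning a boundary counts once,
    in its start hour. Hours with no bouts of a state get zero totals and an
    undefined (NaN) mean.
    """
    epoch_len = bouts.attrs.get("epoch_len", 4.0)
    end_epoch = int(bouts["start_epoch"].iloc[-1] + bouts["n_epochs"].iloc[-1])
    w0 = window_start / epoch_len
    if w0 < 0 or (window_start + n_hours * 3600.0) / epoch_len > end_epoch + 1e-9:
        raise ValueError("window outside recording")
    eph = 3600.0 / epoch_len  # epochs per hour
    states = sorted(bouts["state"].unique())
    idx = pd.MultiIndex.from_product([range(n_hours), states], names=["hour", "state"])
    out = pd.DataFrame({"total_min": 0.0, "n_bouts": 0}, index=idx)
    for row in bouts.itertuples():
        b0, b1 = row.start_epoch, row.start_epoch + row.n_epochs
        for h in range(n_hours):
            h0, h1 = w0 + h * eph, w0 + (h + 1) * eph
            overlap = min(b1, h1) - max(b0, h0)
            if overlap > 0:
                out.loc[(h, row.state), "total_min"] += overlap * epoch_len / 60.0
            if h0 <= b0 < h1:
                out.loc[(h, row.state), "n_bouts"] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        out["mean_bout_s"] = np.where(
            out["n_bouts"] > 0, out["total_min"] * 60.0 / out["n_bouts"], np.nan
        )
    return out


def nrem_to_rem_transitions(hyp) -> list[np.ndarray]:
    """Indices of the last 3 NREM epochs (12 s) before each REM bout.

    NREM runs shorter than 3 epochs before REM are skipped (and logged).
    """
    labels = hyp.labels if isinstance(hyp, Hypnogram) else np.asarray(hyp, dtype=str)
    windows = []
    skipped = 0
    runs = list(iter_runs(labels))
    for (s, i, j), (s2, i2, _) in zip(runs, runs[1:]):
        if s == "NR" and s2 == "R":
            if j - i >= 3:
                windows.append(np.arange(j - 3, j))
            else:
                skipped += 1
    if skipped:
        logger.info("skipped %d NREM→REM transitions with < 3 NREM epochs", skipped)
    return windows


def compare_dt_vs_transition(recordings, alpha: float = 0.05):
    """Mean EEG band fractions and EMG integral during DT sleep versus the
    NREM→REM transition, with per-band paired t-tests across recordings.

    ``recordings`` is a list of (features, hypnogram/labels) pairs (one per
    animal/recording); a single pair may be given, in which case only the
    means are returned and the tests are skipped with a notice. Raw p-values
    are Bonferroni-adjusted over the compared bands. Recordings lacking
    either DT epochs or transitions are excluded (and logged); if none
    remain, a ValueError is raised.

    Returns (per-recording means DataFrame, tests DataFrame or None).
    """
    if isinstance(recordings, tuple) and len(recordings) == 2:
        recordings = [recordings]
    rows = []
    for k, (features, hyp) in enumerate(recordings):
        labels = hyp.labels if isinstance(hyp, Hypnogram) else np.asarray(hyp, dtype=str)
        d_mask = labels == "D"
        windows = nrem_to_rem_transitions(labels)
        if not d_mask.any() or not windows:
            logger.info("recording %d lacks DT epochs or transitions; excluded", k)
            continue
        tr_idx = np.concatenate(windows)
        for cond, sel in (("DT", np.flatnonzero(d_mask)), ("transition", tr_idx)):
            row = {"recording": k, "condition": cond, "n_epochs": len(sel)}
            for b in features.bands:
                row[f"fraction_{b}"] = float(np.nanmean(features.band_fraction[b][sel]))
            row["emg_integral"] = float(np.mean(features.emg_integral[sel]))
            rows.append(row)
    if not rows:
        raise ValueError("no recording contains both DT epochs and NREM→REM transitions")
    means = pd.DataFrame(rows)
    n_rec = means["recording"].nunique()
    if n_rec < 2:
        logger.info("single recording: paired tests skipped")
        return means, None
    bands = [c for c in means.columns if c.startswith("fraction_")] + ["emg_integral"]
    piv = means.pivot(index="recording", columns="condition", values=bands)
    tests = []
    m = len(bands)
    for b in bands:
        t, p = stats.ttest_rel(piv[(b, "DT")], piv[(b, "transition")])
        tests.append(
            {
                "measure": b,
                "t": float(t),
                "df": n_rec - 1,
                "p_raw": float(p),
                "p_bonferroni": min(1.0, float(p) * m),
                "significant": bool(min(1.0, float(p) * m) < alpha),
            }
        )
    return means, pd.DataFrame(tests)


def group_tests(groups: dict, design: str = "unpaired") -> pd.DataFrame:
    """Standard group comparisons: paired/unpaired t-test or one-way ANOVA
    followed by Bonferroni-adjusted pairwise t-tests.

    ``groups`` maps group name -> 1-D array of per-animal values.
    """
    names = list(groups)
    vals = [np.asarray(groups[g], dtype=float) for g in names]
    if len(vals) < 2 or any(len(v) < 2 for v in vals):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if all(np.ptp(v) == 0 for v in vals):
        raise ValueError("zero variance in all groups; tests undefined")
    rows = []
    if design in ("paired", "unpaired"):
        if len(vals) != 2:
            raise ValueError("t-test designs need exactly 2 groups")
        a, b = vals
        if design == "paired":
            if np.all(a == b):  # identical pairs: no difference by definition
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(a, b)
            df = len(a) - 1
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
            df = len(a) + len(b) - 2
        rows.append({"comparison": f"{names[0]} vs {names[1]}", "statistic": float(t),
                     "df": df, "p_raw": float(p), "p_adjusted": float(p)})
    elif design == "oneway_bonferroni":
        f, p = stats.f_oneway(*vals)
        rows.append({"comparison": "ANOVA", "statistic": float(f),
                     "df": (len(vals) - 1, sum(len(v) for v in vals) - len(vals)),
                     "p_raw": float(p), "p_adjusted": float(p)})
        pairs = [(i, j) for i in range(len(vals)) for j in range(i + 1, len(vals))]
        m = len(pairs)
        for i, j in pairs:
            t, pr = stats.ttest_ind(vals[i], vals[j], equal_var=True)
            rows.append({"comparison": f"{names[i]} vs {names[j]}", "statistic": float(t),
                         "df": len(vals[i]) + len(vals[j]) - 2, "p_raw": float(pr),
                         "p_adjusted": min(1.0, float(pr) * m)})
    else:
        raise ValueError(f"unknown design {design!r}")
    return pd.DataFrame(rows)
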