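"""Small purpose-built simulation configs for tests: short recordings rich in
both DT bouts and NREM→REM transitions, with optional spectral ties between
DT sleep and NREM (for null calibration of the DT-vs-transition comparison).
"""

from dataclasses import replace

from dtsleep.synthetic import DwellDist, SimulationConfig, default_profiles


def dt_rich_config(
    seed: int,
    duration: float = 1200.0,
    nr_same_as_d: bool = False,
    d_delta_scale: float = 1.0,
) -> SimulationConfig:
    """Frequent DT bouts and REM entries in a short recording.

    ``nr_same_as_d`` gives NREM the same signal profile as DT sleep, making
    the NREM→REM transition spectrally identical to DT (a true null for the
    band comparison). ``d_delta_scale`` multiplies the DT δ amplitude.

    State switches are hard (no crossfade): boundary-epoch blending would
    contaminate transition epochs with REM and DT epochs with wake, which is
    a genuine (if tiny) systematic difference that a paired test across
    recordings would correctly flag. The exact null needs exchangeable
    epochs.
    """
    profiles = default_profiles()
    del profiles["C"]
    profiles["W"] = replace(profiles["W"], dwell=DwellDist(60.0))
    profiles["R"] = replace(profiles["R"], dwell=DwellDist(30.0))
    profiles["D"] = replace(profiles["D"], dwell=DwellDist(14.4))
    if nr_same_as_d:
        profiles["NR"] = replace(
            profiles["D"], state="NR", dwell=DwellDist(40.0)
        )
    else:
        profiles["NR"] = replace(profiles["NR"], dwell=DwellDist(40.0))
    d_amps = dict(profiles["D"].band_amplitudes)
    d_amps["delta"] *= d_delta_scale  # applied after any NR tie, so the tie breaks
    profiles["D"] = replace(profiles["D"], band_amplitudes=d_amps)
    tw = {
        ("W", "NR"): 0.5,
        ("W", "D"): 0.5,
        ("NR", "W"): 0.5,
        ("NR", "R"): 0.5,
        ("R", "W"): 1.0,
        ("D", "W"): 1.0,
    }
    return SimulationConfig(
        duration=duration, profiles=profiles, transition_weights=tw, seed=seed,
        crossfade_s=0.0,
    )
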