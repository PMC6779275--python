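"""Shared helpers for the test suite."""

import numpy as np

from ripoptosim.hybrid import CellTrajectory, Scenario


def make_traj(times, rate):
    """Minimal CellTrajectory carrying a synthetic FRET cleavage-rate trace."""
    times = np.asarray(times, dtype=float)
    rate = np.asarray(rate, dtype=float)
    n = len(times)
    z = np.zeros(n)
    return CellTrajectory(
        times=times, cum_active_casp8=z, ded12_released=z,
        rip1_rip3_heterodimers=z, mean_fadd_per_origin=z,
        max_platform_mass_kda=z,
        cascade={"fret_cleaved": np.cumsum(rate)},
        fret_cleavage_rate=rate, free_pools={}, seed=0,
        scenario=Scenario(5.0, True), n_origins=0,
    )
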