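"""Reduced test configurations generated programmatically.

``tiny_network`` uses a cell volume chosen so that 1 nM == 1 molecule, making
copy-number configs exact and the assembly state space small enough for
brute-force chemical-master-equation validation.
"""

from __future__ import annotations

import numpy as np

from .params import AVOGADRO, ModelConfig, ValidationError

__all__ = ["generate_fixtures", "ONE_COPY_VOLUME_L"]

# volume for which copies_per_nm == 1 (1 nM corresponds to a single molecule)
ONE_COPY_VOLUME_L = 1.0 / (AVOGADRO * 1e-9)


def generate_fixtures(kind: str, seed: int = 0):
    """Return ``(fixture, expected)`` for a named test fixture kind.

    tiny_network
        A one-origin, four-species assembly config (2 free RIP1, 1 FADD,
        1 ProCasp8, irreversible binding, no cFLIP/RIP3/clustering) whose
        master equation has at most 32 states; ``fixture`` is a ModelConfig
        to be used with ``n_origins=1``.
    default_like
        The full network at one-tenth copy numbers (volume / 10) for fast
        continuous-integration runs; ``fixture`` is a ModelConfig.
    two_mode_delays
        Synthetic death-delay samples from a well-separated two-Gaussian
        mixture with known bimodality; ``fixture`` is a 1-D array (minutes).
    """
    if kind == "tiny_network":
        cfg = ModelConfig().replace(
            geometry={"volume_l": ONE_COPY_VOLUME_L},
            initial_nm={
                "rip1": 3.0,   # 1 origin seed + 2 free
                "rip3": 0.0,
                "fadd": 1.0,
                "procasp8": 1.0,
                "cflip_l": 0.0,
                "cflip_s": 0.0,
                "procasp3": 0.0,
                "procasp6": 0.0,
                "xiap": 63.0,
                "fret_substrate": 1.0,
            },
            rates={
                # irreversible binding only; rates O(1) per minute
                "kon_rip1_rip1": 1.0,
                "kon_fadd_platform": 0.5,
                "kon_procasp8_ded": 0.8,
                "kon_rip3_rip1": 0.0,
                "kon_cflip_l_ded": 0.0,
                "kon_cflip_s_ded": 0.0,
                "kon_ded12_ded": 0.0,
                "koff_rip1_rip1": 0.0,
                "koff_rip3_rip1": 0.0,
                "koff_fadd_platform": 0.0,
                "koff_procasp8_ded": 0.0,
                "koff_cflip_l_ded": 0.0,
                "koff_cflip_s_ded": 0.0,
                "koff_ded12_ded": 0.0,
                "k_cis_dimer": 0.0,
                "k_trans_dimer": 0.0,
                "k_dimer_diss": 0.0,
                "k_casp8_activation": 0.0,
            },
        )
        expected = {
            "n_origins": 1,
            "max_states": 32,
            "species": ("rip1", "fadd", "procasp8"),
        }
        return cfg, expected

    if kind == "default_like":
        base = ModelConfig()
        cfg = base.replace(
            geometry={"volume_l": base.geometry.volume_l / 10.0})
        expected = {"copies_per_nm": cfg.copies_per_nm,
                    "runtime_contract_s": 60.0,
                    "n_cells_contract": 10}
        return cfg, expected

    if kind == "two_mode_delays":
        rng = np.random.default_rng(seed)
        early = rng.normal(120.0, 25.0, size=150)
        late = rng.normal(480.0, 40.0, size=150)
        delays = np.clip(np.concatenate([early, late]), 1.0, None)
        expected = {"bimodal": True, "mode_means_min": (120.0, 480.0),
                    "n": delays.size}
        return delays, expected

    raise ValidationError(f"unknown fixture kind {kind!r}")
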