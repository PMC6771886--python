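"""Default pool parameters, saturation protocol and fitting priors.

One registry serves the forward model, the phantom generator and the
voxelwise fits, so simulated data and the models fitted to it share a single
source of truth.  Tissue is described generically (no separate GM/WM
compartments) by four pools at 3 T; the CSF compartment is a single free-water
pool whose equilibrium signal is tied to the tissue water signal by the
CSF/tissue concentration ratio (default 0.53).

The solute values are literature-typical for amide proton transfer imaging at
3 T rather than certified constants; they are plain data here and can be
overridden per fit or per phantom.
"""

from __future__ import annotations

import numpy as np

from cestpvc.forward import Pool, PulseTrain, SaturationProtocol

__all__ = [
    "CSF_TISSUE_RATIO",
    "default_tissue_pools",
    "default_csf_pool",
    "default_protocol",
    "default_pulse_train",
    "default_offsets",
    "default_prior_table",
    "DEFAULT_FREE_PARAMS",
]

#: Mean ratio of CSF to tissue water equilibrium signal (proton density
#: modulated by T1 saturation), used to pin the CSF compartment scale.
CSF_TISSUE_RATIO = 0.53


def default_tissue_pools() -> list[Pool]:
    """4-pool tissue model: water, amide (+3.5 ppm), symmetric semisolid MT,
    and an upfield NOE pool."""
    return [
        Pool("water", m0=1.0, kex=0.0, t1=1.3, t2=0.055, dw=0.0),
        Pool("amide", m0=6.5e-4, kex=30.0, t1=1.0, t2=0.02, dw=3.5),
        Pool("mt", m0=0.08, kex=25.0, t1=1.0, t2=1.0e-5, dw=0.0),
        Pool("noe", m0=1.0e-3, kex=16.0, t1=1.3, t2=0.005, dw=-3.5),
    ]


def default_csf_pool(tissue_water_m0: float = 1.0, ratio: float = CSF_TISSUE_RATIO) -> Pool:
    """1-pool CSF model: long-T1 free water, concentration tied to tissue.

    ``t2`` is an effective (apparent) transverse relaxation time.  The
    intrinsic CSF T2 at 3 T approaches 2 s, but under off-resonance
    irradiation the observable linewidth is set by intravoxel dephasing and
    the pulsed nature of real saturation, which damp transverse coherence far
    faster; an intrinsic-T2 continuous-wave pool would additionally predict
    undamped Rabi oscillations over a 2 s saturation that real z-spectra do
    not show.
    """
    return Pool("csf", m0=ratio * tissue_water_m0, kex=0.0, t1=4.3, t2=0.2, dw=0.0)


def default_offsets() -> list[float]:
    """32 offsets spanning -4.5 .. 4.5 ppm plus a 300 ppm reference."""
    return [float(x) for x in np.linspace(-4.5, 4.5, 32)] + [300.0]


def default_pulse_train() -> PulseTrain:
    """50 Gaussian pulses, 184 degrees, 20 ms pulse / 20 ms gap."""
    return PulseTrain(
        n_pulses=50,
        flip_angle=184.0,
        pulse_duration=0.020,
        inter_pulse_delay=0.020,
        shape="gaussian",
        gaussian_truncation=0.01,
    )


def default_protocol() -> SaturationProtocol:
    """CW-equivalent acquisition: B1 = 0.55 uT, 2 s saturation, 3 T."""
    return SaturationProtocol(
        b1=0.55,
        t_sat=2.0,
        offsets=default_offsets(),
        larmor=127.74,
        reference_offset=300.0,
    )


# Free parameters per model; everything else (solute T1, chemical shifts,
# CSF relaxation inside the PVC mixture) stays at the compartment defaults.
DEFAULT_FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "four_pool": (
        "water_m0", "water_t1", "water_t2",
        "amide_m0", "amide_kex", "amide_t2",
        "mt_m0", "mt_kex", "mt_t2",
        "noe_m0", "noe_kex", "noe_t2",
        "b0_shift",
    ),
    "pvc": (
        "water_m0", "water_t1", "water_t2",
        "amide_m0", "amide_kex", "amide_t2",
        "mt_m0", "mt_kex", "mt_t2",
        "noe_m0", "noe_kex", "noe_t2",
        "b0_shift",
    ),
    "csf_only": ("csf_m0", "csf_t2", "b0_shift"),
}


def default_prior_table() -> dict[str, tuple[float, float, str]]:
    """Gaussian priors as ``name -> (mean, sd, scale)``.

    Concentrations and exchange rates are given on a log scale (mean is the
    natural-scale value, sd applies to log); relaxation times and frequency
    shifts are linear.
    """
    return {
        "water_m0": (1.0, 0.2, "log"),
        "water_t1": (1.3, 0.3, "linear"),
        "water_t2": (0.055, 0.02, "linear"),
        "amide_m0": (6.5e-4, 0.35, "log"),
        "amide_kex": (30.0, 0.2, "log"),
        "amide_t2": (0.02, 0.01, "linear"),
        "mt_m0": (0.08, 0.3, "log"),
        "mt_kex": (25.0, 0.2, "log"),
        "mt_t2": (1.0e-5, 5.0e-6, "linear"),
        "noe_m0": (1.0e-3, 0.35, "log"),
        "noe_kex": (16.0, 0.2, "log"),
        "noe_t2": (0.005, 0.003, "linear"),
        "b0_shift": (0.0, 0.3, "linear"),
        "csf_m0": (0.53, 0.3, "log"),
        "csf_t1": (4.3, 0.5, "linear"),
        "csf_t2": (0.2, 0.1, "linear"),
    }
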