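"""Plain-text (YAML) configuration files.

Keys mirror the standard parameter-table names::

    model:
      A: 3.25          # mV
      B: 22.0          # mV
      a: 100.0         # 1/s
      b: 50.0          # 1/s
      C1: 135.0
      C2: 108.0
      C3: 33.75
      C4: 33.75
      e0: 2.5          # 1/s
      v0: 6.0          # mV
      r: 0.56          # 1/mV
    network:
      n_columns: 4
      coupling_strength: 15.0
      constant_input: 75.0          # Hz
    noise:
      noise_intensity: 350.0        # Hz
      noise_correlation_time: 0.15  # s
    drive:
      mode: sine                    # none | sine | composed
      driving_amplitude: 45.0       # Hz
      driving_frequency: 0.25       # Hz
      composed_amplitude: 10.76     # Hz (optional; recomputed if absent)
      composed_f_min: 0.05          # Hz
      composed_f_max: 4.0           # Hz
      composed_f_step: 0.05         # Hz
      composed_phases: [...]        # optional, cycles in [0, 1)
      composed_phase_seed: 1        # used when phases absent
    simulation:
      integration_step: 0.001       # s
      simulation_length: 1010.0     # s
      transient_length: 10.0        # s
      seed: 0
      record_stride: 1

Every section is optional and defaults to the reference values above.
"""

from __future__ import annotations

import yaml

from .drive import DriveSpec, OUConfig, calibrate_composed_amplitude, sample_phases
from .params import ColumnParameters, NetworkConfig
from .simulate import SimulationConfig

__all__ = ["load_config", "parse_config"]


def load_config(path) -> dict:
    """Read a YAML configuration file; see :func:`parse_config`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return parse_config(doc)


def parse_config(doc: dict) -> dict:
    """Turn a nested mapping into the package's configuration objects.

    Returns a dict with keys ``params``, ``network``, ``noise``, ``drive``
    (None when mode is ``none``) and ``simulation``.
    """
    model = doc.get("model") or {}
    params = ColumnParameters(**model)

    net_doc = doc.get("network") or {}
    N = int(net_doc.get("n_columns", 4))
    p_const = float(net_doc.get("constant_input", 75.0 if N > 1 else 90.0))
    if N == 1:
        network = NetworkConfig.single_column(p_const)
    else:
        network = NetworkConfig.homogeneous(N, float(net_doc.get("coupling_strength", 15.0)), p_const)

    noise_doc = doc.get("noise") or {}
    noise = OUConfig(
        D=float(noise_doc.get("noise_intensity", 350.0)),
        tau=float(noise_doc.get("noise_correlation_time", 0.15)),
    )

    drive_doc = doc.get("drive") or {}
    mode = drive_doc.get("mode", "none")
    if mode == "none":
        drive = None
    elif mode == "sine":
        drive = DriveSpec(
            mode="sine",
            amplitude=float(drive_doc.get("driving_amplitude", 45.0)),
            frequency=float(drive_doc.get("driving_frequency", 0.25)),
        )
    elif mode == "composed":
        f_min = float(drive_doc.get("composed_f_min", 0.05))
        f_max = float(drive_doc.get("composed_f_max", 4.0))
        f_step = float(drive_doc.get("composed_f_step", 0.05))
        if "composed_amplitude" in drive_doc:
            amp = float(drive_doc["composed_amplitude"])
        else:
            amp = calibrate_composed_amplitude(
                float(drive_doc.get("driving_amplitude", 45.0)), f_min, f_max, f_step
            )
        if "composed_phases" in drive_doc:
            phases = drive_doc["composed_phases"]
        else:
            n_comp = int(round(f_max / f_step)) - int(round(f_min / f_step)) + 1
            phases = sample_phases(n_comp, int(drive_doc.get("composed_phase_seed", 0)))
        drive = DriveSpec(
            mode="composed", amplitude=amp, f_min=f_min, f_max=f_max, f_step=f_step, phases=phases
        )
    else:
        raise ValueError(f"unknown drive mode {mode!r}")

    sim_doc = doc.get("simulation") or {}
    simulation = SimulationConfig(
        h=float(sim_doc.get("integration_step", 0.001)),
        duration=float(sim_doc.get("simulation_length", 1010.0)),
        transient=float(sim_doc.get("transient_length", 10.0)),
        seed=int(sim_doc.get("seed", 0)),
        record_stride=int(sim_doc.get("record_stride", 1)),
    )
    return {
        "params": params,
        "network": network,
        "noise": noise,
        "drive": drive,
        "simulation": simulation,
    }
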