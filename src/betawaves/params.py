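"""Network parameter sets and named presets.

Units follow the reference parameter table throughout: synaptic weights in
mV*s, currents in mV, rates in Hz, times in ms, kernel ranges in grid units
(1 grid unit = 400 um, the electrode pitch).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

__all__ = ["NetworkParams", "PRESETS", "preset", "PITCH_UM"]

PITCH_UM = 400.0  # electrode pitch; converts grid units to physical distance


@dataclass
class NetworkParams:
    # recurrent synaptic strengths (mV*s)
    w_ee: float = 0.96
    w_ei: float = 2.08
    w_ie: float = 1.0
    w_ii: float = 0.87
    # external-input synaptic strengths; by convention w_e_ext = w_ee and
    # w_i_ext = 2 * w_ie so that decreasing the shared drive moves the
    # operating point across the oscillatory bifurcation line
    w_e_ext: float = 0.96
    w_i_ext: float = 2.0
    # long-range excitatory kernel ranges (grid units); isotropic if equal
    l_x: float = 2.0
    l_y: float = 2.0
    # local-input spread kernel; None -> point-like local inputs
    l_input_x: float | None = None
    l_input_y: float | None = None
    # conduction delay slope (ms per grid unit of Euclidean distance)
    delay_ms_per_unit: float = 1.3
    # synaptic kinetics (ms)
    tau_r_e: float = 0.7
    tau_d_e: float = 3.5
    tau_l_e: float = 0.5
    tau_r_i: float = 0.7
    tau_d_i: float = 3.5
    tau_l_i: float = 0.5
    # population sizes per module
    n_e: float = 16000.0
    n_i: float = 4000.0
    # external input statistics
    tau_ext_ms: float = 25.0
    nu_ext_hz: float = 3.0
    c: float = 0.4  # fraction of shared (global) input power
    # baseline external currents (mV)
    i_e_ext0: float = 9.72
    i_i_ext0: float = 0.08
    # target steady rates (Hz) used for boundary clamping / steady state
    r_e_target: float = 5.0
    r_i_target: float = 10.0
    # grid geometry: dynamic interior, frozen boundary ring depth, central
    # measurement window (all in modules per side)
    grid_size: int = 24
    boundary_depth: int = 2
    measure_size: int = 10
    boundary: str = "fixed"  # "fixed" (frozen ring) or "periodic"
    preset_name: str = field(default="custom", compare=False)

    def __post_init__(self):
        for name in ("tau_r_e", "tau_d_e", "tau_l_e", "tau_r_i", "tau_d_i",
                     "tau_l_i", "tau_ext_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("global-input fraction c must lie in [0, 1]")
        if self.l_x < 0 or self.l_y < 0:
            raise ValueError("kernel ranges must be nonnegative")
        if self.boundary not in ("fixed", "periodic"):
            raise ValueError("boundary must be 'fixed' or 'periodic'")
        if self.measure_size > self.grid_size:
            raise ValueError("measurement window larger than dynamic grid")

    @property
    def total_grid(self) -> int:
        """Total lattice side including the frozen boundary ring."""
        if self.boundary == "periodic":
            return self.grid_size
        return self.grid_size + 2 * self.boundary_depth

    @property
    def input_is_point(self) -> bool:
        return self.l_input_x is None and self.l_input_y is None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "NetworkParams":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        name = data.pop("preset", None)
        base = preset(name).to_dict() if name else {}
        base.update(data)
        return cls.from_dict(base)

    def with_overrides(self, **kw) -> "NetworkParams":
        return replace(self, **kw)


def _mk(name, *, w_ee, w_ei, i_e_ext0, delay, c) -> NetworkParams:
    return NetworkParams(
        w_ee=w_ee, w_ei=w_ei, w_e_ext=w_ee, w_i_ext=2.0,
        i_e_ext0=i_e_ext0, delay_ms_per_unit=delay, c=c, preset_name=name,
    )


# Named presets of the reference parameter table.  SN: steady network;
# SN': steady network refit to the second animal; ON: oscillating network;
# SN_0: steady network without propagation delays.
PRESETS = {
    "SN": _mk("SN", w_ee=0.96, w_ei=2.08, i_e_ext0=9.72, delay=1.3, c=0.4),
    "SN'": _mk("SN'", w_ee=1.12, w_ei=1.80, i_e_ext0=6.12, delay=1.3, c=0.3),
    "ON": _mk("ON", w_ee=0.96, w_ei=2.48, i_e_ext0=13.72, delay=1.3, c=0.4),
    "SN_0": _mk("SN_0", w_ee=1.20, w_ei=1.80, i_e_ext0=5.72, delay=0.0, c=0.3),
}
PRESETS["SNp"] = PRESETS["SN'"]
PRESETS["SN0"] = PRESETS["SN_0"]


def preset(name: str) -> NetworkParams:
    """Return a copy of the named preset (SN, SN', ON, SN_0)."""
    try:
        return replace(PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; have {sorted(set(PRESETS))}")
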