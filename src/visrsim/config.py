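"""Study configuration: imaging, push, tracking and generator parameters.

Defaults follow a conventional linear-array VisR acquisition: 4.21 MHz
push (70 us), 6.15 MHz tracking at 10 kHz PRF sampled at 40 MHz, 512 um
NCC kernel with an 80 um search region, 20 mm focus, 40 dB system SNR.
Values are stored in SI internally; the YAML boundary uses the
engineering units named in the keys.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["StudyConfig", "load_config", "save_config"]

_ORIENTATIONS = ("longitudinal", "transverse")
_MODES = ("displacement", "rf")


@dataclass
class StudyConfig:
    # ARF push / medium
    intensity_w_cm2: float = 5000.0
    alpha_db_cm_mhz: float = 0.5
    c_m_s: float = 1540.0
    push_freq_mhz: float = 4.21
    # imaging / tracking
    track_freq_mhz: float = 6.15
    fs_mhz: float = 40.0
    prf_khz: float = 10.0
    focal_depth_mm: float = 20.0
    push_focal_config: float = 1.5
    track_tx_focal_config: float = 1.5
    track_rx_focal_config: float = 0.75
    frac_bandwidth: float = 0.6
    # push timing
    t_arf_us: float = 70.0
    t_s_ms: float = 0.4
    t_total_ms: float = 4.35
    # NCC
    kernel_um: float = 512.0
    search_um: float = 80.0
    # generator
    snr_db: float = 40.0
    c_E: float = 0.05
    m_mass_kg: float = 1.0e-3
    viscosity_model: str = "constant_zeta"  # or "constant_tau"
    damping_zeta: float = 1.0
    tau_s: float = 0.4e-3
    A_ref_n: float = 0.25
    disp_noise_rel: float = 0.002
    scatterers_per_cell: float = 12.0
    roi_mm: float = 2.0
    roi_spacing_mm: float = 0.2
    # study design
    angle_set_deg: list[float] = field(
        default_factory=lambda: [90.0, 86.0, 78.0, 70.0, 66.0, 58.0, 46.0]
    )
    orientations: list[str] = field(
        default_factory=lambda: ["longitudinal", "transverse"]
    )
    mode: str = "displacement"
    n_realizations: int = 10
    master_seed: int = 42
    material_panel: str | None = None  # None -> packaged 12-material panel
    out_dir: str = "visrsim_out"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            "intensity_w_cm2", "alpha_db_cm_mhz", "c_m_s", "push_freq_mhz",
            "track_freq_mhz", "fs_mhz", "prf_khz", "focal_depth_mm",
            "frac_bandwidth", "t_arf_us", "t_total_ms", "kernel_um",
            "search_um", "c_E", "m_mass_kg", "damping_zeta", "tau_s", "A_ref_n",
            "scatterers_per_cell", "roi_mm", "roi_spacing_mm",
        ]
        for name in positive:
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not v > 0.0:
                raise ValueError(f"config key {name!r} must be positive, got {v!r}")
        if self.t_s_ms < 0.0:
            raise ValueError("config key 't_s_ms' must be non-negative")
        if self.disp_noise_rel < 0.0:
            raise ValueError("config key 'disp_noise_rel' must be non-negative")
        if self.n_realizations < 1:
            raise ValueError("config key 'n_realizations' must be >= 1")
        if not self.angle_set_deg or any(
            not 0.0 < a <= 90.0 for a in self.angle_set_deg
        ):
            raise ValueError("config key 'angle_set_deg' entries must lie in (0, 90]")
        if 90.0 not in self.angle_set_deg:
            raise ValueError("config key 'angle_set_deg' must include the 90 degree reference")
        if self.viscosity_model not in ("constant_zeta", "constant_tau"):
            raise ValueError(
                "config key 'viscosity_model' must be 'constant_zeta' or 'constant_tau'"
            )
        if self.mode not in _MODES:
            raise ValueError(f"config key 'mode' must be one of {_MODES}, got {self.mode!r}")
        bad = [o for o in self.orientations if o not in _ORIENTATIONS]
        if bad or not self.orientations:
            raise ValueError(
                f"config key 'orientations' entries must be in {_ORIENTATIONS}, got {bad!r}"
            )

    # -- derived SI helpers -------------------------------------------------
    @property
    def fs(self) -> float:
        return self.fs_mhz * 1e6

    @property
    def prf(self) -> float:
        return self.prf_khz * 1e3

    @property
    def t_arf(self) -> float:
        return self.t_arf_us * 1e-6

    @property
    def t_s(self) -> float:
        return self.t_s_ms * 1e-3

    @property
    def t_total(self) -> float:
        return self.t_total_ms * 1e-3

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None) -> StudyConfig:
    """Load a YAML config; unknown keys are rejected by name.

    An empty or absent file yields all defaults.
    """
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"config file {path} must contain a mapping")
            data = loaded
    known = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return StudyConfig(**data)


def save_config(cfg: StudyConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
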