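"""Study configuration with YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .selection import SelectionConfig

__all__ = ["RunConfig", "default_voi_volumes"]


def default_voi_volumes(n: int = 26) -> list[float]:
    """Log-spaced VOI volume grid from 0.5 to 1000 ml."""
    return [float(v) for v in np.geomspace(0.5, 1000.0, n)]


@dataclass
class RunConfig:
    """Everything needed to run the full three-phantom study."""

    master_seed: int = 1
    # ground-truth grid
    truth_voxel_mm: float = 2.0
    grid: int = 128
    # imaging model
    noise_scale: float = 120.0
    n_levels: int = 64
    # volume-dependence stage (homogeneous cylinder on three "scanners")
    volume_scanners: list = field(default_factory=lambda: ["A", "C", "E"])
    volume_acq_time_s: float = 120.0
    cylinder_diameter_mm: float = 200.0
    cylinder_length_mm: float = 200.0
    cylinder_activity_kbq_ml: float = 5.0
    voi_volumes_ml: list = field(default_factory=default_voi_volumes)
    # reproducibility stage (triplicate Revolver grid)
    settings: list = field(default_factory=lambda: ["A", "B", "C", "D", "E", "F"])
    acq_times_s: list = field(default_factory=lambda: [60.0, 120.0, 180.0, 240.0])
    n_replicates: int = 3
    background_kbq_ml: float = 5.0
    syringe_activities: list = field(
        default_factory=lambda: [80.0, 40.0, 40.0, 20.0, 20.0, 20.0, 5.0]
    )
    seg_threshold: float = 2.5
    # sensitivity stage (dual-isotope dynamic series)
    c11_activity_kbq_ml: float = 80.0
    f18_activity_kbq_ml: float = 40.0
    c11_syringes: list = field(default_factory=lambda: [0, 1, 2, 3])
    frame_cycle_min: float = 4.0
    n_frames: int = 20
    frame_acq_time_s: float = 120.0
    dynamic_setting: str = "B"
    # selection thresholds
    v_min_ml: float = 30.0
    slope_tol: float = 0.065
    r2_min: float = 0.8
    scatter_tol: float = 0.015
    cv_max: float = 0.10
    cell_pass_fraction: float = 0.75
    s_min: float = 0.20
    # output
    outdir: str | None = None

    def selection_config(self) -> SelectionConfig:
        return SelectionConfig(
            v_min_ml=self.v_min_ml,
            slope_tol=self.slope_tol,
            r2_min=self.r2_min,
            scatter_tol=self.scatter_tol,
            cv_max=self.cv_max,
            cell_pass_fraction=self.cell_pass_fraction,
            s_min=self.s_min,
        )

    def validate(self) -> None:
        if not self.settings:
            raise ValueError("settings grid must not be empty")
        if not self.acq_times_s:
            raise ValueError("acquisition-time grid must not be empty")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if self.n_frames < 1:
            raise ValueError("need at least 1 dynamic frame")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
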