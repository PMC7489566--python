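"""Pipeline configuration: every tunable the measurement stages expose.

Defaults are chosen for posterior-anterior wrist radiographs at roughly
0.1-0.3 mm/pixel. Configs load from YAML (nested keys mirror the dataclass
fields, e.g. ``canny: {sigma: 2.0}``) and serialise back for run manifests.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields


@dataclass
class CannyConfig:
    sigma: float = 2.0          # Gaussian smoothing before gradient, px
    low_frac: float = 0.55      # low hysteresis threshold as fraction of high


@dataclass
class HoughConfig:
    n_peaks: int = 5            # strongest accumulator peaks kept
    theta_res_deg: float = 0.5  # angular resolution of the accumulator
    min_angle_deg: float = 5.0  # minimum angular separation between peaks
    min_distance_px: int = 20   # minimum rho separation between peaks


@dataclass
class CollimatorConfig:
    dilation_px: int = 5        # disc radius for mask dilation


@dataclass
class WidthConfig:
    first_line_offset_mm: float = 5.0   # line 1 below the lunate row
    line_spacing_mm: float = 10.0       # 1 cm between consecutive lines
    smooth_window_rows: int = 11        # median smoothing of boundaries
    max_missing_frac: float = 0.30      # tolerated fraction of edgeless rows


@dataclass
class FingerConfig:
    roi_side_mm: float = 30.0           # square ROI side around the landmark
    peak_prominence_frac: float = 0.05  # of dynamic range, suppresses texture
    background_frac: float = 0.10       # outer columns used for background


@dataclass
class LbpConfig:
    roi_side_mm: float = 15.0
    offset_along_mm: float = 10.0       # styloid -> lunate direction
    offset_proximal_mm: float = 10.0    # image-down direction


@dataclass
class ProfileConfig:
    edge_drop_frac: float = 0.5         # termination threshold x early median
    short_segment_frac: float = 0.5     # leading fraction for the short slope
    step_px: float = 1.0


@dataclass
class PipelineConfig:
    canny: CannyConfig = field(default_factory=CannyConfig)
    hough: HoughConfig = field(default_factory=HoughConfig)
    collimator: CollimatorConfig = field(default_factory=CollimatorConfig)
    width: WidthConfig = field(default_factory=WidthConfig)
    finger: FingerConfig = field(default_factory=FingerConfig)
    lbp: LbpConfig = field(default_factory=LbpConfig)
    profile: ProfileConfig = field(default_factory=ProfileConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = {}
        for f in fields(cls):
            sub = raw.get(f.name, {})
            sub_cls = f.default_factory  # type: ignore[union-attr]
            known = {x.name for x in fields(sub_cls)}
            unknown = set(sub) - known
            if unknown:
                raise ValueError(f"unknown config keys under {f.name}: {sorted(unknown)}")
            kwargs[f.name] = sub_cls(**sub)
        unknown_top = set(raw) - {f.name for f in fields(cls)}
        if unknown_top:
            raise ValueError(f"unknown config sections: {sorted(unknown_top)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
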