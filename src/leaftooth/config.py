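"""Pipeline configuration: every tunable in one flat record.

Defaults follow the working parameter set of the method: delta=4,
C=1.5, T_angle=162, Canny H=0.35 / L=0, Gap_size=3, endpoint on,
sinus-curvature threshold 0.05 (1/px at the normalised working scale),
spacing factor 0.6, leaf major axis normalised to 512 px.  Note the
convexity disk radius and the Canny low threshold are distinct
parameters even though the source notation uses "L" for both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .css import CSSParams
from .tooth_points import ConvexityTestParams


@dataclass
class PipelineConfig:
    css: CSSParams = field(default_factory=CSSParams)
    disk_radius: int | None = None  # None -> max(5, round(1.5 * delta))
    st_tol_factor: float = 0.12     # straight-flank tolerance: factor / chord
    sinus_threshold: float = 0.05   # 1/px; angular iff mean curvature above
    spacing_factor: float = 0.6     # regular iff d_min > factor * d_max
    normalize_size: int | None = 512  # leaf major axis after rescale; None=off
    polarity: str = "auto"          # "auto" | "dark" | "light"
    close_radius: int = 2

    def convexity_params(self) -> ConvexityTestParams:
        if self.disk_radius is not None:
            return ConvexityTestParams(disk_radius=self.disk_radius)
        return ConvexityTestParams.from_delta(self.css.delta)


_CSS_KEYS = ("delta", "C", "t_angle", "canny_h", "canny_l", "gap_size",
             "endpoint")
_TOP_KEYS = ("disk_radius", "st_tol_factor", "sinus_threshold",
             "spacing_factor", "normalize_size", "polarity", "close_radius")


def save_config(config: PipelineConfig, path) -> None:
    """Write the configuration as a flat key = value text file."""
    lines = []
    for k in _CSS_KEYS:
        lines.append(f"{k} = {getattr(config.css, k)}")
    for k in _TOP_KEYS:
        lines.append(f"{k} = {getattr(config, k)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_value(key: str, raw: str):
    raw = raw.strip()
    if raw in ("None", "none", ""):
        return None
    if key == "endpoint":
        return raw in ("True", "true", "1", "on")
    if key == "polarity":
        return raw
    if key in ("disk_radius", "normalize_size", "close_radius"):
        return int(raw)
    return float(raw)


def load_config(path) -> PipelineConfig:
    """Read a flat key = value configuration file."""
    values = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, raw = line.split("=", 1)
            key = key.strip()
            values[key] = _parse_value(key, raw)
    css_kwargs = {k: values[k] for k in _CSS_KEYS if k in values}
    if "gap_size" in css_kwargs and css_kwargs["gap_size"] is not None:
        css_kwargs["gap_size"] = float(css_kwargs["gap_size"])
    top_kwargs = {k: values[k] for k in _TOP_KEYS if k in values}
    return PipelineConfig(css=CSSParams(**css_kwargs), **top_kwargs)
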