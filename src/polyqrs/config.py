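"""Flat key-value pipeline configuration shared by the CLI subcommands."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

from .fiducial import DelineationParams, FeatureWeights
from .polygonal import ApproxParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline in one serialisable place.

    Serialises to ``key = value`` lines; unknown keys are rejected on load
    so that typos fail loudly rather than silently using defaults.
    """

    channel: int = 0
    apply_filter: bool = True
    bp_low_hz: float = 1.0
    bp_high_hz: float = 25.0
    bp_order: int = 2
    support_ms: float = 10.0
    curv_threshold: float = 0.15
    tolerance: float = 0.02
    window_s: float = 0.3
    cos_exponent: float = 1.0
    sin_exponent: float = 2.0
    match_window_ms: float = 150.0
    seed: int = 0

    def to_text(self) -> str:
        return "".join(f"{k} = {v}\n" for k, v in asdict(self).items())

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        types = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, sep, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if not sep or key not in types:
                raise ValueError(f"line {lineno}: unknown or malformed entry {raw!r}")
            t = types[key]
            if t in ("bool", bool):
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif t in ("int", int):
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
        return cls(**kwargs)

    def delineation_params(self, rpeaks=None, diagnostics: bool = False) -> DelineationParams:
        return DelineationParams(
            channel=self.channel,
            apply_filter=self.apply_filter,
            bp_low_hz=self.bp_low_hz,
            bp_high_hz=self.bp_high_hz,
            bp_order=self.bp_order,
            approx=ApproxParams(self.support_ms, self.curv_threshold, self.tolerance),
            weights=FeatureWeights(self.window_s, self.cos_exponent, self.sin_exponent),
            rpeaks=rpeaks,
            diagnostics=diagnostics,
        )
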