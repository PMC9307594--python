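"""Analysis configuration with experiment-derived defaults.

Defaults mirror the standard recording conditions: 33 ms frames
(30.3 frames per second; a 100 ms variant is used for the slow head-
reporter experiment), a 33 s observation window (100 s variant),
photobleaching constant 0.03 1/s, and donor bleed-through 0.13.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field, fields


@dataclass
class AnalysisConfig:
    frame_interval: float = 0.033
    t_observation: float = 33.0
    k_photobleach: float = 0.03
    bleedthrough_beta: float = 0.13
    bin_width: float = 0.02
    hmm_mode: str = "bic"        # "bic" (per-trace state count) or "fixed"
    k_min: int = 2
    k_max: int = 5
    idealize_decode: str = "posterior"   # or "viterbi"
    sync_rule_kind: str = "first_below"
    sync_rule_value: float | str = 0.5
    dwell_fit_floor: int = 20
    stable_post_frames: int = 10
    min_total: float = 50.0
    n_boot: int = 1000
    seed: int = 0

    def __post_init__(self):
        for name in ("frame_interval", "t_observation", "bin_width",
                     "min_total"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("k_photobleach", "bleedthrough_beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.hmm_mode not in ("bic", "fixed"):
            raise ValueError("hmm_mode must be 'bic' or 'fixed'")
        if self.idealize_decode not in ("posterior", "viterbi"):
            raise ValueError("idealize_decode must be 'posterior' or 'viterbi'")
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError("need 1 <= k_min <= k_max")

    @property
    def k_range(self):
        return None if self.hmm_mode == "fixed" else range(self.k_min,
                                                           self.k_max + 1)

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path):
        """Write as a flat key = value text file."""
        with open(path, "w") as fh:
            for key, value in self.to_dict().items():
                fh.write(f"{key} = {value}\n")

    @classmethod
    def load(cls, path):
        raw = {}
        with open(path) as fh:
            for line_no, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{line_no}: expected key = value")
                key, value = (s.strip() for s in line.split("=", 1))
                raw[key] = value
        typed = {}
        defaults = cls()
        for f in fields(cls):
            if f.name not in raw:
                continue
            current = getattr(defaults, f.name)
            v = raw.pop(f.name)
            if isinstance(current, bool):
                typed[f.name] = v.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                typed[f.name] = int(v)
            elif isinstance(current, float):
                try:
                    typed[f.name] = float(v)
                except ValueError:
                    typed[f.name] = v
            else:
                typed[f.name] = v
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cls(**typed)
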