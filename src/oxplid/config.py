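"""Loading of rule, fragmentation-profile and scoring configuration files.

All configuration is YAML; the package ships calibrated defaults under
``oxplid/data`` which are used when no path is given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .oxidation import LevelLimits, OxidationRuleSet, Transform


def _read_yaml(path: str | Path | None, default_name: str) -> dict:
    if path is None:
        ref = resources.files("oxplid.data") / default_name
        return yaml.safe_load(ref.read_text())
    return yaml.safe_load(Path(path).read_text())


def load_rules(path: str | Path | None = None) -> OxidationRuleSet:
    """Load an oxidation rule set (packaged defaults when ``path`` is None)."""
    raw = _read_yaml(path, "default_rules.yaml")
    oap = [
        Transform(
            name=t["name"],
            kind=t["type"],
            target=t.get("target", ""),
            shifted=False,
            delta_o=t["delta"].get("O", 0),
            delta_h=t["delta"].get("H", 0),
            pattern=t.get("pattern", ""),
            replacement=t.get("replacement", ""),
        )
        for t in raw["oap_transforms"]
    ]
    ocp = [
        Transform(
            name=t["name"],
            kind=t["terminal"],
            target="double-bond",
            shifted=bool(t.get("shifted", False)),
            delta_o=t["delta"].get("O", 0),
            delta_h=t["delta"].get("H", 0),
        )
        for t in raw["ocp_transforms"]
    ]
    levels = {
        int(k): LevelLimits(
            oap_types=tuple(v["oap_types"]),
            max_total_mods=int(v["max_total_mods"]),
            max_oxygens=int(v["max_oxygens"]),
            ocp_terminals=tuple(v["ocp_terminals"]),
            shifted_cleavage=bool(v["shifted_cleavage"]),
            ocp_decoration=bool(v["ocp_decoration"]),
            decoration_min_residual=int(v["decoration_min_residual"]),
            prostane_rings=tuple(v["prostane_rings"]),
        )
        for k, v in raw["levels"].items()
    }
    return OxidationRuleSet(
        oap_transforms=oap,
        ocp_transforms=ocp,
        prostane_templates=tuple(t["ring"] for t in raw["prostane_templates"]),
        levels=levels,
        default_level=int(raw.get("default_level", 2)),
        include_lyso=bool(raw.get("include_lyso", False)),
    )


@dataclass
class ScoringConfig:
    """Tunables of the five-score identification system."""

    m: float = 0.6  # exponent on peak intensity in the weight function
    n: float = 3.0  # exponent on m/z in the weight function
    f_amplify: float = 10.4795  # specificity amplification factor
    w_frag: dict = field(default_factory=dict)  # per-signal-class weights
    ms1_ppm: float = 10.0
    ms2_ppm: float = 20.0
    isotope_depth: int = 2
    # per-score acceptance thresholds (package defaults, instrument-tunable)
    min_similarity: float = 20.0
    min_rank: float = 20.0
    min_fingerprint: float = 10.0
    min_specificity: float = 0.0
    min_isotope: float = 60.0
    min_overall: float = 40.0

    def __post_init__(self):
        if self.m <= 0 or self.n <= 0 or self.f_amplify <= 0:
            raise ValueError("m, n and f_amplify must be positive")
        if self.ms1_ppm <= 0 or self.ms2_ppm <= 0:
            raise ValueError("mass tolerances must be positive")
        if self.isotope_depth not in (1, 2):
            raise ValueError("isotope_depth must be 1 or 2")

    def weight_for(self, signal_class: str) -> float:
        return float(self.w_frag.get(signal_class, 1.0))


def load_scoring(path: str | Path | None = None) -> ScoringConfig:
    raw = _read_yaml(path, "default_scoring.yaml")
    return ScoringConfig(**raw)
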