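"""Run configuration: classifier gates, solver settings, scenario files.

Configuration is plain YAML (key: value with sections).  Units are stated
where they matter: retention quantities in minutes, kinetic rates and times
in days.  A scenario file defines the substrate, the enzyme community
(name, class_label, weights w1..w6, k, mix) with sorption/Pi-uptake/lag
terms, the sampling days and the noise model.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields

import yaml

from .kinetics import CLASS_LABELS, CommunityModel, EnzymeModel
from .profiling import ClassifierParams
from .synthetic import Scenario, make_substrate, preset_enzyme

__all__ = ["RunConfig", "load_config", "scenario_from_config", "scenario_to_config"]

_FRACTION_FIELDS = (
    "activity_threshold",
    "dominance_share",
    "minpp_5oh_min",
    "minpp_13oh_max",
    "theta_report",
    "qc_impurity_threshold",
)


@dataclass
class RunConfig:
    """Defaults for every command; all overridable from a YAML file."""

    # classifier gates (fractions)
    activity_threshold: float = 0.05
    dominance_share: float = 0.5
    dominance_ratio: float = 2.0
    minpp_5oh_min: float = 0.05
    minpp_13oh_max: float = 0.05
    theta_report: float = 0.01
    qc_impurity_threshold: float = 0.10
    # chromatography (minutes)
    retention_tolerance: float = 0.4
    # kinetics solver (days)
    solver_method: str = "expm"
    solver_max_step: float = 0.01
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        for name in _FRACTION_FIELDS:
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a non-negative integer")
        if self.solver_method not in ("expm", "rk4"):
            raise ValueError("solver_method must be 'expm' or 'rk4'")

    def classifier_params(self) -> ClassifierParams:
        return ClassifierParams(
            activity_threshold=self.activity_threshold,
            dominance_share=self.dominance_share,
            dominance_ratio=self.dominance_ratio,
            minpp_5oh_min=self.minpp_5oh_min,
            minpp_13oh_max=self.minpp_13oh_max,
            theta_report=self.theta_report,
            qc_impurity_threshold=self.qc_impurity_threshold,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def load_config(path: str | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**data)


def scenario_from_config(path: str) -> Scenario:
    """Build a scenario from a YAML description.

    Enzymes are either preset names (``preset: ac12_minpp``) or explicit
    definitions with ``weights`` (w1..w6), ``k`` (1/day) and an optional
    ``class_label``; each carries a ``mix`` weight.
    """
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    name = data.get("name", "custom")
    substrate = make_substrate(data.get("substrate"))
    enzymes = []
    for spec in data.get("enzymes", []):
        mix = float(spec.get("mix", 1.0))
        if "preset" in spec:
            enz = preset_enzyme(spec["preset"])
        else:
            label = spec.get("class_label", "GENERIC")
            if label not in CLASS_LABELS:
                raise ValueError(f"{path}: unknown class_label {label!r}")
            enz = EnzymeModel(
                name=spec.get("name", "custom"),
                class_label=label,
                weights=tuple(float(spec[f"w{i}"]) for i in range(1, 7)),
                k=float(spec["k"]),
            )
        enzymes.append((enz, mix))
    community = CommunityModel(
        enzymes=enzymes,
        sorption_rate=float(data.get("sorption", 0.0)),
        pi_uptake_rate=float(data.get("pi_uptake", 0.0)),
        t_lag=float(data.get("t_lag", 0.0)),
        tau=float(data.get("tau", 0.25)),
    )
    species = data.get("substrate_species")
    return Scenario(
        name=name,
        substrate=substrate,
        substrate_species={k: float(v) for k, v in species.items()} if species else None,
        community=community,
        sampling_days=[float(d) for d in data.get("sampling_days", [0, 2])],
        baseline=float(data.get("baseline", 0.02)),
        snr=float(data.get("snr", 50.0)),
        seed=int(data.get("seed", 0)),
        description=data.get("description", ""),
    )


def scenario_to_config(s: Scenario) -> str:
    """YAML dump of a scenario (presets expanded to explicit enzymes)."""
    data = {
        "name": s.name,
        "description": s.description,
        "substrate": {c: float(a) for c, a in s.substrate.items()},
        **(
            {"substrate_species": {k: float(v) for k, v in s.substrate_species.items()}}
            if s.substrate_species
            else {}
        ),
        "enzymes": [
            {
                "name": e.name,
                "class_label": e.class_label,
                **{f"w{i + 1}": float(w) for i, w in enumerate(e.weights)},
                "k": float(e.k),
                "mix": float(m),
            }
            for e, m in s.community.enzymes
        ],
        "sorption": float(s.community.sorption_rate),
        "pi_uptake": float(s.community.pi_uptake_rate),
        "t_lag": float(s.community.t_lag),
        "tau": float(s.community.tau),
        "sampling_days": [float(d) for d in s.sampling_days],
        "baseline": float(s.baseline),
        "snr": float(s.snr),
        "seed": int(s.seed),
    }
    return yaml.safe_dump(data, sort_keys=False)
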