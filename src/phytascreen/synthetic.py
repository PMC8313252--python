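"""Packaged generators and calibrated scenario presets.

Everything the screen measures can be regenerated here without any external
data: a "clean" phytate substrate carrying ~5% InsP5 [1/3-OH] impurity, a
deliberately dirty "commercial" substrate, pure-isolate degradation time
courses, and multi-enzyme soil-community time courses with optional phytate
sorption and Pi scavenging.  Generators are deterministic given (name,
seed).

Enzyme presets encode the canonical positional specificities:

* ``bsubtilis_bpp``     beta-propeller phytase, initial 1D-3 attack
* ``buttiauxella_appa`` AppA-family histidine (acid) phosphatase, 1D-6
* ``ac12_minpp``        promiscuous MINPP-like histidine phosphatase
                        (4/6 >> 5 >> 1/2/3)
* ``btminpp``           a broader MINPP, intermediates at many positions
* ``five_phytase``      EC 3.1.3.72-type, 5-position
* ``pputida_null``      no phytase activity (k = 0)

Rate constants are in 1/day and were chosen so the packaged two-day isolate
scenarios land in the qualitative regimes the screen distinguishes (partial
degradation for the beta-propeller strain, near-complete initial attack
with persistent InsP4/InsP5 intermediates for the histidine phosphatases);
the weight ratios, not the absolute rates, carry the positional signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chromatogram import Chromatogram, default_retention_table, synthesize
from .kinetics import CommunityModel, EnzymeModel, TimeCourse, simulate_timecourse
from .kinetics import class_profile as kinetic_class_profile
from .profiles import PI_POOL, ClassProfile

__all__ = [
    "Scenario",
    "make_substrate",
    "preset_enzyme",
    "preset_scenario",
    "generate_experiment",
    "ENZYME_PRESETS",
    "SCENARIO_PRESETS",
]


def make_substrate(purity_profile: dict[str, float] | str | None = None) -> ClassProfile:
    """Initial substrate composition as a normalized class profile.

    Default is the laboratory "clean" phytate preparation: 95% InsP6 with a 5%
    InsP5 [1/3-OH] contaminant.  ``"commercial"`` returns a deliberately
    impure preset (lower inositol phosphates plus free Pi) that fails QC.
    """
    if purity_profile is None:
        fractions = {"InsP6": 0.95, "InsP5 [1/3-OH]": 0.05}
    elif purity_profile == "commercial":
        fractions = {
            "InsP6": 0.80,
            "InsP5 [1/3-OH]": 0.06,
            "InsP5 [4/6-OH]": 0.02,
            "d/l-Ins(1,2,5,6)P4": 0.02,
            "InsP3": 0.02,
            PI_POOL: 0.08,
        }
    elif purity_profile == "pure":
        fractions = {"InsP6": 1.0}
    elif isinstance(purity_profile, str):
        raise KeyError(f"unknown substrate preset {purity_profile!r}")
    else:
        fractions = dict(purity_profile)
    if any(v < 0 for v in fractions.values()):
        raise ValueError("substrate fractions must be non-negative")
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"substrate fractions must sum to 1, got {total}")
    return ClassProfile(amounts=fractions, normalized=True)


#: (class_label, weights w1..w6, k per day)
ENZYME_PRESETS: dict[str, tuple[str, tuple[float, ...], float]] = {
    "bsubtilis_bpp": ("BPP_3PHYTASE", (0.01, 0.01, 1.0, 0.01, 0.01, 0.01), 0.2),
    "buttiauxella_appa": ("HAP_6PHYTASE", (0.20, 0.001, 0.001, 0.001, 0.05, 10.0), 0.2),
    "ac12_minpp": ("MINPP", (0.02, 0.05, 0.02, 0.8, 0.5, 1.6), 0.3),
    "btminpp": ("MINPP", (0.3, 0.15, 0.3, 1.0, 0.6, 1.3), 0.3),
    "five_phytase": ("FIVE_PHYTASE", (0.01, 0.01, 0.01, 0.01, 1.0, 0.01), 1.0),
    "pputida_null": ("GENERIC", (1.0, 1.0, 1.0, 1.0, 1.0, 1.0), 0.0),
}


def preset_enzyme(name: str) -> EnzymeModel:
    """A calibrated position-preference enzyme model by preset name."""
    try:
        label, weights, k = ENZYME_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown enzyme preset {name!r}; available: {sorted(ENZYME_PRESETS)}"
        ) from None
    return EnzymeModel(name=name, class_label=label, weights=weights, k=k)


@dataclass
class Scenario:
    """A complete simulated experiment: substrate, community, sampling plan."""

    name: str
    substrate: ClassProfile
    community: CommunityModel
    sampling_days: list[float]
    substrate_species: dict[str, float] | None = None
    baseline: float = 0.02
    snr: float = 50.0  # peak signal-to-noise of the tallest day-0 peak
    seed: int = 0
    description: str = ""

    def __post_init__(self) -> None:
        if 0 not in self.sampling_days:
            raise ValueError("sampling days must include day 0")
        self.substrate.check_normalized(
            include_pi=self.substrate[PI_POOL] == 0, tol=1e-6
        )


def _community(names_mixes, **kw) -> CommunityModel:
    return CommunityModel(
        enzymes=[(preset_enzyme(n), m) for n, m in names_mixes], **kw
    )


#: Species-resolved composition of the clean substrate.  The InsP5 [1/3-OH]
#: contaminant ships as the d-1-OH enantiomer: the pair is indistinguishable
#: on the column, and this member is the one consistent with the two-product
#: InsP4 pattern the AppA-type isolate shows when it consumes the impurity.
CLEAN_SUBSTRATE_SPECIES = {
    "Ins(1,2,3,4,5,6)P6": 0.95,
    "Ins(2,3,4,5,6)P5": 0.05,
}


def _scenarios() -> dict[str, Scenario]:
    clean = make_substrate()
    species = dict(CLEAN_SUBSTRATE_SPECIES)
    return {
        # PSM-plate control strains, sampled day 0 vs day 2
        "pputida_null": Scenario(
            name="pputida_null",
            substrate=clean,
            substrate_species=species,
            community=_community([("pputida_null", 1.0)]),
            sampling_days=[0, 2],
            seed=101,
            description="strain with no phytase activity: profiles unchanged",
        ),
        "bsubtilis_eskape": Scenario(
            name="bsubtilis_eskape",
            substrate=clean,
            substrate_species=species,
            community=_community([("bsubtilis_bpp", 1.0)]),
            sampling_days=[0, 2],
            seed=102,
            description="beta-propeller 3-phytase: partial InsP6 loss, 1/3-OH and Pi up",
        ),
        "ecoli_btminpp": Scenario(
            name="ecoli_btminpp",
            substrate=clean,
            substrate_species=species,
            community=_community([("btminpp", 1.0)]),
            sampling_days=[0, 2],
            seed=103,
            description="plasmid-borne MINPP: many InsP5/InsP4/InsP3 intermediates",
        ),
        # isolates
        "ch1064": Scenario(
            name="ch1064",
            substrate=clean,
            substrate_species=species,
            community=_community([("buttiauxella_appa", 1.0)]),
            sampling_days=[0, 2],
            seed=104,
            description="AppA-family 6-phytase isolate: 4/6-OH then two InsP4 products",
        ),
        "ac12": Scenario(
            name="ac12",
            substrate=clean,
            substrate_species=species,
            community=_community([("ac12_minpp", 1.0)]),
            sampling_days=[0, 2],
            seed=105,
            description="MINPP-like isolate: dominant 4/6-OH, smaller 5-OH, little 1/3",
        ),
        # soil communities
        "agricultural_soil": Scenario(
            name="agricultural_soil",
            substrate=clean,
            substrate_species=species,
            community=_community(
                [("bsubtilis_bpp", 3.0), ("buttiauxella_appa", 0.25), ("ac12_minpp", 1.5)],
                t_lag=3.2,
                tau=0.25,
            ),
            sampling_days=list(range(9)),
            seed=106,
            description=(
                "mixed soil community with a ~3-day lag: onset at day 3, "
                "<5% InsP6 left by day 5, intermediates at every level"
            ),
        ),
        "broadbalk": Scenario(
            name="broadbalk",
            substrate=clean,
            substrate_species=species,
            community=CommunityModel(
                enzymes=[], sorption_rate=1.5, pi_uptake_rate=2.0
            ),
            sampling_days=list(range(9)),
            seed=107,
            description=(
                "high-clay soil, unsupplemented: phytate sorbs to particles, "
                "neither phytate nor lower inositol phosphates recovered"
            ),
        ),
        "broadbalk_supplemented": Scenario(
            name="broadbalk_supplemented",
            substrate=clean,
            substrate_species=species,
            community=_community(
                [("bsubtilis_bpp", 3.0)],
                sorption_rate=0.4,
                pi_uptake_rate=2.0,
                t_lag=3.0,
                tau=0.25,
            ),
            sampling_days=list(range(9)),
            seed=108,
            description=(
                "same soil supplemented with extra phytate: 1/3-OH appears over "
                "8 days while the microflora scavenge released Pi"
            ),
        ),
    }


SCENARIO_PRESETS = tuple(sorted(_scenarios()))


def preset_scenario(name: str) -> Scenario:
    """A fully calibrated scenario preset by name."""
    table = _scenarios()
    try:
        return table[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(table)}"
        ) from None


def generate_experiment(
    s: Scenario,
    rt=None,
    noise_free: bool = False,
) -> tuple[list[tuple[float, Chromatogram]], TimeCourse]:
    """Simulate a scenario and render one chromatogram per sampling day.

    Returns the (day, trace) series plus the ground-truth time course for
    parameter-recovery tests.  Noise is seeded per day from the scenario
    seed, so a scenario regenerates bit-identically.
    """
    rt = rt or default_retention_table()
    # dense internal grid so off-sample days interpolate accurately
    t_end = max(s.sampling_days)
    grid = np.unique(np.concatenate([np.linspace(0, t_end, 161) if t_end > 0 else [0.0], np.asarray(s.sampling_days, float)]))
    x0 = s.substrate_species if s.substrate_species is not None else s.substrate
    tc = simulate_timecourse(s.community, x0, grid)

    # noise floor set by the tallest day-0 peak at the requested S/N
    day0 = kinetic_class_profile(tc, 0.0)
    peak_height = max(
        (a / (rt.sigma(c) * np.sqrt(2 * np.pi)))
        for c, a in day0.items()
        if a > 0 and c in rt.entries
    )
    noise_sd = 0.0 if noise_free else peak_height / s.snr

    series: list[tuple[float, Chromatogram]] = []
    seeds = np.random.SeedSequence(s.seed).spawn(len(s.sampling_days))
    for day, ss in zip(s.sampling_days, seeds):
        prof = kinetic_class_profile(tc, float(day))
        chrom = synthesize(
            prof,
            rt,
            baseline=s.baseline,
            noise_sd=noise_sd,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            metadata={"sample": s.name, "day": float(day), "scenario": s.name},
        )
        series.append((float(day), chrom))
    return series, tc
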