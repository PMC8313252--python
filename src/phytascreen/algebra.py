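"""Combinatorics and stereochemistry of myo-inositol phosphate species.

A phosphorylation state of the myo-inositol ring is a subset of the ring
carbons {1..6} bearing phosphate; InsP6 (phytate) is the full set, free
inositol the empty set.  Simple anion-exchange HPLC cannot distinguish a
species from its mirror image, so the chromatographically meaningful unit
is the orbit of a species under the ring mirror symmetry

    sigma: 1 <-> 3, 4 <-> 6, 2 and 5 fixed.

Orbits of size one are meso species (no enantiomer); orbits of size two are
enantiomeric pairs that co-elute.  Counting orbits with Burnside's lemma
gives (2^6 + 2^4)/2 = 40 distinguishable classes, distributed
1/4/9/12/9/4/1 over phosphorylation levels 6..0.

D/L enantiomers are deliberately not modelled: any input naming a specific
enantiomer maps to its orbit.  Only the myo stereoisomer is covered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "POSITIONS",
    "MIRROR",
    "Species",
    "ChromClass",
    "as_species",
    "mirror_image",
    "classify_species",
    "enumerate_classes",
    "name_species",
    "display_name",
    "all_species",
    "degradation_graph",
    "class_listing",
    "species_for_class",
]

POSITIONS: FrozenSet[int] = frozenset({1, 2, 3, 4, 5, 6})

#: The ring mirror map sigma.  This convention is the unique one reproducing
#: the observed meso species (2-OH, 5-OH InsP5) and enantiomeric pairs
#: (1/3-OH, 4/6-OH InsP5).
MIRROR = {1: 3, 2: 2, 3: 1, 4: 6, 5: 5, 6: 4}

Species = FrozenSet[int]

#: Levels whose orbits are collapsed to a single chromatographic class when
#: lumping is on (the gradient resolves only one InsP3 peak, and lower
#: species even less).
LUMPED_LEVELS = (1, 2, 3)


class InvalidSpeciesError(ValueError):
    """Raised for phosphate positions outside ring carbons 1..6."""


def as_species(positions: Iterable[int]) -> Species:
    """Validate and freeze a collection of ring positions into a species."""
    s = frozenset(int(p) for p in positions)
    if not s <= POSITIONS:
        bad = sorted(s - POSITIONS)
        raise InvalidSpeciesError(f"positions outside ring carbons 1..6: {bad}")
    return s


def mirror_image(s: Iterable[int]) -> Species:
    """Apply the ring mirror symmetry sigma to every position of *s*."""
    return frozenset(MIRROR[p] for p in as_species(s))


def _locants(s: Species) -> tuple[int, ...]:
    return tuple(sorted(s))


def _orbit(s: Species) -> tuple[Species, ...]:
    """The sigma-orbit of *s*, members ordered by locant sequence."""
    m = mirror_image(s)
    if m == s:
        return (s,)
    return tuple(sorted((s, m), key=_locants))


def _insp5_missing_label(orbit: Sequence[Species]) -> str:
    missing = sorted({next(iter(POSITIONS - m)) for m in orbit})
    return "/".join(str(p) for p in missing)


def name_species(s: Iterable[int]) -> str:
    """Canonical name of the chromatographic class containing species *s*.

    InsP5 classes use the field's missing-position bracket notation
    ("InsP5 [4/6-OH]"); other classes are named Ins(p1,...,pn)Pn from the
    orbit member with the lexicographically smallest locant sequence, with
    a "d/l-" prefix marking enantiomeric pairs.
    """
    sp = as_species(s)
    return _orbit_name(_orbit(sp))


def _orbit_name(orbit: Sequence[Species]) -> str:
    rep = orbit[0]
    n = len(rep)
    if n == 6:
        return "InsP6"
    if n == 0:
        return "Ins"
    if n == 5:
        return f"InsP5 [{_insp5_missing_label(orbit)}-OH]"
    prefix = "d/l-" if len(orbit) == 2 else ""
    locs = ",".join(str(p) for p in _locants(rep))
    return f"{prefix}Ins({locs})P{n}"


@dataclass(frozen=True)
class ChromClass:
    """A chromatographically distinguishable class of species.

    Either a single sigma-orbit (one meso species or an enantiomeric pair)
    or, for lumped low levels, all species of one phosphorylation level.
    """

    members: tuple[Species, ...]
    canonical_name: str
    level: int
    is_meso: bool
    lumped: bool = False

    def __contains__(self, s: Iterable[int]) -> bool:
        return as_species(s) in self.members


def _lumped_class(level: int) -> ChromClass:
    members = tuple(
        sorted((s for s in all_species() if len(s) == level), key=_locants)
    )
    return ChromClass(
        members=members,
        canonical_name=f"InsP{level}",
        level=level,
        is_meso=False,
        lumped=True,
    )


def classify_species(s: Iterable[int], lumping: bool = False) -> ChromClass:
    """Return the chromatographic class (sigma-orbit) containing *s*.

    With ``lumping=True`` species at levels 1..3 collapse into one class
    per level, mirroring what the gradient actually resolves.
    """
    sp = as_species(s)
    level = len(sp)
    if lumping and level in LUMPED_LEVELS:
        return _lumped_class(level)
    orbit = _orbit(sp)
    return ChromClass(
        members=orbit,
        canonical_name=_orbit_name(orbit),
        level=level,
        is_meso=len(orbit) == 1,
        lumped=False,
    )


def all_species() -> list[Species]:
    """All 64 phosphorylation states, by descending level then locants."""
    out: list[Species] = []
    for mask in range(64):
        out.append(frozenset(p for p in range(1, 7) if mask & (1 << (p - 1))))
    out.sort(key=lambda s: (-len(s), _locants(s)))
    return out


def enumerate_classes(level: int | None = None, lumping: bool = False) -> list[ChromClass]:
    """All chromatographic classes, in a stable canonical order.

    Order: descending level, then lexicographic locant sequence of the
    canonical orbit member.  ``level=None`` enumerates every level 6..0.
    """
    if level is not None and not (0 <= level <= 6):
        raise ValueError(f"level must be in 0..6, got {level}")
    levels = range(6, -1, -1) if level is None else (level,)
    out: list[ChromClass] = []
    for lv in levels:
        if lumping and lv in LUMPED_LEVELS:
            out.append(_lumped_class(lv))
            continue
        seen: set[tuple[Species, ...]] = set()
        for s in all_species():
            if len(s) != lv:
                continue
            orbit = _orbit(s)
            if orbit in seen:
                continue
            seen.add(orbit)
            out.append(classify_species(s, lumping=False))
    return out


def display_name(c: ChromClass) -> str:
    """Human-facing name listing both locant sets of an enantiomeric pair."""
    if c.lumped or c.is_meso or c.level in (0, 6):
        return c.canonical_name
    alias = "/".join("".join(str(p) for p in _locants(m)) for m in c.members)
    if c.level == 5:
        return c.canonical_name
    return f"{c.canonical_name} ({alias})"


def species_for_class(name: str, lumping: bool = True) -> tuple[Species, ...]:
    """Members of the class with the given canonical name."""
    for c in enumerate_classes(lumping=lumping):
        if c.canonical_name == name:
            return c.members
    raise KeyError(f"unknown chromatographic class: {name!r}")


def degradation_graph() -> nx.DiGraph:
    """The full dephosphorylation DAG over all 64 species.

    Edge (S, S - {p}) for every phosphate p of S, labelled by the removed
    position; 64 nodes, 192 edges, every maximal path runs InsP6 -> Ins in
    six steps (720 distinct routes).
    """
    g = nx.DiGraph()
    for s in all_species():
        g.add_node(s, level=len(s))
    for s in all_species():
        for p in sorted(s):
            g.add_edge(s, s - {p}, removed=p)
    return g


def class_listing(lumping: bool = False) -> pd.DataFrame:
    """Tabular export of the class enumeration.

    Columns: level, canonical_name, members (slash-joined locant strings),
    is_meso, lumped.
    """
    rows = []
    for c in enumerate_classes(lumping=lumping):
        members = "/".join(
            "".join(str(p) for p in _locants(m)) if m else "-" for m in c.members
        )
        rows.append(
            {
                "level": c.level,
                "canonical_name": c.canonical_name,
                "members": members,
                "is_meso": c.is_meso,
                "lumped": c.lumped,
            }
        )
    return pd.DataFrame(rows, columns=["level", "canonical_name", "members", "is_meso", "lumped"])
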