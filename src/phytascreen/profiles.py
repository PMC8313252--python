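"""Class-abundance profiles: the common currency between kinetics,
chromatography and classification.

A :class:`ClassProfile` maps canonical chromatographic class names (plus the
pooled ``Pi/InsP1`` class — inorganic phosphate co-elutes with InsP1 at the
solvent front on this gradient) to amounts, either absolute moles or mole
fractions.  Free inositol carries no phosphate and is invisible to the
detector; it is excluded from chromatographic profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import pandas as pd

__all__ = ["PI_POOL", "FREE_INOSITOL", "ClassProfile", "read_profile", "write_profile"]

#: Pooled solvent-front class: inorganic phosphate + all InsP1 species.
PI_POOL = "Pi/InsP1"

#: Name of the undetectable level-0 species.
FREE_INOSITOL = "Ins"


@dataclass
class ClassProfile:
    """Amounts per chromatographic class.

    ``normalized`` marks a mole-fraction profile (sums to 1 over the chosen
    basis).  ``unassigned`` carries material that could not be attributed to
    any class during quantification — it is reported, never dropped.
    """

    amounts: dict[str, float]
    normalized: bool = False
    unassigned: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, a in self.amounts.items():
            if a < 0:
                raise ValueError(f"negative amount for class {name!r}: {a}")

    def __getitem__(self, name: str) -> float:
        return self.amounts.get(name, 0.0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.amounts)

    def items(self):
        return self.amounts.items()

    def total(self, include_pi: bool = False) -> float:
        """Total inositol phosphate; the Pi pool only on request."""
        return sum(
            a for c, a in self.amounts.items() if include_pi or c != PI_POOL
        )

    def normalize(self, include_pi: bool = False) -> "ClassProfile":
        """Mole-fraction profile over total inositol phosphate.

        With ``include_pi=False`` (default) the Pi pool is excluded from the
        basis but retained in the output as a fraction of that same basis,
        so percentage statements read "x% of total inositol phosphate".
        """
        tot = self.total(include_pi=include_pi)
        if tot <= 0:
            raise ValueError("cannot normalize an empty profile")
        amounts = {c: a / tot for c, a in self.amounts.items()}
        if not include_pi:
            # keep Pi on the same basis, outside the unit sum
            pass
        return ClassProfile(amounts=amounts, normalized=True, unassigned=list(self.unassigned))

    def check_normalized(self, include_pi: bool = False, tol: float = 1e-9) -> None:
        s = self.total(include_pi=include_pi)
        if not math.isclose(s, 1.0, abs_tol=tol):
            raise ValueError(f"profile is not normalized (sum {s!r})")

    def scaled(self, factor: float) -> "ClassProfile":
        return ClassProfile(
            amounts={c: a * factor for c, a in self.amounts.items()},
            normalized=False,
            unassigned=list(self.unassigned),
        )

    def without_pi(self) -> "ClassProfile":
        return ClassProfile(
            amounts={c: a for c, a in self.amounts.items() if c != PI_POOL},
            normalized=self.normalized,
            unassigned=list(self.unassigned),
        )

    def to_frame(self) -> pd.DataFrame:
        col = "mole_fraction" if self.normalized else "amount"
        return pd.DataFrame(
            {"class": list(self.amounts), col: list(self.amounts.values())}
        )


def write_profile(profile: ClassProfile, path) -> None:
    """TSV export: columns ``class`` and ``mole_fraction``/``amount``."""
    profile.to_frame().to_csv(path, sep="\t", index=False)


def read_profile(path) -> ClassProfile:
    df = pd.read_csv(path, sep="\t")
    if "class" not in df.columns:
        raise ValueError(f"{path}: missing 'class' column")
    value_col = next(
        (c for c in ("mole_fraction", "amount") if c in df.columns), None
    )
    if value_col is None:
        raise ValueError(f"{path}: missing 'mole_fraction' or 'amount' column")
    amounts: Mapping[str, float] = dict(zip(df["class"], df[value_col].astype(float)))
    return ClassProfile(amounts=dict(amounts), normalized=value_col == "mole_fraction")
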