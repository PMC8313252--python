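"""The screen's interpretive logic.

Substrate purity QC, cleared/non-cleared differential profiling,
degradation extent, and inference of the phytase class from the InsP5
isomer pattern.  The stereochemical basis: the gradient resolves the two
meso InsP5 species (2-OH, 5-OH) from the two enantiomeric pairs (1/3-OH,
4/6-OH), so the initial position of attack — the EC-level ontology of
phytases — is readable straight off the isomer shares:

* dominant 1/3-OH  -> 3-phytase (EC 3.1.3.8, beta-propeller type)
* dominant 4/6-OH  -> 4-/6-phytase (EC 3.1.3.26 / acid phosphatase
  EC 3.1.3.2, AppA-like histidine phosphatases)
* dominant 5-OH    -> 5-phytase (EC 3.1.3.72)
* dominant 4/6-OH with an appreciable 5-OH peak but little 1/3-OH ->
  MINPP-like promiscuous histidine phosphatase
* many isomers at several levels -> a mixed community (or a single MINPP,
  which the evidence block reports as a compatible reading)

All numeric gates operationalize qualitative statements ("dominant",
"smaller", "little to no") and are configuration-exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chromatogram import (
    Chromatogram,
    RetentionTable,
    detect_peaks,
    integrate_and_assign,
    quantify,
)
from .profiles import PI_POOL, ClassProfile

__all__ = [
    "LABELS",
    "ClassifierParams",
    "QCReport",
    "ClassificationResult",
    "ScreenReport",
    "substrate_qc",
    "diff_profiles",
    "degradation_extent",
    "insp5_shares",
    "classify_activity",
    "analyze_screen",
]

LABELS = (
    "NO_ACTIVITY",
    "PHYTASE_3",       # EC 3.1.3.8-type, initial 1D-3 attack
    "PHYTASE_4_6",     # EC 3.1.3.26 / EC 3.1.3.2-type, 1D-4/6 attack
    "PHYTASE_5",       # EC 3.1.3.72-type
    "MINPP_LIKE",      # promiscuous histidine phosphatase
    "MIXED_COMMUNITY",
    "UNCLASSIFIED_2POS",
)

INSP5_CLASSES = ("InsP5 [1/3-OH]", "InsP5 [2-OH]", "InsP5 [4/6-OH]", "InsP5 [5-OH]")


@dataclass(frozen=True)
class ClassifierParams:
    """Numeric gates of the rule cascade (all fractions in (0,1))."""

    activity_threshold: float = 0.05     # min InsP6 loss to call activity
    dominance_share: float = 0.5         # share of total InsP5 for dominance
    dominance_ratio: float = 2.0         # vs runner-up
    minpp_5oh_min: float = 0.05          # 5-OH share marking promiscuity
    minpp_13oh_max: float = 0.05         # 1/3-OH share still "little to no"
    theta_report: float = 0.01           # mole fraction to call a peak real
    qc_impurity_threshold: float = 0.10


@dataclass
class QCReport:
    impurity: float
    passed: bool
    impurity_classes: dict[str, float]
    threshold: float


@dataclass
class ClassificationResult:
    label: str
    evidence: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


@dataclass
class ScreenReport:
    qc: QCReport
    remaining_insp6: float
    diff: dict[str, float]
    flagged_classes: list[str]
    classification: ClassificationResult
    profile_t0: ClassProfile
    profile_tn: ClassProfile

    def to_text(self) -> str:
        lines = [
            "[qc]",
            f"impurity: {self.qc.impurity:.4f}",
            f"passed: {self.qc.passed}",
            "[degradation]",
            f"remaining_insp6: {self.remaining_insp6:.4f}",
            "[classification]",
            f"label: {self.classification.label}",
        ]
        for k, v in self.classification.evidence.items():
            lines.append(f"evidence.{k}: {v}")
        for n in self.classification.notes:
            lines.append(f"note: {n}")
        lines.append("[new_or_increased_classes]")
        for cname in self.flagged_classes:
            lines.append(f"flagged: {cname}")
        return "\n".join(lines)

    def evidence_rows(self) -> list[dict]:
        rows = []
        for cname in sorted(set(self.profile_t0) | set(self.profile_tn)):
            rows.append(
                {
                    "class": cname,
                    "fraction_t0": self.profile_t0[cname],
                    "fraction_tn": self.profile_tn[cname],
                    "delta": self.diff.get(cname, 0.0),
                    "flagged": cname in self.flagged_classes,
                }
            )
        return rows


def substrate_qc(
    p: ClassProfile, impurity_threshold: float = 0.10
) -> QCReport:
    """Purity check of the phytate substrate.

    Impurity is one minus the InsP6 mole fraction; every non-InsP6 class is
    itemized.  The profile must be normalized (mole fractions).
    """
    p.check_normalized(include_pi=True, tol=1e-6)
    impurity = 1.0 - p["InsP6"]
    others = {c: a for c, a in p.items() if c != "InsP6" and a > 0}
    return QCReport(
        impurity=impurity,
        passed=impurity <= impurity_threshold,
        impurity_classes=others,
        threshold=impurity_threshold,
    )


def diff_profiles(
    test: ClassProfile, reference: ClassProfile, theta_report: float = 0.01
) -> tuple[dict[str, float], list[str]]:
    """Per-class change test minus reference (both mole fractions).

    Normalization absorbs extraction-efficiency differences between e.g.
    cleared and non-cleared agar cores.  Returns the delta map and the
    classes newly appearing above the reporting threshold.
    """
    if not (test.normalized and reference.normalized):
        raise ValueError("diff_profiles requires normalized profiles")
    test_u = {c for c, a in test.items() if a > 0}
    ref_u = {c for c, a in reference.items() if a > 0}
    universe = set(test) | set(reference)
    missing = sorted((test_u | ref_u) - universe)
    if missing:  # defensive; universes are unions so this cannot trigger silently
        raise ValueError(f"class universes differ: {missing}")
    delta = {c: test[c] - reference[c] for c in sorted(universe)}
    flagged = [
        c
        for c in sorted(universe)
        if test[c] >= theta_report and reference[c] < theta_report
    ]
    return delta, flagged


def degradation_extent(t_n: ClassProfile, t_0: ClassProfile) -> float:
    """Fraction of the starting InsP6 remaining at t_n, clipped to [0, 1]."""
    start = t_0["InsP6"]
    if start <= 0:
        raise ValueError("no InsP6 in the reference profile")
    return min(max(t_n["InsP6"] / start, 0.0), 1.0)


def insp5_shares(p: ClassProfile) -> dict[str, float]:
    """Each InsP5 class as a share of total InsP5 (zeros if none present)."""
    tot = sum(p[c] for c in INSP5_CLASSES)
    if tot <= 0:
        return {c: 0.0 for c in INSP5_CLASSES}
    return {c: p[c] / tot for c in INSP5_CLASSES}


def _count_above(p: ClassProfile, level: int, theta: float) -> int:
    total = p.total(include_pi=False)
    if total <= 0:
        return 0
    count = 0
    for cname, a in p.items():
        if cname == PI_POOL:
            continue
        if _level_of(cname) == level and a / total >= theta:
            count += 1
    return count


def _level_of(cname: str) -> int:
    if cname == "Ins":
        return 0
    if cname.startswith("InsP"):
        return int(cname[4])
    return int(cname.rsplit("P", 1)[1])


def classify_activity(
    t_n: ClassProfile,
    t_0: ClassProfile,
    params: ClassifierParams = ClassifierParams(),
) -> ClassificationResult:
    """Rule cascade from InsP6 loss and the InsP5 isomer pattern.

    1. InsP6 loss below the activity threshold -> NO_ACTIVITY.
    2. Compute InsP5 class shares; a class is dominant if it holds at least
       ``dominance_share`` of total InsP5 and ``dominance_ratio`` times the
       runner-up.
    3. Dominant 1/3-OH -> PHYTASE_3; dominant 4/6-OH with negligible 5-OH
       -> PHYTASE_4_6; dominant 5-OH -> PHYTASE_5; dominant 2-OH ->
       UNCLASSIFIED_2POS (no EC class attacks position 2 first).
    4. Dominant 4/6-OH with appreciable 5-OH but negligible 1/3-OH ->
       MINPP_LIKE.
    5. Otherwise MIXED_COMMUNITY; when many InsP5 and InsP4 classes are up,
       a single promiscuous MINPP stays listed as a compatible reading.
    """
    remaining = degradation_extent(t_n, t_0)
    loss = 1.0 - remaining
    shares = insp5_shares(t_n)
    n5 = _count_above(t_n, 5, params.theta_report)
    n4 = _count_above(t_n, 4, params.theta_report)
    n3 = _count_above(t_n, 3, params.theta_report)
    evidence = {
        "remaining_insp6": round(remaining, 6),
        "insp5_shares": {c: round(v, 6) for c, v in shares.items()},
        "n_insp5_above_theta": n5,
        "n_insp4_above_theta": n4,
        "n_insp3_above_theta": n3,
    }

    if loss < params.activity_threshold:
        return ClassificationResult(
            label="NO_ACTIVITY",
            evidence=evidence,
            notes=[f"InsP6 loss {loss:.3f} below activity threshold {params.activity_threshold}"],
        )

    ranked = sorted(shares.items(), key=lambda kv: kv[1], reverse=True)
    (top, top_share), (_, runner_up) = ranked[0], ranked[1]
    dominant = top_share >= params.dominance_share and top_share >= params.dominance_ratio * max(
        runner_up, 1e-12
    )

    if sum(shares.values()) == 0:
        return ClassificationResult(
            label="MIXED_COMMUNITY",
            evidence=evidence,
            notes=[
                "InsP6 lost but no InsP5 intermediate above the reporting "
                "threshold: pattern consistent with sorption loss or complete "
                "turnover to Pi; classification by position of attack is not possible"
            ],
        )

    if dominant:
        if top == "InsP5 [1/3-OH]":
            return ClassificationResult("PHYTASE_3", evidence)
        if top == "InsP5 [4/6-OH]" and shares["InsP5 [5-OH]"] < params.minpp_5oh_min:
            return ClassificationResult("PHYTASE_4_6", evidence)
        if top == "InsP5 [5-OH]":
            return ClassificationResult("PHYTASE_5", evidence)
        if top == "InsP5 [2-OH]":
            return ClassificationResult(
                "UNCLASSIFIED_2POS",
                evidence,
                notes=["no recognized phytase class initiates attack at the 2-position"],
            )
        if (
            top == "InsP5 [4/6-OH]"
            and shares["InsP5 [5-OH]"] >= params.minpp_5oh_min
            and shares["InsP5 [1/3-OH]"] < params.minpp_13oh_max
        ):
            return ClassificationResult(
                "MINPP_LIKE",
                evidence,
                notes=["dominant 4/6-OH with a smaller 5-OH peak and little 1/3-OH"],
            )

    notes = []
    if n5 >= 3 and n4 >= 3:
        notes.append(
            "multiple InsP5 and InsP4 intermediates: consistent with several "
            "phytases acting together, or with a single promiscuous MINPP"
        )
    return ClassificationResult("MIXED_COMMUNITY", evidence, notes=notes)


def analyze_screen(
    chrom_0: Chromatogram,
    chrom_n: Chromatogram,
    rt: RetentionTable,
    params: ClassifierParams = ClassifierParams(),
) -> ScreenReport:
    """End-to-end analysis of a sample pair (t0 vs tn).

    Runs detection, integration/assignment and quantification on both
    traces, then substrate QC on t0, degradation extent, differential
    profiling and the classifier.  Errors from a stage are re-raised with
    the stage named.
    """
    profs = []
    for stage, chrom in (("t0", chrom_0), ("tn", chrom_n)):
        try:
            pk = detect_peaks(chrom)
            pk = integrate_and_assign(pk, chrom, rt)
            profs.append(quantify(pk, normalize=True, include_pi=False))
        except Exception as exc:
            raise RuntimeError(f"analysis failed at stage {stage!r}: {exc}") from exc
    p0, pn = profs
    qc = substrate_qc(p0.without_pi().normalize(), params.qc_impurity_threshold)
    remaining = degradation_extent(pn, p0)
    delta, flagged = diff_profiles(pn, p0, params.theta_report)
    result = classify_activity(pn, p0, params)
    return ScreenReport(
        qc=qc,
        remaining_insp6=remaining,
        diff=delta,
        flagged_classes=flagged,
        classification=result,
        profile_t0=p0,
        profile_tn=pn,
    )
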