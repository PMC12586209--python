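"""Threshold-based hip-fracture risk classification.

Each subject is classified three ways: densitometrically by T-score
(osteoporotic <= -2.5 < osteopenic < -1 <= normal), by FRAX 10-year
hip-fracture probability against a 2% intervention threshold, and by
simulated femoral strength against sex-specific fragility thresholds
(3 kN female / 3.5 kN male, derived from a Korean cohort and not
validated against incident fractures — a documented caveat).  The
cross-tabulation reports both the exclusive joint categories
(both / frax_only / strength_only / neither) and the marginal totals,
because the two views answer different questions.

Boundary conventions (chosen, since inclusivity is rarely stated):
T = -2.5 exactly is osteoporotic; FRAX >= 2% is at risk; strength
strictly below the threshold is fragile.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import ETHNICITIES, SEXES, SubjectRecord

JOINT_CLASSES = ("both", "frax_only", "strength_only", "neither")
BMD_CLASSES = ("osteoporotic", "osteopenic", "normal")


@dataclass
class RiskThresholds:
    tscore_osteoporosis: float = -2.5
    tscore_normal: float = -1.0
    frax_at_risk: float = 2.0            # %
    strength_fragile_female: float = 3.0  # kN
    strength_fragile_male: float = 3.5    # kN

    def validate(self) -> None:
        if self.tscore_osteoporosis >= self.tscore_normal:
            raise ValueError("osteoporosis threshold must lie below the normal threshold")
        if self.frax_at_risk <= 0:
            raise ValueError("frax_at_risk must be > 0")
        if self.strength_fragile_female <= 0 or self.strength_fragile_male <= 0:
            raise ValueError("strength thresholds must be > 0")

    def strength_threshold(self, sex: str) -> float:
        return {"female": self.strength_fragile_female,
                "male": self.strength_fragile_male}[sex]


@dataclass
class RiskLabel:
    bmd_class: str
    frax_at_risk: bool
    strength_fragile: bool
    joint_class: str


def classify_subject(rec: SubjectRecord, th: RiskThresholds | None = None) -> RiskLabel:
    """Apply all three threshold rules to one subject."""
    if th is None:
        th = RiskThresholds()
    th.validate()
    for name in ("t_score", "frax_hfp", "strength", "sex"):
        if getattr(rec, name, None) is None:
            raise ValueError(f"missing field {name!r}; no silent imputation")
    t = rec.t_score
    if t <= th.tscore_osteoporosis:
        bmd = "osteoporotic"
    elif t < th.tscore_normal:
        bmd = "osteopenic"
    else:
        bmd = "normal"
    frax = rec.frax_hfp >= th.frax_at_risk
    fragile = rec.strength < th.strength_threshold(rec.sex)
    joint = {(True, True): "both", (True, False): "frax_only",
             (False, True): "strength_only", (False, False): "neither"}[(frax, fragile)]
    return RiskLabel(bmd, frax, fragile, joint)


def _stratum_table(records, th) -> dict:
    n = len(records)
    counts = {c: 0 for c in JOINT_CLASSES}
    bmd_counts = {c: 0 for c in BMD_CLASSES}
    for rec in records:
        lab = classify_subject(rec, th)
        counts[lab.joint_class] += 1
        bmd_counts[lab.bmd_class] += 1
    pct = {c: (100.0 * v / n if n else None) for c, v in counts.items()}
    bmd_pct = {c: (100.0 * v / n if n else None) for c, v in bmd_counts.items()}
    frax_total = counts["both"] + counts["frax_only"]
    strength_total = counts["both"] + counts["strength_only"]
    return {
        "n": n,
        "counts": counts,
        "percent": pct,
        "bmd_counts": bmd_counts,
        "bmd_percent": bmd_pct,
        "frax_at_risk_total": frax_total,
        "strength_fragile_total": strength_total,
        "frax_at_risk_percent": 100.0 * frax_total / n if n else None,
        "strength_fragile_percent": 100.0 * strength_total / n if n else None,
    }


def cross_tabulate(records, th: RiskThresholds | None = None) -> dict:
    """Per-(sex, ethnicity) and per-sex pooled risk cross-tabulation.

    For every stratum: counts and percentages of the exclusive joint
    classes (which partition the stratum), the T-score classes, and the
    marginal at-risk totals (frax total = both + frax_only, strength
    total = both + strength_only).  Empty strata report n = 0 with null
    percentages.  Row order of the input is irrelevant.
    """
    if th is None:
        th = RiskThresholds()
    if len(records) == 0:
        raise ValueError("empty cohort")
    out = {}
    for sex in SEXES:
        sex_recs = [r for r in records if r.sex == sex]
        out[(sex, "pooled")] = _stratum_table(sex_recs, th)
        for eth in ETHNICITIES:
            sub = [r for r in sex_recs if r.ethnicity == eth]
            out[(sex, eth)] = _stratum_table(sub, th)
    return out
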