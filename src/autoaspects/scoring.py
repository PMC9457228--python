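"""ASPECTS totalization and dichotomization.

Each hemisphere starts at 10 and loses one point per affected region, so
``hemisphere_score = 10 - #affected``.  Both hemispheres are scored; the
*reported* score is the minimum of the two (the clinically conservative
side — a declared convention, since bilateral involvement has no single
standard collapse).  The dichotomized category splits at the thrombectomy
eligibility cutoff: ``">=6"`` iff the reported score is at least 6.
"""

from __future__ import annotations

from dataclasses import dataclass

from .atlas import ASPECTSRegion, HEMISPHERES, REGION_NAMES, all_regions

__all__ = ["ASPECTSResult", "compute_aspects", "dichotomize", "DICHOTOMY_CUTOFF"]

DICHOTOMY_CUTOFF = 6


def dichotomize(score: int) -> str:
    """Collapse a 0-10 ASPECTS to the ``">=6"`` / ``"<6"`` category."""
    if not 0 <= int(score) <= 10 or int(score) != score:
        raise ValueError(f"ASPECTS must be an integer in 0..10, got {score!r}")
    return ">=6" if score >= DICHOTOMY_CUTOFF else "<6"


@dataclass(frozen=True)
class ASPECTSResult:
    decisions: dict
    left_score: int
    right_score: int

    @property
    def reported_score(self) -> int:
        return min(self.left_score, self.right_score)

    @property
    def category(self) -> str:
        return dichotomize(self.reported_score)


def compute_aspects(decisions: dict[ASPECTSRegion, bool]) -> ASPECTSResult:
    """Score a complete set of 20 per-region infarct decisions.

    ``decisions[region] = True`` means the region is called infarcted.
    Raises listing the missing regions if the set is incomplete.
    """
    expected = set(all_regions())
    got = set(decisions)
    if got != expected:
        missing = sorted(expected - got)
        extra = sorted(got - expected, key=str)
        parts = []
        if missing:
            parts.append("missing regions: " + ", ".join(map(str, missing)))
        if extra:
            parts.append("unexpected keys: " + ", ".join(map(str, extra)))
        raise ValueError("incomplete decision set — " + "; ".join(parts))
    scores = {}
    for hemi in HEMISPHERES:
        affected = sum(bool(decisions[ASPECTSRegion(n, hemi)]) for n in REGION_NAMES)
        scores[hemi] = 10 - affected
    return ASPECTSResult(decisions=dict(decisions),
                         left_score=scores["left"], right_score=scores["right"])
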