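"""Rule-based evaluation of the three fit hypotheses.

The narrative judgements of the study design are operationalized as
explicit, configurable rules over the significance codes and positional
shares; the report header states this plainly. With MOU baseline share
``q`` = (#MOU actors) / (#actors):

* **H1 -- the network displays good fit.** Evidence *for*: a good-fit
  block over-represented (``+``/``++``) or a poor-fit block
  under-represented (``-``/``--``). Evidence *against*: the reverse.
  Supported with >=1 signal for and none against; partially supported with
  signals both ways; otherwise not supported. Indeterminate if no labelled
  block could be evaluated.
* **H2 -- fit stems directly from MOU positions.** Supported if the MOU
  share of the good-fit actor positions (the lake-chain slot ``c-1``, and
  ``h-1`` where block *h* occurs) exceeds ``q``. Partially supported if
  MOU actors appear in every lake-chain collaboration (MOU tally at
  ``h-1`` >= count(*h*) > 0) while not driving *c*. Indeterminate when
  neither block occurs.
* **H3 -- fit stems from MOU influence on others.** Supported if the MOU
  share of the external-support position ``g-2`` exceeds ``q`` *and* MOU
  actors hold the majority of the communication hub ``e-1`` (share >
  max(q, 0.5)); partially supported if exactly one condition holds;
  indeterminate when both blocks are absent.

All thresholds live in :class:`RuleConfig`. Verdicts are a pure function
of the inputs and every verdict cites at least one evidence row.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .motifs import BlockCatalog
from .network import ActorCategory
from .nullmodel import NullDistribution
from .positions import PositionOccupancy, category_share

SUPPORTED = "supported"
PARTIAL = "partially_supported"
NOT_SUPPORTED = "not_supported"
INDETERMINATE = "indeterminate"

_OVER = ("+", "++")
_UNDER = ("-", "--")


@dataclass(frozen=True)
class RuleConfig:
    focal_category: ActorCategory = ActorCategory.MOU
    baseline_share: float | None = None  # None: focal category's actor share
    hub_majority: float = 0.5
    good_positions: tuple[tuple[str, str], ...] = (("c", "c-1"), ("h", "h-1"))
    support_position: tuple[str, str] = ("g", "g-2")
    hub_position: tuple[str, str] = ("e", "e-1")


@dataclass(frozen=True)
class Evidence:
    block_id: str
    finding: str
    rule: str


@dataclass
class HypothesisReport:
    verdicts: dict[str, str]
    evidence: dict[str, list[Evidence]]
    baseline_share: float
    rules: RuleConfig

    def to_json(self) -> str:
        return json.dumps(
            {
                "note": "codified operationalization of the narrative hypotheses; "
                "thresholds configurable via RuleConfig",
                "baseline_share": self.baseline_share,
                "verdicts": self.verdicts,
                "evidence": {
                    h: [{"block_id": e.block_id, "finding": e.finding, "rule": e.rule} for e in ev]
                    for h, ev in self.evidence.items()
                },
            },
            indent=2,
        )

    def to_markdown(self) -> str:
        lines = [
            "# Hypothesis report",
            "",
            "*Verdicts are produced by an explicit rule-based operationalization "
            "of the three fit hypotheses; all thresholds are configurable.*",
            "",
            f"Baseline {self.rules.focal_category.value} actor share: "
            f"{self.baseline_share:.3f}",
            "",
        ]
        for h in sorted(self.verdicts):
            lines.append(f"## {h}: **{self.verdicts[h]}**")
            for e in self.evidence[h]:
                lines.append(f"- [{e.block_id}] {e.finding} (rule: {e.rule})")
            lines.append("")
        return "\n".join(lines)


def _share(occ: PositionOccupancy, block: str, pos: str, cat: ActorCategory) -> float:
    if (block, pos) not in occ.counts:
        return math.nan
    return category_share(occ, block, pos, cat)


def evaluate_hypotheses(
    nulldist: NullDistribution,
    occupancy: PositionOccupancy,
    catalog: BlockCatalog,
    rules: RuleConfig | None = None,
) -> HypothesisReport:
    """Apply the codified H1-H3 rules to one network's results."""
    rules = rules or RuleConfig()
    cats = occupancy.actor_categories
    n_actors = len(cats)
    n_focal = sum(1 for c in cats.values() if c == rules.focal_category)
    baseline = (
        rules.baseline_share
        if rules.baseline_share is not None
        else (n_focal / n_actors if n_actors else math.nan)
    )
    verdicts: dict[str, str] = {}
    evidence: dict[str, list[Evidence]] = {"H1": [], "H2": [], "H3": []}

    # ---- H1: codes on fit-labelled blocks --------------------------------
    signals_for = 0
    signals_against = 0
    evaluated = 0
    for block in catalog:
        label = block.fit_label("H1")
        if label == "neutral" or block.block_id not in nulldist.blocks:
            continue
        evaluated += 1
        code = nulldist.blocks[block.block_id].code
        bid = block.block_id
        if label == "good" and code in _OVER:
            signals_for += 1
            evidence["H1"].append(Evidence(bid, f"good-fit block coded {code}", "H1.for"))
        elif label == "poor" and code in _UNDER:
            signals_for += 1
            evidence["H1"].append(Evidence(bid, f"poor-fit block coded {code}", "H1.for"))
        elif label == "good" and code in _UNDER:
            signals_against += 1
            evidence["H1"].append(Evidence(bid, f"good-fit block coded {code}", "H1.against"))
        elif label == "poor" and code in _OVER:
            signals_against += 1
            evidence["H1"].append(Evidence(bid, f"poor-fit block coded {code}", "H1.against"))
        else:
            evidence["H1"].append(Evidence(bid, f"{label}-fit block coded {code}", "H1.neutral"))
    if evaluated == 0:
        verdicts["H1"] = INDETERMINATE
        evidence["H1"].append(Evidence("-", "no fit-labelled block evaluated", "H1.empty"))
    elif signals_for and not signals_against:
        verdicts["H1"] = SUPPORTED
    elif signals_for and signals_against:
        verdicts["H1"] = PARTIAL
    else:
        verdicts["H1"] = NOT_SUPPORTED

    focal = rules.focal_category

    # ---- H2: focal share of good-fit actor positions ---------------------
    good_defined = []
    for bid, pos in rules.good_positions:
        s = _share(occupancy, bid, pos, focal)
        if not math.isnan(s):
            good_defined.append((bid, pos, s))
            evidence["H2"].append(
                Evidence(bid, f"{focal.value} share of {pos} = {s:.3f} vs baseline {baseline:.3f}",
                         "H2.position_share")
            )
    if not good_defined:
        verdicts["H2"] = INDETERMINATE
        evidence["H2"].append(Evidence("-", "no good-fit block occurs", "H2.empty"))
    else:
        all_exceed = all(s > baseline for _, _, s in good_defined)
        # "MOU in every lake-chain collaboration": tally at h-1 covers count(h)
        h_tally = occupancy.counts.get(("h", "h-1"), {})
        h_count = occupancy.block_counts.get("h", 0)
        focal_tally = sum(
            t for a, t in h_tally.items() if cats.get(a) == focal
        )
        in_every_h = h_count > 0 and focal_tally >= h_count
        if all_exceed:
            verdicts["H2"] = SUPPORTED
        elif in_every_h:
            verdicts["H2"] = PARTIAL
            evidence["H2"].append(
                Evidence("h", f"{focal.value} tally at h-1 ({focal_tally}) covers every "
                              f"occurrence (count {h_count})", "H2.in_every_h")
            )
        else:
            verdicts["H2"] = NOT_SUPPORTED

    # ---- H3: focal share of g-2 and hub majority at e-1 ------------------
    g_bid, g_pos = rules.support_position
    e_bid, e_pos = rules.hub_position
    s_g = _share(occupancy, g_bid, g_pos, focal)
    s_e = _share(occupancy, e_bid, e_pos, focal)
    conds = []
    if not math.isnan(s_g):
        ok = s_g > baseline
        conds.append(ok)
        evidence["H3"].append(
            Evidence(g_bid, f"{focal.value} share of {g_pos} = {s_g:.3f} vs baseline "
                            f"{baseline:.3f}", "H3.support_share")
        )
    if not math.isnan(s_e):
        thr = max(baseline, rules.hub_majority)
        ok = s_e > thr
        conds.append(ok)
        evidence["H3"].append(
            Evidence(e_bid, f"{focal.value} share of hub {e_pos} = {s_e:.3f} vs "
                            f"threshold {thr:.3f}", "H3.hub_majority")
        )
    if not conds:
        verdicts["H3"] = INDETERMINATE
        evidence["H3"].append(Evidence("-", "neither support nor hub block occurs", "H3.empty"))
    elif all(conds) and len(conds) == 2:
        verdicts["H3"] = SUPPORTED
    elif any(conds):
        verdicts["H3"] = PARTIAL
    else:
        verdicts["H3"] = NOT_SUPPORTED

    return HypothesisReport(
        verdicts=verdicts, evidence=evidence, baseline_share=baseline, rules=rules
    )
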