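"""End-to-end convenience: census -> null model -> positions -> hypotheses."""

from __future__ import annotations

from dataclasses import dataclass

from .census import MotifCensus, census
from .hypotheses import HypothesisReport, RuleConfig, evaluate_hypotheses
from .motifs import BlockCatalog, default_catalog
from .network import SESNetwork, validate
from .nullmodel import NullDistribution, RandomizationScheme, null_distribution
from .positions import PositionOccupancy, positional_occupancy


@dataclass
class AnalysisResult:
    census: MotifCensus
    nulls: NullDistribution
    occupancy: PositionOccupancy
    report: HypothesisReport


def run_analysis(
    net: SESNetwork,
    catalog: BlockCatalog | None = None,
    scheme: RandomizationScheme | None = None,
    R: int = 1000,
    seed: int = 0,
    rules: RuleConfig | None = None,
) -> AnalysisResult:
    """Run the full fit analysis on a validated network."""
    problems = validate(net)
    if problems:
        raise ValueError("invalid network: " + "; ".join(v.message for v in problems))
    catalog = catalog or default_catalog()
    cens = census(net, catalog, keep_occurrences=True)
    nulls = null_distribution(net, catalog, scheme=scheme, R=R, seed=seed)
    occupancy = positional_occupancy(net, catalog, cens)
    report = evaluate_hypotheses(nulls, occupancy, catalog, rules=rules)
    return AnalysisResult(census=cens, nulls=nulls, occupancy=occupancy, report=report)
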