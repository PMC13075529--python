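"""Convenience wrapper: simulate both arms and compare them."""

from __future__ import annotations

from .cohort import simulate_arm
from .parameters import LifeTable, ModelParameters
from .valuation import CEResult, accumulate_outcomes, compare_arms

__all__ = ["run_base_case"]


def run_base_case(
    p: ModelParameters,
    perspective: str | None = None,
    life_table: LifeTable | None = None,
) -> CEResult:
    """Simulate both arms with the given parameters and return the comparison."""
    treated = simulate_arm(p, "ritlecitinib", life_table=life_table)
    untreated = simulate_arm(p, "no_treatment", life_table=life_table)
    a = accumulate_outcomes(treated, p, perspective)
    b = accumulate_outcomes(untreated, p, perspective)
    return compare_arms(a, b, p.settings.wtp_threshold)
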