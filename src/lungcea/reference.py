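"""Published reference results used as arithmetic fixtures.

Total discounted costs (EUR) and QALYs per 100,000 smokers/ex-smokers for
six annual LDCT screening windows and the no-screening reference, as
printed in a published Dutch cost-effectiveness evaluation of lung-cancer
screening, together with the incremental columns that publication prints.
These are *inputs* for consistency checks of the incremental and
dominance arithmetic — the package does not attempt to reproduce the
underlying totals, which depend on registry- and trial-derived parameter
values not in the public domain.
"""

from __future__ import annotations

from .cea import ScenarioResult

#: (label, total discounted cost EUR, total discounted QALYs), per 100,000,
#: in the publication's cost order.
TABLE1_PER_100K: list[tuple[str, float, float]] = [
    ("no screening", 18_475_224.0, 2520.9),
    ("70+",          19_931_407.0, 2608.7),
    ("60-70",        22_264_907.0, 2770.5),
    ("50-60",        23_143_766.0, 2852.2),
    ("60+",          23_721_090.0, 2858.3),
    ("50-70",        26_933_449.0, 3101.8),
    ("50+",          28_389_632.0, 3189.5),
]

#: Printed incremental costs versus no screening (EUR).
PRINTED_COST_VS_NO_SCREENING = {
    "70+": 1_456_183.0,
    "60-70": 3_789_683.0,
    "50-60": 4_668_542.0,
    "60+": 5_245_866.0,
    "50-70": 8_458_225.0,
    "50+": 9_914_408.0,
}

#: Printed QALYs gained versus no screening.  The 50-60 entry (331.2) is
#: inconsistent at the last printed digit with the printed totals
#: (2852.2 - 2520.9 = 331.3); the publication evidently differenced
#: unrounded values, so that row is excluded from exact checks.
PRINTED_QALYS_GAINED = {
    "70+": 87.8,
    "60-70": 249.6,
    "50-60": 331.2,
    "60+": 337.4,
    "50-70": 580.9,
    "50+": 668.6,
}

#: Printed sequential ICERs of the frontier rows (EUR/QALY).
PRINTED_FRONTIER_ICERS = {"50-60": 14_094.0, "50-70": 15_182.0, "50+": 16_594.0}

#: Printed CERs versus no screening (EUR/QALY).
PRINTED_CERS = {
    "70+": 16_594.0,
    "60-70": 15_182.0,
    "50-60": 14_094.0,
    "60+": 15_549.0,
    "50-70": 14_561.0,
    "50+": 14_828.0,
}

#: Scenarios the publication marks as excluded by extended dominance.
PRINTED_EXTENDED_DOMINATED = frozenset({"70+", "60-70", "60+"})

#: Willingness-to-pay threshold (EUR per QALY) used as the reference point.
WTP_THRESHOLD = 20_000.0


def table1_results() -> list[ScenarioResult]:
    """The printed (cost, QALY) pairs as ScenarioResult objects."""
    return [ScenarioResult(label, cost, q) for label, cost, q in TABLE1_PER_100K]
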