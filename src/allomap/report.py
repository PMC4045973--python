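"""Count arithmetic over marker-development funnels.

A study of this kind reports its headline numbers as sums and
differences of per-genome or per-stage components (SNPs per subgenome,
markers surviving each screen, per-genome map lengths).  The helpers
here recompute those totals from their components and check funnel
consistency, so a report — ours or a published one — can be verified
arithmetically.
"""

from __future__ import annotations

from .snp import funnel_report


def combine_subgenome_counts(count_A: float, count_B: float) -> float:
    """Total of a per-subgenome pair of counts (A + B)."""
    if count_A < 0 or count_B < 0:
        raise ValueError("counts must be non-negative")
    return count_A + count_B


def surviving_markers(entering: int, removed: int) -> int:
    """Markers left after a screening step (entering - removed)."""
    if removed > entering:
        raise ValueError("cannot remove more markers than entered")
    return entering - removed


def percentage(part: float, whole: float) -> float:
    if whole <= 0:
        raise ValueError("whole must be positive")
    return 100.0 * part / whole


def marker_funnel(stages: list):
    """Validated funnel table (monotone non-increasing stage counts)."""
    return funnel_report(stages)
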