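"""Nested unrelated-panel construction from final relationship calls.

Three tiers, each built from the previous tier's survivors so the panels
nest: (1) remove one member of every duplicate/MZ pair, (2) remove
individuals until no first-degree call remains, (3) remove individuals
until no second-degree call remains.  Removal is greedy by current
degree in the relationship graph -- the individual with the most
relationships at the tier's degree goes first, recomputing degrees after
every removal, which maximises the number of retained samples; ties go
to the sample with more missing data, then to the lexicographically
larger id, so output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .relationships import DEGREE_FIRST, DEGREE_MZ, DEGREE_SECOND

__all__ = ["Panel", "build_panels"]


@dataclass
class Panel:
    """A tier's keep-list plus the ordered exclusion log."""

    tier: str  # dedup | first_free | second_free
    kept: List[str]
    excluded: List[dict] = field(default_factory=list)


def _edges_at(calls: pd.DataFrame, degree: str) -> List[Tuple[str, str]]:
    sel = calls[calls["degree"] == degree]
    return [tuple(sorted((r.id_i, r.id_j))) for r in sel.itertuples(index=False)]


def _greedy_remove(
    samples: Sequence[str],
    edges: List[Tuple[str, str]],
    missingness: Mapping[str, float],
    tier: str,
    reason: str,
) -> Tuple[List[str], List[dict]]:
    keep: Set[str] = set(samples)
    adj: Dict[str, Set[str]] = {}
    for a, b in edges:
        if a in keep and b in keep:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    removed = []
    while True:
        live = {s: nb for s, nb in adj.items() if nb}
        if not live:
            break
        # max degree, then max missingness, then lexicographically larger id
        victim = max(
            live,
            key=lambda s: (len(live[s]), missingness.get(s, 0.0), s),
        )
        removed.append(
            {
                "sample_id": victim,
                "tier": tier,
                "reason": reason,
                "degree_at_removal": len(live[victim]),
            }
        )
        keep.discard(victim)
        for nb in adj.pop(victim):
            adj[nb].discard(victim)
    return [s for s in samples if s in keep], removed


def build_panels(
    calls: pd.DataFrame,
    missingness: Mapping[str, float],
    sample_ids: Optional[Sequence[str]] = None,
) -> Tuple[Panel, Panel, Panel]:
    """Construct the three nested panels from final calls.

    ``missingness`` maps sample id -> fraction of missing genotypes (the
    tie-breaker).  ``sample_ids`` fixes the cohort and its order;
    defaults to the sorted union of ids in ``calls`` and ``missingness``.
    Returns (dedup, first_free, second_free); within each panel no
    remaining pair has a call at or above the tier's degree.
    """
    if sample_ids is None:
        ids = set(missingness) | set(calls["id_i"]) | set(calls["id_j"])
        sample_ids = sorted(ids)
    kept1, rem1 = _greedy_remove(
        sample_ids, _edges_at(calls, DEGREE_MZ), missingness, "dedup", "MZ/duplicate"
    )
    kept2, rem2 = _greedy_remove(
        kept1, _edges_at(calls, DEGREE_FIRST), missingness, "first_free", "first-degree"
    )
    kept3, rem3 = _greedy_remove(
        kept2, _edges_at(calls, DEGREE_SECOND), missingness, "second_free", "second-degree"
    )
    return (
        Panel(tier="dedup", kept=kept1, excluded=rem1),
        Panel(tier="first_free", kept=kept2, excluded=rem2),
        Panel(tier="second_free", kept=kept3, excluded=rem3),
    )
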