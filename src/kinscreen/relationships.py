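"""Relationship classification, reconciliation and pedigree validation.

Kinship bands (inclusive lower bounds, matching the convention of keeping
boundary pairs at the closer degree to stay conservative when building
unrelated panels):

    phi >  0.354            monozygotic twin / duplicate sample
    0.177 <= phi <= 0.354   first-degree (PO split from FS by IBS0)
    0.0884 <= phi < 0.177   second-degree
    below                   unrelated or more distant

Initial band calls are then reconciled against the method-of-moments IBD
estimates (PI_HAT and Z0) by a fixed ordered rule set; each final call
records which rule decided it.  Parent-offspring calls are assembled into
trios and duos and cross-checked against sex calls and sibling structure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import networkx as nx
import pandas as pd

from .estimators import PairEstimates
from .genotype_io import FEMALE, MALE

__all__ = [
    "CallThresholds",
    "RelationshipCall",
    "PedigreeReport",
    "classify_pair",
    "reconcile_call",
    "call_pairs",
    "build_pedigrees",
    "summarize",
]

DEGREE_MZ = "MZ"
DEGREE_FIRST = "first"
DEGREE_SECOND = "second"
DEGREE_UNRELATED = "unrelated"

_DEGREE_ORDER = {DEGREE_MZ: 0, DEGREE_FIRST: 1, DEGREE_SECOND: 2, DEGREE_UNRELATED: 3}


@dataclass
class CallThresholds:
    """All tunable cutoffs of the classification pipeline.

    Kinship bands and the IBD reconciliation cutoffs are the published
    thresholds for 50K-array data.  ``po_ibs0_max`` separates PO from FS
    within the first-degree band by the fraction of opposite-homozygote
    markers: a true PO pair shows IBS0 only through genotyping error
    (about 0.64 x error rate of IBS0 per marker), a full-sib pair shows
    about 0.25 * E[2 p^2 q^2] ~ 0.018 even without error.  The default
    0.012 is the geometric midpoint of the two class means at a 1%
    genotype error rate on 50k markers.
    """

    mz_min_kinship: float = 0.354
    first_min_kinship: float = 0.177
    second_min_kinship: float = 0.0884
    po_ibs0_max: float = 0.012
    mz_min_pi_hat: float = 0.99
    po_min_pi_hat: float = 0.5
    po_max_z0: float = 0.013
    fs_min_pi_hat: float = 0.44
    fs_min_z0: float = 0.13
    fs_promote_min_pi_hat: float = 0.49
    fs_demote_max_pi_hat: float = 0.41
    cross_subset_min_kinship: float = 0.0442  # first-cousin-or-closer bound

    def validate(self) -> None:
        if not (
            0.0
            < self.second_min_kinship
            < self.first_min_kinship
            < self.mz_min_kinship
            < 0.5
        ):
            raise ValueError("kinship bands must be ordered within (0, 0.5)")


@dataclass
class RelationshipCall:
    id_i: str
    id_j: str
    degree: str  # MZ | first | second | unrelated
    subtype: Optional[str]  # MZ | PO | FS | None
    rule_fired: str
    cross_population: bool = False
    cross_subset: bool = False
    inconsistent: bool = False


def classify_pair(e: PairEstimates, thresholds: CallThresholds = None) -> RelationshipCall:
    """Initial kinship-band call; PO vs FS split by IBS0 fraction."""
    t = thresholds or CallThresholds()
    k = e.kinship
    if k > t.mz_min_kinship:
        degree, subtype = DEGREE_MZ, "MZ"
    elif k >= t.first_min_kinship:
        degree = DEGREE_FIRST
        subtype = "PO" if e.ibs0_frac < t.po_ibs0_max else "FS"
    elif k >= t.second_min_kinship:
        degree, subtype = DEGREE_SECOND, None
    else:
        degree, subtype = DEGREE_UNRELATED, None
    return RelationshipCall(
        id_i=e.id_i,
        id_j=e.id_j,
        degree=degree,
        subtype=subtype,
        rule_fired="kinship_band",
    )


def reconcile_call(
    initial: RelationshipCall,
    e: PairEstimates,
    thresholds: CallThresholds = None,
) -> RelationshipCall:
    """Final call after the ordered IBD reconciliation rules.

    In order: (1) confirm MZ at PI_HAT > 0.99; a band-MZ pair with
    PI_HAT < 0.5 is contradictory and is degraded to first-degree with an
    inconsistency flag instead of raising; (2) confirm PO at PI_HAT > 0.5
    and Z0 < 0.013; (3) confirm FS at PI_HAT > 0.44 and Z0 > 0.13;
    (4) promote band-second to FS at PI_HAT > 0.49; (5) demote band-FS to
    second at PI_HAT < 0.41; (6) record an FS-like IBD signature below the
    second-degree band as second-degree (conservative).  Otherwise the
    kinship-band call stands.
    """
    t = thresholds or CallThresholds()
    c = RelationshipCall(
        id_i=initial.id_i,
        id_j=initial.id_j,
        degree=initial.degree,
        subtype=initial.subtype,
        rule_fired="kinship_band_default",
        cross_population=initial.cross_population,
        cross_subset=initial.cross_subset,
    )
    if initial.degree == DEGREE_MZ:
        if e.pi_hat > t.mz_min_pi_hat:
            c.rule_fired = "mz_ibd_confirmed"
        elif e.pi_hat < t.po_min_pi_hat:
            c.degree, c.subtype = DEGREE_FIRST, "FS" if e.ibs0_frac >= t.po_ibs0_max else "PO"
            c.rule_fired = "mz_degraded_low_pihat"
            c.inconsistent = True
        else:
            c.rule_fired = "mz_band_retained"
        return c
    if initial.degree == DEGREE_FIRST:
        if e.pi_hat > t.po_min_pi_hat and e.z0 < t.po_max_z0:
            c.subtype, c.rule_fired = "PO", "po_ibd_confirmed"
        elif e.pi_hat > t.fs_min_pi_hat and e.z0 > t.fs_min_z0:
            c.subtype, c.rule_fired = "FS", "fs_ibd_confirmed"
        elif initial.subtype == "FS" and e.pi_hat < t.fs_demote_max_pi_hat:
            c.degree, c.subtype = DEGREE_SECOND, None
            c.rule_fired = "fs_demoted_second"
        return c
    if initial.degree == DEGREE_SECOND:
        if e.pi_hat > t.fs_promote_min_pi_hat:
            c.degree, c.subtype = DEGREE_FIRST, "FS"
            c.rule_fired = "second_promoted_fs"
        return c
    # below the second-degree band
    if e.pi_hat > t.fs_min_pi_hat and e.z0 > t.fs_min_z0:
        c.degree, c.subtype = DEGREE_SECOND, None
        c.rule_fired = "below_band_recorded_second"
    return c


def call_pairs(
    estimates: pd.DataFrame,
    population: Optional[Mapping[str, str]] = None,
    source_subset: Optional[Mapping[str, str]] = None,
    thresholds: CallThresholds = None,
    keep_unrelated: bool = True,
) -> pd.DataFrame:
    """Classify and reconcile every row of a pair-estimates table.

    Cross-population and cross-subset flags are set from the metadata
    mappings; cross-subset pairs weaker than the first-cousin-or-closer
    kinship bound are filtered to unrelated (the degree bands already
    exceed the bound, so this only affects sub-band pairs, but the rule
    is recorded for auditability).
    """
    t = thresholds or CallThresholds()
    t.validate()
    rows = []
    for r in estimates.itertuples(index=False):
        e = PairEstimates(
            id_i=r.id_i,
            id_j=r.id_j,
            kinship=r.kinship,
            ibs0_frac=r.ibs0_frac,
            z0=r.z0,
            z1=r.z1,
            z2=r.z2,
            pi_hat=r.pi_hat,
            n_valid=r.n_valid,
        )
        call = reconcile_call(classify_pair(e, t), e, t)
        if population is not None:
            call.cross_population = population.get(r.id_i) != population.get(r.id_j)
        if source_subset is not None:
            call.cross_subset = source_subset.get(r.id_i) != source_subset.get(r.id_j)
        if (
            call.cross_subset
            and call.degree != DEGREE_UNRELATED
            and e.kinship < t.cross_subset_min_kinship
        ):
            call.degree, call.subtype = DEGREE_UNRELATED, None
            call.rule_fired = "cross_subset_filtered"
        rows.append(call.__dict__.copy())
    df = pd.DataFrame(
        rows,
        columns=[
            "id_i",
            "id_j",
            "degree",
            "subtype",
            "rule_fired",
            "cross_population",
            "cross_subset",
            "inconsistent",
        ],
    )
    if not keep_unrelated:
        df = df[df["degree"] != DEGREE_UNRELATED].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------
# Pedigree assembly and validation
# ---------------------------------------------------------------------

@dataclass
class PedigreeReport:
    """Trios, duos, family components and constraint violations."""

    components: List[List[str]] = field(default_factory=list)
    trios: List[Dict[str, Optional[str]]] = field(default_factory=list)
    duos: List[Tuple[str, str]] = field(default_factory=list)
    grandparental: List[Tuple[str, str]] = field(default_factory=list)
    inconsistencies: List[str] = field(default_factory=list)


def build_pedigrees(
    calls: pd.DataFrame, sexes: Mapping[str, str]
) -> PedigreeReport:
    """Assemble trios and duos from final calls and check consistency.

    A trio (child C, parents A, B) requires PO calls C-A and C-B, no
    relationship call between A and B (the paper's worked family has
    unrelated spouses), sexes admitting a father and a mother (unknown
    sex fills either role), and PO edges not already used by an accepted
    trio.  A candidate rejected only because both parents share a
    declared sex is recorded as an inconsistency.  PO calls in no trio
    become unoriented duos.  Full sibs who are both trio children must
    share their parent set.  Second-degree calls that connect an
    individual to a trio child via a PO link with one of the child's
    parents are noted as grandparental.
    """
    report = PedigreeReport()
    called = calls[calls["degree"] != DEGREE_UNRELATED]
    related_pairs = {
        frozenset((r.id_i, r.id_j)) for r in called.itertuples(index=False)
    }
    po = called[(called["degree"] == DEGREE_FIRST) & (called["subtype"] == "PO")]
    fs = called[(called["degree"] == DEGREE_FIRST) & (called["subtype"] == "FS")]
    second = called[called["degree"] == DEGREE_SECOND]

    partners: Dict[str, List[str]] = {}
    for r in po.itertuples(index=False):
        partners.setdefault(r.id_i, []).append(r.id_j)
        partners.setdefault(r.id_j, []).append(r.id_i)

    used_edges = set()
    child_parents: Dict[str, Tuple[str, str]] = {}
    for child in sorted(partners):
        cands = []
        for a, b in itertools.combinations(sorted(partners[child]), 2):
            if frozenset((a, b)) in related_pairs:
                continue
            if frozenset((child, a)) in used_edges or frozenset((child, b)) in used_edges:
                continue
            sa, sb = sexes.get(a), sexes.get(b)
            if sa in (MALE, FEMALE) and sa == sb:
                report.inconsistencies.append(
                    f"trio rejected for child {child}: candidate parents "
                    f"{a} and {b} share declared sex {sa}"
                )
                continue
            cands.append((a, b))
        if not cands:
            continue
        if len(cands) > 1:
            report.inconsistencies.append(
                f"ambiguous parent pairs for child {child}: {cands}; "
                f"keeping {cands[0]}"
            )
        a, b = cands[0]
        sa, sb = sexes.get(a), sexes.get(b)
        if sa == MALE or sb == FEMALE:
            father, mother = a, b
        elif sb == MALE or sa == FEMALE:
            father, mother = b, a
        else:
            father, mother = a, b
        report.trios.append({"child": child, "father": father, "mother": mother})
        child_parents[child] = (father, mother)
        used_edges.add(frozenset((child, a)))
        used_edges.add(frozenset((child, b)))

    for r in po.itertuples(index=False):
        if frozenset((r.id_i, r.id_j)) not in used_edges:
            report.duos.append(tuple(sorted((r.id_i, r.id_j))))

    for r in fs.itertuples(index=False):
        pi = child_parents.get(r.id_i)
        pj = child_parents.get(r.id_j)
        if pi is not None and pj is not None and set(pi) != set(pj):
            report.inconsistencies.append(
                f"full sibs {r.id_i} and {r.id_j} assigned different parent "
                f"sets {sorted(pi)} vs {sorted(pj)}"
            )

    po_pairs = {frozenset((r.id_i, r.id_j)) for r in po.itertuples(index=False)}
    for r in second.itertuples(index=False):
        for x, c in ((r.id_i, r.id_j), (r.id_j, r.id_i)):
            parents = child_parents.get(c)
            if parents and any(frozenset((x, p)) in po_pairs for p in parents):
                report.grandparental.append(tuple(sorted((r.id_i, r.id_j))))
                break

    graph = nx.Graph()
    for r in called.itertuples(index=False):
        graph.add_edge(r.id_i, r.id_j)
    report.components = [sorted(c) for c in nx.connected_components(graph)]
    report.components.sort()
    return report


def summarize(
    calls: pd.DataFrame,
    population: Mapping[str, str],
    report: Optional[PedigreeReport] = None,
    sexes: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Per-population relationship counts (MZ, Trios, Duos, FS, 2nd).

    Pairs (or trios) whose members span populations are tallied in a
    separate ``*CROSS`` row rather than under either population.
    """
    if report is None:
        report = build_pedigrees(calls, sexes or {})
    pops = sorted(set(population.values()))
    rows = {p: {"POP": p, "MZ": 0, "Trios": 0, "Duos": 0, "FS": 0, "2nd": 0} for p in pops}
    cross = {"POP": "*CROSS", "MZ": 0, "Trios": 0, "Duos": 0, "FS": 0, "2nd": 0}

    def bucket(members):
        ps = {population.get(m) for m in members}
        return rows[ps.pop()] if len(ps) == 1 else cross

    called = calls[calls["degree"] != DEGREE_UNRELATED]
    for r in called.itertuples(index=False):
        b = bucket((r.id_i, r.id_j))
        if r.degree == DEGREE_MZ:
            b["MZ"] += 1
        elif r.degree == DEGREE_FIRST and r.subtype == "FS":
            b["FS"] += 1
        elif r.degree == DEGREE_SECOND:
            b["2nd"] += 1
    for t in report.trios:
        bucket((t["child"], t["father"], t["mother"]))["Trios"] += 1
    for a, b_ in report.duos:
        bucket((a, b_))["Duos"] += 1
    out = [rows[p] for p in pops] + [cross]
    return pd.DataFrame(out, columns=["POP", "MZ", "Trios", "Duos", "FS", "2nd"])
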