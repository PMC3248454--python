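"""Pedigree gene-drop simulation with exact relationship truth.

Founder genotypes are drawn independently per marker under Hardy-Weinberg
equilibrium with minor-allele frequencies uniform on a configurable
interval; non-founders inherit one random allele from each parent
(Mendelian transmission at unlinked markers).  X-chromosome markers are
hemizygous in males (a single maternal allele, stored in diploid coding
as 0/2).  Duplicate individuals (monozygotic twins or repeated DNA
samples) copy their source's genotypes before any error is applied.

The exact pedigree kinship coefficient of every pair, together with a
relationship label, is returned alongside the genotypes so that
downstream estimators can be tested for parameter recovery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .genotype_io import FEMALE, MALE, MISSING, UNKNOWN, GenotypeDataset

__all__ = [
    "PedigreeSpec",
    "SimulationConfig",
    "pedigree_kinship",
    "gene_drop",
    "corrupt",
    "standard_cohort",
    "two_population_cohort",
    "mendelian_violations",
]


@dataclass
class PedigreeSpec:
    """Directed parentage graph with sexes, founders and duplicate samples.

    ``sex`` maps individual id -> "male"/"female"; ``parents`` maps id ->
    (father, mother), both ``None`` for founders.  ``duplicates`` maps a
    copy id to its source id (monozygotic twin / duplicate DNA sample);
    copies do not appear in ``parents``.
    """

    sex: Dict[str, str]
    parents: Dict[str, Tuple[Optional[str], Optional[str]]]
    duplicates: Dict[str, str] = field(default_factory=dict)

    @property
    def individuals(self) -> List[str]:
        return list(self.sex)

    @property
    def founders(self) -> List[str]:
        return [
            i
            for i in self.sex
            if i not in self.duplicates and self.parents.get(i, (None, None))[0] is None
        ]

    def validate(self) -> None:
        for i, (f, m) in self.parents.items():
            if (f is None) != (m is None):
                raise ValueError(f"{i}: a non-founder needs exactly two parents")
            if f is not None:
                if self.sex.get(f) != MALE:
                    raise ValueError(f"{i}: father {f} is not male")
                if self.sex.get(m) != FEMALE:
                    raise ValueError(f"{i}: mother {m} is not female")
        for copy, src in self.duplicates.items():
            if src not in self.sex:
                raise ValueError(f"duplicate {copy}: unknown source {src}")
            if copy in self.parents and self.parents[copy][0] is not None:
                raise ValueError(f"duplicate {copy} cannot also have parents")
        self.topological_order()  # raises on cycles

    def topological_order(self) -> List[str]:
        """Founders-first ordering; raises ``ValueError`` on a cycle."""
        order, state = [], {}

        def visit(i):
            if state.get(i) == 1:
                raise ValueError(f"pedigree cycle detected at {i}")
            if state.get(i) == 2:
                return
            state[i] = 1
            f, m = self.parents.get(i, (None, None))
            for p in (f, m):
                if p is not None:
                    visit(p)
            state[i] = 2
            order.append(i)

        for i in self.sex:
            if i not in self.duplicates:
                visit(i)
        return order


@dataclass
class SimulationConfig:
    """Gene-drop parameters.

    Defaults mirror the 50K SNP-array setting the package targets:
    50,000 autosomal and 1,153 X-linked markers, minor-allele frequencies
    uniform on [0.05, 0.5], and clean genotypes (error and missingness
    are opt-in; 0.05 and 0.01 are the rates referenced for array data).
    """

    n_markers_autosomal: int = 50_000
    n_markers_x: int = 1_153
    maf_range: Tuple[float, float] = (0.05, 0.5)
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for r in (self.genotype_error_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")


# ---------------------------------------------------------------------
# Exact pedigree kinship
# ---------------------------------------------------------------------

def pedigree_kinship(ped: PedigreeSpec) -> pd.DataFrame:
    """Exact kinship matrix by the tabular recursion over parents.

    Founders are assumed unrelated and non-inbred, so phi(i,i) =
    0.5 * (1 + F_i) with F_i the kinship of i's parents.  A duplicate
    copy shares all kinship values with its source; the copy-source
    kinship equals the source's self-kinship (0.5 for outbred sources).
    """
    order = ped.topological_order()
    ids = order + [c for c in ped.sex if c in ped.duplicates]
    pos = {s: k for k, s in enumerate(ids)}
    n = len(ids)
    K = np.zeros((n, n))
    for i in order:
        a = pos[i]
        f, m = ped.parents.get(i, (None, None))
        if f is None:
            K[a, a] = 0.5
        else:
            fa, ma = pos[f], pos[m]
            row = 0.5 * (K[fa] + K[ma])
            K[a, :] = row
            K[:, a] = row
            K[a, a] = 0.5 * (1.0 + K[fa, ma])
    for copy, src in ped.duplicates.items():
        a, s = pos[copy], pos[src]
        K[a, :] = K[s, :]
        K[:, a] = K[:, s]
        K[a, a] = K[s, s]
        K[a, s] = K[s, a] = K[s, s]
    return pd.DataFrame(K, index=ids, columns=ids)


def _truth_labels(ped: PedigreeSpec, K: pd.DataFrame) -> pd.DataFrame:
    ids = list(K.index)
    pos = {s: k for k, s in enumerate(ids)}
    n = len(ids)
    phi = K.to_numpy()

    is_po = np.zeros((n, n), dtype=bool)
    is_fs = np.zeros((n, n), dtype=bool)
    is_mz = np.zeros((n, n), dtype=bool)

    # resolve duplicates to their source for structural relations
    src_of = {i: ped.duplicates.get(i, i) for i in ids}
    parents_of = {
        i: ped.parents.get(src_of[i], (None, None)) for i in ids
    }
    for i, j in itertools.combinations(ids, 2):
        a, b = pos[i], pos[j]
        si, sj = src_of[i], src_of[j]
        if si == sj:
            is_mz[a, b] = is_mz[b, a] = True
            continue
        fi, mi = parents_of[i]
        fj, mj = parents_of[j]
        if si in (fj, mj) or sj in (fi, mi):
            is_po[a, b] = is_po[b, a] = True
        elif fi is not None and fi == fj and mi == mj:
            is_fs[a, b] = is_fs[b, a] = True

    iu, ju = np.triu_indices(n, k=1)
    lab = np.full(len(iu), "other", dtype=object)
    p = phi[iu, ju]
    lab[np.isclose(p, 0.0)] = "unrelated"
    lab[np.isclose(p, 0.125)] = "second"
    lab[is_fs[iu, ju]] = "FS"
    lab[is_po[iu, ju]] = "PO"
    lab[is_mz[iu, ju]] = "MZ"
    return pd.DataFrame(
        {
            "id_i": [ids[k] for k in iu],
            "id_j": [ids[k] for k in ju],
            "phi": p,
            "label": lab,
        }
    )


# ---------------------------------------------------------------------
# Gene drop
# ---------------------------------------------------------------------

def gene_drop(
    ped: PedigreeSpec, cfg: SimulationConfig
) -> Tuple[GenotypeDataset, pd.DataFrame]:
    """Drop alleles through ``ped`` and return (dataset, truth table).

    The truth table holds, for every unordered pair, the exact pedigree
    kinship coefficient and a relationship label (MZ, PO, FS, second,
    unrelated, other).  Identical seeds give identical output.
    """
    ped.validate()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.maf_range
    ma, mx = cfg.n_markers_autosomal, cfg.n_markers_x
    p_auto = rng.uniform(lo, hi, ma)
    p_x = rng.uniform(lo, hi, mx)

    order = ped.topological_order()
    auto: Dict[str, np.ndarray] = {}
    xgen: Dict[str, np.ndarray] = {}
    for i in order:
        f, m = ped.parents.get(i, (None, None))
        male = ped.sex[i] == MALE
        if f is None:
            auto[i] = rng.binomial(2, p_auto).astype(np.int8)
            if male:
                xgen[i] = (2 * rng.binomial(1, p_x)).astype(np.int8)
            else:
                xgen[i] = rng.binomial(2, p_x).astype(np.int8)
        else:
            pat = rng.binomial(1, auto[f] / 2.0)
            mat = rng.binomial(1, auto[m] / 2.0)
            auto[i] = (pat + mat).astype(np.int8)
            mat_x = rng.binomial(1, xgen[m] / 2.0)
            if male:
                xgen[i] = (2 * mat_x).astype(np.int8)
            else:
                pat_x = xgen[f] // 2  # hemizygous father transmits his allele
                xgen[i] = (mat_x + pat_x).astype(np.int8)
    for copy, src in ped.duplicates.items():
        auto[copy] = auto[src].copy()
        xgen[copy] = xgen[src].copy()

    ids = list(ped.sex)
    geno = np.concatenate(
        [
            np.stack([auto[i] for i in ids]) if ma else np.empty((len(ids), 0), np.int8),
            np.stack([xgen[i] for i in ids]) if mx else np.empty((len(ids), 0), np.int8),
        ],
        axis=1,
    ).astype(np.int8)

    # orient each marker to the realized minor allele so that text
    # round-trips through the ped-map dialect are exact
    flip = geno.sum(axis=0) > geno.shape[0]  # minor copies > half of 2n
    geno[:, flip] = 2 - geno[:, flip]

    chrom = np.array(
        [str(1 + (k % 22)) for k in range(ma)] + ["X"] * mx, dtype=object
    )
    marker_ids = [f"rs{k + 1}" for k in range(ma)] + [f"rsX{k + 1}" for k in range(mx)]
    ds = GenotypeDataset(
        sample_ids=ids,
        marker_ids=marker_ids,
        chrom=chrom,
        genotypes=geno,
        sex_declared=np.array([ped.sex[i] for i in ids], dtype=object),
        population=np.array(["P1"] * len(ids), dtype=object),
        source_subset=np.array(["S1"] * len(ids), dtype=object),
    )
    if cfg.genotype_error_rate > 0 or cfg.missing_rate > 0:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        ds = corrupt(ds, cfg.genotype_error_rate, cfg.missing_rate, sub_seed)

    truth = _truth_labels(ped, pedigree_kinship(ped))
    return ds, truth


def corrupt(
    ds: GenotypeDataset, error_rate: float, missing_rate: float, seed: int
) -> GenotypeDataset:
    """Perturb genotypes, then mask some as missing.

    Each non-missing genotype is independently re-drawn, with probability
    ``error_rate``, uniformly from the other two states.  Hemizygous X
    genotypes of males only have one alternative state, so an error there
    flips 0 <-> 2.  Each surviving call is then set missing with
    probability ``missing_rate``.
    """
    for r in (error_rate, missing_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    g = ds.genotypes.copy()
    nonmiss = g != MISSING
    err = (rng.random(g.shape) < error_rate) & nonmiss
    pick = rng.integers(0, 2, g.shape)
    first_other = np.where(g > 0, 0, 1)
    second_other = np.where(g < 2, 2, 1)
    new = np.where(pick == 0, first_other, second_other).astype(np.int8)
    if ds.sex_declared is not None and ds.is_x.any():
        male = np.asarray(ds.sex_declared) == MALE
        block = np.ix_(male, np.flatnonzero(ds.is_x))
        new[block] = (2 - g[block]).astype(np.int8)
    g = np.where(err, new, g)
    miss = (rng.random(g.shape) < missing_rate) & (g != MISSING)
    g = np.where(miss, MISSING, g).astype(np.int8)
    out = GenotypeDataset(
        sample_ids=list(ds.sample_ids),
        marker_ids=list(ds.marker_ids),
        chrom=ds.chrom.copy(),
        genotypes=g,
        sex_declared=None if ds.sex_declared is None else ds.sex_declared.copy(),
        population=None if ds.population is None else ds.population.copy(),
        source_subset=None if ds.source_subset is None else ds.source_subset.copy(),
    )
    return out


# ---------------------------------------------------------------------
# Cohort builders
# ---------------------------------------------------------------------

def standard_cohort(
    n_mz: int = 0,
    n_po: int = 0,
    n_fs: int = 0,
    n_half_sib: int = 0,
    n_avuncular: int = 0,
    n_grandparent: int = 0,
    n_unrelated_pairs: int = 0,
) -> Tuple[PedigreeSpec, pd.DataFrame]:
    """Disjoint families delivering one focal pair per requested relationship.

    Returns the pedigree and a table of focal pairs (id_i, id_j, label)
    with labels MZ, PO, FS, second (half-sib, avuncular or
    grandparent-grandchild) and unrelated.
    """
    sex: Dict[str, str] = {}
    parents: Dict[str, Tuple[Optional[str], Optional[str]]] = {}
    duplicates: Dict[str, str] = {}
    focal = []

    def founder(name, s):
        sex[name] = s
        parents[name] = (None, None)
        return name

    def child(name, s, f, m):
        sex[name] = s
        parents[name] = (f, m)
        return name

    for k in range(n_mz):
        a = founder(f"mz{k}a", MALE if k % 2 else FEMALE)
        b = f"mz{k}b"
        sex[b] = sex[a]
        duplicates[b] = a
        focal.append((a, b, "MZ"))
    for k in range(n_po):
        f = founder(f"po{k}f", MALE)
        m = founder(f"po{k}m", FEMALE)
        c = child(f"po{k}c", MALE if k % 2 else FEMALE, f, m)
        focal.append((f, c, "PO"))
    for k in range(n_fs):
        f = founder(f"fs{k}f", MALE)
        m = founder(f"fs{k}m", FEMALE)
        c1 = child(f"fs{k}c1", MALE, f, m)
        c2 = child(f"fs{k}c2", FEMALE, f, m)
        focal.append((c1, c2, "FS"))
    for k in range(n_half_sib):
        m = founder(f"hs{k}m", FEMALE)
        f1 = founder(f"hs{k}f1", MALE)
        f2 = founder(f"hs{k}f2", MALE)
        c1 = child(f"hs{k}c1", MALE, f1, m)
        c2 = child(f"hs{k}c2", FEMALE, f2, m)
        focal.append((c1, c2, "second"))
    for k in range(n_avuncular):
        gf = founder(f"av{k}gf", MALE)
        gm = founder(f"av{k}gm", FEMALE)
        u = child(f"av{k}u", MALE, gf, gm)
        p = child(f"av{k}p", FEMALE, gf, gm)
        s = founder(f"av{k}s", MALE)
        n = child(f"av{k}n", FEMALE, s, p)
        focal.append((u, n, "second"))
    for k in range(n_grandparent):
        gf = founder(f"gp{k}gf", MALE)
        gm = founder(f"gp{k}gm", FEMALE)
        p = child(f"gp{k}p", FEMALE, gf, gm)
        s = founder(f"gp{k}s", MALE)
        c = child(f"gp{k}c", MALE, s, p)
        focal.append((gf, c, "second"))
    for k in range(n_unrelated_pairs):
        a = founder(f"un{k}a", MALE)
        b = founder(f"un{k}b", FEMALE)
        focal.append((a, b, "unrelated"))

    ped = PedigreeSpec(sex=sex, parents=parents, duplicates=duplicates)
    return ped, pd.DataFrame(focal, columns=["id_i", "id_j", "label"])


def two_population_cohort(
    n_per_pop: int,
    n_markers: int,
    fst: float = 0.1,
    seed: int = 0,
    maf_range: Tuple[float, float] = (0.05, 0.5),
) -> GenotypeDataset:
    """Unrelated founders from two diverged populations.

    Population allele frequencies follow the Balding-Nichols model: an
    ancestral frequency p0 ~ U(maf_range) and per-population frequencies
    Beta(p0 (1-F)/F, (1-p0)(1-F)/F) with F = ``fst``.  Used for the
    structure-visualisation checks; no within-population relatedness.
    """
    rng = np.random.default_rng(seed)
    lo, hi = maf_range
    p0 = rng.uniform(lo, hi, n_markers)
    a = p0 * (1 - fst) / fst
    b = (1 - p0) * (1 - fst) / fst
    rows, pops = [], []
    for pop in ("POP1", "POP2"):
        pk = np.clip(rng.beta(a, b), 1e-3, 1 - 1e-3)
        rows.append(rng.binomial(2, pk, size=(n_per_pop, n_markers)))
        pops += [pop] * n_per_pop
    geno = np.concatenate(rows).astype(np.int8)
    ids = [f"{p}_{i}" for p, i in zip(pops, itertools.count())]
    chrom = np.array([str(1 + (k % 22)) for k in range(n_markers)], dtype=object)
    return GenotypeDataset(
        sample_ids=ids,
        marker_ids=[f"rs{k + 1}" for k in range(n_markers)],
        chrom=chrom,
        genotypes=geno,
        sex_declared=np.array([UNKNOWN] * len(ids), dtype=object),
        population=np.array(pops, dtype=object),
        source_subset=np.array(pops, dtype=object),
    )


def mendelian_violations(ds: GenotypeDataset, ped: PedigreeSpec) -> int:
    """Count autosomal trio genotypes incompatible with Mendelian transmission.

    Transmittable allele counts are {0} from genotype 0, {0,1} from 1 and
    {1} from 2; a child's count must be a sum of one transmittable count
    from each parent.  Missing calls are skipped.  Error-free gene-drop
    output must score zero.
    """
    pos = {s: i for i, s in enumerate(ds.sample_ids)}
    aut = ~ds.is_x
    g = ds.genotypes[:, aut]
    bad = 0
    for c, (f, m) in ped.parents.items():
        if f is None or c not in pos:
            continue
        gc, gf, gm = g[pos[c]], g[pos[f]], g[pos[m]]
        ok_mask = (gc != MISSING) & (gf != MISSING) & (gm != MISSING)
        lo = (gf == 2).astype(int) + (gm == 2).astype(int)
        hi = 2 - (gf == 0).astype(int) - (gm == 0).astype(int)
        bad += int(np.sum(ok_mask & ((gc < lo) | (gc > hi))))
    return bad
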