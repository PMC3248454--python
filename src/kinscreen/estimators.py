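"""Per-pair and per-sample relatedness statistics.

Implements the structure-robust kinship estimator built from heterozygote
concordance and opposite-homozygote counts,

    phi_hat = (N_AaAa - 2 N_AAaa) / (N_Aa(i) + N_Aa(j)),

the method-of-moments IBD decomposition (Z0, Z1, Z2 and
PI_HAT = Z2 + Z1/2) from the IBS histogram under HWE, identity-by-state
distances for classical MDS, and the X-chromosome inbreeding coefficient
F used for sex inference.  All pair statistics are computed over markers
non-missing in both members, autosomes only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genotype_io import MALE, MISSING, GenotypeDataset, allele_frequencies

__all__ = [
    "JointGenotypeCounts",
    "PairEstimates",
    "IbdEstimate",
    "SexCall",
    "joint_genotype_counts",
    "robust_kinship",
    "mom_ibd",
    "pair_estimates",
    "ibs_distance_matrix",
    "x_inbreeding",
    "classify_sex",
    "sex_check",
]


@dataclass
class JointGenotypeCounts:
    """Marker counts over the jointly non-missing positions of one pair."""

    n_both_het: int
    n_opposite_hom: int
    n_het_i: int
    n_het_j: int
    n_valid: int
    ibs_counts: Tuple[int, int, int]  # (# IBS0, # IBS1, # IBS2)


@dataclass
class PairEstimates:
    """Full per-pair statistics consumed by the relationship pipeline."""

    id_i: str
    id_j: str
    kinship: float
    ibs0_frac: float
    z0: float
    z1: float
    z2: float
    pi_hat: float
    n_valid: int


@dataclass
class IbdEstimate:
    z0: float
    z1: float
    z2: float
    pi_hat: float
    n_valid: int


@dataclass
class SexCall:
    sample_id: str
    F: float
    call: str  # "female" | "male" | "uncertain"


def joint_genotype_counts(g_i: np.ndarray, g_j: np.ndarray) -> JointGenotypeCounts:
    """Count joint genotype classes over markers non-missing in both rows.

    IBS at a marker is ``2 - |g_i - g_j|``; opposite homozygotes
    (0 vs 2) are exactly the IBS0 markers.
    """
    g_i = np.asarray(g_i)
    g_j = np.asarray(g_j)
    if g_i.shape != g_j.shape:
        raise ValueError("genotype rows differ in length")
    valid = (g_i != MISSING) & (g_j != MISSING)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no jointly non-missing markers for this pair")
    a = g_i[valid].astype(np.int16)
    b = g_j[valid].astype(np.int16)
    diff = np.abs(a - b)
    n_ibs0 = int((diff == 2).sum())
    n_ibs1 = int((diff == 1).sum())
    return JointGenotypeCounts(
        n_both_het=int(((a == 1) & (b == 1)).sum()),
        n_opposite_hom=n_ibs0,
        n_het_i=int((a == 1).sum()),
        n_het_j=int((b == 1).sum()),
        n_valid=n_valid,
        ibs_counts=(n_ibs0, n_ibs1, n_valid - n_ibs0 - n_ibs1),
    )


def robust_kinship(c: JointGenotypeCounts) -> float:
    """Structure-robust kinship from heterozygote/opposite-homozygote counts.

    Unbiased for any allele-frequency spectrum and any population
    substructure because it conditions on the pair's own heterozygosity;
    may be negative for unrelated pairs.  Undefined (raises) when neither
    individual has a heterozygous call.
    """
    denom = c.n_het_i + c.n_het_j
    if denom == 0:
        raise ValueError("kinship undefined: no heterozygous markers in either sample")
    return (c.n_both_het - 2.0 * c.n_opposite_hom) / denom


# ---------------------------------------------------------------------
# Method-of-moments IBD
# ---------------------------------------------------------------------

def _ibs_given_ibd(p: np.ndarray):
    """Per-marker P(IBS = s | IBD = k) under HWE for the needed (s, k)."""
    q = 1.0 - p
    e_ibs0_ibd0 = 2.0 * p**2 * q**2
    e_ibs1_ibd0 = 4.0 * p**3 * q + 4.0 * p * q**3
    e_ibs1_ibd1 = 2.0 * p**2 * q + 2.0 * p * q**2
    return e_ibs0_ibd0, e_ibs1_ibd0, e_ibs1_ibd1


def _mom_from_counts(
    n_ibs: Tuple[int, int, int],
    s_ibs0_ibd0: float,
    s_ibs1_ibd0: float,
    s_ibs1_ibd1: float,
    n_valid: int,
) -> IbdEstimate:
    if s_ibs0_ibd0 <= 0.0 or s_ibs1_ibd1 <= 0.0:
        raise ValueError("uninformative allele frequencies (all 0 or 1)")
    z0 = n_ibs[0] / s_ibs0_ibd0
    z0 = min(max(z0, 0.0), 1.0)
    z1 = (n_ibs[1] - z0 * s_ibs1_ibd0) / s_ibs1_ibd1
    z1 = min(max(z1, 0.0), 1.0)
    z2 = 1.0 - z0 - z1
    z2 = min(max(z2, 0.0), 1.0)
    total = z0 + z1 + z2
    z0, z1, z2 = z0 / total, z1 / total, z2 / total
    return IbdEstimate(z0=z0, z1=z1, z2=z2, pi_hat=z2 + 0.5 * z1, n_valid=n_valid)


def mom_ibd(g_i: np.ndarray, g_j: np.ndarray, freqs: np.ndarray) -> IbdEstimate:
    """Method-of-moments IBD proportions for one pair.

    ``freqs`` are per-marker minor-allele frequencies estimated on the
    analysis cohort.  Z0 is estimated from the observed IBS0 count
    against its IBD0 expectation, Z1 from the residual IBS1 count, and
    Z2 by complement; components are clamped to [0, 1] sequentially and
    renormalised to sum to one.
    """
    g_i = np.asarray(g_i)
    g_j = np.asarray(g_j)
    freqs = np.asarray(freqs, dtype=np.float64)
    valid = (g_i != MISSING) & (g_j != MISSING)
    if not valid.any():
        raise ValueError("no jointly non-missing markers for this pair")
    a = g_i[valid].astype(np.int16)
    b = g_j[valid].astype(np.int16)
    diff = np.abs(a - b)
    n0 = int((diff == 2).sum())
    n1 = int((diff == 1).sum())
    n_valid = int(valid.sum())
    e00, e10, e11 = _ibs_given_ibd(freqs[valid])
    return _mom_from_counts(
        (n0, n1, n_valid - n0 - n1),
        float(e00.sum()),
        float(e10.sum()),
        float(e11.sum()),
        n_valid,
    )


def pair_estimates(
    ds: GenotypeDataset,
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
    freqs: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Kinship, IBS0 fraction and method-of-moments IBD for sample pairs.

    Autosomal markers only.  ``pairs`` defaults to all unordered pairs;
    ``freqs`` defaults to cohort allele frequencies of the autosomal
    subset.  Returns one row per pair with columns id_i, id_j, n_valid,
    kinship, ibs0_frac, z0, z1, z2, pi_hat.
    """
    aut = ds.autosomal()
    if freqs is None:
        freqs = allele_frequencies(aut)
    freqs = np.asarray(freqs, dtype=np.float64)
    if len(freqs) != aut.n_markers:
        raise ValueError("freqs length does not match autosomal marker count")
    e00, e10, e11 = _ibs_given_ibd(freqs)
    g = aut.genotypes
    pos = {s: i for i, s in enumerate(aut.sample_ids)}
    if pairs is None:
        ids = aut.sample_ids
        pairs = [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    rows = []
    for sid_i, sid_j in pairs:
        gi, gj = g[pos[sid_i]], g[pos[sid_j]]
        valid = (gi != MISSING) & (gj != MISSING)
        n_valid = int(valid.sum())
        if n_valid == 0:
            raise ValueError(f"pair ({sid_i}, {sid_j}): no jointly non-missing markers")
        a = gi[valid].astype(np.int16)
        b = gj[valid].astype(np.int16)
        diff = np.abs(a - b)
        n0 = int((diff == 2).sum())
        n1 = int((diff == 1).sum())
        het_i = int((a == 1).sum())
        het_j = int((b == 1).sum())
        if het_i + het_j == 0:
            raise ValueError(
                f"pair ({sid_i}, {sid_j}): kinship undefined, no heterozygotes"
            )
        kin = (int(((a == 1) & (b == 1)).sum()) - 2.0 * n0) / (het_i + het_j)
        ibd = _mom_from_counts(
            (n0, n1, n_valid - n0 - n1),
            float(e00[valid].sum()),
            float(e10[valid].sum()),
            float(e11[valid].sum()),
            n_valid,
        )
        rows.append(
            {
                "id_i": sid_i,
                "id_j": sid_j,
                "n_valid": n_valid,
                "kinship": kin,
                "ibs0_frac": n0 / n_valid,
                "z0": ibd.z0,
                "z1": ibd.z1,
                "z2": ibd.z2,
                "pi_hat": ibd.pi_hat,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# IBS distance matrix
# ---------------------------------------------------------------------

def ibs_distance_matrix(ds: GenotypeDataset) -> Tuple[list, np.ndarray]:
    """Pairwise IBS distance D_ij = 1 - mean(IBS)/2 over joint markers.

    Returns (sample ids, symmetric matrix with zero diagonal).  Raises if
    any pair has no jointly non-missing marker.
    """
    if ds.n_samples < 2:
        raise ValueError("need at least two samples")
    g = ds.genotypes
    nonmiss = (g != MISSING).astype(np.float64)
    ind = [(np.where(nonmiss.astype(bool), g == v, False)).astype(np.float64) for v in (0, 1, 2)]
    a0, a1, a2 = ind
    # sum over markers of |g_i - g_j| restricted to jointly non-missing
    absdiff = (
        a0 @ a1.T + a1 @ a0.T + a1 @ a2.T + a2 @ a1.T + 2.0 * (a0 @ a2.T + a2 @ a0.T)
    )
    n_valid = nonmiss @ nonmiss.T
    off = ~np.eye(ds.n_samples, dtype=bool)
    if np.any(n_valid[off] == 0):
        raise ValueError("a sample pair has no jointly non-missing markers")
    with np.errstate(invalid="ignore"):
        d = absdiff / (2.0 * n_valid)
    np.fill_diagonal(d, 0.0)
    return list(ds.sample_ids), d


# ---------------------------------------------------------------------
# X-chromosome sex inference
# ---------------------------------------------------------------------

def x_inbreeding(
    ds: GenotypeDataset, freqs: Optional[np.ndarray] = None
) -> np.ndarray:
    """Per-sample X-chromosome inbreeding coefficient F.

    F = (O_hom - E_hom) / (N - E_hom) with O_hom the observed homozygous
    count, E_hom = sum(1 - 2 p q) the HWE expectation over the sample's
    non-missing X markers and N that marker count.  Hemizygous males,
    coded as homozygotes, give F = 1; outbred females give F near 0.
    """
    x = ds.x_only()
    if x.n_markers == 0:
        raise ValueError("dataset has no X-chromosome markers")
    if freqs is None:
        freqs = allele_frequencies(x)
    freqs = np.asarray(freqs, dtype=np.float64)
    p, q = freqs, 1.0 - freqs
    per_marker_ehom = 1.0 - 2.0 * p * q
    g = x.genotypes
    nonmiss = g != MISSING
    n = nonmiss.sum(axis=1).astype(np.float64)
    if np.any(n == 0):
        bad = [x.sample_ids[i] for i in np.flatnonzero(n == 0)]
        raise ValueError(f"samples with no non-missing X markers: {bad}")
    o_hom = (nonmiss & (g != 1)).sum(axis=1).astype(np.float64)
    e_hom = nonmiss @ per_marker_ehom
    denom = n - e_hom
    if np.any(denom == 0):
        bad = [x.sample_ids[i] for i in np.flatnonzero(denom == 0)]
        raise ValueError(f"uninformative X markers for samples: {bad}")
    return (o_hom - e_hom) / denom


def classify_sex(F, female_max: float = 0.2, male_min: float = 0.8):
    """Threshold rule: F < female_max -> female; F > male_min -> male.

    Anything in between is ``uncertain``.  Accepts a scalar or an array
    and returns the matching shape.
    """
    arr = np.asarray(F, dtype=np.float64)
    out = np.where(arr < female_max, "female", np.where(arr > male_min, "male", "uncertain"))
    if arr.ndim == 0:
        return str(out)
    return out.astype(object)


def sex_check(
    ds: GenotypeDataset,
    female_max: float = 0.2,
    male_min: float = 0.8,
    freqs: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """X-homozygosity sex inference for every sample.

    Returns a table with columns sample_id, F, call.
    """
    F = x_inbreeding(ds, freqs=freqs)
    return pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "F": F,
            "call": classify_sex(F, female_max, male_min),
        }
    )
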