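"""Genotype matrices in PED/MAP and tabular text dialects.

Genotypes are stored as counts of the per-marker minor allele (0, 1, 2)
with a single reserved missing sentinel (:data:`MISSING`).  The minor
allele of each marker is fixed when a file is read -- it is the less
frequent allele across all non-missing calls, with ties broken by
lexicographic order of the allele letters -- and never re-oriented
afterwards, so downstream counts are reproducible.

X-chromosome genotypes of males are hemizygous but carried in the same
diploid coding: a male is either 0 or 2 on X (one allele, written as a
homozygote pair in PED output).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

#: Reserved integer marking a missing genotype call.
MISSING: int = -1

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

_PED_SEX = {"1": MALE, "2": FEMALE}
_SEX_PED = {MALE: "1", FEMALE: "2", UNKNOWN: "0"}

_VALID_ALLELES = frozenset("ACGT")


@dataclass
class GenotypeDataset:
    """Samples x markers matrix of minor-allele counts with metadata.

    Attributes
    ----------
    sample_ids : list of str
        Unique sample identifiers, row order of ``genotypes``.
    marker_ids : list of str
        Marker identifiers, column order of ``genotypes``.  May contain
        duplicates until :func:`filter_markers` has been applied.
    chrom : ndarray of str
        Per-marker chromosome label, ``"1"``..``"22"`` or ``"X"``.
    genotypes : ndarray of int8
        Values in {0, 1, 2, MISSING}.
    sex_declared : ndarray of str, optional
        Per-sample ``male`` / ``female`` / ``unknown``.
    population : ndarray of str, optional
        Per-sample population label.
    source_subset : ndarray of str, optional
        Per-sample data-source subset used for per-subset analyses.
    """

    sample_ids: list
    marker_ids: list
    chrom: np.ndarray
    genotypes: np.ndarray
    sex_declared: Optional[np.ndarray] = None
    population: Optional[np.ndarray] = None
    source_subset: Optional[np.ndarray] = None

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        for name in ("sex_declared", "population", "source_subset"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=object))
        if self.genotypes.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise ValueError(
                "genotype matrix shape %s does not match %d samples x %d markers"
                % (self.genotypes.shape, len(self.sample_ids), len(self.marker_ids))
            )
        if len(self.chrom) != len(self.marker_ids):
            raise ValueError("chrom length does not match marker count")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")

    # -- basic queries -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def is_x(self) -> np.ndarray:
        """Boolean mask of X-chromosome markers."""
        return self.chrom == "X"

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated invariant."""
        g = self.genotypes
        ok = (g == MISSING) | ((g >= 0) & (g <= 2))
        if not ok.all():
            raise ValueError("genotype values outside {0,1,2,MISSING}")
        if self.sex_declared is not None and self.is_x.any():
            males = np.asarray(self.sex_declared) == MALE
            gx = g[np.ix_(males, self.is_x)]
            if np.any(gx == 1):
                raise ValueError("heterozygous X genotype in a male sample")

    # -- subsetting ----------------------------------------------------
    def subset_markers(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return replace(
            self,
            marker_ids=[self.marker_ids[i] for i in idx],
            chrom=self.chrom[idx],
            genotypes=self.genotypes[:, idx],
        )

    def subset_samples(self, ids_or_mask) -> "GenotypeDataset":
        if isinstance(ids_or_mask, np.ndarray) and ids_or_mask.dtype == bool:
            idx = np.flatnonzero(ids_or_mask)
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            idx = np.array([pos[s] for s in ids_or_mask], dtype=int)

        def take(v):
            return None if v is None else v[idx]

        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            genotypes=self.genotypes[idx],
            sex_declared=take(self.sex_declared),
            population=take(self.population),
            source_subset=take(self.source_subset),
        )

    def autosomal(self) -> "GenotypeDataset":
        return self.subset_markers(~self.is_x)

    def x_only(self) -> "GenotypeDataset":
        return self.subset_markers(self.is_x)

    def missing_fraction(self) -> np.ndarray:
        """Per-sample fraction of missing genotype calls."""
        return (self.genotypes == MISSING).mean(axis=1)

    # -- equality (used by round-trip tests) ---------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.marker_ids == other.marker_ids
            and list(self.chrom) == list(other.chrom)
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class FilterReport:
    """Counts and identities of markers removed by :func:`filter_markers`."""

    n_duplicate_removed: int = 0
    n_monomorphic_removed: int = 0
    removed_ids: list = field(default_factory=list)


# ---------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------

def read_dataset(path: str, dialect: str = "ped-map") -> GenotypeDataset:
    """Read a genotype dataset.

    For the ``ped-map`` dialect ``path`` is a prefix and ``path + ".ped"``
    / ``path + ".map"`` are read; allele codes are A/C/G/T with ``0`` for
    missing.  For the ``tabular`` dialect ``path + ".genotypes.tsv"``
    (sample metadata plus 0/1/2/NA counts under marker-id headers) and
    ``path + ".markers.tsv"`` (marker id, chromosome) are read.
    """
    if dialect == "ped-map":
        return _read_ped_map(path)
    if dialect == "tabular":
        return _read_tabular(path)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_map(path: str):
    marker_ids, chrom = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 fields, got {len(fields)}")
            chrom.append(fields[0])
            marker_ids.append(fields[1])
    if not marker_ids:
        raise ValueError(f"{path}: empty marker file")
    return marker_ids, chrom


def _read_ped_map(prefix: str) -> GenotypeDataset:
    marker_ids, chrom = _read_map(prefix + ".map")
    m = len(marker_ids)
    sample_ids, sexes, pops = [], [], []
    allele_rows = []  # per sample: 2*m allele letters ('0' = missing)
    with open(prefix + ".ped") as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * m:
                raise ValueError(
                    f"{prefix}.ped:{ln}: expected {6 + 2 * m} fields "
                    f"({m} markers), got {len(fields)}"
                )
            fid, iid, _father, _mother, sex, _pheno = fields[:6]
            sample_ids.append(iid)
            pops.append(fid)
            sexes.append(_PED_SEX.get(sex, UNKNOWN))
            alleles = fields[6:]
            for k in range(m):
                a, b = alleles[2 * k], alleles[2 * k + 1]
                if (a == "0") != (b == "0"):
                    raise ValueError(
                        f"{prefix}.ped:{ln}: half-missing genotype at marker "
                        f"{marker_ids[k]}"
                    )
                for al in (a, b):
                    if al != "0" and al not in _VALID_ALLELES:
                        raise ValueError(
                            f"{prefix}.ped:{ln}: invalid allele code {al!r}"
                        )
            allele_rows.append(alleles)
    n = len(sample_ids)
    geno = np.full((n, m), MISSING, dtype=np.int8)
    # fix minor allele per marker: less frequent across non-missing calls,
    # ties broken lexicographically
    for k in range(m):
        counts: dict = {}
        for row in allele_rows:
            for al in (row[2 * k], row[2 * k + 1]):
                if al != "0":
                    counts[al] = counts.get(al, 0) + 1
        if len(counts) > 2:
            raise ValueError(
                f"marker {marker_ids[k]}: more than two alleles observed"
            )
        if not counts:
            continue  # all missing; stays MISSING
        observed = sorted(counts)  # lexicographic
        if len(counts) == 1:
            minor = None  # monomorphic in the observed allele: count 0
        else:
            a, b = observed
            if counts[a] < counts[b]:
                minor = a
            elif counts[b] < counts[a]:
                minor = b
            else:
                minor = a  # tie -> lexicographically smaller
        for i, row in enumerate(allele_rows):
            a, b = row[2 * k], row[2 * k + 1]
            if a == "0":
                continue
            if minor is None:
                geno[i, k] = 0
            else:
                geno[i, k] = (a == minor) + (b == minor)
    return GenotypeDataset(
        sample_ids=sample_ids,
        marker_ids=marker_ids,
        chrom=np.array(chrom, dtype=object),
        genotypes=geno,
        sex_declared=np.array(sexes, dtype=object),
        population=np.array(pops, dtype=object),
    )


def _read_tabular(prefix: str) -> GenotypeDataset:
    import pandas as pd

    markers = pd.read_csv(prefix + ".markers.tsv", sep="\t", dtype=str)
    if markers.empty:
        raise ValueError(f"{prefix}.markers.tsv: empty marker file")
    geno_df = pd.read_csv(prefix + ".genotypes.tsv", sep="\t", dtype={"sample_id": str})
    meta_cols = ["sample_id", "sex", "population", "source_subset"]
    marker_ids = list(markers["marker_id"])
    expect = meta_cols + marker_ids
    if list(geno_df.columns) != expect:
        raise ValueError(
            f"{prefix}.genotypes.tsv: header does not match marker file "
            f"(expected {len(expect)} columns, got {len(geno_df.columns)})"
        )
    g = geno_df[marker_ids].to_numpy(dtype=float)
    bad = ~(np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{prefix}.genotypes.tsv: invalid genotype value "
            f"{g[i, j]!r} (sample row {i + 1}, marker {marker_ids[j]})"
        )
    geno = np.where(np.isnan(g), MISSING, g).astype(np.int8)
    return GenotypeDataset(
        sample_ids=list(geno_df["sample_id"]),
        marker_ids=marker_ids,
        chrom=markers["chrom"].to_numpy(dtype=object),
        genotypes=geno,
        sex_declared=geno_df["sex"].to_numpy(dtype=object),
        population=geno_df["population"].to_numpy(dtype=object),
        source_subset=geno_df["source_subset"].to_numpy(dtype=object),
    )


# ---------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------

def write_dataset(ds: GenotypeDataset, path: str, dialect: str = "ped-map") -> None:
    """Write ``ds`` so that :func:`read_dataset` reproduces genotypes and ids.

    The ped-map dialect writes the minor allele as ``A`` and the major as
    ``C``; missing calls as ``0 0``; hemizygous X males as homozygote
    pairs.  Note that the read-time rule "minor = less frequent" only
    reproduces the stored orientation when the stored minor allele really
    is the less frequent one (ties resolve to ``A``, consistently).
    """
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise ValueError(f"unwritable path: directory {parent} does not exist")
    if dialect == "ped-map":
        _write_ped_map(ds, path)
    elif dialect == "tabular":
        _write_tabular(ds, path)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


_GENO_PAIR = {0: "C C", 1: "A C", 2: "A A", MISSING: "0 0"}


def _write_ped_map(ds: GenotypeDataset, prefix: str) -> None:
    with open(prefix + ".map", "w") as fh:
        for k, (mid, ch) in enumerate(zip(ds.marker_ids, ds.chrom)):
            fh.write(f"{ch}\t{mid}\t0\t{k + 1}\n")
    sexes = ds.sex_declared if ds.sex_declared is not None else [UNKNOWN] * ds.n_samples
    pops = ds.population if ds.population is not None else ["POP"] * ds.n_samples
    with open(prefix + ".ped", "w") as fh:
        for i, sid in enumerate(ds.sample_ids):
            lead = [str(pops[i]), sid, "0", "0", _SEX_PED.get(sexes[i], "0"), "0"]
            pairs = [_GENO_PAIR[int(g)] for g in ds.genotypes[i]]
            fh.write(" ".join(lead) + " " + " ".join(pairs) + "\n")


def _write_tabular(ds: GenotypeDataset, prefix: str) -> None:
    import pandas as pd

    pd.DataFrame(
        {"marker_id": ds.marker_ids, "chrom": list(ds.chrom)}
    ).to_csv(prefix + ".markers.tsv", sep="\t", index=False)
    g = ds.genotypes.astype(object)
    g[g == MISSING] = "NA"
    meta = {
        "sample_id": ds.sample_ids,
        "sex": list(ds.sex_declared) if ds.sex_declared is not None else UNKNOWN,
        "population": list(ds.population) if ds.population is not None else "NA",
        "source_subset": (
            list(ds.source_subset) if ds.source_subset is not None else "NA"
        ),
    }
    df = pd.DataFrame(meta)
    df = pd.concat(
        [df, pd.DataFrame(g, columns=ds.marker_ids, index=df.index)], axis=1
    )
    df.to_csv(prefix + ".genotypes.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------
# Marker filters and allele frequencies
# ---------------------------------------------------------------------

def filter_markers(ds: GenotypeDataset):
    """Remove duplicate-id and monomorphic markers.

    Duplicate marker ids keep the first occurrence.  A marker is
    monomorphic when at most one allele is present among its non-missing
    calls (all 0, all 2, or fully missing).  Returns the filtered dataset
    and a :class:`FilterReport`; applying the filter twice is a no-op.
    """
    seen = set()
    dup_idx = []
    for k, mid in enumerate(ds.marker_ids):
        if mid in seen:
            dup_idx.append(k)
        else:
            seen.add(mid)
    dup_ids = [ds.marker_ids[k] for k in dup_idx]
    keep = np.ones(ds.n_markers, dtype=bool)
    keep[dup_idx] = False

    g = ds.genotypes
    nonmiss = g != MISSING
    minor_copies = np.where(nonmiss, g, 0).sum(axis=0)
    major_copies = np.where(nonmiss, 2 - g, 0).sum(axis=0)
    mono = (minor_copies == 0) | (major_copies == 0)
    mono_keep = mono & keep
    mono_ids = [ds.marker_ids[k] for k in np.flatnonzero(mono_keep)]
    keep &= ~mono

    report = FilterReport(
        n_duplicate_removed=len(dup_ids),
        n_monomorphic_removed=len(mono_ids),
        removed_ids=dup_ids + mono_ids,
    )
    return ds.subset_markers(keep), report


def allele_frequencies(
    ds: GenotypeDataset, samples: Optional[Sequence[str]] = None
) -> np.ndarray:
    """Per-marker minor-allele frequency in [0, 1].

    Frequency is (sum of minor-allele copies) / (total allele slots) over
    non-missing calls.  On the X chromosome a male sample carries a single
    allele: his diploid-coded genotype contributes ``g/2`` copies to one
    slot.  Raises ``ValueError`` if any marker has no non-missing call.
    """
    sub = ds if samples is None else ds.subset_samples(samples)
    g = sub.genotypes.astype(np.float64)
    nonmiss = sub.genotypes != MISSING
    copies = np.where(nonmiss, g, 0.0)
    slots = np.where(nonmiss, 2.0, 0.0)
    if sub.sex_declared is not None and sub.is_x.any():
        male = np.asarray(sub.sex_declared) == MALE
        xcols = sub.is_x
        block = np.ix_(male, np.flatnonzero(xcols))
        copies[block] = copies[block] / 2.0
        slots[block] = np.where(nonmiss[block], 1.0, 0.0)
    total = slots.sum(axis=0)
    empty = total == 0
    if empty.any():
        bad = [sub.marker_ids[k] for k in np.flatnonzero(empty)]
        raise ValueError(f"markers with all genotypes missing: {bad}")
    return copies.sum(axis=0) / total
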