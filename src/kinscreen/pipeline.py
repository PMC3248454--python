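"""End-to-end orchestration: one call from genotype files to panels.

Stages run in the order sex check -> pair statistics -> MDS ->
relationship calls (whole cohort and per data-source subset, compared) ->
pedigree validation -> summary -> nested panels, writing every artifact
as headered TSV (pedigree report as JSON) plus a manifest.  The same
configuration and inputs always produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import estimators, genotype_io, mds, panels, relationships
from .genotype_io import FEMALE, MALE, UNKNOWN, GenotypeDataset
from .relationships import CallThresholds

__all__ = ["PipelineConfig", "run_pipeline", "subsample_consistency"]

ARTIFACTS = (
    "sex_calls",
    "pair_stats",
    "mds",
    "calls",
    "subset_comparison",
    "pedigree",
    "summary",
    "panels",
)


@dataclass
class PipelineConfig:
    """Declarative configuration of a full screening run."""

    input_prefix: str
    outdir: str
    dialect: str = "tabular"
    sex_female_max: float = 0.2
    sex_male_min: float = 0.8
    mds_k: int = 2
    thresholds: CallThresholds = field(default_factory=CallThresholds)
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["thresholds"] = CallThresholds(**d.get("thresholds", {}))
        return cls(**d)


def _infer_sexes(ds: GenotypeDataset, cfg: PipelineConfig):
    """Sex calls from X homozygosity; declared sexes where X is absent."""
    if ds.is_x.any():
        sex_df = estimators.sex_check(
            ds, female_max=cfg.sex_female_max, male_min=cfg.sex_male_min
        )
    else:
        declared = (
            list(ds.sex_declared)
            if ds.sex_declared is not None
            else [UNKNOWN] * ds.n_samples
        )
        sex_df = pd.DataFrame(
            {"sample_id": ds.sample_ids, "F": np.nan, "call": declared}
        )
    mapping = {}
    for r in sex_df.itertuples(index=False):
        mapping[r.sample_id] = r.call if r.call in (MALE, FEMALE) else UNKNOWN
    return sex_df, mapping


def run_pipeline(
    cfg: PipelineConfig, ds: Optional[GenotypeDataset] = None
) -> dict:
    """Run every stage and return the manifest (also written as JSON).

    ``ds`` may be supplied directly (e.g. fresh from the simulator);
    otherwise it is read from ``cfg.input_prefix``.  A stage failure
    raises with the stage name; the manifest flags completed artifacts.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: dict = {
        "artifacts": {},
        "log": [],
        "config": dataclasses.asdict(cfg),
    }

    def log(msg):
        manifest["log"].append(msg)

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # annotate with the failing stage
            manifest["partial"] = True
            _write_manifest(cfg, manifest)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    def artifact(name, filename):
        path = os.path.join(cfg.outdir, filename)
        manifest["artifacts"][name] = filename
        return path

    if ds is None:
        ds = run_stage(
            "read", lambda: genotype_io.read_dataset(cfg.input_prefix, cfg.dialect)
        )
    ds, report = run_stage("filter", lambda: genotype_io.filter_markers(ds))
    log(
        f"filter: removed {report.n_duplicate_removed} duplicate and "
        f"{report.n_monomorphic_removed} monomorphic markers; "
        f"{ds.n_markers} markers retained "
        f"({int((~ds.is_x).sum())} autosomal, {int(ds.is_x.sum())} X)"
    )
    manifest["filter"] = {
        "n_duplicate_removed": report.n_duplicate_removed,
        "n_monomorphic_removed": report.n_monomorphic_removed,
    }

    # sex inference
    sex_df, sexes = run_stage("sex_check", lambda: _infer_sexes(ds, cfg))
    sex_df.to_csv(artifact("sex_calls", "sex_calls.tsv"), sep="\t", index=False)
    log(
        "sex_check: thresholds F<%.3g female, F>%.3g male; "
        "%d female, %d male, %d uncertain"
        % (
            cfg.sex_female_max,
            cfg.sex_male_min,
            int((sex_df["call"] == "female").sum()),
            int((sex_df["call"] == "male").sum()),
            int((sex_df["call"] == "uncertain").sum()),
        )
    )

    # pair statistics on the whole cohort
    est = run_stage("pair_stats", lambda: estimators.pair_estimates(ds))
    est.to_csv(artifact("pair_stats", "pair_stats.tsv"), sep="\t", index=False)

    # classical MDS on autosomal IBS distances
    def do_mds():
        ids, D = estimators.ibs_distance_matrix(ds.autosomal())
        return mds.mds_table(ids, mds.classical_mds(D, k=cfg.mds_k))

    mds_df = run_stage("mds", do_mds)
    mds_df.to_csv(artifact("mds", "mds.tsv"), sep="\t", index=False)

    # relationship calls, whole cohort
    pop_map = (
        dict(zip(ds.sample_ids, ds.population))
        if ds.population is not None
        else {s: "POP" for s in ds.sample_ids}
    )
    subset_map = (
        dict(zip(ds.sample_ids, ds.source_subset))
        if ds.source_subset is not None
        else {s: "S1" for s in ds.sample_ids}
    )
    calls = run_stage(
        "calls",
        lambda: relationships.call_pairs(
            est, population=pop_map, source_subset=subset_map, thresholds=cfg.thresholds
        ),
    )
    calls.to_csv(artifact("calls", "calls.tsv"), sep="\t", index=False)
    t = cfg.thresholds
    log(
        f"calls: bands MZ>{t.mz_min_kinship}, first>={t.first_min_kinship}, "
        f"second>={t.second_min_kinship}; po_ibs0_max={t.po_ibs0_max}"
    )

    # per-subset re-analysis with subset allele frequencies, compared
    comparison = run_stage(
        "subset_comparison",
        lambda: _subset_comparison(ds, calls, subset_map, pop_map, cfg.thresholds),
    )
    comparison.to_csv(
        artifact("subset_comparison", "subset_comparison.tsv"), sep="\t", index=False
    )
    n_disc = int((comparison["whole_degree"] != comparison["subset_degree"]).sum())
    log(f"subset_comparison: {n_disc} within-subset pairs differ from whole-cohort calls")

    # pedigree validation
    ped = run_stage("pedigree", lambda: relationships.build_pedigrees(calls, sexes))
    with open(artifact("pedigree", "pedigree_report.json"), "w") as fh:
        json.dump(
            {
                "components": ped.components,
                "trios": ped.trios,
                "duos": [list(d) for d in ped.duos],
                "grandparental": [list(g) for g in ped.grandparental],
                "inconsistencies": ped.inconsistencies,
            },
            fh,
            indent=2,
        )

    # summary table
    summary = run_stage(
        "summary", lambda: relationships.summarize(calls, pop_map, report=ped)
    )
    summary.to_csv(artifact("summary", "summary.tsv"), sep="\t", index=False)

    # nested panels
    missing = dict(zip(ds.sample_ids, ds.missing_fraction()))
    p1, p2, p3 = run_stage(
        "panels", lambda: panels.build_panels(calls, missing, sample_ids=ds.sample_ids)
    )
    panel_files = {}
    for p in (p1, p2, p3):
        fname = f"panel_{p.tier}.txt"
        with open(os.path.join(cfg.outdir, fname), "w") as fh:
            fh.write("\n".join(p.kept) + ("\n" if p.kept else ""))
        panel_files[p.tier] = fname
    excl = pd.DataFrame(
        p1.excluded + p2.excluded + p3.excluded,
        columns=["sample_id", "tier", "reason", "degree_at_removal"],
    )
    excl.to_csv(os.path.join(cfg.outdir, "exclusions.tsv"), sep="\t", index=False)
    manifest["artifacts"]["panels"] = panel_files
    manifest["panels"] = {p.tier: len(p.kept) for p in (p1, p2, p3)}
    manifest["exclusions"] = "exclusions.tsv"
    log(
        "panels: kept %d / %d / %d samples at tiers dedup / first_free / second_free"
        % (len(p1.kept), len(p2.kept), len(p3.kept))
    )

    manifest["partial"] = False
    _write_manifest(cfg, manifest)
    return manifest


def _write_manifest(cfg: PipelineConfig, manifest: dict) -> None:
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _subset_comparison(ds, whole_calls, subset_map, pop_map, thresholds):
    """Within-subset calls using subset allele frequencies, vs whole-cohort."""
    whole = {
        frozenset((r.id_i, r.id_j)): r.degree
        for r in whole_calls.itertuples(index=False)
    }
    rows = []
    for subset in sorted(set(subset_map.values())):
        members = [s for s in ds.sample_ids if subset_map[s] == subset]
        if len(members) < 2:
            continue
        sub = ds.subset_samples(members)
        est = estimators.pair_estimates(sub)
        calls = relationships.call_pairs(
            est, population=pop_map, source_subset=subset_map, thresholds=thresholds
        )
        for r in calls.itertuples(index=False):
            rows.append(
                {
                    "subset": subset,
                    "id_i": r.id_i,
                    "id_j": r.id_j,
                    "whole_degree": whole.get(frozenset((r.id_i, r.id_j)), "unrelated"),
                    "subset_degree": r.degree,
                }
            )
    return pd.DataFrame(
        rows, columns=["subset", "id_i", "id_j", "whole_degree", "subset_degree"]
    )


def subsample_consistency(
    ds: GenotypeDataset,
    fractions: Sequence[float] = (0.25, 0.5, 0.75),
    reps: int = 1,
    seed: int = 0,
    thresholds: Optional[CallThresholds] = None,
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Degree-call agreement between random marker subsets and the full data.

    For each fraction and replicate, final calls are recomputed on a
    random subset of autosomal markers and compared with the full-data
    calls; agreement is the fraction of matching degrees among pairs
    called (non-unrelated) in either analysis (1.0 when neither analysis
    calls anything).  A replicate whose estimators fail (e.g. too few
    markers) is reported with agreement NA.
    """
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError("fractions must lie in (0, 1]")
    t = thresholds or CallThresholds()
    aut = ds.autosomal()
    est_full = estimators.pair_estimates(aut, pairs=pairs)
    calls_full = relationships.call_pairs(est_full, thresholds=t)
    full = {
        frozenset((r.id_i, r.id_j)): r.degree
        for r in calls_full.itertuples(index=False)
    }
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        for rep in range(reps):
            m = max(1, int(round(frac * aut.n_markers)))
            idx = np.sort(rng.choice(aut.n_markers, size=m, replace=False))
            sub = aut.subset_markers(idx)
            try:
                est = estimators.pair_estimates(sub, pairs=pairs)
                calls = relationships.call_pairs(est, thresholds=t)
            except ValueError:
                rows.append(
                    {"fraction": frac, "rep": rep, "n_markers": m,
                     "n_compared": 0, "agreement": np.nan}
                )
                continue
            sub_map = {
                frozenset((r.id_i, r.id_j)): r.degree
                for r in calls.itertuples(index=False)
            }
            keys = {
                k
                for k in set(full) | set(sub_map)
                if full.get(k, "unrelated") != "unrelated"
                or sub_map.get(k, "unrelated") != "unrelated"
            }
            agree = (
                np.mean(
                    [full.get(k, "unrelated") == sub_map.get(k, "unrelated") for k in keys]
                )
                if keys
                else 1.0
            )
            rows.append(
                {"fraction": frac, "rep": rep, "n_markers": m,
                 "n_compared": len(keys), "agreement": float(agree)}
            )
    return pd.DataFrame(rows)
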