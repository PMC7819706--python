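"""End-to-end analysis: filters -> dating -> metrics -> datapoints -> trends.

Given a dataset (real or synthetic), the pipeline (1) screens pfams with the
annotation, keyword, two-species and Dollo contamination filters and drops
every gene containing an excluded pfam; (2) dates each retained pfam on the
time tree with the ancient-strata rules and tags its lineage subset;
(3) computes per-instance metrics (clustering index, composition, mean
disorder with and without cysteines, transmembrane status) on the focal
species only — protists serve purely as dating outgroups; (4) collapses
instances into one datapoint per pfam; and (5) fits phylostratigraphy
slopes for disorder and clustering and per-amino-acid composition profiles
over the standard lineage subsets, always on the non-transmembrane
partition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import homology, quality_filters as qf, trends
from .age_assignment import StratumConfig, assign_age, lineage_tag
from .io import Dataset
from .sequence_metrics import (
    STANDARD_AA,
    DisorderProfile,
    clustering_index,
    composition,
    mean_disorder,
)
from .tm_classify import HelixAnnotation, gene_tm_status, pfam_tm_status

__all__ = ["PipelineResult", "run_pipeline", "compute_filter_report",
           "compute_ages", "compute_instance_metrics", "TREND_SUBSETS"]

#: Lineage subsets over which trend fits are reported.
TREND_SUBSETS = ("all", "ancient", "recent_animal", "recent_plant")


@dataclass
class PipelineResult:
    filter_report: pd.DataFrame
    ages: pd.DataFrame
    instances: pd.DataFrame
    datapoints: pd.DataFrame
    slopes: pd.DataFrame
    aa_profiles: dict[str, pd.DataFrame]

    def slope(self, property_name: str, subset: str) -> pd.Series | None:
        sel = self.slopes[
            (self.slopes["property"] == property_name)
            & (self.slopes["subset"] == subset)
        ]
        return sel.iloc[0] if len(sel) else None


def compute_filter_report(
    ds: Dataset, n_reps: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Apply the full exclusion pipeline; one row per pfam."""
    presence = {
        pfam: set(grp["species_id"])
        for pfam, grp in ds.annotations.groupby("pfam_id")
    }
    meta = {row["pfam_id"]: row for _, row in ds.metadata.iterrows()}
    null = qf.DolloNull(ds.tree, n_reps=n_reps, seed=seed)
    rows = []
    for pfam in sorted(presence):
        m = meta.get(pfam)
        if m is None:
            rows.append({"pfam_id": pfam, "stage_dropped": "annotation",
                         "reason": "no species annotation", "kept": False})
            continue
        md = qf.PfamMetadata(
            pfam_id=pfam,
            taxonomic_annotation=m["taxonomic_annotation"],
            abstract_text=m["abstract_text"],
        )
        base = {"pfam_id": pfam, "k": len(presence[pfam]), "z": np.nan,
                "observed_losses": np.nan, "null_mean": np.nan, "null_sd": np.nan}
        dec = qf.annotation_filter(md)
        if not dec.keep:
            rows.append({**base, "stage_dropped": "annotation",
                         "reason": dec.reason, "kept": False})
            continue
        dec = qf.keyword_filter(md)
        if not dec.keep:
            rows.append({**base, "stage_dropped": "keyword",
                         "reason": dec.reason, "kept": False})
            continue
        dec = qf.two_species_filter(presence[pfam])
        if not dec.keep:
            rows.append({**base, "stage_dropped": "two_species",
                         "reason": dec.reason, "kept": False})
            continue
        res = qf.contamination_test(ds.tree, presence[pfam], pfam_id=pfam, null=null)
        base.update(
            z=res.z if res.z is not None else np.nan,
            observed_losses=res.observed_losses,
            null_mean=res.null_mean,
            null_sd=res.null_sd,
        )
        if res.rejected:
            rows.append({**base, "stage_dropped": "dollo",
                         "reason": "random-contamination z-test", "kept": False})
        else:
            rows.append({**base, "stage_dropped": "kept",
                         "reason": res.note or "kept", "kept": True})
    return pd.DataFrame(rows)


def compute_ages(ds: Dataset, retained: set[str]) -> pd.DataFrame:
    """Date retained pfams and tag lineage subsets and age classes."""
    cfg = replace(ds.stratum, luca_pfam_list=frozenset(ds.luca_pfams))
    clades = ds.clades
    presence = {
        pfam: set(grp["species_id"])
        for pfam, grp in ds.annotations.groupby("pfam_id")
        if pfam in retained
    }
    meta = ds.metadata.set_index("pfam_id")
    rows = []
    for pfam in sorted(presence):
        in_bact = bool(meta.at[pfam, "in_bacteria"]) if "in_bacteria" in meta else False
        in_arch = bool(meta.at[pfam, "in_archaea"]) if "in_archaea" in meta else False
        age = assign_age(
            ds.tree, presence[pfam], clades, cfg,
            pfam_id=pfam, in_bacteria=in_bact, in_archaea=in_arch,
        )
        kingdoms = {clades.get(sp, "other") for sp in presence[pfam]}
        rows.append(
            {
                "pfam_id": pfam,
                "age_my": age,
                "lineage_tag": lineage_tag(age, kingdoms, cfg),
                "n_species": len(presence[pfam]),
            }
        )
    ages = pd.DataFrame(rows)
    # one age class per distinct assigned age, oldest first
    distinct = sorted(ages["age_my"].round(3).unique(), reverse=True)
    labels = {a: f"PS{i + 1:02d}" for i, a in enumerate(distinct)}
    ages["age_class"] = ages["age_my"].round(3).map(labels)
    return ages


def compute_instance_metrics(ds: Dataset, retained: set[str]) -> pd.DataFrame:
    """Per-instance metrics on focal species, excluding tainted genes.

    A gene containing any excluded pfam is dropped entirely.  Metrics for a
    pfam instance are computed on the annotated interval of its gene's
    sequence; disorder without cysteine averages the provided per-residue
    scores over the non-cysteine positions of the interval.
    """
    focal = ds.focal_species
    clades = ds.clades
    gene_pfams = ds.annotations.groupby(["species_id", "gene_id"])["pfam_id"].apply(set)
    tainted = {
        key for key, pfams in gene_pfams.items() if not pfams <= retained
    }
    helix_map: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for _, h in ds.helices.iterrows():
        helix_map.setdefault((h["species_id"], h["gene_id"]), []).append(
            (int(h["helix_start"]), int(h["helix_end"]))
        )
    rows = []
    for _, ann in ds.annotations.iterrows():
        sp, gene, pfam = ann["species_id"], ann["gene_id"], ann["pfam_id"]
        if pfam not in retained or sp not in focal or (sp, gene) in tainted:
            continue
        start, end = int(ann["start"]), int(ann["end"])
        seq = ds.sequences[(sp, gene)]
        sub = seq[start - 1 : end]
        clus = clustering_index(sub)
        comp = composition(sub)
        profile = DisorderProfile(ds.disorder[(sp, gene)], source="external")
        isd = mean_disorder(profile, (start, end))
        scores = profile.scores[start - 1 : end]
        non_c = np.array([aa != "C" for aa in sub])
        isd_no_c = float(scores[non_c].mean()) if non_c.any() else np.nan
        helices = HelixAnnotation(
            gene_id=gene,
            intervals=tuple(helix_map.get((sp, gene), ())),
            gene_length=len(seq),
        )
        row = {
            "pfam_id": pfam,
            "species_id": sp,
            "gene_id": gene,
            "clade": clades.get(sp, "other"),
            "start": start,
            "end": end,
            "length": end - start + 1,
            "psi": clus.psi if clus.defined else np.nan,
            "psi_defined": clus.defined,
            "mean_isd": isd,
            "mean_isd_noC": isd_no_c,
            "tm_pfam": pfam_tm_status((start, end), helices),
            "tm_gene": gene_tm_status(helices),
        }
        for aa in STANDARD_AA:
            row[f"comp_{aa}"] = comp.fractions[aa]
        rows.append(row)
    return pd.DataFrame(rows)


METRIC_COLS = ["psi", "mean_isd", "mean_isd_noC"] + [f"comp_{aa}" for aa in STANDARD_AA]


def _aggregate(instances: pd.DataFrame, ages: pd.DataFrame) -> pd.DataFrame:
    datapoints = homology.aggregate_datapoints(instances, METRIC_COLS, key_col="pfam_id")
    tm = instances.groupby("pfam_id")["tm_pfam"].mean() >= 0.5  # majority rule
    datapoints["tm_status"] = tm
    datapoints = datapoints.drop(columns=["n_species"]).join(
        ages.set_index("pfam_id")[["age_my", "age_class", "lineage_tag", "n_species"]],
        how="inner",
    )
    datapoints["hydrophobic_frac"] = sum(
        datapoints[f"comp_{aa}"] for aa in "FILMVW"
    )
    return datapoints.reset_index()


def run_pipeline(ds: Dataset, n_reps: int = 1000, seed: int = 0) -> PipelineResult:
    """Run every stage; see the module docstring for the flow."""
    report = compute_filter_report(ds, n_reps=n_reps, seed=seed)
    retained = set(report.loc[report["kept"], "pfam_id"])
    ages = compute_ages(ds, retained)
    instances = compute_instance_metrics(ds, retained)
    datapoints = _aggregate(instances, ages)
    non_tm = datapoints[~datapoints["tm_status"]]
    slope_rows = []
    profiles = {}
    for subset in TREND_SUBSETS:
        sub = non_tm if subset == "all" else non_tm[non_tm["lineage_tag"] == subset]
        for prop in ("mean_isd", "mean_isd_noC", "psi", "hydrophobic_frac"):
            res = trends.phylostrat_slope(
                sub["age_my"], sub[prop], property_name=prop, subset=subset
            )
            if res is not None:
                slope_rows.append(
                    {"property": prop, "subset": subset, "slope": res.slope,
                     "se": res.se, "r2": res.r_squared, "p": res.p_value,
                     "n": res.n, "ci_low": res.ci95[0], "ci_high": res.ci95[1]}
                )
        if len(sub) >= 3:
            profiles[subset] = trends.aa_slope_profile(sub, subset=subset)
    return PipelineResult(
        filter_report=report,
        ages=ages,
        instances=instances,
        datapoints=datapoints,
        slopes=pd.DataFrame(slope_rows),
        aa_profiles=profiles,
    )
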