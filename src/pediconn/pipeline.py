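"""End-to-end cohort analysis: metrics -> hubs -> GLM/FDR -> clinical -> NBS.

`run_full_analysis` reproduces the standard analysis flow on a cohort
directory and writes tidy report tables:

- ``global_metrics.tsv``     per-subject global measures
- ``global_stats.tsv``       group + interaction inference per global measure
- ``nodal_stats.tsv``        per-node group/interaction inference with
                             hemisphere-wise FDR (regional report table)
- ``hubs_td.tsv`` / ``hubs_asd.tsv``  hub lists on the 15%-sparsity
                             group-average networks
- ``clinical_correlations.tsv``  age-adjusted correlations of
                             FDR-significant nodes with severity scores
- ``nbs_components.tsv`` / ``nbs_null.tsv`` / ``nbs_summary.json``
- ``provenance.json``        config, seed, package version, timestamp

Every stochastic step (NBS permutations) is driven by the run seed, so
a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectome import Cohort
from .metrics import (
    compute_nodal_metrics,
    global_metrics_table,
    group_hubs,
    nodal_metrics_table,
)
from .nbs import run_nbs
from .simulate import load_cohort
from .stats import (
    clinical_correlation,
    fdr_within_hemisphere,
    group_difference_test,
    interaction_test,
    pergroup_age_correlation,
)

__all__ = ["RunConfig", "run_full_analysis"]

log = logging.getLogger("pediconn")

GLOBAL_MEASURES = ("strength", "Eg", "Eloc", "Lp")


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one full analysis run."""

    cohort_dir: str
    output_dir: str
    min_count: int = 5
    sparsity: float = 0.15
    fdr_q: float = 0.05
    nbs_primary_p: float = 0.05
    nbs_n_perm: int = 10_000
    nbs_direction: str = "asd_gt_td"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.sparsity <= 1:
            raise ValueError("sparsity must be in (0, 1]")
        if not 0 < self.fdr_q < 1 or not 0 < self.nbs_primary_p < 1:
            raise ValueError("q and primary p must lie in (0, 1)")
        if self.nbs_n_perm < 1:
            raise ValueError("nbs_n_perm must be >= 1")


def _global_stats(gm: pd.DataFrame) -> pd.DataFrame:
    rows = []
    groups, ages = gm["group"].to_numpy(), gm["age"].to_numpy()
    for measure in GLOBAL_MEASURES:
        y = gm[measure].to_numpy()
        gd = group_difference_test(y, groups, ages)
        ia = interaction_test(y, groups, ages)
        corr = pergroup_age_correlation(y, ages, groups)
        rows.append(
            {
                "measure": measure,
                "group_coef_td_minus_asd": gd.coef,
                "group_t": gd.t,
                "group_df": gd.df,
                "group_p": gd.p,
                "interaction_coef": ia.interaction.coef,
                "interaction_t": ia.interaction.t,
                "interaction_p": ia.interaction.p,
                "slope_td": ia.slope_td,
                "slope_asd": ia.slope_asd,
                "r_age_td": corr["TD"].r if "TD" in corr else np.nan,
                "p_age_td": corr["TD"].p if "TD" in corr else np.nan,
                "r_age_asd": corr["ASD"].r if "ASD" in corr else np.nan,
                "p_age_asd": corr["ASD"].p if "ASD" in corr else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _nodal_stats(cohort: Cohort, fdr_q: float) -> pd.DataFrame:
    table = cohort.node_table
    groups, ages = cohort.groups, cohort.ages
    e_nodal = np.stack(
        [compute_nodal_metrics(cohort.connectomes[s.subject_id]).e_nodal for s in cohort.subjects]
    )
    rows = []
    for i in range(len(table)):
        y = e_nodal[:, i]
        td, asd = y[groups == "TD"], y[groups == "ASD"]
        if y.std() == 0:
            continue
        gd = group_difference_test(y, groups, ages)
        ia = interaction_test(y, groups, ages)
        rows.append(
            {
                "node": table.abbreviations[i],
                "node_index": i,
                "hemisphere": table.hemispheres[i],
                "mean_td": td.mean(),
                "sd_td": td.std(ddof=1),
                "mean_asd": asd.mean(),
                "sd_asd": asd.std(ddof=1),
                "group_t": gd.t,
                "group_df": gd.df,
                "group_p": gd.p,
                "interaction_t": ia.interaction.t,
                "interaction_p": ia.interaction.p,
            }
        )
    df = pd.DataFrame(rows)
    rej, adj = fdr_within_hemisphere(df["group_p"], df["hemisphere"], q=fdr_q)
    df["group_p_fdr"] = adj
    df["group_significant"] = rej
    rej_i, adj_i = fdr_within_hemisphere(df["interaction_p"], df["hemisphere"], q=fdr_q)
    df["interaction_p_fdr"] = adj_i
    df["interaction_significant"] = rej_i
    return df


def _clinical_table(cohort: Cohort, nodal: pd.DataFrame) -> pd.DataFrame:
    asd = cohort.subset("ASD")
    scores = sorted({k for s in asd.subjects for k in s.clinical})
    sig = nodal[nodal["group_significant"]]
    if not scores or sig.empty:
        return pd.DataFrame(columns=["node", "score", "r", "p", "n"])
    e_nodal = np.stack(
        [compute_nodal_metrics(asd.connectomes[s.subject_id]).e_nodal for s in asd.subjects]
    )
    ages = asd.ages
    rows = []
    for _, nrow in sig.iterrows():
        y = e_nodal[:, int(nrow["node_index"])]
        for name in scores:
            have = [s.subject_id for s in asd.subjects if name in s.clinical]
            keep = np.asarray([s.subject_id in have for s in asd.subjects])
            if keep.sum() < 4:
                continue
            vals = np.asarray([s.clinical[name] for s in asd.subjects if name in s.clinical])
            res = clinical_correlation(y[keep], vals, ages[keep])
            rows.append({"node": nrow["node"], "score": name, "r": res.r, "p": res.p, "n": res.n})
    return pd.DataFrame(rows)


def _float_fmt(x) -> str:
    return "%.6g" % x


def run_full_analysis(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full pipeline on a cohort directory; returns the report
    tables (also written as TSV under ``config.output_dir``)."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    fh = logging.FileHandler(outdir / "run.log")
    log.addHandler(fh)
    try:
        log.info("loading cohort from %s", config.cohort_dir)
        cohort = load_cohort(config.cohort_dir)
        from .connectome import apply_streamline_threshold

        for sid in list(cohort.connectomes):
            cohort.connectomes[sid] = apply_streamline_threshold(
                cohort.connectomes[sid], config.min_count
            )
        n_td = int((cohort.groups == "TD").sum())
        n_asd = int((cohort.groups == "ASD").sum())
        log.info("cohort: %d TD, %d ASD subjects, %d nodes", n_td, n_asd, len(cohort.node_table))

        tables: dict[str, pd.DataFrame] = {}
        tables["global_metrics"] = global_metrics_table(cohort)
        tables["global_stats"] = _global_stats(tables["global_metrics"])
        tables["nodal_metrics"] = nodal_metrics_table(cohort)
        tables["nodal_stats"] = _nodal_stats(cohort, config.fdr_q)

        for grp in ("TD", "ASD"):
            hs = group_hubs(cohort, grp, sparsity=config.sparsity)
            tbl = cohort.node_table
            tables[f"hubs_{grp.lower()}"] = pd.DataFrame(
                {
                    "node": [tbl.abbreviations[i] for i in hs.hubs],
                    "hemisphere": [tbl.hemispheres[i] for i in hs.hubs],
                    "threshold": hs.threshold,
                }
            )

        tables["clinical_correlations"] = _clinical_table(cohort, tables["nodal_stats"])

        log.info("running NBS: %d permutations, direction=%s", config.nbs_n_perm, config.nbs_direction)
        nbs_res = run_nbs(
            cohort,
            primary_p=config.nbs_primary_p,
            n_perm=config.nbs_n_perm,
            direction=config.nbs_direction,
            seed=config.seed,
        )
        tbl = cohort.node_table
        comp_rows = []
        for ci, comp in enumerate(nbs_res.components):
            for i, j in comp.edges:
                comp_rows.append(
                    {
                        "component": ci,
                        "size": comp.size,
                        "corrected_p": comp.corrected_p,
                        "node_a": tbl.abbreviations[i],
                        "node_b": tbl.abbreviations[j],
                    }
                )
        tables["nbs_components"] = pd.DataFrame(
            comp_rows, columns=["component", "size", "corrected_p", "node_a", "node_b"]
        )
        tables["nbs_null"] = pd.DataFrame({"max_component_size": nbs_res.null_max_sizes})

        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")

        summary = {
            "n_components": len(nbs_res.components),
            "significant_components": len(nbs_res.significant()),
            "largest_component_size": max((c.size for c in nbs_res.components), default=0),
            "n_perm": nbs_res.n_perm,
            "direction": nbs_res.direction,
        }
        (outdir / "nbs_summary.json").write_text(json.dumps(summary, indent=2) + "\n")

        cfg_dict = dataclasses.asdict(config)
        provenance = {
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True).encode()
            ).hexdigest(),
            "seed": config.seed,
            "pediconn_version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "elapsed_s": round(time.time() - t0, 2),
        }
        (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
        log.info("analysis complete in %.1fs; tables in %s", time.time() - t0, outdir)
        return tables
    finally:
        log.removeHandler(fh)
        fh.close()
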