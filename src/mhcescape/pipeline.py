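"""End-to-end orchestration: run every figure-analog analysis on a cohort.

Mirrors the study design: synonymous-only patients are removed everywhere;
with ``mss_only`` (the default) every burden / presentation / timing /
immune contrast is restricted to microsatellite-stable patients, while the
MSI-enrichment tests necessarily use the full cohort.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from . import cohort_stats, presentation, timing
from .cohort_stats import ComparisonResult, Group
from .synthetic_cohort import Cohort

__all__ = ["DEFAULT_CURVE_CUTOFFS", "run_pipeline", "write_results"]

DEFAULT_CURVE_CUTOFFS = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0)


def _results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


def _group_ids(patients: pd.DataFrame, group: Group, strict: bool = False) -> pd.Index:
    if strict:
        mask = patients["group"] == group.value
    else:
        mask = patients["group"].isin([group.value, Group.BOTH.value])
    return pd.Index(patients.loc[mask, "patient_id"])


def run_pipeline(
    cohort: Cohort,
    mss_only: bool = True,
    cutoff: float = presentation.PHBR_BINDING_CUTOFF,
    exclude_cnv: bool = False,
    min_mutated: int = 5,
    curve_cutoffs=DEFAULT_CURVE_CUTOFFS,
) -> dict[str, pd.DataFrame]:
    """Run all analyses; returns a dict of result tables.

    Keys: ``burden``, ``burden_pan``, ``burden_by_type``,
    ``binding_fractions``, ``binding_curve``, ``binding_tests``, ``bias``,
    ``bias_test``, ``timing``, ``timing_tests``, ``immune``,
    ``immune_pan``, ``immune_by_type``, ``msi``.
    """
    full = cohort.patients[cohort.patients["group"] != Group.SYN_ONLY.value].copy()
    analyzed = full
    if mss_only:
        mss = full["mantis_score"].map(cohort_stats.msi_status) == "MSS"
        analyzed = full[mss]
    ids = pd.Index(analyzed["patient_id"])
    muts = cohort.mutations[cohort.mutations["patient_id"].isin(ids)]

    wt_ids = _group_ids(analyzed, Group.WT)
    b2m_ids = _group_ids(analyzed, Group.B2M_MUT)
    hla_ids = _group_ids(analyzed, Group.HLA_MUT)

    out: dict[str, pd.DataFrame] = {}

    # --- mutation burden --------------------------------------------------
    burden = cohort_stats.burden_table(muts, ids)
    out["burden"] = burden.reset_index()
    pan = [
        cohort_stats.mann_whitney(burden[b2m_ids], burden[wt_ids], "burden:B2M-vs-WT"),
        cohort_stats.mann_whitney(burden[hla_ids], burden[wt_ids], "burden:HLA-vs-WT"),
        cohort_stats.mann_whitney(burden[b2m_ids], burden[hla_ids], "burden:B2M-vs-HLA"),
    ]
    out["burden_pan"] = _results_frame(pan)
    out["burden_by_type"] = _results_frame(
        cohort_stats.per_tumor_type_contrast(analyzed, burden, "burden", min_mutated)
    )

    # --- neoantigen binding fractions -------------------------------------
    fractions = presentation.binding_fractions(muts, cohort.ranks, ids, cutoff)
    out["binding_fractions"] = fractions.reset_index()
    curves = {}
    for name, gids in (("WT", wt_ids), ("B2M_MUT", b2m_ids), ("HLA_MUT", hla_ids)):
        try:
            curves[name] = presentation.binding_fraction_curve(
                muts, cohort.ranks, gids, curve_cutoffs
            )
        except cohort_stats.ValidationError:
            pass
    out["binding_curve"] = pd.DataFrame(curves).rename_axis("cutoff").reset_index()
    binding_tests = []
    for name, gids in (("B2M", b2m_ids), ("HLA", hla_ids)):
        mut_f = fractions[gids].dropna()
        wt_f = fractions[wt_ids].dropna()
        if len(mut_f) and len(wt_f):
            binding_tests.append(
                cohort_stats.mann_whitney(mut_f, wt_f, f"binding-fraction:{name}-vs-WT")
            )
            binding_tests.append(
                cohort_stats.ks_two_sample(mut_f, wt_f, f"binding-fraction-ks:{name}-vs-WT")
            )
    out["binding_tests"] = _results_frame(binding_tests)

    # --- mutated-allele bias ----------------------------------------------
    bias = presentation.bias_results(analyzed, muts, cohort.ranks, cutoff)
    out["bias"] = pd.DataFrame(
        [
            {
                "patient_id": b.patient_id,
                "n_mut_allele": b.n_mut_allele,
                "mean_other": b.mean_other,
                "direction": b.direction.value,
            }
            for b in bias
        ]
    )
    bias_tests = []
    if len(bias) >= 2:
        bias_tests.append(presentation.bias_test(bias))
    out["bias_test"] = _results_frame(bias_tests)

    # --- allelic-fraction timing -------------------------------------------
    tim = timing.annotate_cohort(analyzed, muts, cohort.segments, exclude_cnv=exclude_cnv)
    out["timing"] = tim
    timing_tests: list[ComparisonResult] = []
    b2m_pct = tim.loc[tim["gene_class"] == "B2M", "percentile"]
    hla_pct = tim.loc[tim["gene_class"] == "HLA", "percentile"]
    if len(b2m_pct) and len(hla_pct):
        timing_tests.append(timing.timing_distribution_test(b2m_pct, hla_pct))
    try:
        timing_tests.append(
            presentation.timing_bias_contrast(analyzed, muts, cohort.ranks, tim, cutoff)
        )
    except cohort_stats.ValidationError:
        pass  # an empty early or late stratum: contrast undefined
    out["timing_tests"] = _results_frame(timing_tests)

    # --- immune activity ----------------------------------------------------
    expr = cohort.expression[cohort.expression["patient_id"].isin(ids)].reset_index(drop=True)
    cyt = cohort_stats.cytolytic_scores(expr)
    immune = expr.assign(cytolytic_score=cyt.to_numpy())
    out["immune"] = immune
    series = {
        "cytolytic": immune.set_index("patient_id")["cytolytic_score"],
        "cd8": immune.set_index("patient_id")["cd8_level"],
        "nk": immune.set_index("patient_id")["nk_level"],
    }
    immune_pan = []
    for var, vals in series.items():
        for name, gids in (("B2M", b2m_ids), ("HLA", hla_ids)):
            immune_pan.append(
                cohort_stats.mann_whitney(vals[gids], vals[wt_ids], f"{var}:{name}-vs-WT")
            )
    out["immune_pan"] = _results_frame(immune_pan)
    # one BH family per immune variable (per figure panel)
    by_type: list[ComparisonResult] = []
    for var, vals in series.items():
        by_type.extend(
            cohort_stats.per_tumor_type_contrast(analyzed, vals, var, min_mutated)
        )
    out["immune_by_type"] = _results_frame(by_type)

    # --- MSI enrichment (needs the full cohort, incl. MSI-H) ---------------
    out["msi"] = _results_frame(
        [
            cohort_stats.msi_enrichment(full, Group.B2M_MUT),
            cohort_stats.msi_enrichment(full, Group.HLA_MUT),
        ]
    )
    return out


def write_results(results: dict[str, pd.DataFrame], out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write each result table as ``<key>.tsv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for key, frame in results.items():
        paths[key] = out_dir / f"{key}.tsv"
        frame.to_csv(paths[key], sep="\t", index=False)
    return paths
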