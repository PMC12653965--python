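"""Group-level inference on scored tables: the report bundle.

Runs the figure-analogue contrasts (all two-sided Mann–Whitney):

* rested sham vs irradiated success rates per stage;
* rested vs post-SF success within each group, among SF-tested subjects;
* SFI sham vs irradiated per stage;
* C13 hole-selection frequencies, rested vs post-SF within group;
* C13 error-class counts, rested vs post-SF within group;

plus the below-chance risk analysis on rested C12 success rates
(empirical proportions and the KDE-smoothed variant).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats
from .task import STAGE_ORDER

_HOLE_COLS = ["hole_2", "hole_4", "hole_12", "hole_14", "omission"]
_ERR_COLS = ["n_initial", "n_perseverative", "n_regressive"]


@dataclass
class ReportBundle:
    """Inferential outputs plus the manifest needed to regenerate them."""

    comparisons: pd.DataFrame
    risk: pd.DataFrame
    manifest: dict

    def tables(self) -> dict:
        return {"comparisons": self.comparisons, "risk": self.risk}


def _compare(label, stage, a, b, names, tail, rows, min_n=1):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < min_n or b.size < min_n:
        return
    res = stats.mann_whitney_exact(a, b, tail=tail)
    rows.append({"analysis": label, "stage": stage, "group_a": names[0],
                 "group_b": names[1], "n1": res.n1, "n2": res.n2,
                 "mean_a": float(a.mean()), "mean_b": float(b.mean()),
                 "u_statistic": res.u_statistic, "p_two_sided": res.p_two_sided,
                 "method": res.method})


def analyze_bundle(bundle: dict, kde_bandwidth="silverman", tail: str = "doubled",
                   holm: bool = False, manifest_extra: dict | None = None) -> ReportBundle:
    """Run all group contrasts on a :func:`armitsim.scoring.score_bundle` output."""
    summary = bundle["stage_summary"]
    rows: list = []

    rested = summary[summary["sleep_condition"] == "rested"]
    post = summary[summary["sleep_condition"] == "sf"]
    sf_subjects = set(post["subject_id"].unique())

    for stage in STAGE_ORDER:
        r = rested[rested["stage"] == stage]
        _compare("rested_sham_vs_gcr", stage,
                 r.loc[r["radiation_group"] == "sham", "success_rate"],
                 r.loc[r["radiation_group"] == "gcr", "success_rate"],
                 ("sham", "gcr"), tail, rows)
        for group in ("sham", "gcr"):
            rg = r[(r["radiation_group"] == group)
                   & r["subject_id"].isin(sf_subjects)]
            pg = post[(post["radiation_group"] == group) & (post["stage"] == stage)]
            _compare(f"{group}_rested_vs_sf", stage,
                     rg["success_rate"], pg["success_rate"],
                     ("rested", "sf"), tail, rows)

    sfi = bundle["sfi"]
    for stage in STAGE_ORDER:
        s = sfi[(sfi["stage"] == stage) & sfi["defined"]]
        _compare("sfi_sham_vs_gcr", stage,
                 s.loc[s["radiation_group"] == "sham", "sfi"],
                 s.loc[s["radiation_group"] == "gcr", "sfi"],
                 ("sham", "gcr"), tail, rows)

    holes = bundle["hole_frequencies"]
    holes_sf = holes[holes["sleep_condition"] == "sf"]
    holes_rested = holes[holes["sleep_condition"] == "rested"]
    for group in ("sham", "gcr"):
        hr = holes_rested[(holes_rested["radiation_group"] == group)
                          & holes_rested["subject_id"].isin(sf_subjects)]
        hs = holes_sf[holes_sf["radiation_group"] == group]
        for col in _HOLE_COLS:
            if col in holes.columns:
                _compare(f"{group}_hole_{col}_rested_vs_sf", "C13",
                         hr[col], hs[col], ("rested", "sf"), tail, rows)

    errors = bundle["errors"]
    err_sf = errors[errors["sleep_condition"] == "sf"]
    err_rested = errors[errors["sleep_condition"] == "rested"]
    for group in ("sham", "gcr"):
        er = err_rested[(err_rested["radiation_group"] == group)
                        & err_rested["subject_id"].isin(sf_subjects)]
        es = err_sf[err_sf["radiation_group"] == group]
        for col in _ERR_COLS:
            _compare(f"{group}_{col}_rested_vs_sf", "C13",
                     er[col], es[col], ("rested", "sf"), tail, rows)

    comparisons = pd.DataFrame(rows)
    if holm and len(comparisons):
        comparisons["p_holm"] = stats.holm_adjust(comparisons["p_two_sided"])

    risk = _risk_table(rested, kde_bandwidth)
    manifest = {"n_comparisons": int(len(comparisons)),
                "tail": tail, "kde_bandwidth": str(kde_bandwidth)}
    if manifest_extra:
        manifest.update(manifest_extra)
    return ReportBundle(comparisons=comparisons, risk=risk, manifest=manifest)


def _risk_table(rested: pd.DataFrame, kde_bandwidth) -> pd.DataFrame:
    rows = []
    for stage in ("C12", "C13"):
        r = rested[(rested["stage"] == stage) & rested["defined"]]
        sham = r.loc[r["radiation_group"] == "sham", "success_rate"].to_numpy(float)
        gcr = r.loc[r["radiation_group"] == "gcr", "success_rate"].to_numpy(float)
        if sham.size == 0 or gcr.size == 0:
            continue
        thr = stats.chance_level(stage)
        emp = stats.absolute_risk([x < thr for x in sham], [x < thr for x in gcr])
        rows.append(_risk_row(stage, "empirical", emp))
        try:
            kde = stats.absolute_risk_kde(sham, gcr, stage, kde_bandwidth)
            rows.append(_risk_row(stage, "kde", kde))
        except ValueError:
            pass  # degenerate sample, automatic bandwidth unavailable
    return pd.DataFrame(rows)


def _risk_row(stage: str, estimator: str, est: stats.RiskEstimate) -> dict:
    return {"stage": stage, "estimator": estimator,
            "p_below_chance_gcr": est.p_exposed,
            "p_below_chance_sham": est.p_control,
            "risk_difference": est.risk_difference,
            "nnh": np.nan if est.nnh is None else est.nnh}


def write_bundle(report: ReportBundle, out_dir) -> list:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in report.tables().items():
        p = out_dir / f"{name}.csv"
        frame.to_csv(p, index=False)
        written.append(p)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(report.manifest, indent=2, sort_keys=True))
    written.append(manifest_path)
    return written


def render_report(report: ReportBundle) -> str:
    """Markdown summary of the comparisons and risk tables."""
    lines = ["# ARMIT simulation report", ""]
    lines.append("## Group comparisons (two-sided Mann-Whitney)")
    lines.append("")
    if len(report.comparisons):
        lines.append("```")
        lines.append(report.comparisons.to_string(index=False, float_format="%.4f"))
        lines.append("```")
    else:
        lines.append("_no comparisons could be run_")
    lines.append("")
    lines.append("## Absolute risk of below-chance performance (rested)")
    lines.append("")
    if len(report.risk):
        lines.append("```")
        lines.append(report.risk.to_string(index=False, float_format="%.4f"))
        lines.append("```")
    else:
        lines.append("_no risk estimates_")
    lines.append("")
    lines.append("## Manifest")
    lines.append("")
    lines.append("```json")
    lines.append(json.dumps(report.manifest, indent=2, sort_keys=True))
    lines.append("```")
    return "\n".join(lines) + "\n"
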