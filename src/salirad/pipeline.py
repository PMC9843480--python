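"""Replication analysis orchestration.

Composes the imaging, texture and modelling layers into the full study:
per-patient feature extraction with artifact handling, the univariate
association table, reference-vs-extended logistic models per endpoint
and subgroup (likelihood-ratio test and apparent AUC), the 2D-vs-3D
Short Run Emphasis agreement study on artifact-free parotids, and a
deterministic JSON/CSV report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
import scipy.stats

from . import __version__
from .config import PipelineConfig
from .cohort import GLANDS, PatientImaging
from .imaging import CtVolume, EmptyRoiError, RoiMask, discretise, exclude_artifact_slices
from .modelling import (
    DegenerateFeatureError,
    fit_logistic,
    likelihood_ratio_test,
    auc,
    univariate_association,
    zscore_normalise,
)
from .texture import compute_2d, compute_3d, max_hu

__all__ = [
    "SubgroupDefinition",
    "DataError",
    "run_extraction",
    "standard_subgroups",
    "run_endpoint_analysis",
    "compare_2d_3d",
    "univariate_table",
    "emit_report",
    "run_analysis",
    "load_cohort_dir",
]

log = logging.getLogger("salirad")


class DataError(ValueError):
    """Inconsistent or unreadable cohort inputs."""


@dataclass(frozen=True)
class SubgroupDefinition:
    """A named pure predicate over the merged per-patient table."""

    name: str
    predicate: Callable[[pd.DataFrame], pd.Series]

    def select(self, table: pd.DataFrame) -> pd.Series:
        keep = self.predicate(table)
        return keep.fillna(False).astype(bool)


# ---------------------------------------------------------------------------
# feature extraction


#: per-gland feature columns emitted by run_extraction
_GLAND_COLUMNS = ("n_slices", "n_excluded", "excluded_fraction", "maxhu", "sre_2d", "idm_2d")


def _extract_one(
    patient: PatientImaging, config: PipelineConfig
) -> dict[str, float]:
    row: dict[str, float] = {"patient_id": patient.patient_id}
    for gland in GLANDS:
        prefix = gland if gland == "parotid" else gland
        for col in _GLAND_COLUMNS:
            row[f"{prefix}_{col}"] = np.nan
        row.setdefault("parotid_sre_3d", np.nan)
        mask = patient.masks.get(gland)
        if mask is None:
            log.info("%s: gland %s absent/resected, features missing", patient.patient_id, gland)
            continue
        n_bearing = int(mask.bearing_slices.size)
        row[f"{prefix}_n_slices"] = n_bearing
        try:
            sel = exclude_artifact_slices(patient.volume, mask, config.hu_artifact_threshold)
        except EmptyRoiError:
            log.warning(
                "%s: all %d slices of %s artifacted, features missing",
                patient.patient_id, n_bearing, gland,
            )
            row[f"{prefix}_n_excluded"] = n_bearing
            row[f"{prefix}_excluded_fraction"] = 1.0
            continue
        row[f"{prefix}_n_excluded"] = n_bearing - len(sel)
        row[f"{prefix}_excluded_fraction"] = sel.excluded_fraction
        roi = discretise(patient.volume, mask, sel)
        row[f"{prefix}_maxhu"] = max_hu(patient.volume, mask, sel)
        v = compute_2d(roi, "sre")
        row[f"{prefix}_sre_2d"] = np.nan if v is None else v
        v = compute_2d(roi, "inverse_difference_moment")
        row[f"{prefix}_idm_2d"] = np.nan if v is None else v
        if gland == "parotid" and sel.excluded_fraction == 0.0:
            v = compute_3d(roi, "sre")
            row["parotid_sre_3d"] = np.nan if v is None else v
        log.info(
            "%s: %s slices=%d excluded=%d", patient.patient_id, gland,
            n_bearing, n_bearing - len(sel),
        )
    return row


def run_extraction(
    patients: list[PatientImaging], config: Optional[PipelineConfig] = None
) -> pd.DataFrame:
    """Per-patient radiomics feature table; one row per patient.

    Failures are per-patient: a broken volume yields a row of missing
    features and an ``error`` note, and the run continues.
    """
    config = config or PipelineConfig()
    rows = []
    n_failed = 0
    for patient in sorted(patients, key=lambda p: p.patient_id):
        try:
            rows.append(_extract_one(patient, config))
        except Exception as exc:  # keep going; summarise at the end
            n_failed += 1
            log.error("%s: extraction failed: %s", patient.patient_id, exc)
            rows.append({"patient_id": patient.patient_id, "error": str(exc)})
    if n_failed:
        log.warning("extraction finished with %d failed patient(s)", n_failed)
    table = pd.DataFrame(rows)
    # bilateral SMG pooling: mean of present glands, single gland passes through
    table["smg_maxhu"] = table[["smg_left_maxhu", "smg_right_maxhu"]].mean(axis=1)
    table["smg_sre_2d"] = table[["smg_left_sre_2d", "smg_right_sre_2d"]].mean(axis=1)
    return table


def load_cohort_dir(cohort_dir) -> tuple[list[PatientImaging], pd.DataFrame]:
    """Read the on-disk cohort layout (NIfTI images + clinical.csv)."""
    cohort_dir = Path(cohort_dir)
    clinical_path = cohort_dir / "clinical.csv"
    if not clinical_path.exists():
        raise DataError(f"no clinical.csv under {cohort_dir}")
    clinical = pd.read_csv(clinical_path)
    images = cohort_dir / "images"
    patients = []
    for pid in clinical["patient_id"]:
        ct_path = images / f"{pid}_ct.nii.gz"
        if not ct_path.exists():
            raise DataError(f"missing CT volume for {pid}")
        volume = CtVolume.from_nifti(ct_path)
        masks = {}
        for gland in GLANDS:
            mpath = images / f"{pid}_mask_{gland}.nii.gz"
            if mpath.exists():
                masks[gland] = RoiMask.from_nifti(mpath, gland)
        patients.append(PatientImaging(str(pid), volume, masks))
    return patients, clinical


# ---------------------------------------------------------------------------
# subgroups


def standard_subgroups(config: Optional[PipelineConfig] = None) -> list[SubgroupDefinition]:
    """The analysed patient strata: whole cohort, intact glands, low slice
    exclusion, and the modal fractionation schedule."""
    config = config or PipelineConfig()
    cut = config.exclusion_fraction_cut
    return [
        SubgroupDefinition("all_patients", lambda t: pd.Series(True, index=t.index)),
        SubgroupDefinition(
            "both_smg_intact",
            lambda t: t["smg_left_intact"].astype(bool) & t["smg_right_intact"].astype(bool),
        ),
        SubgroupDefinition(
            "parotid_low_exclusion",
            lambda t, c=cut: t["parotid_excluded_fraction"] < c,
        ),
        SubgroupDefinition(
            "fractionation_65gy_30fx",
            lambda t: (t["prescription_gy"] == 65) & (t["n_fractions"] == 30),
        ),
    ]


# ---------------------------------------------------------------------------
# endpoint models


def _baseline_values(table: pd.DataFrame, column: str, config: PipelineConfig) -> pd.Series:
    grades = table[column].astype(float)
    if config.baseline_encoding == "binary":
        return (grades >= 3).astype(float)
    return grades


def run_endpoint_analysis(
    table: pd.DataFrame,
    endpoint: str,
    subgroup: SubgroupDefinition,
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Reference vs radiomics-extended logistic models on one subgroup.

    Returns a report fragment: n, events, apparent AUC of both models,
    and the likelihood-ratio test for the added feature.  Subgroups below
    the size floor, with a single outcome class, or with a degenerate
    feature are marked not evaluable with the reason.
    """
    config = config or PipelineConfig()
    spec = config.endpoint_features[endpoint]
    fragment = {
        "endpoint": endpoint,
        "subgroup": subgroup.name,
        "feature": spec["feature"],
        "evaluable": False,
    }
    sub = table[subgroup.select(table)]
    fragment["n_subgroup"] = int(len(sub))
    cols = [endpoint, spec["baseline"], spec["dose"], spec["feature"]]
    data = sub[cols].dropna()
    n_dropped = len(sub) - len(data)
    fragment["n"] = int(len(data))
    fragment["n_dropped_missing"] = int(n_dropped)
    if len(data) < config.subgroup_min_n:
        fragment["reason"] = f"subgroup below floor ({len(data)} < {config.subgroup_min_n})"
        return fragment
    y = data[endpoint].astype(int)
    fragment["events"] = int(y.sum())
    if y.nunique() < 2:
        fragment["reason"] = "single outcome class"
        return fragment
    try:
        feature_z = zscore_normalise(data[spec["feature"]].to_numpy(), spec["feature"])
    except DegenerateFeatureError as exc:
        fragment["reason"] = str(exc)
        return fragment
    design_ref = pd.DataFrame(
        {
            "baseline": _baseline_values(data, spec["baseline"], config).to_numpy(),
            "dose": data[spec["dose"]].to_numpy(),
        }
    )
    design_ext = design_ref.assign(feature=feature_z)
    ref = fit_logistic(design_ref, y.to_numpy())
    ext = fit_logistic(design_ext, y.to_numpy())
    lrt = likelihood_ratio_test(ref, ext)
    score_ref = design_ref.to_numpy() @ ref.params[["baseline", "dose"]].to_numpy()
    score_ext = design_ext.to_numpy() @ ext.params[["baseline", "dose", "feature"]].to_numpy()
    fragment.update(
        evaluable=True,
        converged=bool(ref.converged and ext.converged),
        coefficients_reference={k: float(v) for k, v in ref.params.items()},
        coefficients_extended={k: float(v) for k, v in ext.params.items()},
        auc_reference=auc(score_ref, y.to_numpy()).auc,
        auc_extended=auc(score_ext, y.to_numpy()).auc,
        lrt_statistic=lrt.statistic,
        lrt_df=lrt.df,
        lrt_p=lrt.pvalue,
        significant=bool(lrt.pvalue < config.alpha),
    )
    return fragment


def univariate_table(
    table: pd.DataFrame, config: Optional[PipelineConfig] = None
) -> pd.DataFrame:
    """Wald p-value of each configured predictor per endpoint (whole table).

    Mirrors the layout predictor x endpoint -> p; features are
    z-normalised, dose and baseline enter on their natural scales.
    """
    config = config or PipelineConfig()
    rows = []
    for endpoint, spec in config.endpoint_features.items():
        predictors = {
            spec["dose"]: table[spec["dose"]],
            spec["baseline"]: _baseline_values(table, spec["baseline"], config),
            spec["feature"]: table[spec["feature"]],
        }
        for name, values in predictors.items():
            x = np.asarray(values, dtype=float)
            y = table[endpoint].astype(int).to_numpy()
            keep = ~np.isnan(x)
            entry = {"endpoint": endpoint, "predictor": name, "n": int(keep.sum())}
            try:
                entry["p"] = univariate_association(x[keep], y[keep], name)
            except (DegenerateFeatureError, ValueError) as exc:
                entry["p"] = np.nan
                entry["note"] = str(exc)
            rows.append(entry)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 2D vs 3D agreement


def compare_2d_3d(table: pd.DataFrame) -> dict:
    """Pearson correlation between 2D- and 3D-computed parotid SRE.

    Restricted to artifact-free parotids (no excluded slices), where the
    3D value is defined.  Scatter pairs are kept for the report figure.
    """
    ok = (
        (table["parotid_excluded_fraction"] == 0.0)
        & table["parotid_sre_2d"].notna()
        & table["parotid_sre_3d"].notna()
    )
    pairs = table.loc[ok, ["patient_id", "parotid_sre_2d", "parotid_sre_3d"]]
    result = {"n_glands": int(len(pairs)), "evaluable": False}
    if len(pairs) < 3:
        result["reason"] = f"only {len(pairs)} artifact-free parotids (need >= 3)"
        return result
    r, p = scipy.stats.pearsonr(pairs["parotid_sre_2d"], pairs["parotid_sre_3d"])
    result.update(
        evaluable=True,
        pearson_r=float(r),
        p=float(p),
        scatter=[
            {"patient_id": str(row.patient_id), "sre_2d": float(row.parotid_sre_2d),
             "sre_3d": float(row.parotid_sre_3d)}
            for row in pairs.itertuples()
        ],
    )
    return result


# ---------------------------------------------------------------------------
# report


def run_analysis(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    config: Optional[PipelineConfig] = None,
    seed: Optional[int] = None,
) -> dict:
    """The full statistical analysis on an extracted feature table."""
    config = config or PipelineConfig()
    table = clinical.merge(features, on="patient_id", how="inner", validate="1:1")
    if len(table) < len(clinical):
        log.warning(
            "%d clinical record(s) had no matching feature row", len(clinical) - len(table)
        )
    fragments = []
    for endpoint in config.endpoint_features:
        for subgroup in standard_subgroups(config):
            fragments.append(run_endpoint_analysis(table, endpoint, subgroup, config))
    report = {
        "meta": {
            "package_version": __version__,
            "config_digest": config.digest(),
            "seed": seed,
            "n_patients": int(len(table)),
        },
        "univariate": univariate_table(table, config).to_dict(orient="records"),
        "models": fragments,
        "sre_2d_vs_3d": compare_2d_3d(table),
    }
    return report


def emit_report(report: dict, out_dir) -> Path:
    """Write report.json, univariate.csv and a markdown summary.

    The JSON carries a ``generated_at`` timestamp; everything else is a
    pure function of inputs and configuration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamped = dict(report)
    stamped["generated_at"] = datetime.now(timezone.utc).isoformat()
    with open(out_dir / "report.json", "w") as fh:
        json.dump(stamped, fh, indent=1, default=float)
    uni = pd.DataFrame(report["univariate"])
    uni.to_csv(out_dir / "univariate.csv", index=False)
    lines = ["# Replication analysis report", ""]
    lines += ["## Univariate associations", ""]
    if uni.empty:
        lines.append("_no univariate results_")
    else:
        lines.append(uni.to_markdown(index=False))
    lines += ["", "## Model comparisons (reference vs + feature)", ""]
    for frag in report["models"]:
        if frag.get("evaluable"):
            lines.append(
                f"- **{frag['endpoint']} / {frag['subgroup']}** (n={frag['n']}, "
                f"events={frag['events']}): AUC {frag['auc_reference']:.3f} -> "
                f"{frag['auc_extended']:.3f}, LRT p = {frag['lrt_p']:.3f}"
            )
        else:
            lines.append(
                f"- **{frag['endpoint']} / {frag['subgroup']}**: not evaluable "
                f"({frag.get('reason', 'unknown')})"
            )
    agree = report["sre_2d_vs_3d"]
    lines += ["", "## 2D vs 3D Short Run Emphasis", ""]
    if agree.get("evaluable"):
        lines.append(
            f"Pearson r = {agree['pearson_r']:.3f} on {agree['n_glands']} artifact-free parotids."
        )
    else:
        lines.append(f"Not evaluable ({agree.get('reason', 'unknown')}).")
    (out_dir / "report.md").write_text("\n".join(lines) + "\n")
    return out_dir / "report.json"


def write_exclusion_report(features: pd.DataFrame, path) -> None:
    """Per-patient, per-gland slice-exclusion CSV."""
    rows = []
    for _, row in features.iterrows():
        for gland in GLANDS:
            if not np.isnan(row.get(f"{gland}_n_slices", np.nan)):
                rows.append(
                    {
                        "patient_id": row["patient_id"],
                        "gland": gland,
                        "n_slices": int(row[f"{gland}_n_slices"]),
                        "n_excluded": int(row[f"{gland}_n_excluded"]),
                        "excluded_fraction": row[f"{gland}_excluded_fraction"],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)
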