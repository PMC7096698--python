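"""Study orchestration: per-subject metric extraction and the analysis battery.

The battery mirrors a marker-validation study design:

* **associations** — for each SVD marker, robust regressions of PSMD on the
  marker under two covariate sets (Model 1: head motion; Model 2: head
  motion + sex + age + diagnosis), Holm-corrected across the marker family;
* **importance** — dominance and relative-weights decompositions of R²:
  regions within each marker predicting PSMD, the four global markers
  predicting PSMD, WMH vs brain volumes predicting PSMD (with and without
  diagnosis and cognition as covariates), and PSMD plus the four markers
  predicting cognition (ACE-R);
* **regional matrix** — percentage-bend correlations of every regional PSMD
  with every regional WMH volume, Holm-corrected, with r-to-z contrasts of
  corresponding vs non-corresponding region pairs;
* **ROC battery** — AUC of each score for discriminating cognitive
  impairment (ACE-R < 83), each compared against PSMD with DeLong's test;
  orientation is explicit per score (pathology markers point up, volumes and
  FA point down).

Missingness is handled by listwise deletion per model, with the n used
reported on every output row.  All outputs are plain tidy tables; at a fixed
seed the written CSVs are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as pio
from .cohort import REGIONS, CohortSimParams, generate_cohort
from .lesions import normalize_and_transform, partition_wmh, segment_wmh
from .phantom import PhantomSpec, PhantomVolumes, generate_phantom
from .ratings import SvdRatings, svd_burden_score, validate_ratings
from .skeleton import InsufficientRegion, compute_psmd, compute_regional_psmd
from .stats import (
    delong_compare,
    delong_variance,
    fisher_rz_compare,
    holm_bonferroni,
    importance_analysis,
    robust_correlation,
    robust_fit,
)

logger = logging.getLogger("psmdkit")

#: Table-2-style marker battery: (label, cohort column).
DEFAULT_MARKERS = (
    ("fazekas_pvh", "fazekas_pvh"),
    ("fazekas_dwmh", "fazekas_dwmh"),
    ("fazekas_total", "fazekas_total"),
    ("wmh_volume_pvh", "wmh_pvh_transformed"),
    ("wmh_volume_dwmh", "wmh_dwmh_transformed"),
    ("wmh_volume_total", "wmh_transformed"),
    ("epvs_cso", "epvs_cso"),
    ("epvs_bg", "epvs_bg"),
    ("epvs_midbrain", "epvs_midbrain"),
    ("microbleeds_lobar", "microbleeds_lobar"),
    ("microbleeds_deep", "microbleeds_deep"),
    ("microbleeds_total", "microbleeds_total"),
    ("lacunes_lobar", "lacunes_lobar"),
    ("lacunes_deep", "lacunes_deep"),
    ("lacunes_total", "lacunes_total"),
    ("svd_burden", "svd_burden"),
)

#: ROC battery: (label, column, orientation). +1: larger score = more impaired.
DEFAULT_ROC_SCORES = (
    ("psmd", "psmd", +1),
    ("wmh_volume", "wmh_transformed", +1),
    ("fazekas_total", "fazekas_total", +1),
    ("epvs_bg", "epvs_bg", +1),
    ("microbleeds_total", "microbleeds_total", +1),
    ("lacunes_total", "lacunes_total", +1),
    ("svd_burden", "svd_burden", +1),
    ("gm_volume", "gm_volume", -1),
    ("wm_volume", "wm_volume", -1),
    ("mean_md", "mean_md", +1),
    ("sd_md", "sd_md", +1),
    ("mean_fa", "mean_fa", -1),
    ("sd_fa", "sd_fa", +1),
)


@dataclass
class StudyConfig:
    """Everything one `run_study` needs; covariate sets are fixed by design."""

    sim: CohortSimParams = field(default_factory=CohortSimParams)
    markers: tuple = DEFAULT_MARKERS
    model1_covariates: tuple[str, ...] = ("head_motion",)
    model2_covariates: tuple[str, ...] = ("head_motion", "sex", "age", "diagnosis")
    regional: bool = True
    roc_scores: tuple = DEFAULT_ROC_SCORES
    acer_cutoff: float = 83.0
    alpha: float = 0.05
    min_complete_cases: int = 20
    imaging_substudy_n: int = 0
    seed: int = 0

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = dataclasses.asdict(self.sim)
        return d


def load_study_config(path: str) -> StudyConfig:
    raw = pio.load_yaml(path)
    sim = CohortSimParams(**raw.pop("sim", {}))
    if "markers" in raw:
        raw["markers"] = tuple(tuple(m) for m in raw["markers"])
    if "roc_scores" in raw:
        raw["roc_scores"] = tuple(tuple(s) for s in raw["roc_scores"])
    for key in ("model1_covariates", "model2_covariates"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return StudyConfig(sim=sim, **raw)


# ---------------------------------------------------------------------------
# design-matrix helper
# ---------------------------------------------------------------------------

def _design_matrix(df: pd.DataFrame, columns: tuple[str, ...]):
    """Numeric design matrix: categoricals expand to treatment dummies
    (reference: 'control' for diagnosis, 'female' for sex)."""
    blocks, names = [], []
    for col in columns:
        s = df[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            if col == "sex":
                blocks.append((s == "male").astype(float).to_numpy())
                names.append("sex_male")
            else:
                levels = [lv for lv in sorted(s.unique()) if lv != "control"]
                for lv in levels:
                    blocks.append((s == lv).astype(float).to_numpy())
                    names.append(f"{col}_{lv}")
        else:
            blocks.append(s.to_numpy(dtype=float))
            names.append(col)
    return np.column_stack(blocks), names


def _complete_cases(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    return df.dropna(subset=[c for c in columns if c in df.columns])


# ---------------------------------------------------------------------------
# batteries
# ---------------------------------------------------------------------------

def run_association_battery(
    cohort: pd.DataFrame, config: StudyConfig | None = None
) -> pd.DataFrame:
    """Robust regressions of PSMD on each marker under Models 1 and 2.

    Per marker and model: listwise deletion, Huber IRLS fit of
    ``psmd ~ marker + covariates``, and the marker term's t and p.  Holm
    correction is applied across the marker family within each model.
    """
    config = config or StudyConfig()
    rows = []
    for model_name, covariates in (
        ("model1", config.model1_covariates),
        ("model2", config.model2_covariates),
    ):
        for label, column in config.markers:
            needed = ["psmd", column, *covariates]
            data = _complete_cases(cohort, needed)
            n = len(data)
            if n < config.min_complete_cases:
                logger.warning(
                    "skipping %s under %s: only %d complete cases", label, model_name, n
                )
                continue
            X, names = _design_matrix(data, (column, *covariates))
            fit = robust_fit(data["psmd"].to_numpy(), X, names=names)
            i = fit.names.index(column)
            rows.append(
                {
                    "marker": label,
                    "model": model_name,
                    "n": n,
                    "beta": fit.params[i],
                    "t": fit.tvalues[i],
                    "p": fit.pvalues[i],
                    "converged": fit.converged,
                    "covariates": "+".join(covariates),
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    for model_name in out["model"].unique():
        sel = out["model"] == model_name
        adj, rej = holm_bonferroni(out.loc[sel, "p"].to_numpy(), alpha=config.alpha)
        out.loc[sel, "p_holm"] = adj
        out.loc[sel, "significant"] = rej
    return out


_IMPORTANCE_TABLES = {
    "regional_wmh_fazekas": ("psmd", ["fazekas_pvh", "fazekas_dwmh"]),
    "regional_wmh_volume": ("psmd", ["wmh_pvh_transformed", "wmh_dwmh_transformed"]),
    "regional_epvs": ("psmd", ["epvs_cso", "epvs_bg", "epvs_midbrain"]),
    "regional_microbleeds": ("psmd", ["microbleeds_lobar", "microbleeds_deep"]),
    "regional_lacunes": ("psmd", ["lacunes_lobar", "lacunes_deep"]),
    "four_markers": (
        "psmd",
        ["wmh_transformed", "epvs_bg", "microbleeds_total", "lacunes_total"],
    ),
    "svd_vs_neurodegeneration": (
        "psmd",
        ["wmh_transformed", "gm_volume", "wm_volume"],
    ),
    "cognition": (
        "acer",
        ["psmd", "wmh_transformed", "epvs_bg", "microbleeds_total", "lacunes_total"],
    ),
}


def run_importance_battery(
    cohort: pd.DataFrame, config: StudyConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Dominance + relative-weights tables for the standard model set.

    The adjusted SVD-vs-neurodegeneration model additionally conditions on
    diagnosis and cognition by including them as predictors in the
    decomposition.
    """
    config = config or StudyConfig()
    tables: dict[str, pd.DataFrame] = {}
    jobs = dict(_IMPORTANCE_TABLES)
    for name, (outcome, predictors) in jobs.items():
        data = _complete_cases(cohort, [outcome, *predictors])
        res = importance_analysis(
            data[outcome].to_numpy(),
            data[predictors].to_numpy(dtype=float),
            names=list(predictors),
        )
        frame = res.to_frame()
        frame.insert(0, "outcome", outcome)
        frame["n"] = len(data)
        frame["r_squared"] = res.r_squared
        tables[name] = frame

    # adjusted variant: diagnosis dummies + ACE-R enter the decomposition
    outcome, predictors = _IMPORTANCE_TABLES["svd_vs_neurodegeneration"]
    needed = [outcome, *predictors, "diagnosis", "acer"]
    data = _complete_cases(cohort, needed)
    X, names = _design_matrix(data, (*predictors, "diagnosis", "acer"))
    res = importance_analysis(data[outcome].to_numpy(), X, names=names)
    frame = res.to_frame()
    frame.insert(0, "outcome", outcome)
    frame["n"] = len(data)
    frame["r_squared"] = res.r_squared
    tables["svd_vs_neurodegeneration_adjusted"] = frame
    return tables


def run_regional_matrix(
    cohort: pd.DataFrame, config: StudyConfig | None = None
) -> pd.DataFrame:
    """Robust correlation of every regional PSMD × regional WMH volume pair.

    Holm correction spans all pairs; each off-diagonal cell also carries a
    Fisher r-to-z contrast against the corresponding-region cell of the same
    PSMD region (diffuse pathology predicts mostly non-significant
    contrasts).
    """
    config = config or StudyConfig()
    rows = []
    r_lookup: dict[tuple[str, str], tuple[float, int]] = {}
    for pr in REGIONS:
        for wr in REGIONS:
            pcol, wcol = f"psmd_{pr}", f"wmh_transformed_{wr}"
            if pcol not in cohort.columns or wcol not in cohort.columns:
                logger.warning("regional pair (%s, %s) missing; skipped", pr, wr)
                continue
            data = _complete_cases(cohort, [pcol, wcol])
            r, p = robust_correlation(data[pcol].to_numpy(), data[wcol].to_numpy())
            r_lookup[(pr, wr)] = (r, len(data))
            rows.append(
                {"psmd_region": pr, "wmh_region": wr, "r": r, "p": p, "n": len(data)}
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    adj, rej = holm_bonferroni(out["p"].to_numpy(), alpha=config.alpha)
    out["p_holm"] = adj
    out["significant"] = rej
    z_list, pz_list = [], []
    for row in out.itertuples(index=False):
        if row.psmd_region == row.wmh_region:
            z_list.append(np.nan)
            pz_list.append(np.nan)
            continue
        r_corr, n_corr = r_lookup[(row.psmd_region, row.psmd_region)]
        z, pz = fisher_rz_compare(r_corr, n_corr, row.r, row.n)
        z_list.append(z)
        pz_list.append(pz)
    out["z_vs_corresponding"] = z_list
    out["p_vs_corresponding"] = pz_list
    return out


def run_roc_battery(
    cohort: pd.DataFrame, config: StudyConfig | None = None
) -> pd.DataFrame:
    """AUC of each score for ACE-R-defined impairment, DeLong-tested vs PSMD.

    Impairment label: ACE-R < cutoff (default 83).  Each score is multiplied
    by its configured orientation before the AUC so that larger always means
    "more impaired"; the orientation is recorded per row.
    """
    config = config or StudyConfig()
    labels_all = cohort["acer"] < config.acer_cutoff
    rows = []
    psmd_col = dict((lbl, (col, ori)) for lbl, col, ori in config.roc_scores)["psmd"]
    for label, column, orientation in config.roc_scores:
        data = _complete_cases(cohort, [column, psmd_col[0], "acer"])
        y = (data["acer"] < config.acer_cutoff).to_numpy()
        if y.all() or not y.any():
            raise ValueError("both impairment classes must be present")
        score = orientation * data[column].to_numpy(dtype=float)
        auc, var = delong_variance(score, y)
        psmd_score = psmd_col[1] * data[psmd_col[0]].to_numpy(dtype=float)
        cmp = delong_compare(psmd_score, score, y)
        crit = 1.959963984540054
        rows.append(
            {
                "score": label,
                "orientation": orientation,
                "n": len(data),
                "n_impaired": int(y.sum()),
                "auc": auc,
                "ci_low": auc - crit * np.sqrt(var),
                "ci_high": auc + crit * np.sqrt(var),
                "auc_psmd": cmp.auc_a,
                "z_vs_psmd": cmp.z,
                "p_vs_psmd": cmp.p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-subject extraction from volumes
# ---------------------------------------------------------------------------

def extract_subject_metrics(
    volumes: PhantomVolumes,
    ratings: SvdRatings | None = None,
    covariates: dict | None = None,
    fa_threshold: float = 0.2,
    k: float = 1.40,
    pv_distance_mm: float = 10.0,
    min_region_voxels: int = 100,
) -> dict:
    """One fully populated subject record from template-space volumes.

    Composes the skeleton peak-width analysis, WMH segmentation/partition and
    the rating schema; every derived field is recomputable from the inputs.
    Input hashes and parameters are logged for provenance.
    """
    for name, arr in (
        ("md", volumes.bundle.md),
        ("flair", volumes.flair),
    ):
        logger.info(
            "extract_subject_metrics input %s sha256=%s",
            name,
            hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16],
        )
    logger.info(
        "extract_subject_metrics params fa_threshold=%s k=%s pv_distance_mm=%s",
        fa_threshold,
        k,
        pv_distance_mm,
    )
    record: dict = dict(covariates or {})

    res = compute_psmd(volumes.bundle, fa_threshold)
    record.update(
        psmd=res.psmd,
        psmd_p95=res.p95,
        psmd_p5=res.p5,
        skeleton_n_voxels=res.n_voxels,
        mean_md=res.mean_md,
        sd_md=res.sd_md,
        mean_fa=res.mean_fa,
        sd_fa=res.sd_fa,
    )
    regional = compute_regional_psmd(
        volumes.bundle, volumes.atlas, fa_threshold, min_voxels=min_region_voxels
    )
    for region, rres in regional.items():
        record[f"psmd_{region}"] = (
            np.nan if isinstance(rres, InsufficientRegion) else rres.psmd
        )

    seg = segment_wmh(
        volumes.flair, volumes.brain_mask, k=k, voxel_size_mm=volumes.spec.voxel_size_mm
    )
    partition_wmh(
        seg,
        volumes.ventricle_mask,
        volumes.atlas,
        pv_distance_mm=pv_distance_mm,
        voxel_size_mm=volumes.spec.voxel_size_mm,
    )
    record.update(
        wmh_total_mm3=seg.total_volume,
        wmh_pvh_mm3=seg.pvh_volume,
        wmh_dwmh_mm3=seg.dwmh_volume,
        wmh_modal_intensity=seg.modal_intensity,
        wmh_threshold=seg.threshold,
    )
    for region, vol in (seg.lobar_volumes or {}).items():
        record[f"wmh_mm3_{region}"] = vol
    tiv = record.get("tiv")
    if tiv is None:
        tiv = float(volumes.brain_mask.sum()) * volumes.bundle.voxel_volume_mm3
        record["tiv"] = tiv
    normalized, transformed = normalize_and_transform(seg.total_volume, tiv)
    record["wmh_norm"] = normalized
    record["wmh_transformed"] = transformed

    if ratings is not None:
        validate_ratings(ratings)
        burden = svd_burden_score(ratings)
        record.update(
            fazekas_pvh=_nan_if_none(ratings.fazekas_pvh),
            fazekas_dwmh=_nan_if_none(ratings.fazekas_dwmh),
            epvs_cso=_nan_if_none(ratings.epvs_cso),
            epvs_bg=_nan_if_none(ratings.epvs_bg),
            epvs_midbrain=_nan_if_none(ratings.epvs_midbrain),
            microbleeds_lobar=_nan_if_none(ratings.microbleeds_lobar),
            microbleeds_deep=_nan_if_none(ratings.microbleeds_deep),
            microbleeds_total=_nan_if_none(ratings.microbleeds_total),
            lacunes_lobar=_nan_if_none(ratings.lacunes_lobar),
            lacunes_deep=_nan_if_none(ratings.lacunes_deep),
            lacunes_total=_nan_if_none(ratings.lacunes_total),
            svd_burden=_nan_if_none(burden),
        )
    return record


def _nan_if_none(v):
    return np.nan if v is None else v


# ---------------------------------------------------------------------------
# end-to-end study
# ---------------------------------------------------------------------------

_CSV_FLOAT_FORMAT = "%.10g"


def _write_csv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)


def run_study(config: StudyConfig, out_dir: str) -> dict[str, pd.DataFrame]:
    """Generate a cohort, run the full battery, write deterministic CSVs.

    The study seed overrides the simulation seed so one integer pins the
    whole run.  Timestamps appear only in ``run_log.txt``; every CSV is a
    pure function of (config, seed).
    """
    os.makedirs(out_dir, exist_ok=True)
    sim = dataclasses.replace(config.sim, seed=config.seed)
    cohort = generate_cohort(sim)

    results: dict[str, pd.DataFrame] = {"subjects": cohort}
    results["associations"] = run_association_battery(cohort, config)
    for name, table in run_importance_battery(cohort, config).items():
        results[f"importance_{name}"] = table
    if config.regional:
        results["regional_matrix"] = run_regional_matrix(cohort, config)
    results["roc_comparison"] = run_roc_battery(cohort, config)

    if config.imaging_substudy_n > 0:
        results["subjects_imaging"] = _imaging_substudy(cohort, config)

    log_lines = [f"run_study completed at {time.strftime('%Y-%m-%dT%H:%M:%S')}"]
    for name, df in results.items():
        _write_csv(df, os.path.join(out_dir, f"{name}.csv"))
        log_lines.append(f"{name}.csv: {len(df)} rows")
    pio.dump_yaml(config.resolved(), os.path.join(out_dir, "config_resolved.yaml"))
    with open(os.path.join(out_dir, "run_log.txt"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return results


def _imaging_substudy(cohort: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Phantom round trip for the first k subjects: plant the tabulated PSMD
    and a lesion matching the tabulated WMH volume, re-extract both."""
    rows = []
    n = min(config.imaging_substudy_n, len(cohort))
    for i in range(n):
        row = cohort.iloc[i]
        target = float(row["psmd"])
        wmh_mm3 = float(row["wmh_total_mm3"]) if np.isfinite(row["wmh_total_mm3"]) else 0.0
        blobs = []
        if wmh_mm3 > 0:
            radius = min((3.0 * wmh_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0), 10.0)
            blobs.append(((42, 32, 32), radius, 1.6))
        spec = PhantomSpec(
            grid_shape=(64, 64, 64),
            target_psmd=target,
            skeleton_fraction=0.10,
            lesion_blobs=blobs,
            seed=int(config.seed * 100003 + i) % (2**31 - 1),
        )
        volumes = generate_phantom(spec)
        record = extract_subject_metrics(volumes, covariates={"tiv": float(row["tiv"])})
        rows.append(
            {
                "subject_id": row["subject_id"],
                "planted_psmd": target,
                "recovered_psmd": record["psmd"],
                "planted_wmh_mm3": float(volumes.planted_lesion_mask.sum())
                * volumes.bundle.voxel_volume_mm3,
                "recovered_wmh_mm3": record["wmh_total_mm3"],
                "skeleton_n_voxels": record["skeleton_n_voxels"],
            }
        )
    return pd.DataFrame(rows)
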