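"""Synthetic subject cohorts with the dependence structure the analyses assume.

One latent per-subject SVD severity drives all four marker classes — WMH
volume (log-normal), microbleed and lacune counts (negative binomial, i.e.
gamma-mixed Poisson, to reproduce the heavy overdispersion of real counts),
and EPVS grades (thresholded latent) — each loading on the latent with
``marker_correlation``.  PSMD is then a linear function of normalized WMH,
microbleed count and head motion plus Gaussian noise, and cognition (ACE-R)
is a linear function of PSMD and grey-matter volume plus noise, truncated to
[0, 100]; MMSE derives from ACE-R.  Diagnostic groups act as additive shifts
on the latent severity and on ACE-R, and head motion is a positive scalar
correlated with the latent severity, reproducing the confounding that the
head-motion covariate adjusts for downstream.

Setting every effect slope to zero yields null cohorts in which PSMD is pure
noise — the substrate for type-I-error checks of the downstream tests.

Default magnitudes are anchored to a 145-subject memory-clinic cohort:
WMH 0.69 ± 0.71 %TIV, microbleeds 1.44 ± 6.3, lacunes 0.86 ± 2.7,
GM 39.0 ± 2.9 %TIV, WM 32.3 ± 2.7 %TIV, PSMD ≈ 5.5e-4 ± 1.0e-4 mm²/s,
ACE-R 79.4 ± 15.0, age 70.6 ± 7.8, 60.7% male, with diagnostic groups
(control/MCI/AD/PSP/DLB/depression/FTD) in proportions 33:20:16:23:26:6:21.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DIAGNOSIS_GROUPS = ("control", "mci", "ad", "psp", "dlb", "depression", "ftd")
_DEFAULT_PROPORTIONS = tuple(n / 145.0 for n in (33, 20, 16, 23, 26, 6, 21))

#: additive shifts on the latent severity (z units) per diagnostic group
_SEVERITY_SHIFT = {
    "control": -0.6,
    "mci": 0.0,
    "ad": 0.3,
    "psp": 0.35,
    "dlb": 0.35,
    "depression": 0.0,
    "ftd": 0.3,
}
#: additive shifts on ACE-R (points) per diagnostic group
_ACER_SHIFT = {
    "control": 8.0,
    "mci": -2.0,
    "ad": -10.0,
    "psp": -8.0,
    "dlb": -9.0,
    "depression": -1.0,
    "ftd": -9.0,
}

#: the eight lobar regions shared with the phantom atlas
REGIONS = (
    "left_frontal",
    "left_parietal",
    "left_temporal",
    "left_occipital",
    "right_frontal",
    "right_parietal",
    "right_temporal",
    "right_occipital",
)


@dataclass
class CohortSimParams:
    """Generative parameters of one synthetic cohort.

    Slopes are on natural scales: ``effect_wmh_on_psmd`` in (mm²/s) per %TIV
    of normalized WMH volume, ``effect_mb_on_psmd`` in (mm²/s) per microbleed,
    ``effect_motion_on_psmd`` in (mm²/s) per motion unit,
    ``effect_psmd_on_acer`` in ACE-R points per (mm²/s), ``effect_gm_on_acer``
    in points per %TIV of GM.  ``marker_correlation`` is the loading of each
    marker on the shared latent severity.
    """

    n_subjects: int = 145
    effect_wmh_on_psmd: float = 9.0e-5
    effect_mb_on_psmd: float = 2.0e-6
    effect_motion_on_psmd: float = 3.0e-5
    effect_psmd_on_acer: float = -6.0e4
    effect_gm_on_acer: float = 1.2
    noise_sd_psmd: float = 5.0e-5
    noise_sd_acer: float = 8.0
    marker_correlation: float = 0.6
    motion_severity_corr: float = 0.2
    group_proportions: tuple[float, ...] = _DEFAULT_PROPORTIONS
    mb_dispersion: float = 0.054
    lacune_dispersion: float = 0.115
    psmd_intercept: float = 4.5e-4
    acer_intercept: float = 76.0
    n_missing_swi: int = 0
    n_missing_wmh_volume: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        for name in ("noise_sd_psmd", "noise_sd_acer"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise ValueError("group_proportions must sum to 1")
        if len(self.group_proportions) != len(DIAGNOSIS_GROUPS):
            raise ValueError(
                f"group_proportions needs {len(DIAGNOSIS_GROUPS)} entries"
            )
        if not 0.0 <= self.marker_correlation <= 1.0:
            raise ValueError("marker_correlation must lie in [0, 1]")
        if not (0 <= self.n_missing_swi <= self.n_subjects):
            raise ValueError("n_missing_swi out of range")
        if not (0 <= self.n_missing_wmh_volume <= self.n_subjects):
            raise ValueError("n_missing_wmh_volume out of range")


def _neg_binomial(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-mixed Poisson with Var = m + m²/k (k = dispersion parameter)."""
    lam = mean * rng.gamma(shape=dispersion, scale=1.0 / dispersion, size=mean.shape)
    return rng.poisson(lam)


def _graded(latent: np.ndarray, cutpoints: list[float]) -> np.ndarray:
    return np.searchsorted(np.asarray(cutpoints), latent, side="right").astype(int)


def generate_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Simulate a cohort table; identical params reproduce identical tables.

    Column dictionary (units): ``psmd`` and ``psmd_<region>`` mm²/s;
    ``wmh_norm``/``wmh_pvh_norm``/``wmh_dwmh_norm``/``wmh_norm_<region>``
    %TIV; ``wmh_transformed*`` sqrt(%TIV); ``wmh_total_mm3`` mm³;
    ``gm_volume``/``wm_volume`` %TIV; ``tiv`` mm³; ``fazekas_*`` 0–3;
    ``epvs_cso``/``epvs_bg`` 0–4; ``epvs_midbrain`` 0/1; ``microbleeds_*``,
    ``lacunes_*`` counts; ``svd_burden`` 0–4; ``mean_md`` mm²/s; ``mean_fa``
    dimensionless; ``acer`` 0–100; ``mmse`` 0–30; ``age`` years; ``sex``
    {male, female}; ``diagnosis`` category; ``head_motion`` a.u. (positive).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_subjects
    a = params.marker_correlation
    a_res = math.sqrt(max(0.0, 1.0 - a * a))

    diagnosis = rng.choice(DIAGNOSIS_GROUPS, size=n, p=params.group_proportions)
    severity_shift = np.array([_SEVERITY_SHIFT[d] for d in diagnosis])
    latent = rng.normal(size=n) + severity_shift

    age = np.clip(rng.normal(70.6, 7.8, size=n), 45.0, 95.0)
    sex = np.where(rng.random(n) < 0.607, "male", "female")
    tiv = rng.normal(1.45e6, 1.2e5, size=n)

    # head motion: positive scalar correlated with latent severity
    rho = params.motion_severity_corr
    motion_lat = rho * latent + math.sqrt(max(0.0, 1.0 - rho * rho)) * rng.normal(size=n)
    head_motion = np.exp(0.3 * motion_lat)

    # --- WMH volume: log-normal around 0.69 %TIV (right-skewed) ------------
    wmh_lat = a * latent + a_res * rng.normal(size=n)
    wmh_norm = np.exp(-0.731 + 0.85 * wmh_lat)  # mean ~0.69, SD ~0.71 %TIV
    wmh_total_mm3 = wmh_norm / 100.0 * tiv
    pvh_frac = np.clip(rng.normal(0.60, 0.10, size=n), 0.05, 0.95)
    wmh_pvh_norm = pvh_frac * wmh_norm
    wmh_dwmh_norm = wmh_norm - wmh_pvh_norm
    region_shares = rng.dirichlet(alpha=np.full(len(REGIONS), 4.0), size=n)

    # --- counts: negative binomial driven by the latent ---------------------
    mb_mean = 1.44 * np.exp(1.0 * a * latent - 0.5 * a * a)
    microbleeds_total = _neg_binomial(rng, mb_mean, params.mb_dispersion)
    microbleeds_lobar = rng.binomial(microbleeds_total, 0.6)
    microbleeds_deep = microbleeds_total - microbleeds_lobar
    lac_mean = 0.86 * np.exp(1.0 * a * latent - 0.5 * a * a)
    lacunes_total = _neg_binomial(rng, lac_mean, params.lacune_dispersion)
    lacunes_lobar = rng.binomial(lacunes_total, 0.55)
    lacunes_deep = lacunes_total - lacunes_lobar

    # --- ordinal ratings -----------------------------------------------------
    epvs_bg = _graded(a * latent + a_res * rng.normal(size=n), [-0.85, 0.85, 2.0, 3.0])
    epvs_cso = _graded(a * latent + a_res * rng.normal(size=n), [-0.85, 0.85, 2.0, 3.0])
    epvs_midbrain = (a * latent + a_res * rng.normal(size=n) > 1.2).astype(int)
    log_wmh = np.log(wmh_norm)
    fazekas_pvh = _graded(log_wmh + rng.normal(0, 0.35, size=n), [-1.8, -0.4, 0.8])
    fazekas_dwmh = _graded(log_wmh + rng.normal(0, 0.35, size=n), [-1.6, -0.1, 1.0])

    # --- brain volumes (atrophy tracks severity) -----------------------------
    gm_volume = 39.0 - 1.2 * latent + rng.normal(0, 2.5, size=n)
    wm_volume = 32.3 - 0.8 * latent + rng.normal(0, 2.4, size=n)

    # --- PSMD ----------------------------------------------------------------
    psmd = (
        params.psmd_intercept
        + params.effect_wmh_on_psmd * wmh_norm
        + params.effect_mb_on_psmd * microbleeds_total
        + params.effect_motion_on_psmd * head_motion
        + rng.normal(0, params.noise_sd_psmd, size=n)
    )
    regional_psmd = psmd[:, None] + rng.normal(0, 0.3e-4, size=(n, len(REGIONS)))

    # companion diffusion summaries, correlated with the peak width
    mean_md = 6.2e-4 + 0.25 * psmd + rng.normal(0, 2.0e-5, size=n)
    sd_md = psmd / 3.4 + rng.normal(0, 1.0e-5, size=n)
    mean_fa = np.clip(0.49 - 200.0 * (psmd - 5.5e-4), 0.2, 0.8) + rng.normal(
        0, 0.02, size=n
    )
    sd_fa = np.clip(0.12 + 100.0 * (psmd - 5.5e-4), 0.05, 0.3) + rng.normal(
        0, 0.01, size=n
    )

    # --- cognition ------------------------------------------------------------
    acer_shift = np.array([_ACER_SHIFT[d] for d in diagnosis])
    acer_linear = (
        params.acer_intercept
        + params.effect_psmd_on_acer * (psmd - 5.5e-4)
        + params.effect_gm_on_acer * (gm_volume - 39.0)
        + acer_shift
    )
    acer = np.clip(acer_linear + rng.normal(0, params.noise_sd_acer, size=n), 0.0, 100.0)
    mmse = np.clip(acer * 0.3 + rng.normal(0, 1.0, size=n), 0.0, 30.0)

    burden = (
        ((fazekas_pvh == 3) | (fazekas_dwmh >= 2)).astype(int)
        + (epvs_bg >= 2).astype(int)
        + (lacunes_total >= 1).astype(int)
        + (microbleeds_total >= 1).astype(int)
    )

    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:04d}" for i in range(n)],
            "diagnosis": diagnosis,
            "age": age,
            "sex": sex,
            "head_motion": head_motion,
            "tiv": tiv,
            "gm_volume": gm_volume,
            "wm_volume": wm_volume,
            "psmd": psmd,
            "mean_md": mean_md,
            "sd_md": sd_md,
            "mean_fa": mean_fa,
            "sd_fa": sd_fa,
            "wmh_total_mm3": wmh_total_mm3,
            "wmh_norm": wmh_norm,
            "wmh_transformed": np.sqrt(wmh_norm),
            "wmh_pvh_norm": wmh_pvh_norm,
            "wmh_pvh_transformed": np.sqrt(wmh_pvh_norm),
            "wmh_dwmh_norm": wmh_dwmh_norm,
            "wmh_dwmh_transformed": np.sqrt(wmh_dwmh_norm),
            "fazekas_pvh": fazekas_pvh,
            "fazekas_dwmh": fazekas_dwmh,
            "fazekas_total": fazekas_pvh + fazekas_dwmh,
            "epvs_cso": epvs_cso,
            "epvs_bg": epvs_bg,
            "epvs_midbrain": epvs_midbrain,
            "microbleeds_lobar": microbleeds_lobar.astype(float),
            "microbleeds_deep": microbleeds_deep.astype(float),
            "microbleeds_total": microbleeds_total.astype(float),
            "lacunes_lobar": lacunes_lobar,
            "lacunes_deep": lacunes_deep,
            "lacunes_total": lacunes_total,
            "svd_burden": burden.astype(float),
            "acer": acer,
            "mmse": mmse,
            "acer_linear": acer_linear,  # pre-truncation linear predictor (provenance)
        }
    )
    for j, region in enumerate(REGIONS):
        table[f"psmd_{region}"] = regional_psmd[:, j]
        table[f"wmh_norm_{region}"] = region_shares[:, j] * wmh_norm
        table[f"wmh_transformed_{region}"] = np.sqrt(region_shares[:, j] * wmh_norm)

    # --- missingness (modality absent, not zero) ------------------------------
    if params.n_missing_swi:
        idx = rng.choice(n, size=params.n_missing_swi, replace=False)
        for col in ("microbleeds_lobar", "microbleeds_deep", "microbleeds_total"):
            table.loc[idx, col] = np.nan
        table.loc[idx, "svd_burden"] = np.nan
    if params.n_missing_wmh_volume:
        idx = rng.choice(n, size=params.n_missing_wmh_volume, replace=False)
        wmh_cols = [c for c in table.columns if c.startswith("wmh_")]
        table.loc[idx, wmh_cols] = np.nan
    return table
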