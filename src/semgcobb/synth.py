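"""Synthetic cohort generator calibrated to the study's printed cohort statistics.

The generator emulates the study design — 143 adolescent idiopathic
scoliosis patients, four Schroth exercise holds of ~20 s recorded at
1,000 Hz over eight muscles, at weeks 0/8/16/24 — and the statistical
structure the downstream analysis assumes:

* patient descriptors drawn from truncated normals whose *truncated*
  means are solved to hit the cohort targets (age 14.6 y, BMI 17.29, ...);
* lumbar/thoracic Cobb angles at baseline, multiplied by a per-patient
  improvement ratio calibrated so the week-24 lumbar mean/sd land on the
  cohort values (15.28 -> 9.53 deg); trajectories linear in week;
* per-channel EMG amplitude targets in which the convex-side member of
  each bilateral pair exceeds the concave side by a factor
  1 + gain * (regional Cobb), so paraspinal asymmetry (PMSI) carries a
  learnable Cobb signal;
* raw signals as band-limited Gaussian noise at the target RMS plus
  sub-20 Hz motion-artifact and >400 Hz high-frequency contamination, so
  band-pass filtering is consequential.

Everything is deterministic given (SimParams, seed): per-patient and
per-recording random streams are derived from ``numpy.random.SeedSequence``
keyed by the seed and stable patient identifiers.

A note on the erector spinae calibration: the three printed erector
spinae statistics (concave RMS 25.56 +/- 7.83 uV, convex 38.57 +/- 7.43 uV,
PMSI 1.37 +/- 0.19) are jointly infeasible as population moments — with
those standard deviations the covariance needed between the concave
level and the asymmetry ratio exceeds its Cauchy-Schwarz bound.  The
generator reproduces all three *means* exactly (via a strong positive
level-asymmetry correlation) and lets the erector spinae PMSI spread
land near 0.5; see docs/methods.md.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy import signal as sps

from .cohort import (
    EXERCISES,
    MEASUREMENT_WEEKS,
    MUSCLE_PAIRS,
    PAIR_REGION,
    Cohort,
    EMGRecording,
    ExerciseType,
    MuscleChannel,
    OutcomeMeasures,
    OutcomePanel,
    PatientStatic,
)
from .preprocess import FilterSpec

# Latent-noise truncation bound (standard normal units) for the
# multiplicative asymmetry noise; keeps amplitude tails physiological.
_NU_BOUND = 2.5

# multiplicative asymmetry-noise scale of the erector spinae pair; large by
# design — it provides the ratio spread the printed mean structure demands
_ES_NOISE = 1.3

# physiological clip range for any convex/concave amplitude ratio
_R_CLIP = (0.2, 3.5)


@dataclass(frozen=True)
class SimParams:
    """Generator parameters; defaults are the study's cohort statistics."""

    n_patients: int = 143
    seed: int = 0
    duration_s: float = 20.0
    sample_rate_hz: float = 1000.0
    # statics
    age_mean: float = 14.6
    age_sd: float = 2.7
    frac_female: float = 0.46
    bmi_mean: float = 17.29
    bmi_sd: float = 1.23
    risser_mean: float = 1.52
    risser_sd: float = 1.21
    frac_left_curve: float = 0.647
    # Cobb angles (degrees)
    cobbT0_mean: float = 19.12
    cobbT0_sd: float = 5.95
    cobbL0_mean: float = 15.28
    cobbL0_sd: float = 6.71
    cobbL24_mean: float = 9.53
    cobbL24_sd: float = 4.21
    # thoracic post-treatment cell is not reported; default = the lumbar
    # relative reduction (1 - 9.53/15.28)
    cobbT_reduction_frac: float = 0.376
    # erector spinae EMG amplitude targets (uV)
    rms_concave_mean: float = 25.56
    rms_concave_sd: float = 7.83
    rms_convex_mean: float = 38.57
    rms_convex_sd: float = 7.43  # not jointly attainable; see module docstring
    pmsi_mean: float = 1.37
    # PMSI-Cobb coupling, per degree of regional Cobb.  None -> calibrated
    # so the baseline erector spinae PMSI mean equals pmsi_mean.
    asym_gain: float | None = None
    # signal contamination outside the 20-400 Hz analysis band (RMS, uV)
    artifact_amp: float = 10.0
    hf_noise_amp: float = 4.0
    # per-recording multiplicative RMS jitter (log-sd)
    rec_jitter_sd: float = 0.03
    # outcome noise multipliers
    art_noise_scale: float = 1.0
    srs_noise_scale: float = 1.0
    bst_noise_scale: float = 1.0


# unprinted per-pair constants: concave-side mean RMS level (uV), level sd,
# baseline PMSI mean target and multiplicative asymmetry noise scale.
# The erector spinae entries are overridden by the moment calibration.
_PAIR_LEVELS = {
    "erector_spinae": {"level": 25.56, "level_sd": 7.83, "pmsi0": 1.37, "noise": None},
    "multifidus": {"level": 20.0, "level_sd": 5.0, "pmsi0": 1.30, "noise": 0.18},
    "rectus_abdominis": {"level": 10.0, "level_sd": 2.5, "pmsi0": 1.25, "noise": 0.18},
    "external_oblique": {"level": 13.0, "level_sd": 3.0, "pmsi0": 1.25, "noise": 0.18},
}

# cohort outcome anchors: (baseline mean, baseline sd, week-24 mean, week-24 sd)
_OUTCOME_ANCHORS = {
    "art_T": (8.97, 2.58, 3.64, 2.10),
    "art_L": (4.36, 2.65, 2.23, 1.97),
    "srs22": (3.25, 0.32, 4.54, 0.26),
    "bst": (88.34, 35.17, 109.85, 43.67),
}

# linear coupling of each noisy outcome to the regional Cobb deviation;
# SRS-22 and ART-L are deliberately (near-)decoupled so they stay poorly
# predictable, mirroring the study's finding.
_OUTCOME_COUPLING = {"art_T": ("cobb_T", 0.30), "art_L": ("cobb_L", 0.05),
                     "srs22": (None, 0.0), "bst": ("cobb_T", -2.5)}


def _crc(pid: str) -> int:
    return zlib.crc32(pid.encode())


def _rng(*keys: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(list(keys))))


def _trunc_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Parent location of a truncated normal whose truncated mean hits target."""
    if sd == 0:
        return target_mean

    def f(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    lo_b, hi_b = target_mean - 4 * sd, target_mean + 4 * sd
    return float(optimize.brentq(f, lo_b, hi_b, xtol=1e-10))


def _trunc_stats(loc: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    a, b = (lo - loc) / sd, (hi - loc) / sd
    m, v = stats.truncnorm.stats(a, b, loc=loc, scale=sd, moments="mv")
    return float(m), float(v)


def _draw_trunc(rng, loc, sd, lo, hi, size=None):
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


@dataclass(frozen=True)
class _Calib:
    """Derived constants solved from SimParams (deterministic, no RNG)."""

    age_loc: float
    bmi_loc: float
    risser_loc: float
    cobbT0_loc: float
    cobbL0_loc: float
    cobbT0_m: float
    cobbT0_v: float
    cobbL0_m: float
    cobbL0_v: float
    rhoL_mean: float
    rhoL_sd: float
    rhoT_mean: float
    rhoT_sd: float
    pair_gain: dict  # pair -> per-degree asymmetry gain
    pair_noise: dict  # pair -> multiplicative noise scale s (Lambda = 1 + s*u)
    es_alpha: float  # rank-correlation weight of the concave level on the ratio
    es_r_grid: np.ndarray  # quantile grid of the baseline ES ratio (for normal scores)
    es_q_grid: np.ndarray
    es_z_mean: float
    nu_var: float  # variance of the truncated standard normal u


@lru_cache(maxsize=32)
def _calibrate(params: SimParams) -> _Calib:
    p = params
    age_loc = _trunc_loc(p.age_mean, p.age_sd, 10.0, 18.0)
    bmi_loc = _trunc_loc(p.bmi_mean, p.bmi_sd, 1e-6, np.inf)
    risser_loc = _trunc_loc(p.risser_mean, p.risser_sd, 0.0, 5.0)
    cobbT0_loc = _trunc_loc(p.cobbT0_mean, p.cobbT0_sd, 10.0, 40.0)
    cobbL0_loc = _trunc_loc(p.cobbL0_mean, p.cobbL0_sd, 5.0, 40.0)
    mT, vT = _trunc_stats(cobbT0_loc, p.cobbT0_sd, 10.0, 40.0)
    mL, vL = _trunc_stats(cobbL0_loc, p.cobbL0_sd, 5.0, 40.0)

    # improvement ratio rho (week-24 = rho * baseline), independent of the
    # baseline draw: mean and sd solved from the week-24 moment targets.
    rhoL_mean = p.cobbL24_mean / mL
    e_l0_sq = mL**2 + vL
    v_rho = (p.cobbL24_sd**2 - vL * rhoL_mean**2) / e_l0_sq
    rhoL_sd = float(np.sqrt(max(v_rho, 1e-6)))
    rhoT_mean = 1.0 - p.cobbT_reduction_frac
    rhoT_sd = rhoL_sd

    nu_var = float(stats.truncnorm.var(-_NU_BOUND, _NU_BOUND))

    # default per-degree gains: baseline mean PMSI target per pair
    region_mean = {"lumbar": mL, "thoracic": mT}
    default_es_gain = (p.pmsi_mean - 1.0) / mL
    pair_gain, pair_noise = {}, {}
    for pair, cfg in _PAIR_LEVELS.items():
        g_default = (cfg["pmsi0"] - 1.0) / region_mean[PAIR_REGION[pair]]
        if p.asym_gain is None:
            g = g_default
        else:
            # explicit gain is the erector spinae gain; others scale with it
            g = p.asym_gain * (g_default / default_es_gain)
        pair_gain[pair] = g
        pair_noise[pair] = cfg["noise"]
    pair_noise["erector_spinae"] = _ES_NOISE

    # Erector spinae moment structure, solved on a deterministic internal
    # Monte-Carlo sample of the latent drivers: (i) re-solve the ES gain so
    # the *clipped* baseline ratio has mean pmsi_mean; (ii) couple the
    # concave level to the ratio through its normal scores with weight
    # alpha chosen so E[level * ratio] = rms_convex_mean.  The normal-score
    # link keeps the concave level exactly Gaussian while realising the
    # near-maximal covariance the printed means require (module docstring).
    mc = _rng(987_654_321)
    M = 80_000
    c_mc = _draw_trunc(mc, cobbL0_loc, p.cobbL0_sd, 5.0, 40.0, size=M)
    u_mc = _draw_trunc(mc, 0.0, 1.0, -_NU_BOUND, _NU_BOUND, size=M)
    lam_mc = 1.0 + _ES_NOISE * u_mc

    def _r_of(g):
        return np.clip(1.0 + g * c_mc * lam_mc, _R_CLIP[0], _R_CLIP[1])

    if p.asym_gain is None:
        g_es = float(
            optimize.brentq(lambda g: _r_of(g).mean() - p.pmsi_mean, 1e-6, 0.2)
        )
        pair_gain["erector_spinae"] = g_es
    else:
        g_es = pair_gain["erector_spinae"]

    es_alpha, es_z_mean = 0.0, 0.0
    qs = np.linspace(0.0, 1.0, 2050)[1:-1]
    r_mc = _r_of(g_es)
    r_grid = np.quantile(r_mc, qs)
    cov_needed = p.rms_convex_mean - p.rms_concave_mean * float(r_mc.mean())
    if np.ptp(r_grid) > 1e-9 and cov_needed > 1e-9:
        z_mc = stats.norm.ppf(np.clip(np.interp(r_mc, r_grid, qs), qs[0], qs[-1]))
        es_z_mean = float(z_mc.mean())
        zc = z_mc - es_z_mean
        cov_zr = float(np.mean(zc * r_mc))
        es_alpha = float(min(1.0, cov_needed / (p.rms_concave_sd * cov_zr)))

    return _Calib(
        age_loc=age_loc, bmi_loc=bmi_loc, risser_loc=risser_loc,
        cobbT0_loc=cobbT0_loc, cobbL0_loc=cobbL0_loc,
        cobbT0_m=mT, cobbT0_v=vT, cobbL0_m=mL, cobbL0_v=vL,
        rhoL_mean=rhoL_mean, rhoL_sd=rhoL_sd,
        rhoT_mean=rhoT_mean, rhoT_sd=rhoT_sd,
        pair_gain=pair_gain, pair_noise=pair_noise,
        es_alpha=es_alpha, es_r_grid=r_grid, es_q_grid=qs,
        es_z_mean=es_z_mean, nu_var=nu_var,
    )


@dataclass
class GroundTruth:
    """Latent generator state: true Cobb trajectories and RMS targets.

    ``cobb`` has one row per (patient, week) with the latent thoracic and
    lumbar Cobb angles (linear in week between the two draws);
    ``rms_targets`` one row per (patient, week, channel) with the in-band
    RMS amplitude target in uV.
    """

    cobb: pd.DataFrame
    rms_targets: pd.DataFrame


# ---------------------------------------------------------------------------
# Statics
# ---------------------------------------------------------------------------


def simulate_statics(params: SimParams) -> list[PatientStatic]:
    cal = _calibrate(params)
    statics = []
    for i in range(params.n_patients):
        pid = f"P{i:04d}"
        rng = _rng(params.seed, _crc(pid), 3)
        age = float(_draw_trunc(rng, cal.age_loc, params.age_sd, 10.0, 18.0))
        sex = "female" if rng.random() < params.frac_female else "male"
        bmi = float(_draw_trunc(rng, cal.bmi_loc, params.bmi_sd, 1e-6, np.inf))
        risser = float(_draw_trunc(rng, cal.risser_loc, params.risser_sd, 0.0, 5.0))
        direction = "left" if rng.random() < params.frac_left_curve else "right"
        # main thoracic curve convex toward the curve direction, with the
        # typical compensatory lumbar curve convex to the opposite side
        thor = "L" if direction == "left" else "R"
        lumb = "R" if thor == "L" else "L"
        statics.append(
            PatientStatic(
                patient_id=pid, age=age, sex=sex, bmi=bmi, risser=risser,
                curve_direction=direction,
                convex_side={"thoracic": thor, "lumbar": lumb},
            )
        )
    return statics


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------


def _cobb_traj(c0: float, c24: float, week: int) -> float:
    return c0 + (c24 - c0) * week / 24.0


def _cobb_week_moments(m0, v0, rho_m, rho_sd, week):
    """Mean/variance of lerp(C0, rho*C0) at a given week (independent rho)."""
    f = week / 24.0
    e_l = (1 - f) + f * rho_m
    e_l2 = (1 - f) ** 2 + 2 * f * (1 - f) * rho_m + f**2 * (rho_m**2 + rho_sd**2)
    e_c2 = m0**2 + v0
    mean = m0 * e_l
    var = e_c2 * e_l2 - mean**2
    return mean, var


def simulate_outcomes(
    statics: list[PatientStatic], params: SimParams
) -> tuple[list[OutcomePanel], GroundTruth]:
    """Draw Cobb trajectories and the secondary outcomes for each patient.

    Cobb angles are stored in the panels only at weeks 0 and 24 (the
    radiographic protocol); the full latent trajectory goes into the
    ground truth, along with the per-channel RMS amplitude targets.
    """
    cal = _calibrate(params)
    p = params
    panels, cobb_rows, rms_rows = [], [], []
    for s in statics:
        rng = _rng(p.seed, _crc(s.patient_id), 7)
        t0 = float(_draw_trunc(rng, cal.cobbT0_loc, p.cobbT0_sd, 10.0, 40.0))
        l0 = float(_draw_trunc(rng, cal.cobbL0_loc, p.cobbL0_sd, 5.0, 40.0))
        rho_t = float(np.clip(rng.normal(cal.rhoT_mean, cal.rhoT_sd), 0.05, 1.2))
        rho_l = float(np.clip(rng.normal(cal.rhoL_mean, cal.rhoL_sd), 0.05, 1.2))
        t24, l24 = t0 * rho_t, l0 * rho_l

        panel = OutcomePanel(patient_id=s.patient_id)
        for w in MEASUREMENT_WEEKS:
            f = w / 24.0
            cw = {"cobb_T": _cobb_traj(t0, t24, w), "cobb_L": _cobb_traj(l0, l24, w)}
            cobb_rows.append({"patient_id": s.patient_id, "week": w, **cw})
            vals = {}
            for name, (m0, sd0, m24, sd24) in _OUTCOME_ANCHORS.items():
                base = m0 + (m24 - m0) * f
                sd_target = sd0 + (sd24 - sd0) * f
                region, beta = _OUTCOME_COUPLING[name]
                signal = 0.0
                coupled_var = 0.0
                if region is not None and beta != 0.0:
                    if region == "cobb_T":
                        mw, vw = _cobb_week_moments(
                            cal.cobbT0_m, cal.cobbT0_v, cal.rhoT_mean, cal.rhoT_sd, w)
                    else:
                        mw, vw = _cobb_week_moments(
                            cal.cobbL0_m, cal.cobbL0_v, cal.rhoL_mean, cal.rhoL_sd, w)
                    signal = beta * (cw[region] - mw)
                    coupled_var = beta**2 * vw
                scale = {"art_T": p.art_noise_scale, "art_L": p.art_noise_scale,
                         "srs22": p.srs_noise_scale, "bst": p.bst_noise_scale}[name]
                noise_sd = np.sqrt(max(sd_target**2 - coupled_var, (0.1 * sd_target) ** 2))
                vals[name] = base + signal + scale * noise_sd * rng.standard_normal()
            measures = OutcomeMeasures(
                art_T=float(np.clip(vals["art_T"], 0.0, None)),
                art_L=float(np.clip(vals["art_L"], 0.0, None)),
                srs22=float(np.clip(vals["srs22"], 1.0, 5.0)),
                bst=float(np.clip(vals["bst"], 0.0, 240.0)),
            )
            if w in (0, 24):
                measures.cobb_T = float(np.clip(cw["cobb_T"], 0.0, 90.0))
                measures.cobb_L = float(np.clip(cw["cobb_L"], 0.0, 90.0))
            panel.weeks[w] = measures
        panels.append(panel)

        targets = _rms_targets(s, panel, params)
        for (w, ch), uv in targets.items():
            rms_rows.append(
                {"patient_id": s.patient_id, "week": w, "channel": ch.name, "target_uv": uv}
            )

    gt = GroundTruth(cobb=pd.DataFrame(cobb_rows), rms_targets=pd.DataFrame(rms_rows))
    return panels, gt


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------


def _patient_latents(params: SimParams, patient_id: str) -> dict:
    """Patient-level EMG latents, reproducible from (params.seed, id)."""
    cal = _calibrate(params)
    rng = _rng(params.seed, _crc(patient_id), 11)
    lam, level_noise = {}, {}
    for pair, cfg in _PAIR_LEVELS.items():
        u = float(_draw_trunc(rng, 0.0, 1.0, -_NU_BOUND, _NU_BOUND))
        lam[pair] = 1.0 + cal.pair_noise[pair] * u
        level_noise[pair] = float(rng.standard_normal())
    return {"lam": lam, "level_noise": level_noise}


def _regional_cobb(panel: OutcomePanel, region: str, week: int) -> float:
    name = "cobb_T" if region == "thoracic" else "cobb_L"
    c0 = panel.value(0, name)
    c24 = panel.value(24, name)
    if c0 is None or c24 is None:
        raise ValueError(f"{panel.patient_id}: Cobb {name} missing at week 0/24")
    return _cobb_traj(c0, c24, week)


def _rms_targets(
    static: PatientStatic, panel: OutcomePanel, params: SimParams
) -> dict[tuple[int, MuscleChannel], float]:
    """In-band RMS amplitude target (uV) per (week, channel).

    One target per (patient, week, channel), shared across exercises;
    per-recording realisations add only small jitter.
    """
    cal = _calibrate(params)
    lat = _patient_latents(params, static.patient_id)
    out: dict[tuple[int, MuscleChannel], float] = {}
    for pair, (chL, chR) in MUSCLE_PAIRS.items():
        region = PAIR_REGION[pair]
        cfg = _PAIR_LEVELS[pair]
        gain = cal.pair_gain[pair]
        lam = lat["lam"][pair]
        eta = lat["level_noise"][pair]
        r0 = float(np.clip(1.0 + gain * _regional_cobb(panel, region, 0) * lam, *_R_CLIP))
        if pair == "erector_spinae" and cal.es_alpha > 0:
            # concave level correlated with the baseline asymmetry ratio
            # through its normal score (keeps the level marginal Gaussian)
            q = float(np.interp(r0, cal.es_r_grid, cal.es_q_grid))
            z = float(stats.norm.ppf(np.clip(q, cal.es_q_grid[0], cal.es_q_grid[-1])))
            z -= cal.es_z_mean
            driver = cal.es_alpha * z + np.sqrt(1.0 - cal.es_alpha**2) * eta
            level = cfg["level"] + cfg["level_sd"] * driver
        else:
            level = cfg["level"] + cfg["level_sd"] * eta
        level = float(np.clip(level, 3.0, 100.0))
        convex_ch = chL if static.convex_side[region] == "L" else chR
        for w in MEASUREMENT_WEEKS:
            r_w = float(np.clip(1.0 + gain * _regional_cobb(panel, region, w) * lam, *_R_CLIP))
            for ch in (chL, chR):
                out[(w, ch)] = level * r_w if ch is convex_ch else level
    return out


def synthesize_recording(
    static: PatientStatic,
    outcome_panel: OutcomePanel,
    week: int,
    exercise: ExerciseType,
    params: SimParams,
    seed: int | None = None,
) -> EMGRecording:
    """Generate one 8-channel recording for (patient, week, exercise).

    Each channel is in-band shaped Gaussian noise scaled so its
    band-passed RMS matches the channel's amplitude target (with small
    per-recording jitter), plus a sub-20 Hz motion-artifact tone and a
    >400 Hz contamination tone.
    """
    if week not in MEASUREMENT_WEEKS:
        raise ValueError(f"unknown measurement week {week}")
    p = params
    seed = p.seed if seed is None else seed
    targets = _rms_targets(static, outcome_panel, p)
    n = int(round(p.duration_s * p.sample_rate_hz))
    rng = _rng(seed, _crc(static.patient_id), week, exercise.value, 23)

    spec = FilterSpec()
    sos = spec.sos(p.sample_rate_hz)
    white = rng.standard_normal((len(MuscleChannel), n))
    core = sps.sosfiltfilt(sos, white, axis=-1)
    # scale so that the *band-pass filtered* signal hits the target RMS
    meas = sps.sosfiltfilt(sos, core, axis=-1)
    meas_rms = np.sqrt(np.mean(meas**2, axis=-1))

    t = np.arange(n) / p.sample_rate_hz
    sig = np.empty((len(MuscleChannel), n), dtype=np.float32)
    for ch in MuscleChannel:
        target = targets[(week, ch)] * float(np.exp(rng.normal(0.0, p.rec_jitter_sd)))
        scaled = core[ch.value] * (target / meas_rms[ch.value])
        f_lo = rng.uniform(0.3, 8.0)
        f_hi = rng.uniform(420.0, 478.0)
        lf = p.artifact_amp * np.sqrt(2.0) * np.sin(2 * np.pi * f_lo * t + rng.uniform(0, 2 * np.pi))
        hf = p.hf_noise_amp * np.sqrt(2.0) * np.sin(2 * np.pi * f_hi * t + rng.uniform(0, 2 * np.pi))
        sig[ch.value] = (scaled + lf + hf).astype(np.float32)

    return EMGRecording(
        patient_id=static.patient_id, week=week, exercise=exercise,
        sample_rate_hz=p.sample_rate_hz, signals=sig,
    )


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------


def simulate_cohort(params: SimParams) -> tuple[Cohort, GroundTruth]:
    """Compose statics, outcomes and recordings into a complete cohort.

    A complete cohort has 4 exercises x 4 weeks = 16 recordings per
    patient (2,288 at the study's n = 143, 572 per measurement week).
    """
    statics = simulate_statics(params)
    panels, gt = simulate_outcomes(statics, params)
    by_id = {o.patient_id: o for o in panels}
    recordings = []
    for s in statics:
        panel = by_id[s.patient_id]
        for w in MEASUREMENT_WEEKS:
            for ex in EXERCISES:
                recordings.append(
                    synthesize_recording(s, panel, w, ex, params, seed=params.seed)
                )
    return Cohort(statics=statics, outcomes=panels, recordings=recordings), gt
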