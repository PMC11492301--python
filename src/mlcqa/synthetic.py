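"""Synthetic study generator with planted statistical structure.

No clinical plans, delivery logs or self-check files are distributed with
this package, so every pipeline stage is exercised on synthetic data whose
generative structure is known exactly:

* ``synth_plan`` builds sliding-aperture VMAT-like beams on an HD120-style
  bank. A per-field *jitter* knob drives how much adjacent apertures differ
  (both the per-CP translation step and per-leaf noise, so zero jitter means
  a static aperture and field Dice exactly 1), and a *roughness* knob drives
  static leaf-edge irregularity (fluence texture) independently of Dice.
* ``synth_wear_series`` draws per-parameter linear drifts plus session noise
  for both banks, with optional repair resets that appear as mutation points
  in the normalized series. LG is given zero drift — it is the planted null
  covariate.
* ``synth_dynalog`` plants the generative link the pipeline must recover:
  each file's mean absolute deviation is targeted at

      mu = b0 + b_dice z(dice) + b_homog z(homogeneity) + b_pwm z(PWM)
           [+ interaction and quadratic terms when nonlinear]
           + file noise,

  where z(.) are within-study z-scores of the *measured* covariates. Leaf
  deviations are half-normal in magnitude with random sign (i.e. Gaussian),
  scaled so the expected mean absolute deviation equals mu — matching the
  absolute-deviation statistic directly.
* ``synth_dose_pair`` produces a smooth reference dose plane plus a
  perturbed "delivery" plane whose perturbation amplitude is proportional to
  the planted deviation, enabling the deviation-vs-gamma correlation study.

The default study is a balanced crossed design: every treatment plan is
delivered at every wear session and each delivery yields 2 fields x 2 banks
= 4 dynalog files, mirroring the same-day matching of logs to self-checks.
Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import datetime as _dt
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynalog import DynalogRecordSet, deviation_summary, write_dynalog
from .errors import ValidationError
from .features import field_features
from .geometry import BANKS, MlcGeometry, hd120
from .plan_fluence import Beam, ControlPoint, save_plan
from .delivery_quality import DosePlane, write_dose_plane
from .wear import WEAR_PARAMS, WearRecord, write_init


@dataclass(frozen=True)
class DeviationModel:
    """Planted link from covariates to each file's target mean absolute
    deviation (mm). Slopes act on within-study z-scores of the measured
    covariates (within-bank for PWM, since the two banks have distinct
    mechanical states and are analyzed separately); signs mirror the
    observed directions (deviation falls with Dice, homogeneity and PWM)."""

    intercept_mm: float = 0.41
    beta_dice: float = -0.035
    beta_homogeneity: float = -0.035
    beta_pwm: float = -0.035
    beta_dice_pwm: float = 0.025  # interaction, active when nonlinear
    beta_homogeneity_quad: float = 0.02  # quadratic, active when nonlinear
    noise_sd_mm: float = 0.012
    floor_mm: float = 0.05
    nonlinear: bool = True


def _default_slopes() -> dict[str, float]:
    # relative drift over the whole study; LG is the planted null (no drift)
    return {"ME": -0.04, "BL": 0.06, "MSC": 0.05, "PWM": -0.06, "LG": 0.0, "LO": 0.10, "CO": 0.07}


def _default_baselines() -> dict[str, float]:
    return {"ME": 0.12, "BL": 0.18, "MSC": 55.0, "PWM": 35.0, "LG": 0.9, "LO": 4.2e5, "CO": 1.3e4}


@dataclass(frozen=True)
class WearDriftModel:
    """Linear per-parameter drift + session noise + leaf-to-leaf spread;
    ``repair_resets`` lists session indices at which ``reset_params`` jump
    back to baseline (mutation points)."""

    slopes: dict[str, float] = field(default_factory=_default_slopes)
    baselines: dict[str, float] = field(default_factory=_default_baselines)
    session_noise_sd: float = 0.035  # relative; dominates the slow trend so
    # different parameters stay decorrelated session to session
    leaf_spread_sd: float = 0.05  # relative, static per leaf
    bank_baseline_sd: float = 0.08  # relative baseline difference between banks
    repair_resets: tuple[int, ...] = ()
    reset_params: tuple[str, ...] = ("BL", "MSC", "PWM")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions. The default scale (5 treatments x 10 sessions x 2
    fields x 2 banks = 200 files) runs at desk scale; recovery experiments
    use 8 x 16 = 512 files."""

    seed: int = 0
    n_treatments: int = 5
    n_sessions: int = 10
    n_fields: int = 2
    n_cp_per_beam: int = 20
    n_samples_per_file: int = 120
    pixel_pitch_mm: float = 1.25
    n_levels: int = 16
    edge_weight: float = 2.0
    jitter_range_mm: tuple[float, float] = (0.5, 2.4)
    roughness_range_mm: tuple[float, float] = (1.0, 6.0)
    deviation_model: DeviationModel = field(default_factory=DeviationModel)
    wear_model: WearDriftModel = field(default_factory=WearDriftModel)
    dose_perturbation_cgy_per_mm: float = 6.0
    dose_plane_shape: tuple[int, int] = (61, 61)
    dose_pitch_mm: float = 4.0
    start_date: _dt.date = _dt.date(2020, 7, 1)
    session_spacing_days: int = 5

    @property
    def n_files(self) -> int:
        return self.n_treatments * self.n_sessions * self.n_fields * len(BANKS)


def _rng(seed: int, *key) -> np.random.Generator:
    """Deterministic child generator keyed by strings/ints (crc32 of the
    textual key keeps everything below 2^32)."""
    tokens = [seed & 0xFFFFFFFF]
    for item in key:
        tokens.append(zlib.crc32(str(item).encode()) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(tokens))


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


# ---------------------------------------------------------------------------
# plans


def synth_beam(
    config: SimulationConfig,
    rng: np.random.Generator,
    beam_id: str,
    jitter_mm: float,
    roughness_mm: float,
    geometry: MlcGeometry | None = None,
) -> Beam:
    """One sliding-aperture beam. ``jitter_mm`` scales the per-CP aperture
    change (translation step + per-leaf noise); ``roughness_mm`` shapes a
    static irregular boundary."""
    g = geometry or hd120()
    n_cp = config.n_cp_per_beam
    if n_cp < 2:
        raise ValidationError("a beam needs at least 2 control points")

    n_active = int(rng.integers(14, 31))
    first = g.n_pairs // 2 - n_active // 2 + int(rng.integers(-2, 3))
    rel = np.linspace(-1.0, 1.0, n_active)
    width_scale = float(rng.uniform(0.7, 1.4))
    base_hw = width_scale * (10.0 + 9.0 * np.sqrt(np.maximum(1.0 - rel**2, 0.0)))
    rough = roughness_mm * rng.standard_normal(n_active)
    rough = np.convolve(rough, [0.25, 0.5, 0.25], mode="same")  # spatially smooth
    half_width = np.clip(base_hw + rough, 3.0, 42.0)

    # The aperture center reciprocates across a fixed-amplitude window: the
    # oscillation frequency scales with jitter and sets how much adjacent
    # apertures differ (Dice), while the swept extent is governed by the
    # independent amplitude draw, keeping temporal variability and fluence
    # texture decoupled. jitter=0 freezes the aperture entirely.
    amplitude = float(rng.uniform(8.0, 14.0))
    cycles = jitter_mm
    leaf_noise_sd = 0.15 * jitter_mm
    u = np.linspace(0.0, 1.0, n_cp)
    centers = amplitude * np.sin(2.0 * np.pi * cycles * u)

    edges = g.leaf_edges()
    jaw_y1, jaw_y2 = float(edges[first]), float(edges[first + n_active])
    jaw_x1, jaw_x2 = -45.0, 45.0

    increments = rng.uniform(0.5, 1.5, n_cp - 1)
    cum = np.concatenate([[0.0], np.cumsum(increments)])
    cum /= cum[-1]
    gantry = np.linspace(181.0, 179.0, n_cp) % 360.0
    collimator = float(np.round(rng.uniform(0.0, 90.0), 1))

    cps = []
    for t in range(n_cp):
        bank_a = np.zeros(g.n_pairs)
        bank_b = np.zeros(g.n_pairs)
        noise_b = leaf_noise_sd * rng.standard_normal(n_active)
        noise_a = leaf_noise_sd * rng.standard_normal(n_active)
        b = centers[t] - half_width + noise_b
        a = centers[t] + half_width + noise_a
        a = np.maximum(a, b + 0.5)
        sl = slice(first, first + n_active)
        bank_b[sl] = np.clip(b, g.travel_min, g.travel_max)
        bank_a[sl] = np.clip(a, g.travel_min, g.travel_max)
        cps.append(
            ControlPoint(
                index=t,
                bank_a=bank_a,
                bank_b=bank_b,
                cumulative_meterset_weight=float(cum[t]),
                jaw_x1=jaw_x1,
                jaw_x2=jaw_x2,
                jaw_y1=jaw_y1,
                jaw_y2=jaw_y2,
                gantry_angle=float(gantry[t]),
                collimator_angle=collimator,
            )
        )
    return Beam(
        beam_id=beam_id,
        beam_mu=float(np.round(rng.uniform(180.0, 320.0), 1)),
        collimator_angle=collimator,
        control_points=cps,
    )


def synth_plan(config: SimulationConfig, treatment: int, geometry: MlcGeometry | None = None) -> list[Beam]:
    """The 2-arc plan of one treatment: per-field jitter and roughness are
    drawn from the configured ranges."""
    beams = []
    for f in range(config.n_fields):
        rng = _rng(config.seed, "plan", treatment, f)
        jitter = float(rng.uniform(*config.jitter_range_mm))
        roughness = float(rng.uniform(*config.roughness_range_mm))
        beams.append(
            synth_beam(config, rng, f"t{treatment:02d}_f{f + 1}", jitter, roughness, geometry)
        )
    return beams


# ---------------------------------------------------------------------------
# wear


def synth_wear_series(config: SimulationConfig, geometry: MlcGeometry | None = None) -> list[WearRecord]:
    """Per-session wear records for both banks: baseline x (1 + drift +
    session noise) with a static leaf-to-leaf pattern; resets restart the
    drift clock for the configured parameters."""
    g = geometry or hd120()
    wm = config.wear_model
    S = config.n_sessions
    records = []
    for bank in BANKS:
        rng = _rng(config.seed, "wear", bank)
        baselines = {
            p: wm.baselines[p] * (1.0 + wm.bank_baseline_sd * rng.standard_normal())
            for p in WEAR_PARAMS
        }
        leaf_pattern = {p: wm.leaf_spread_sd * rng.standard_normal(g.n_pairs) for p in WEAR_PARAMS}
        for s in range(S):
            date = config.start_date + _dt.timedelta(days=s * config.session_spacing_days)
            values = {}
            for p in WEAR_PARAMS:
                last_reset = 0
                if p in wm.reset_params:
                    for r in wm.repair_resets:
                        if 0 < r <= s:
                            last_reset = r
                trend = wm.slopes[p] * (s - last_reset) / max(S - 1, 1)
                session_level = baselines[p] * (
                    1.0 + trend + wm.session_noise_sd * rng.standard_normal()
                )
                values[p] = session_level * (
                    1.0 + leaf_pattern[p] + 0.005 * rng.standard_normal(g.n_pairs)
                )
            records.append(WearRecord(session_date=date, bank=bank, values=values))
    return records


# ---------------------------------------------------------------------------
# dynalogs and dose planes


def synth_dynalog(
    beam: Beam,
    bank: str,
    target_mu_mm: float,
    n_samples: int,
    rng: np.random.Generator,
    field_id: str,
    meta: dict | None = None,
) -> DynalogRecordSet:
    """Planned trajectories interpolated from the beam's CPs at 0.05 s
    sampling; actual = planned + noise scaled so E|actual - planned| equals
    ``target_mu_mm``."""
    if target_mu_mm < 0:
        import warnings

        warnings.warn("negative target deviation clipped to 0.01 mm")
        target_mu_mm = 0.01
    weights = np.asarray([cp.cumulative_meterset_weight for cp in beam.control_points])
    positions = np.stack(
        [cp.bank_a if bank == "A" else cp.bank_b for cp in beam.control_points]
    )  # (n_cp, n_leaves)
    frac = np.linspace(0.0, 1.0, n_samples)
    planned = np.stack(
        [np.interp(frac, weights, positions[:, leaf]) for leaf in range(positions.shape[1])],
        axis=1,
    )
    sigma = target_mu_mm * np.sqrt(np.pi / 2.0)  # half-normal magnitude, random sign
    actual = planned + sigma * rng.standard_normal(planned.shape)
    return DynalogRecordSet(
        bank=bank,
        field_id=field_id,
        sample_times=0.05 * np.arange(n_samples),
        planned=planned,
        actual=actual,
        meta=dict(meta or {}),
    )


def synth_dose_pair(
    deviation_mm: float, config: SimulationConfig, rng: np.random.Generator
) -> tuple[DosePlane, DosePlane]:
    """Smooth reference dome plus a spatially correlated perturbation whose
    amplitude is ``dose_perturbation_cgy_per_mm * deviation``."""
    from scipy.ndimage import gaussian_filter

    ny, nx = config.dose_plane_shape
    pitch = config.dose_pitch_mm
    x = pitch * (np.arange(nx) - (nx - 1) / 2.0)
    y = pitch * (np.arange(ny) - (ny - 1) / 2.0)
    xx, yy = np.meshgrid(x, y)
    ref = 10.0 + 190.0 * np.exp(-(xx**2 + yy**2) / (2 * 70.0**2))

    pert = gaussian_filter(rng.standard_normal((ny, nx)), sigma=2.0, mode="reflect")
    pert /= np.sqrt(np.mean(pert**2))
    amplitude = config.dose_perturbation_cgy_per_mm * deviation_mm
    evaluated = np.maximum(ref + amplitude * pert, 0.0)
    origin = (float(x[0]), float(y[0]))
    return DosePlane(ref, pitch, origin), DosePlane(evaluated, pitch, origin)


# ---------------------------------------------------------------------------
# full study


@dataclass
class SyntheticStudy:
    """Everything one simulated cohort produces: plans, per-field features,
    wear records, dynalogs, the planted truth and the assembled modeling
    table (one row per dynalog file)."""

    config: SimulationConfig
    geometry: MlcGeometry
    plans: dict[int, list[Beam]]
    field_features: pd.DataFrame
    wear_records: list[WearRecord]
    wear_table: pd.DataFrame
    dynalogs: list[DynalogRecordSet]
    truth: pd.DataFrame
    table: pd.DataFrame

    def treatment_record_deviations(self) -> pd.DataFrame:
        """Per (treatment, session): the treatment-level deviation, i.e. the
        mean over its 4 files (2 fields x 2 banks)."""
        grp = self.table.groupby(["treatment", "session"])["deviation_mm"].mean()
        return grp.reset_index()

    def dose_pair(self, treatment: int, session: int) -> tuple[DosePlane, DosePlane]:
        dev = self.table[
            (self.table.treatment == treatment) & (self.table.session == session)
        ]["deviation_mm"].mean()
        rng = _rng(self.config.seed, "dose", treatment, session)
        return synth_dose_pair(float(dev), self.config, rng)


def synth_study(config: SimulationConfig, geometry: MlcGeometry | None = None) -> SyntheticStudy:
    """Generate the full crossed study and assemble the modeling table."""
    g = geometry or hd120()
    dm = config.deviation_model

    # plans and per-field fluence/Dice features
    plans: dict[int, list[Beam]] = {}
    feat_rows = []
    for t in range(config.n_treatments):
        plans[t] = synth_plan(config, t, g)
        for f, beam in enumerate(plans[t]):
            feats = field_features(
                beam,
                g,
                pixel_pitch=config.pixel_pitch_mm,
                n_levels=config.n_levels,
                edge_weight=config.edge_weight,
            )
            feat_rows.append({"treatment": t, "field": f + 1, **feats})
    features = pd.DataFrame(feat_rows)

    # wear sessions, summarized per (session, bank)
    wear_records = synth_wear_series(config, g)
    wear_rows = []
    for rec in wear_records:
        session = (rec.session_date - config.start_date).days // config.session_spacing_days
        wear_rows.append(
            {
                "session": session,
                "date": rec.session_date.isoformat(),
                "bank": rec.bank,
                **{p: float(rec.values[p].mean()) for p in WEAR_PARAMS},
            }
        )
    wear_table = pd.DataFrame(wear_rows)

    # within-study z-scores of the planted covariates
    features = features.assign(
        dice_z=_zscore(features["dice"].to_numpy()),
        homogeneity_z=_zscore(features["homogeneity"].to_numpy()),
    )
    # banks have different mechanical states and are analyzed separately, so
    # the planted wear effect acts on the within-bank standardized PWM
    wear_table = wear_table.assign(
        pwm_z=wear_table.groupby("bank")["PWM"].transform(lambda v: _zscore(v.to_numpy()))
    )

    dynalogs: list[DynalogRecordSet] = []
    truth_rows = []
    table_rows = []
    for t in range(config.n_treatments):
        for s in range(config.n_sessions):
            for f in range(config.n_fields):
                beam = plans[t][f]
                frow = features[(features.treatment == t) & (features.field == f + 1)].iloc[0]
                for bank in BANKS:
                    wrow = wear_table[(wear_table.session == s) & (wear_table.bank == bank)].iloc[0]
                    z_d, z_h, z_p = frow.dice_z, frow.homogeneity_z, wrow.pwm_z
                    mu = (
                        dm.intercept_mm
                        + dm.beta_dice * z_d
                        + dm.beta_homogeneity * z_h
                        + dm.beta_pwm * z_p
                    )
                    if dm.nonlinear:
                        mu += dm.beta_dice_pwm * z_d * z_p
                        mu += dm.beta_homogeneity_quad * (z_h**2 - 1.0)
                    rng = _rng(config.seed, "dynalog", t, s, f, bank)
                    mu += dm.noise_sd_mm * rng.standard_normal()
                    mu = max(mu, dm.floor_mm)

                    file_id = f"t{t:02d}_s{s:03d}_f{f + 1}_{bank}"
                    meta = {
                        "treatment": t,
                        "session": s,
                        "date": wrow.date,
                    }
                    rs = synth_dynalog(
                        beam, bank, mu, config.n_samples_per_file, rng, file_id, meta
                    )
                    dynalogs.append(rs)
                    summ = deviation_summary(rs)
                    truth_rows.append(
                        {
                            "file": file_id,
                            "treatment": t,
                            "session": s,
                            "field": f + 1,
                            "bank": bank,
                            "mu_true_mm": mu,
                            "dice_z": z_d,
                            "homogeneity_z": z_h,
                            "pwm_z": z_p,
                            "deviation_mm": summ.mean_abs_dev,
                        }
                    )
                    table_rows.append(
                        {
                            "file": file_id,
                            "treatment": t,
                            "session": s,
                            "field": f + 1,
                            "bank": bank,
                            "date": wrow.date,
                            "deviation_mm": summ.mean_abs_dev,
                            "max_abs_dev_mm": summ.max_abs_dev,
                            "frac_above_threshold": summ.frac_above_threshold,
                            "contrast": frow.contrast,
                            "correlation": frow.correlation,
                            "energy": frow.energy,
                            "entropy": frow.entropy,
                            "homogeneity": frow.homogeneity,
                            "dice": frow.dice,
                            **{p: wrow[p] for p in WEAR_PARAMS},
                        }
                    )

    return SyntheticStudy(
        config=config,
        geometry=g,
        plans=plans,
        field_features=features,
        wear_records=wear_records,
        wear_table=wear_table,
        dynalogs=dynalogs,
        truth=pd.DataFrame(truth_rows),
        table=pd.DataFrame(table_rows),
    )


def write_study(study: SyntheticStudy, out_dir, with_dose: bool = False) -> None:
    """Serialize the study into its dialect files (plans/, dynalog/, init/,
    truth.csv; optionally dose/). Output is byte-stable for a fixed seed."""
    out = Path(out_dir)
    (out / "plans").mkdir(parents=True, exist_ok=True)
    (out / "dynalog").mkdir(exist_ok=True)
    (out / "init").mkdir(exist_ok=True)
    for t, beams in study.plans.items():
        save_plan(beams, out / "plans" / f"plan_t{t:02d}.json", plan_id=f"t{t:02d}")
    for rs in study.dynalogs:
        write_dynalog(rs, out / "dynalog" / f"{rs.field_id}.csv")
    for rec in study.wear_records:
        session = (rec.session_date - study.config.start_date).days // study.config.session_spacing_days
        write_init(rec, out / "init" / f"init_s{session:03d}_{rec.bank}.csv")
    study.truth.to_csv(out / "truth.csv", index=False, float_format="%.6f")
    if with_dose:
        (out / "dose").mkdir(exist_ok=True)
        for t in range(study.config.n_treatments):
            for s in range(study.config.n_sessions):
                ref, ev = study.dose_pair(t, s)
                write_dose_plane(ref, out / "dose" / f"ref_t{t:02d}_s{s:03d}.csv")
                write_dose_plane(ev, out / "dose" / f"eval_t{t:02d}_s{s:03d}.csv")
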