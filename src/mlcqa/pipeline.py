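"""End-to-end assembly: join features, deviations and wear into the
modeling table; produce screening / modeling / delivery-quality reports.

The joining rule mirrors the cohort construction: a dynalog file is matched
to the wear record of the *same calendar date and bank* (no interpolation
across dates) and to the fluence features of its own field.
"""

from __future__ import annotations

import glob as _glob
from pathlib import Path

import numpy as np
import pandas as pd

from .delivery_quality import gamma_pass_rate
from .dynalog import deviation_summary, parse_dynalog
from .errors import ValidationError
from .features import field_features
from .geometry import MlcGeometry, hd120
from .plan_fluence import load_plan
from .stats_model import (
    MODEL_INPUTS,
    RESPONSE,
    SCREENING_FACTORS,
    multi_correlation,
    spearman_screen,
    train_and_evaluate,
)
from .synthetic import SyntheticStudy
from .wear import WEAR_PARAMS, bank_summary, normalize_series, parse_init


def expand_paths(pattern: str) -> list[Path]:
    """Accept a glob pattern, a directory (all *.csv / *.json inside) or a
    single file."""
    p = Path(pattern)
    if p.is_dir():
        return sorted(list(p.glob("*.csv")) + list(p.glob("*.json")) + list(p.glob("*.dcm")))
    if any(ch in pattern for ch in "*?["):
        return sorted(Path(m) for m in _glob.glob(pattern))
    return [p]


# ---------------------------------------------------------------------------
# tabulation from dialect files


def tabulate_deviations(paths, geometry: MlcGeometry | None = None, threshold: float = 1.0) -> pd.DataFrame:
    """One row per dynalog file: deviation statistics plus join keys."""
    rows = []
    for path in paths:
        rs = parse_dynalog(path, geometry)
        s = deviation_summary(rs, threshold)
        rows.append(
            {
                "file": Path(path).stem,
                "field_id": rs.field_id,
                "bank": rs.bank,
                "treatment": int(rs.meta["treatment"]) if "treatment" in rs.meta else -1,
                "session": int(rs.meta["session"]) if "session" in rs.meta else -1,
                "date": rs.meta.get("date", ""),
                "field": _field_number(rs.field_id),
                "mean_abs_dev": s.mean_abs_dev,
                "max_abs_dev": s.max_abs_dev,
                "frac_above_threshold": s.frac_above_threshold,
            }
        )
    if not rows:
        raise ValidationError("no dynalog files found")
    return pd.DataFrame(rows)


def _field_number(field_id: str) -> int:
    for token in reversed(field_id.split("_")):
        if token.startswith("f") and token[1:].isdigit():
            return int(token[1:])
    return -1


def tabulate_features(
    plan_paths,
    geometry: MlcGeometry | None = None,
    pixel_pitch: float = 1.25,
    n_levels: int = 16,
    edge_weight: float = 2.0,
) -> pd.DataFrame:
    """One row per field of each plan: the five texture features + Dice."""
    g = geometry or hd120()
    rows = []
    for path in plan_paths:
        beams = load_plan(path, g)
        stem = Path(path).stem
        treatment = _treatment_number(stem)
        for f, beam in enumerate(beams):
            feats = field_features(beam, g, pixel_pitch, n_levels, edge_weight)
            rows.append({"plan": stem, "treatment": treatment, "field": f + 1, **feats})
    if not rows:
        raise ValidationError("no plan files found")
    return pd.DataFrame(rows)


def _treatment_number(stem: str) -> int:
    for token in reversed(stem.split("_")):
        if token.startswith("t") and token[1:].isdigit():
            return int(token[1:])
    return -1


def tabulate_wear(init_paths, geometry: MlcGeometry | None = None) -> pd.DataFrame:
    """One row per (session, bank): leaf-averaged raw values and the
    first-session-normalized series."""
    summaries = [bank_summary(parse_init(p, geometry)) for p in init_paths]
    if not summaries:
        raise ValidationError("no init files found")
    rows = []
    for bank in sorted({s.bank for s in summaries}):
        series = sorted((s for s in summaries if s.bank == bank), key=lambda s: s.session_date)
        for s in normalize_series(series):
            rows.append(
                {
                    "date": s.session_date.isoformat(),
                    "bank": s.bank,
                    **{p: s.values[p] for p in WEAR_PARAMS},
                    **{f"{p}_norm": s.normalized[p] for p in WEAR_PARAMS},
                }
            )
    return pd.DataFrame(rows).sort_values(["bank", "date"]).reset_index(drop=True)


def assemble_table(
    features: pd.DataFrame, deviations: pd.DataFrame, wear: pd.DataFrame
) -> pd.DataFrame:
    """Join the three tables into the modeling table (one row per file)."""
    dev = deviations.rename(columns={"mean_abs_dev": RESPONSE})
    merged = dev.merge(
        features.drop(columns=[c for c in ("plan",) if c in features.columns]),
        on=["treatment", "field"],
        how="inner",
    )
    merged = merged.merge(
        wear[["date", "bank"] + list(WEAR_PARAMS)], on=["date", "bank"], how="inner"
    )
    if merged.empty:
        raise ValidationError("joining features, deviations and wear produced no rows")
    return merged


# ---------------------------------------------------------------------------
# reports


def screening_report(table: pd.DataFrame) -> pd.DataFrame:
    return spearman_screen(table, SCREENING_FACTORS, RESPONSE)


def modeling_report(table: pd.DataFrame, seed: int = 0, **fit_kwargs) -> dict:
    """Screening + multi-correlation + RF/LM experiment, JSON-serializable."""
    screen = screening_report(table)
    mc = multi_correlation(table[list(MODEL_INPUTS)], table[RESPONSE])
    res = train_and_evaluate(table, seed=seed, **fit_kwargs)
    return {
        "n_files": int(len(table)),
        "mean_deviation_mm": float(table[RESPONSE].mean()),
        "screening": {
            name: {
                "spearman_r": None if np.isnan(row.spearman_r) else round(float(row.spearman_r), 6),
                "p_value": None if np.isnan(row.p_value) else float(f"{row.p_value:.3e}"),
                "effective": bool(row.effective),
            }
            for name, row in screen.iterrows()
        },
        "multi_correlation": {
            "R": round(mc.R, 6),
            "p_value": float(f"{mc.p_value:.3e}"),
            "n": mc.n,
            "k": mc.k,
        },
        "split": {"n_train": res.n_train, "n_test": res.n_test},
        "cross_validation": {
            "fold_mse_scaled": [round(v, 6) for v in res.cv.fold_mse_scaled],
            "mean_mse_scaled": round(res.cv.mse_scaled, 6),
            "mean_mse_raw_mm2": round(res.cv.mse_raw, 8),
            "mean_variance_explained_pct": round(res.cv.variance_explained_pct, 4),
        },
        "test": {
            "rf_mse_scaled": round(res.rf_test_mse_scaled, 6),
            "rf_mse_raw_mm2": round(res.rf_test_mse_raw, 8),
            "lm_mse_scaled": round(res.lm_test_mse_scaled, 6),
            "lm_mse_raw_mm2": round(res.lm_test_mse_raw, 8),
        },
        "rf_oob_variance_explained_pct": round(res.rf_oob_variance_explained_pct, 4),
        "importances_pct": {k: round(v, 4) for k, v in res.importances.items()},
    }


def quality_table(
    study: SyntheticStudy,
    criteria: tuple[tuple[float, float], ...] = ((2.0, 2.0), (3.0, 2.0)),
    low_dose_pct: float = 10.0,
) -> pd.DataFrame:
    """Per (treatment, session) QA record: treatment-level deviation and the
    gamma passing rate of its synthetic dose pair at each criterion."""
    rows = []
    for _, rec in study.treatment_record_deviations().iterrows():
        t, s = int(rec.treatment), int(rec.session)
        ref, ev = study.dose_pair(t, s)
        row = {"treatment": t, "session": s, "deviation_mm": rec.deviation_mm}
        for dose_pct, dta in criteria:
            g = gamma_pass_rate(ref, ev, dose_pct, dta, low_dose_pct)
            row[f"gamma_{dose_pct:g}_{dta:g}"] = g.pass_rate
        rows.append(row)
    return pd.DataFrame(rows)


def quality_report(study: SyntheticStudy, **kwargs) -> dict:
    """Gamma statistics and the deviation-vs-pass-rate Spearman correlations."""
    qt = quality_table(study, **kwargs)
    metric_cols = [c for c in qt.columns if c.startswith("gamma_")]
    screen = spearman_screen(qt, metric_cols, "deviation_mm")
    return {
        "n_records": int(len(qt)),
        "mean_deviation_mm": float(qt.deviation_mm.mean()),
        "gamma": {
            c: {
                "mean_pass_rate_pct": float(qt[c].mean()),
                "spearman_r_vs_deviation": float(screen.loc[c, "spearman_r"]),
                "p_value": float(screen.loc[c, "p_value"]),
            }
            for c in metric_cols
        },
    }
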