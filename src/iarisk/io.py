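"""Cohort CSV schema, run configuration, and the end-to-end analysis pipeline.

The cohort interchange format is a plain CSV (UTF-8, "." decimal) with one
row per patient.  Event/time columns may be omitted when a long-format PSA
series file is supplied instead; the pipeline then derives the biochemical-
recurrence endpoint itself.  All pipeline outputs are tidy CSV tables plus a
JSON run manifest, so a STARD-style accounting of inclusions/exclusions can
be reconstructed from the logs and manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import scoring
from .scoring import (
    ClinicalRecord,
    GleasonInfo,
    ImagingRecord,
    InvalidInputError,
    RiskGroup,
    T_STAGES,
)
from .survival import (
    BcrOutcome,
    backward_stepwise,
    derive_bcr,
    km_estimate,
    stard_filter,
)
from .evaluate import (
    auc_mann_whitney,
    delong_test,
    group_risk_to_probability,
    net_benefit,
    reallocation,
    risk_table,
)

logger = logging.getLogger("iarisk")

__all__ = [
    "COHORT_COLUMNS",
    "CohortFormatError",
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "read_config",
    "write_config",
    "run_pipeline",
]

#: Required columns of the cohort CSV, in order.  ``event`` and
#: ``time_years`` are optional when a PSA-series file is supplied.
COHORT_COLUMNS = [
    "patient_id",
    "age_years",
    "psa_ng_ml",
    "gleason_primary",
    "gleason_secondary",
    "pct_positive_cores",
    "clinical_t_stage",
    "adc_value",
    "repe_likert",
    "lesion_size_mm",
    "event",
    "time_years",
]

_REQUIRED = COHORT_COLUMNS[:10]


class CohortFormatError(ValueError):
    """Malformed cohort file (bad header or irrecoverable content)."""


def _validate_row(row: pd.Series, idx: int) -> Optional[str]:
    """Return an error message for a bad row, or None when valid."""
    try:
        ClinicalRecord(
            patient_id=str(row["patient_id"]),
            age_years=float(row["age_years"]),
            psa_ng_ml=float(row["psa_ng_ml"]),
            gleason=GleasonInfo(int(row["gleason_primary"]), int(row["gleason_secondary"])),
            pct_positive_cores=float(row["pct_positive_cores"]),
            clinical_t_stage=str(row["clinical_t_stage"]),
        )
        ImagingRecord(
            adc_value=float(row["adc_value"]),
            repe_likert=int(row["repe_likert"]),
            lesion_size_mm=None if pd.isna(row.get("lesion_size_mm")) else float(row["lesion_size_mm"]),
        )
    except (InvalidInputError, ValueError, TypeError) as exc:
        return f"row {idx}: {exc}"
    for col in _REQUIRED:
        if col != "lesion_size_mm" and pd.isna(row[col]):
            return f"row {idx}: missing value in required column {col!r}"
    return None


def read_cohort(path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Strict mode raises on the first invalid row; lenient mode drops invalid
    rows and logs each exclusion with its row number (complete-case
    behaviour).
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in _REQUIRED if c not in df.columns]
    if missing_cols:
        raise CohortFormatError(f"cohort file {path} lacks required columns {missing_cols}")
    errors = []
    for idx, row in df.iterrows():
        msg = _validate_row(row, int(idx))
        if msg is not None:
            errors.append((int(idx), msg))
    if errors and strict:
        raise CohortFormatError("; ".join(m for _, m in errors[:10]))
    if errors:
        bad = {i for i, _ in errors}
        for _, m in errors:
            logger.warning("dropping invalid %s", m)
        df = df.drop(index=list(bad)).reset_index(drop=True)
    logger.info("read_cohort: %d records in, %d kept", len(df) + len(errors), len(df))
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table in the canonical column order."""
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    df.loc[:, cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (flat TOML on disk)."""

    input: str = ""
    psa_series: Optional[str] = None
    outdir: str = "iarisk_out"
    seed: int = 0
    horizon_years: float = 2.0
    adc_cutoffs: Tuple[float, float, float] = scoring.DEFAULT_ADC_CUTOFFS
    likert_threshold: int = scoring.DEFAULT_LIKERT_THRESHOLD
    group_point_map: Dict[str, int] = field(
        default_factory=lambda: {"low": 1, "intermediate": 2, "high": 3}
    )
    threshold_grid: Tuple[float, ...] = tuple(np.round(np.arange(0.01, 0.31, 0.01), 4))
    min_followup_days: int = 180

    def __post_init__(self) -> None:
        lo, mid, hi = self.adc_cutoffs
        if not lo < mid < hi:
            raise InvalidInputError("adc_cutoffs must be strictly increasing")
        if not 2 <= self.likert_threshold <= 5:
            raise InvalidInputError("likert_threshold must be in 2..5")
        if set(self.group_point_map) != {"low", "intermediate", "high"}:
            raise InvalidInputError("group_point_map must cover low/intermediate/high")


def read_config(path) -> RunConfig:
    """Load a RunConfig from a flat TOML file; absent keys take defaults."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    kwargs = {}
    for f in dataclasses.fields(RunConfig):
        if f.name in raw:
            v = raw[f.name]
            if f.name in ("adc_cutoffs", "threshold_grid"):
                v = tuple(float(x) for x in v)
            kwargs[f.name] = v
    return RunConfig(**kwargs)


def write_config(config: RunConfig, path) -> None:
    """Serialise a RunConfig as flat TOML."""
    lines = []
    for f in dataclasses.fields(RunConfig):
        v = getattr(config, f.name)
        if v is None:
            continue
        if isinstance(v, str):
            lines.append(f'{f.name} = "{v}"')
        elif isinstance(v, dict):
            inner = ", ".join(f'"{k}" = {val}' for k, val in v.items())
            lines.append(f"{f.name} = {{ {inner} }}")
        elif isinstance(v, (tuple, list)):
            lines.append(f"{f.name} = [{', '.join(str(x) for x in v)}]")
        else:
            lines.append(f"{f.name} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def _records_from_frame(df: pd.DataFrame) -> List[Tuple[ClinicalRecord, ImagingRecord]]:
    out = []
    for _, row in df.iterrows():
        clinical = ClinicalRecord(
            patient_id=str(row["patient_id"]),
            age_years=float(row["age_years"]),
            psa_ng_ml=float(row["psa_ng_ml"]),
            gleason=GleasonInfo(int(row["gleason_primary"]), int(row["gleason_secondary"])),
            pct_positive_cores=float(row["pct_positive_cores"]),
            clinical_t_stage=str(row["clinical_t_stage"]),
        )
        imaging = ImagingRecord(
            adc_value=float(row["adc_value"]),
            repe_likert=int(row["repe_likert"]),
            lesion_size_mm=None if pd.isna(row.get("lesion_size_mm")) else float(row["lesion_size_mm"]),
        )
        out.append((clinical, imaging))
    return out


def score_cohort(df: pd.DataFrame, config: Optional[RunConfig] = None) -> pd.DataFrame:
    """Append CAPRA, D'Amico and image-adjusted columns to a cohort table."""
    config = config or RunConfig()
    gp = config.group_point_map
    rows = []
    for clinical, imaging in _records_from_frame(df):
        c = scoring.capra_score(clinical)
        cg = scoring.capra_group(c)
        dg = scoring.damico_group(clinical)
        a = scoring.adc_points(imaging.adc_value, config.adc_cutoffs)
        r = scoring.repe_points(imaging.repe_likert, config.likert_threshold)
        comp_c = gp[cg.label] + a + r
        comp_d = gp[dg.label] + a + r
        rows.append(
            {
                "capra_score": c,
                "capra_group": cg.label,
                "damico_group": dg.label,
                "adc_points": a,
                "repe_points": r,
                "ia_capra_score": comp_c,
                "ia_capra_group": scoring.composite_to_group(comp_c).label,
                "ia_damico_score": comp_d,
                "ia_damico_group": scoring.composite_to_group(comp_d).label,
            }
        )
    scored = pd.concat([df.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    logger.info("score_cohort: %d patients scored", len(scored))
    return scored


def _outcomes_from_inputs(df: pd.DataFrame, config: RunConfig) -> List[BcrOutcome]:
    if config.psa_series:
        series = pd.read_csv(config.psa_series)
        needed = {"patient_id", "time_years", "psa_ng_ml"}
        if not needed <= set(series.columns):
            raise CohortFormatError(f"PSA series file must have columns {sorted(needed)}")
        grouped = {
            pid: list(zip(g["time_years"], g["psa_ng_ml"]))
            for pid, g in series.sort_values("time_years").groupby("patient_id")
        }
        outcomes = []
        for pid in df["patient_id"].astype(str):
            if pid not in grouped:
                raise CohortFormatError(f"no PSA series for patient {pid}")
            outcomes.append(derive_bcr(grouped[pid]))
        return outcomes
    if not {"event", "time_years"} <= set(df.columns):
        raise CohortFormatError("cohort lacks event/time columns and no PSA series supplied")
    return [
        BcrOutcome(event=bool(e), time_years=float(t))
        for e, t in zip(df["event"], df["time_years"])
    ]


_TOOLS = (
    ("capra", "ia_capra"),
    ("damico", "ia_damico"),
)


def run_pipeline(config: RunConfig) -> Dict[str, pd.DataFrame]:
    """Execute the full analysis: score, filter, survival, evaluation, report.

    Writes tidy CSVs plus a JSON manifest under ``config.outdir`` and
    returns the tables in memory keyed by output name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    df = read_cohort(config.input)
    outcomes = _outcomes_from_inputs(df, config)

    payloads = list(df.itertuples(index=False))
    kept_pairs, tally = stard_filter(
        list(zip(payloads, outcomes)), min_followup_days=config.min_followup_days
    )
    logger.info("stard_filter: %s; kept %d", tally, len(kept_pairs))
    kept_ids = {id(p) for p, _ in kept_pairs}
    kept_mask = [id(p) in kept_ids for p in payloads]
    kept = df.loc[kept_mask].reset_index(drop=True)
    kept_outcomes = [o for p, o in zip(payloads, outcomes) if id(p) in kept_ids]

    scored = score_cohort(kept, config)
    scored["event"] = [int(o.event) for o in kept_outcomes]
    scored["time_years"] = [o.time_years for o in kept_outcomes]

    times = scored["time_years"].to_numpy()
    events = scored["event"].to_numpy().astype(bool)

    tables: Dict[str, pd.DataFrame] = {}
    tables["scored_cohort"] = scored

    # Kaplan-Meier per tool and group
    km_rows = []
    for tool in ("capra_group", "damico_group", "ia_capra_group", "ia_damico_group"):
        for label in ("low", "intermediate", "high"):
            mask = (scored[tool] == label).to_numpy()
            if mask.sum() == 0 or events[mask].sum() == 0:
                continue
            curve = km_estimate(times[mask], events[mask])
            for t, s, r in zip(curve.times, curve.survival, curve.at_risk):
                km_rows.append(
                    {"tool": tool, "group": label, "time_years": t, "survival": s, "at_risk": r}
                )
    tables["km_curves"] = pd.DataFrame(km_rows)

    # Cox backward stepwise on the preoperative + imaging predictor set
    X = np.column_stack(
        [
            scored["age_years"],
            np.log(scored["psa_ng_ml"]),
            scored["pct_positive_cores"],
            (
                scored[["gleason_primary", "gleason_secondary"]]
                .apply(lambda r: scoring.grade_group(GleasonInfo(int(r.iloc[0]), int(r.iloc[1]))), axis=1)
                >= 3
            ).astype(float),
            (767.0 - scored["adc_value"]) / 100.0,
            (scored["repe_likert"] >= config.likert_threshold).astype(float),
            scored["lesion_size_mm"].fillna(scored["lesion_size_mm"].median()),
        ]
    )
    names = [
        "age_years",
        "log_psa",
        "pct_positive_cores",
        "grade_group_3plus",
        "adc_per_minus100",
        "repe_positive",
        "lesion_size_mm",
    ]
    trace = backward_stepwise(X, times, events, names)
    step_rows = []
    for i, step in enumerate(trace.steps):
        for cand, a in step.candidate_aics.items():
            step_rows.append(
                {
                    "step": i,
                    "model_aic": step.current_aic,
                    "candidate_drop": cand,
                    "candidate_aic": a,
                    "dropped": cand == step.dropped,
                }
            )
    tables["stepwise_trace"] = pd.DataFrame(step_rows)
    pvals = trace.final_p_values()
    tables["final_model"] = pd.DataFrame(
        {
            "covariate": list(trace.final_names),
            "coefficient": list(trace.final_fit.coefficients) if trace.final_fit else [],
            "wald_p": [pvals[n] for n in trace.final_names],
        }
    )

    # ROC / DeLong / DCA / reallocation / risk tables per tool
    roc_rows, auc_rows, delong_rows, dca_rows, realloc_rows, risk_rows = [], [], [], [], [], []
    for base, ia in _TOOLS:
        base_scores = (
            scored["capra_score"].to_numpy(float)
            if base == "capra"
            else scored[f"{base}_group"].map(
                {"low": 1, "intermediate": 2, "high": 3}
            ).to_numpy(float)
        )
        ia_scores = scored[f"{ia}_score"].to_numpy(float)
        for tool, s in ((base, base_scores), (ia, ia_scores)):
            roc = auc_mann_whitney(s, events.astype(int))
            auc_rows.append(
                {"tool": tool, "auc": roc.auc, "ci_low": roc.auc_ci[0], "ci_high": roc.auc_ci[1]}
            )
            for t, sn, sp in zip(roc.thresholds, roc.sensitivity, roc.specificity):
                roc_rows.append(
                    {"tool": tool, "threshold": t, "sensitivity": sn, "specificity": sp}
                )
        auc_a, auc_b, z, p = delong_test(ia_scores, base_scores, events.astype(int))
        delong_rows.append(
            {"tool_a": ia, "tool_b": base, "auc_a": auc_a, "auc_b": auc_b, "z": z, "p": p}
        )

        for tool in (base, ia):
            groups = [RiskGroup.from_label(l) for l in scored[f"{tool}_group"]]
            risk = group_risk_to_probability(groups, times, events, config.horizon_years)
            dca = net_benefit(risk, events.astype(int), config.threshold_grid)
            dca.insert(0, "tool", tool)
            dca_rows.append(dca)
            rt = risk_table(groups, events.astype(int))
            rt.insert(0, "tool", tool)
            risk_rows.append(rt)

        base_groups = [RiskGroup.from_label(l) for l in scored[f"{base}_group"]]
        ia_groups = [RiskGroup.from_label(l) for l in scored[f"{ia}_group"]]
        mat = reallocation(base_groups, ia_groups).counts.copy()
        mat.insert(0, "base_group", mat.index)
        mat.insert(0, "tool", base)
        realloc_rows.append(mat.reset_index(drop=True))

    tables["roc_points"] = pd.DataFrame(roc_rows)
    tables["auc_summary"] = pd.DataFrame(auc_rows)
    tables["delong"] = pd.DataFrame(delong_rows)
    tables["decision_curve"] = pd.concat(dca_rows, ignore_index=True)
    tables["reallocation"] = pd.concat(realloc_rows, ignore_index=True)
    tables["risk_table"] = pd.concat(risk_rows, ignore_index=True)

    for name, table in tables.items():
        table.to_csv(outdir / f"{name}.csv", index=False)

    manifest = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_input": int(len(df)),
        "exclusions": tally,
        "n_analysed": int(len(scored)),
        "n_events": int(events.sum()),
        "versions": {
            "iarisk": _package_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("run_pipeline: wrote %d tables to %s", len(tables), outdir)
    return tables


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("iarisk")
    except PackageNotFoundError:
        return "unknown"
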