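"""First-in-man trial summary table: fixture, recomputation, reporting.

The packaged fixture (``data/first_in_man_trial.csv``) transcribes the
published per-patient summary of the 15-patient implant trial: demographics,
diary vs iEEG-confirmed seizure frequencies, phase-completion flags, and
advisory-phase performance.  This module recomputes every derived quantity
printed alongside it — the diary/iEEG discrepancy ratio per patient, the
column averages over their respective denominators, and the per-phase
completion counts — using the table's own rounding convention (half-up, to
the printed precision).

Cell conventions: blank = no data; ``N/E`` = not evaluable (blue indicator
not enabled); ``ALL`` = every seizure occurred under the high-likelihood
advisory (infinite likelihood ratio).  One patient's blue-indicator status
is unknown (explanted before assessment) and is stored as an explicit
``unknown``, excluded from blue denominators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

ALL_SENTINEL = "ALL"
NOT_EVALUABLE = "N/E"

_PCT_COLS = ("red_sens_ccs_pct", "red_sens_ces_pct", "blue_npv_pct",
             "time_high_pct", "time_low_pct")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (the table's printed convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PatientRecord:
    patient: int
    age: int
    gender: str
    zone: str
    prior_resection: bool
    prior_vns: bool
    aeds: str
    sf_pt: float | None
    sf_eeg: float | None
    data_collection_completed: bool
    data_collection_fail_reason: str
    validation_completed: bool
    validation_fail_reason: str
    advisory_completed: bool
    advisory_fail_reason: str
    ccs: float | None
    ces_ccs: float | None
    red_sens_ccs_pct: float | None
    red_sens_ces_pct: float | None
    blue_npv_pct: float | None
    time_high_pct: float | None
    time_low_pct: float | None        # None covers both blank and N/E
    time_low_not_evaluable: bool
    lr_ccs: float | None              # inf encodes the ALL sentinel
    lr_ces: float | None
    blue_enabled: bool | None         # None = unknown
    note: str

    def __post_init__(self) -> None:
        for col in _PCT_COLS:
            v = getattr(self, col)
            if v is not None and not 0 <= v <= 100:
                raise ValueError(f"{col}={v} outside [0, 100]")
        if self.advisory_completed and not self.validation_completed:
            raise ValueError("advisory completion implies validation completion")


def discrepancy_ratio(sf_pt: float, sf_eeg: float) -> float | None:
    """Diary frequency over iEEG-confirmed frequency, half-up to 2 decimals.

    Undefined (None) when no seizure was captured on iEEG.
    """
    if sf_pt < 0 or sf_eeg < 0:
        raise ValueError("seizure frequencies must be non-negative")
    if sf_eeg == 0:
        return None
    return round_half_up(sf_pt / sf_eeg, 2)


def fixture_path() -> Path:
    return Path(resources.files("seizure_advisory") / "data"
                / "first_in_man_trial.csv")


def _parse_opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def load_trial_table(path: Path | None = None) -> list[PatientRecord]:
    """Load and schema-validate the packaged (or an external) fixture."""
    df = pd.read_csv(path or fixture_path(), dtype=str).fillna("")
    required = {"patient", "age", "sf_pt", "sf_eeg", "ccs", "blue_enabled"}
    if not required <= set(df.columns):
        raise ValueError("fixture schema mismatch: missing "
                         f"{sorted(required - set(df.columns))}")
    records = []
    for _, r in df.iterrows():
        def lr(v):
            if v == "":
                return None
            if v == ALL_SENTINEL:
                return float("inf")
            return float(v)

        blue = {"1": True, "0": False, "unknown": None, "": None}[r["blue_enabled"]]
        records.append(PatientRecord(
            patient=int(r["patient"]), age=int(r["age"]), gender=r["gender"],
            zone=r["zone"], prior_resection=r["prior_resection"] == "1",
            prior_vns=r["prior_vns"] == "1", aeds=r["aeds"],
            sf_pt=_parse_opt_float(r["sf_pt"]),
            sf_eeg=_parse_opt_float(r["sf_eeg"]),
            data_collection_completed=r["data_collection_completed"] == "1",
            data_collection_fail_reason=r["data_collection_fail_reason"],
            validation_completed=r["validation_completed"] == "1",
            validation_fail_reason=r["validation_fail_reason"],
            advisory_completed=r["advisory_completed"] == "1",
            advisory_fail_reason=r["advisory_fail_reason"],
            ccs=_parse_opt_float(r["ccs"]),
            ces_ccs=_parse_opt_float(r["ces_ccs"]),
            red_sens_ccs_pct=_parse_opt_float(r["red_sens_ccs_pct"]),
            red_sens_ces_pct=_parse_opt_float(r["red_sens_ces_pct"]),
            blue_npv_pct=_parse_opt_float(r["blue_npv_pct"]),
            time_high_pct=_parse_opt_float(r["time_high_pct"]),
            time_low_pct=(None if r["time_low_pct"] in ("", NOT_EVALUABLE)
                          else float(r["time_low_pct"])),
            time_low_not_evaluable=r["time_low_pct"] == NOT_EVALUABLE,
            lr_ccs=lr(r["lr_ccs"]), lr_ces=lr(r["lr_ces"]),
            blue_enabled=blue, note=r["note"]))
    return records


def save_trial_table(records: list[PatientRecord], path) -> None:
    """Serialize back to the fixture schema (round-trip identity)."""
    rows = []
    for p in records:
        def fmt_lr(v):
            if v is None:
                return ""
            if np.isinf(v):
                return ALL_SENTINEL
            return f"{v:g}"

        def fmt(v, nd=None):
            if v is None:
                return ""
            if nd is not None:
                return f"{v:.{nd}f}"
            return f"{v:g}"

        rows.append({
            "patient": p.patient, "age": p.age, "gender": p.gender,
            "zone": p.zone, "prior_resection": int(p.prior_resection),
            "prior_vns": int(p.prior_vns), "aeds": p.aeds,
            "sf_pt": fmt(p.sf_pt), "sf_eeg": fmt(p.sf_eeg, 2),
            "data_collection_completed": int(p.data_collection_completed),
            "data_collection_fail_reason": p.data_collection_fail_reason,
            "validation_completed": int(p.validation_completed),
            "validation_fail_reason": p.validation_fail_reason,
            "advisory_completed": int(p.advisory_completed),
            "advisory_fail_reason": p.advisory_fail_reason,
            "ccs": fmt(p.ccs), "ces_ccs": fmt(p.ces_ccs),
            "red_sens_ccs_pct": fmt(p.red_sens_ccs_pct),
            "red_sens_ces_pct": fmt(p.red_sens_ces_pct),
            "blue_npv_pct": fmt(p.blue_npv_pct),
            "time_high_pct": fmt(p.time_high_pct),
            "time_low_pct": (NOT_EVALUABLE if p.time_low_not_evaluable
                             else fmt(p.time_low_pct)),
            "lr_ccs": fmt_lr(p.lr_ccs), "lr_ces": fmt_lr(p.lr_ces),
            "blue_enabled": ("unknown" if p.blue_enabled is None and
                             p.advisory_fail_reason else
                             "" if p.blue_enabled is None else
                             str(int(p.blue_enabled))),
            "note": p.note,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class TrialSummary:
    """Column means over their defined denominators, plus phase counts."""

    n_patients: int
    mean_age: float
    n_prior_resection: int
    pct_prior_resection: float
    mean_sf_pt: float
    n_sf_pt: int
    mean_sf_eeg: float
    n_sf_eeg: int
    discrepancy_ratios: dict[int, float | None]
    min_discrepancy: float
    max_discrepancy: float
    n_data_collection: int
    pct_data_collection: float
    n_validation: int
    pct_validation: float
    n_advisory: int
    pct_advisory: float
    mean_ccs: float
    n_ccs: int
    mean_ces_ccs: float
    mean_red_sens_ccs_pct: float
    n_red_sens: int
    mean_red_sens_ces_pct: float
    mean_blue_npv_pct: float
    n_blue_npv: int
    mean_time_high_pct: float
    mean_time_low_pct: float
    n_time_low: int
    mean_lr_ccs: float
    n_lr: int
    mean_lr_ces: float


def _mean(values: list[float]) -> tuple[float, int]:
    if not values:
        raise ValueError("empty table column")
    return float(np.mean(values)), len(values)


def summarize_table(records: list[PatientRecord]) -> TrialSummary:
    """Recompute the table's average row; ALL sentinels and missing cells
    are excluded from their column means, and each mean carries its
    denominator."""
    if not records:
        raise ValueError("empty table")
    n = len(records)
    ratios = {p.patient: (discrepancy_ratio(p.sf_pt, p.sf_eeg)
                          if p.sf_pt is not None and p.sf_eeg is not None
                          else None)
              for p in records}
    defined = [v for v in ratios.values() if v is not None]
    sf_pt, n_sf_pt = _mean([p.sf_pt for p in records if p.sf_pt is not None])
    sf_eeg, n_sf_eeg = _mean([p.sf_eeg for p in records if p.sf_eeg is not None])
    ccs, n_ccs = _mean([p.ccs for p in records if p.ccs is not None])
    ces, _ = _mean([p.ces_ccs for p in records if p.ces_ccs is not None])
    rs_ccs, n_rs = _mean([p.red_sens_ccs_pct for p in records
                          if p.red_sens_ccs_pct is not None])
    rs_ces, _ = _mean([p.red_sens_ces_pct for p in records
                       if p.red_sens_ces_pct is not None])
    npv, n_npv = _mean([p.blue_npv_pct for p in records
                        if p.blue_npv_pct is not None])
    th, _ = _mean([p.time_high_pct for p in records
                   if p.time_high_pct is not None])
    tl, n_tl = _mean([p.time_low_pct for p in records
                      if p.time_low_pct is not None])
    lr_ccs, n_lr = _mean([p.lr_ccs for p in records
                          if p.lr_ccs is not None and np.isfinite(p.lr_ccs)])
    lr_ces, _ = _mean([p.lr_ces for p in records
                       if p.lr_ces is not None and np.isfinite(p.lr_ces)])
    n_dc = sum(p.data_collection_completed for p in records)
    n_val = sum(p.validation_completed for p in records)
    n_adv = sum(p.advisory_completed for p in records)
    n_res = sum(p.prior_resection for p in records)
    return TrialSummary(
        n_patients=n,
        mean_age=round_half_up(np.mean([p.age for p in records]), 1),
        n_prior_resection=n_res,
        pct_prior_resection=round_half_up(100 * n_res / n),
        mean_sf_pt=round_half_up(sf_pt, 2), n_sf_pt=n_sf_pt,
        mean_sf_eeg=round_half_up(sf_eeg, 2), n_sf_eeg=n_sf_eeg,
        discrepancy_ratios=ratios,
        min_discrepancy=min(defined), max_discrepancy=max(defined),
        n_data_collection=n_dc,
        pct_data_collection=round_half_up(100 * n_dc / n),
        n_validation=n_val, pct_validation=round_half_up(100 * n_val / n),
        n_advisory=n_adv, pct_advisory=round_half_up(100 * n_adv / n),
        mean_ccs=round_half_up(ccs, 1), n_ccs=n_ccs,
        mean_ces_ccs=round_half_up(ces, 1),
        mean_red_sens_ccs_pct=round_half_up(rs_ccs), n_red_sens=n_rs,
        mean_red_sens_ces_pct=round_half_up(rs_ces),
        mean_blue_npv_pct=round_half_up(npv, 1), n_blue_npv=n_npv,
        mean_time_high_pct=round_half_up(th),
        mean_time_low_pct=round_half_up(tl), n_time_low=n_tl,
        mean_lr_ccs=round_half_up(lr_ccs, 1), n_lr=n_lr,
        mean_lr_ces=round_half_up(lr_ces, 1))


def render_report(summary: TrialSummary,
                  performance_reports: dict[str, dict] | None = None
                  ) -> tuple[str, dict]:
    """Deterministic human-readable text + JSON bundle."""
    lines = [
        "Trial summary",
        "=============",
        f"patients: {summary.n_patients}  (mean age {summary.mean_age})",
        f"prior resection: {summary.n_prior_resection} "
        f"({summary.pct_prior_resection:.0f}%)",
        f"diary seizure frequency (mean of {summary.n_sf_pt}): "
        f"{summary.mean_sf_pt}/month",
        f"iEEG seizure frequency (mean of {summary.n_sf_eeg}): "
        f"{summary.mean_sf_eeg}/month",
        f"diary/iEEG discrepancy ratio range: "
        f"{summary.min_discrepancy:.2f}–{summary.max_discrepancy:.2f}",
        f"completed data collection: {summary.n_data_collection} "
        f"({summary.pct_data_collection:.0f}%)",
        f"passed validation: {summary.n_validation} "
        f"({summary.pct_validation:.0f}%)",
        f"completed advisory phase: {summary.n_advisory} "
        f"({summary.pct_advisory:.0f}%)",
        f"mean seizures (CCS / CES+CCS, n={summary.n_ccs}): "
        f"{summary.mean_ccs} / {summary.mean_ces_ccs}",
        f"mean red sensitivity (CCS / CES+CCS, n={summary.n_red_sens}): "
        f"{summary.mean_red_sens_ccs_pct:.0f}% / "
        f"{summary.mean_red_sens_ces_pct:.0f}%",
        f"mean blue NPV (n={summary.n_blue_npv}): "
        f"{summary.mean_blue_npv_pct}%",
        f"mean time in high / low advisory: "
        f"{summary.mean_time_high_pct:.0f}% / "
        f"{summary.mean_time_low_pct:.0f}%",
        f"mean likelihood ratio (CCS / CES+CCS, n={summary.n_lr}): "
        f"{summary.mean_lr_ccs} / {summary.mean_lr_ces}",
    ]
    if performance_reports:
        lines += ["", "Run reports", "-----------"]
        for name in sorted(performance_reports):
            rep = performance_reports[name]
            if rep is None:
                lines.append(f"{name}: not evaluable")
                continue
            red = rep["red"]
            lines.append(
                f"{name}: sensitivity "
                f"{red['sensitivity']:.2f} at red time "
                f"{red['time_fraction_red']:.2f} "
                f"(p={red['p_value_vs_chance']:.3g}); "
                f"advances: {rep['validation']['advances']}")
    bundle = {"summary": {k: v for k, v in asdict(summary).items()},
              "runs": performance_reports or {}}
    return "\n".join(lines) + "\n", bundle
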