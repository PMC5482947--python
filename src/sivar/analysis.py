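"""End-to-end cohort analysis: select -> identify -> pool -> compare -> report.

Cohort rules mirror the study design: patients must start therapy within
12 h of ICU admission and have at least 24 h of BG-covered therapy data
(Cohort 1); the >=72 h subset (Cohort 2) controls for dropout/competing risk.
For both cohorts and both metrics (hourly SI level and %dSI variability) the
analysis pools values into 6-h blocks per outcome group, bootstraps the
difference of medians (95% and Bonferroni-consistent 99.6% CIs), applies the
two-sample KS test, and tests clinical equivalence against the
measurement-error-derived range. A cohort-level BG equivalence check against
the +/-1 SD (9.4%) BG-error band is included.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .equivalence import (ComparisonVerdict, EquivalenceRange,
                          bootstrap_median_diff, compare_block,
                          derive_equivalence_range, equivalence_verdict)
from .icing import IcingParameters, ModelInputError
from .identification import InsulinSensitivityModel, SIProfileResults
from .records import PatientRecord
from .variability import (BlockSample, block_summary_table, empirical_cdf,
                          pool_blocks)

logger = logging.getLogger(__name__)

COHORT_RULES = ("cohort1", "cohort2")
REASON_LATE_START = "late_start"
REASON_SHORT_THERAPY = "short_therapy"
REASON_SHORT_STAY = "short_stay_72h"


@dataclass(frozen=True)
class CohortSelection:
    """Inclusion result: ids kept, and an exclusion log (id, reason)."""

    rule: str
    included: tuple[str, ...]
    excluded: tuple[tuple[str, str], ...]

    def to_frame(self) -> pd.DataFrame:
        rows = [(pid, self.rule, "included", "") for pid in self.included]
        rows += [(pid, self.rule, "excluded", reason) for pid, reason in self.excluded]
        return pd.DataFrame(rows, columns=["patient_id", "rule", "status", "reason"])


def select_cohort(records: Sequence[PatientRecord], rule: str) -> CohortSelection:
    """Apply the inclusion rule; edge ties (exactly 12 h / 24 h / 72 h) are
    inclusive. Every input patient appears exactly once."""
    if rule not in COHORT_RULES:
        raise ModelInputError(f"rule must be one of {COHORT_RULES}")
    included, excluded = [], []
    for r in records:
        for fname in ("admission_time", "therapy_start"):
            if getattr(r, fname) is None or not np.isfinite(getattr(r, fname)):
                raise ModelInputError(f"patient {r.patient_id}: missing metadata {fname}")
        delay_h = (r.therapy_start - r.admission_time) / 60.0
        coverage = r.therapy_coverage_hours()
        if delay_h > 12.0:
            excluded.append((r.patient_id, REASON_LATE_START))
        elif coverage < 24.0:
            excluded.append((r.patient_id, REASON_SHORT_THERAPY))
        elif rule == "cohort2" and coverage < 72.0:
            excluded.append((r.patient_id, REASON_SHORT_STAY))
        else:
            included.append(r.patient_id)
    return CohortSelection(rule=rule, included=tuple(included), excluded=tuple(excluded))


def _per_patient_demographics(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        days = max(r.therapy_coverage_hours() / 24.0, 1e-9)
        rows.append((r.patient_id, r.outcome,
                     float(np.median(r.bg_values)),
                     r.bg_times.size / days,
                     float(np.median(r.insulin_rates)),
                     float(np.median(r.nutrition_rates))))
    return pd.DataFrame(rows, columns=["patient_id", "outcome", "median_bg",
                                       "bg_per_day", "median_insulin_u_h",
                                       "median_feed_g_h"])


def _demographics_summary(per_patient: pd.DataFrame) -> pd.DataFrame:
    out = []
    for group, sub in per_patient.groupby("outcome"):
        for col in ("median_bg", "bg_per_day", "median_insulin_u_h", "median_feed_g_h"):
            q25, q50, q75 = np.percentile(sub[col], [25, 50, 75])
            out.append((group, col, q50, q25, q75, len(sub)))
    return pd.DataFrame(out, columns=["group", "variable", "median", "q25", "q75", "n"])


def _block_bg_median(records: Sequence[PatientRecord], block: int,
                     block_hours: int) -> float:
    vals = []
    for r in records:
        rel = (r.bg_times - r.therapy_start) / 60.0
        m = (rel >= block * block_hours) & (rel < (block + 1) * block_hours)
        vals.append(r.bg_values[m])
    pooled = np.concatenate(vals) if vals else np.empty(0)
    return float(np.median(pooled)) if pooled.size else float("nan")


def _verdict_row(v: ComparisonVerdict, block_hours: int) -> dict:
    pct = v.diff_percent
    return {
        "block": v.block,
        "hours": f"{v.block * block_hours}-{(v.block + 1) * block_hours - 1}",
        "median_s": v.median_x, "median_ns": v.median_y,
        "n_s": v.n_x, "n_ns": v.n_y,
        "diff": v.diff.point, "ci95_lo": v.diff.ci95[0], "ci95_hi": v.diff.ci95[1],
        "ci996_lo": v.diff.ci996[0], "ci996_hi": v.diff.ci996[1],
        "diff_pct": pct.point if pct else np.nan,
        "pct_ci95_lo": pct.ci95[0] if pct else np.nan,
        "pct_ci95_hi": pct.ci95[1] if pct else np.nan,
        "ks_p": v.ks_p,
        "sig95": v.difference_significant_95,
        "sig_bonferroni": v.significant_after_bonferroni,
        "half_width": v.equivalence_half_width,
        "equivalent": v.equivalent,
    }


class CohortAnalysis:
    """Fits the full between-group comparison for a set of patient records.

    Parameters mirror the study conventions: 72 analysis hours in twelve 6-h
    blocks, 1000 bootstrap resamples, BG error SD 9.4%. ``seed`` drives all
    bootstrap resampling through per-(cohort, metric, block) substreams so
    adding a block never perturbs the others.
    """

    def __init__(self, records: Sequence[PatientRecord],
                 params: IcingParameters | None = None,
                 horizon_hours: int = 72, block_hours: int = 6,
                 n_boot: int = 1000, bg_error_sd: float = 9.4,
                 seed: int = 0, cohorts: Sequence[str] = COHORT_RULES):
        if horizon_hours % block_hours:
            raise ModelInputError("horizon_hours must be a multiple of block_hours")
        self.records = list(records)
        self.params = params if params is not None else IcingParameters.defaults()
        self.horizon_hours = int(horizon_hours)
        self.block_hours = int(block_hours)
        self.n_blocks = self.horizon_hours // self.block_hours
        self.n_boot = int(n_boot)
        self.bg_error_sd = float(bg_error_sd)
        self.seed = int(seed)
        self.cohorts = tuple(cohorts)
        self._range_cache: dict[float, EquivalenceRange] = {}

    @classmethod
    def from_csv(cls, data_path, meta_path, **kwargs) -> "CohortAnalysis":
        from .records import read_records_csv

        return cls(read_records_csv(data_path, meta_path), **kwargs)

    # -- internals ----------------------------------------------------------
    def _eq_range(self, bg: float) -> EquivalenceRange:
        key = round(float(bg), 1) if np.isfinite(bg) else 6.0
        if key not in self._range_cache:
            self._range_cache[key] = derive_equivalence_range(
                self.params, bg_error_sd=self.bg_error_sd, reference_bg=key)
        return self._range_cache[key]

    def _substream(self, cohort: str, metric: str, block: int) -> np.random.Generator:
        ids = (self.seed, self.cohorts.index(cohort) if cohort in self.cohorts else 9,
               0 if metric == "si" else 1, block)
        return np.random.default_rng(np.random.SeedSequence(ids))

    def _identify(self, records: Sequence[PatientRecord]) -> list[SIProfileResults]:
        profiles = []
        for r in records:
            try:
                # one extra hour so the final block's forward %dSI exists
                profiles.append(InsulinSensitivityModel(r, self.params)
                                .fit(self.horizon_hours + 1))
            except ModelInputError as exc:
                raise ModelInputError(f"patient {r.patient_id}: {exc}") from exc
        return profiles

    # -- public API ---------------------------------------------------------
    def fit(self) -> "CohortAnalysisResults":
        by_id = {r.patient_id: r for r in self.records}
        selections, tables, cdf_frames = {}, {}, {}
        bg_equiv, demographics, notes = {}, {}, []

        for cohort in self.cohorts:
            sel = select_cohort(self.records, cohort)
            selections[cohort] = sel
            recs = [by_id[pid] for pid in sel.included]
            outcomes = {r.patient_id: r.outcome for r in recs}
            groups = set(outcomes.values())
            demographics[cohort] = _demographics_summary(_per_patient_demographics(recs)) \
                if recs else pd.DataFrame()
            if "survivor" not in groups or "non-survivor" not in groups:
                notes.append(f"{cohort}: an outcome arm is empty; comparisons skipped")
                continue

            profiles = self._identify(recs)
            for metric in ("si", "delta_si"):
                samples = pool_blocks(profiles, outcomes, metric=metric,
                                      n_blocks=self.n_blocks,
                                      block_hours=self.block_hours)
                by_key = {(s.block, s.group): s for s in samples}
                rows, cdf_rows = [], []
                for b in range(self.n_blocks):
                    x = by_key[(b, "survivor")]
                    y = by_key[(b, "non-survivor")]
                    for s in (x, y):
                        if s.n:
                            cdf = empirical_cdf(s)
                            frame = cdf.to_frame()
                            frame.insert(0, "group", s.group)
                            frame.insert(0, "block", b)
                            cdf_rows.append(frame)
                    if x.n == 0 or y.n == 0:
                        logger.warning("%s %s block %d empty; excluded from testing",
                                       cohort, metric, b)
                        continue
                    rng_b = self._substream(cohort, metric, b)
                    verdict = compare_block(x, y, self._eq_range(
                        _block_bg_median(recs, b, self.block_hours)),
                        n_boot=self.n_boot, seed=rng_b)
                    rows.append(_verdict_row(verdict, self.block_hours))
                tables[(cohort, metric)] = pd.DataFrame(rows)
                cdf_frames[(cohort, metric)] = (
                    pd.concat(cdf_rows, ignore_index=True) if cdf_rows
                    else pd.DataFrame(columns=["block", "group", "value", "cum_fraction"]))

            bg_equiv[cohort] = self._bg_equivalence(recs, cohort)

        return CohortAnalysisResults(
            model=self, selections=selections, tables=tables,
            cdf_data=cdf_frames, bg_equivalence=bg_equiv,
            demographics=demographics, notes=tuple(notes))

    def _bg_equivalence(self, recs: Sequence[PatientRecord], cohort: str) -> dict:
        bg_s = np.concatenate([r.bg_values for r in recs if r.outcome == "survivor"])
        bg_ns = np.concatenate([r.bg_values for r in recs if r.outcome == "non-survivor"])
        rng = self._substream(cohort, "si", 99)
        ci = bootstrap_median_diff(bg_s, bg_ns, n_boot=self.n_boot, seed=rng,
                                   mode="percent")
        rng_range = EquivalenceRange(half_width=self.bg_error_sd,
                                     basis=self.bg_error_sd,
                                     reference_bg=float(np.median(bg_s)))
        return {"percent_diff": ci.point, "ci95": list(ci.ci95),
                "half_width": rng_range.half_width,
                "equivalent": equivalence_verdict(ci.ci95, rng_range)}


def run_analysis(records: Sequence[PatientRecord],
                 params: IcingParameters | None = None,
                 **kwargs) -> "CohortAnalysisResults":
    """One-call pipeline over both cohort rules and both metrics."""
    return CohortAnalysis(records, params=params, **kwargs).fit()


@dataclass
class CohortAnalysisResults:
    """Results bundle: selection logs, block tables, CDFs, BG equivalence."""

    model: CohortAnalysis
    selections: Mapping[str, CohortSelection]
    tables: Mapping[tuple[str, str], pd.DataFrame]
    cdf_data: Mapping[tuple[str, str], pd.DataFrame]
    bg_equivalence: Mapping[str, dict]
    demographics: Mapping[str, pd.DataFrame]
    notes: tuple[str, ...] = ()

    def table(self, cohort: str = "cohort1", metric: str = "si") -> pd.DataFrame:
        return self.tables[(cohort, metric)]

    def summary(self) -> str:
        lines = ["Cohort comparison of insulin sensitivity and its variability",
                 "=" * 62]
        for note in self.notes:
            lines.append(f"note: {note}")
        for cohort in self.model.cohorts:
            sel = self.selections.get(cohort)
            if sel is None:
                continue
            lines.append(f"\n{cohort}: {len(sel.included)} included, "
                         f"{len(sel.excluded)} excluded")
            for metric, label in (("si", "SI level"), ("delta_si", "%dSI")):
                t = self.tables.get((cohort, metric))
                if t is None or t.empty:
                    continue
                n_eq = int(t["equivalent"].sum())
                n_sig = int(t["sig95"].sum())
                n_bonf = int(t["sig_bonferroni"].sum())
                lines.append(
                    f"  {label:9s}: equivalent in {n_eq}/{len(t)} blocks, "
                    f"significant (95%) in {n_sig}, after Bonferroni in {n_bonf}")
            bg = self.bg_equivalence.get(cohort)
            if bg:
                lines.append(
                    f"  cohort BG: {bg['percent_diff']:+.1f}% "
                    f"[{bg['ci95'][0]:+.1f}, {bg['ci95'][1]:+.1f}] vs "
                    f"+/-{bg['half_width']:.1f}% -> "
                    f"{'equivalent' if bg['equivalent'] else 'not equivalent'}")
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> list[Path]:
        """Write all artefacts as deterministic CSV/JSON; returns paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for (cohort, metric), t in sorted(self.tables.items()):
            p = out / f"results_{cohort}_{metric}.csv"
            t.to_csv(p, index=False, float_format="%.10g")
            written.append(p)
        for (cohort, metric), t in sorted(self.cdf_data.items()):
            p = out / f"cdf_{cohort}_{metric}.csv"
            t.to_csv(p, index=False, float_format="%.10g")
            written.append(p)
        excl = pd.concat([sel.to_frame() for sel in self.selections.values()],
                         ignore_index=True)
        p = out / "cohort_selection.csv"
        excl.to_csv(p, index=False)
        written.append(p)
        for cohort, d in sorted(self.demographics.items()):
            p = out / f"demographics_{cohort}.csv"
            d.to_csv(p, index=False, float_format="%.10g")
            written.append(p)
        p = out / "bg_equivalence.json"
        p.write_text(json.dumps(self.bg_equivalence, indent=2, sort_keys=True) + "\n")
        written.append(p)
        p = out / "summary.txt"
        p.write_text(self.summary() + "\n")
        written.append(p)
        return written

    def plot_cdfs(self, cohort: str = "cohort1", metric: str = "delta_si", ax=None):
        """Per-block empirical CDFs by outcome group (matplotlib)."""
        import matplotlib.pyplot as plt

        data = self.cdf_data[(cohort, metric)]
        n_blocks = self.model.n_blocks
        if ax is None:
            fig, axes = plt.subplots(3, 4, figsize=(14, 9), sharey=True)
            axes = axes.ravel()
        else:
            axes = [ax] * n_blocks
        for b in range(n_blocks):
            a = axes[b]
            for group, color in (("survivor", "tab:blue"), ("non-survivor", "tab:red")):
                sub = data[(data["block"] == b) & (data["group"] == group)]
                if len(sub):
                    a.step(sub["value"], sub["cum_fraction"], where="post",
                           color=color, label=group if b == 0 else None)
            a.set_title(f"hours {b * self.model.block_hours}-"
                        f"{(b + 1) * self.model.block_hours - 1}", fontsize=9)
        axes[0].legend(fontsize=8)
        return axes[0].figure


def render_report(results: CohortAnalysisResults, out_dir: str | Path) -> list[Path]:
    """Write the human-readable summary and all CSV/JSON artefacts."""
    return results.save(out_dir)
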