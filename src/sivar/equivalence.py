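"""Difference and clinical-equivalence testing between outcome groups.

Difference testing follows the study design: percentile bootstrap (1000
resamples with replacement, at the original sample sizes) on the difference
of medians, read at 95% and at 99.6% (the Bonferroni-corrected level for 12
comparisons, 0.05/12 ~ 0.004), plus a two-sample Kolmogorov-Smirnov test.

Equivalence testing accepts two groups as clinically indistinguishable when
the 95% CI of their difference lies wholly inside an equivalence range
derived from blood-glucose measurement error (SD 9.4%): the half-width is
the percent change in identified SI induced by a 1-SD systematic BG error,
taken as the narrowest value across a grid of observed clinical inputs.
Difference and equivalence are deliberately independent verdicts: a
difference can be statistically significant yet clinically equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .icing import IcingParameters, ModelInputError
from .records import PatientRecord
from .variability import BlockSample

N_BOOT_DEFAULT = 1000


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile-bootstrap difference of medians with nested CIs."""

    point: float
    ci95: tuple[float, float]
    ci996: tuple[float, float]
    n_boot: int
    seed: int | None
    mode: str

    def __post_init__(self):
        if not (self.ci95[0] <= self.ci95[1] and self.ci996[0] <= self.ci996[1]):
            raise ModelInputError("CI bounds out of order")


def _resolve_rng(seed) -> tuple[np.random.Generator, int | None]:
    if isinstance(seed, np.random.Generator):
        return seed, None
    return np.random.default_rng(seed), seed


def bootstrap_median_diff(x, y, n_boot: int = N_BOOT_DEFAULT, seed=None,
                          mode: str = "absolute") -> BootstrapCI:
    """Bootstrap med(x) - med(y); ``mode='percent'`` gives
    100*(med(x*) - med(y*))/med(y*) per resample.

    Resamples are drawn with replacement at the original sizes; CIs are
    percentile intervals at 95% and 99.6%. Deterministic given ``seed``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ModelInputError("each sample needs n >= 2 for bootstrapping")
    rng, seed_val = _resolve_rng(seed)

    med_y = np.median(y)
    if mode == "percent" and med_y == 0:
        raise ModelInputError("percent mode undefined: med(y) = 0")
    if mode not in ("absolute", "percent"):
        raise ModelInputError(f"unknown mode {mode!r}")

    bx = np.median(x[rng.integers(0, x.size, size=(n_boot, x.size))], axis=1)
    by = np.median(y[rng.integers(0, y.size, size=(n_boot, y.size))], axis=1)
    if mode == "percent":
        boots = 100.0 * (bx - by) / by
        point = 100.0 * (np.median(x) - med_y) / med_y
    else:
        boots = bx - by
        point = float(np.median(x) - med_y)

    lo95, hi95 = np.percentile(boots, [2.5, 97.5])
    lo996, hi996 = np.percentile(boots, [0.2, 99.8])
    # enforce nesting against percentile-interpolation edge effects
    lo996, hi996 = min(lo996, lo95), max(hi996, hi95)
    return BootstrapCI(point=float(point), ci95=(float(lo95), float(hi95)),
                       ci996=(float(lo996), float(hi996)),
                       n_boot=int(n_boot), seed=seed_val, mode=mode)


def ks_two_sample(x, y, method: str = "auto") -> float:
    """Two-sided two-sample Kolmogorov-Smirnov p-value.

    ``method='auto'`` uses the exact distribution for small samples and the
    asymptotic one at study scale.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ModelInputError("each sample needs n >= 2 for the KS test")
    return float(stats.ks_2samp(x, y, alternative="two-sided", method=method).pvalue)


def bonferroni_threshold(alpha: float = 0.05, m: int = 12) -> float:
    """Per-test alpha under a Bonferroni correction for m comparisons."""
    if m < 1:
        raise ModelInputError("m must be >= 1")
    if not (0 < alpha < 1):
        raise ModelInputError("alpha must lie in (0, 1)")
    return alpha / m


# -- measurement-error equivalence range ------------------------------------

#: observed clinical-input grid over which the narrowest range is taken
FEED_GRID_G_PER_H = (2.0, 3.0, 4.0, 5.0, 6.0)
INSULIN_REF_U_PER_H = 3.0


@dataclass(frozen=True)
class EquivalenceRange:
    """Symmetric equivalence band (percent) derived from BG error."""

    half_width: float        # percent
    basis: float             # BG error SD used (percent)
    reference_bg: float      # mmol/L

    def __post_init__(self):
        # zero only in the degenerate no-error case
        if self.half_width < 0:
            raise ModelInputError("half_width must be >= 0")

    def contains(self, lo: float, hi: float) -> bool:
        return (-self.half_width <= lo) and (hi <= self.half_width)


def _reference_record(bg: float, insulin_u_h: float, feed_g_h: float,
                      hours: int = 24) -> PatientRecord:
    """Synthetic steady reference: constant BG measured hourly under constant
    inputs. Used only to probe the identification operator's error response."""
    times = 60.0 * np.arange(hours + 1)
    return PatientRecord(
        patient_id="__reference__", outcome="survivor",
        admission_time=0.0, therapy_start=0.0,
        bg_times=times, bg_values=np.full(times.size, float(bg)),
        insulin_times=[0.0], insulin_rates=[insulin_u_h],
        nutrition_times=[0.0], nutrition_rates=[feed_g_h],
    )


def _si_at_scale(record: PatientRecord, params: IcingParameters, hour: int,
                 scale: float):
    from .identification import InsulinSensitivityModel

    scaled = PatientRecord(
        patient_id=record.patient_id, outcome=record.outcome,
        admission_time=record.admission_time, therapy_start=record.therapy_start,
        bg_times=record.bg_times, bg_values=record.bg_values * scale,
        insulin_times=record.insulin_times, insulin_rates=record.insulin_rates,
        nutrition_times=record.nutrition_times, nutrition_rates=record.nutrition_rates,
        diabetic_status=record.diabetic_status)
    model = InsulinSensitivityModel(scaled, params)
    arrays = model._prepare(hour + 1)
    if arrays is None:
        raise ModelInputError("reference record too short")
    return model._solve_hour(arrays, hour)


def si_error_sensitivity(record: PatientRecord, params: IcingParameters,
                         bg_error_sd: float, hour: int = 12) -> float:
    """Percent change in identified SI per 1-SD systematic BG error.

    The window's BG is scaled by (1 +/- sd) — a meter calibration error over
    the fitting window — SI is re-identified through the same integral solve,
    and the two perturbation magnitudes are averaged (symmetric sensitivity).
    """
    eps = bg_error_sd / 100.0
    si0, flag0 = _si_at_scale(record, params, hour, 1.0)
    if flag0 != "ok" or si0 is None or si0 <= 0:
        raise ModelInputError("reference scenario is not identifiable")
    if eps == 0:
        return 0.0
    deltas = []
    for scale in (1.0 + eps, 1.0 - eps):
        si, flag = _si_at_scale(record, params, hour, scale)
        if si is None:
            raise ModelInputError("perturbed reference became unidentifiable")
        deltas.append(abs(si - si0) / si0 * 100.0)
    return float(np.mean(deltas))


def derive_equivalence_range(params: IcingParameters | None = None,
                             reference_record: PatientRecord | None = None,
                             bg_error_sd: float = 9.4,
                             reference_bg: float = 6.0,
                             feed_grid: Sequence[float] = FEED_GRID_G_PER_H,
                             insulin_u_h: float = INSULIN_REF_U_PER_H) -> EquivalenceRange:
    """Equivalence half-width (percent) at one reference BG level.

    Without an explicit reference record, steady references are built across
    the observed clinical-input grid (carbohydrate rates; endogenous secretion
    active and suppressed) and the narrowest — most stringent — sensitivity is
    reported, mirroring the choice of the narrowest range across the range of
    clinical inputs observed.
    """
    params = params if params is not None else IcingParameters.defaults()
    if bg_error_sd < 0:
        raise ModelInputError("bg_error_sd must be >= 0")
    if bg_error_sd == 0:
        return EquivalenceRange(half_width=0.0, basis=0.0,
                                reference_bg=float(reference_bg))
    if reference_record is not None:
        hw = si_error_sensitivity(reference_record, params, bg_error_sd)
        return EquivalenceRange(half_width=hw, basis=float(bg_error_sd),
                                reference_bg=float(reference_bg))
    widths = []
    for feed in feed_grid:
        for u_en_active in (True, False):
            p = params.replace(u_en_active=u_en_active)
            rec = _reference_record(reference_bg, insulin_u_h, feed)
            try:
                widths.append(si_error_sensitivity(rec, p, bg_error_sd))
            except ModelInputError:
                continue  # inadmissible corner of the input grid
    if not widths:
        raise ModelInputError("no identifiable reference scenario on the input grid")
    return EquivalenceRange(half_width=float(min(widths)), basis=float(bg_error_sd),
                            reference_bg=float(reference_bg))


def equivalence_range_profile(params: IcingParameters | None = None,
                              bg_grid: Sequence[float] = tuple(np.arange(4.4, 8.01, 0.4)),
                              bg_error_sd: float = 9.4,
                              **kwargs):
    """Half-width as a function of reference BG (the range varies with BG)."""
    import pandas as pd

    rows = [(float(bg), derive_equivalence_range(params, bg_error_sd=bg_error_sd,
                                                 reference_bg=bg, **kwargs).half_width)
            for bg in bg_grid]
    return pd.DataFrame(rows, columns=["bg", "half_width_pct"])


def equivalence_verdict(ci95: tuple[float, float], eq_range: EquivalenceRange) -> bool:
    """True iff the 95% CI lies wholly inside [-half_width, +half_width].

    For SI use the percent-difference CI; for %dSI use the absolute-difference
    CI (already in percent units).
    """
    lo, hi = ci95
    if lo > hi:
        raise ModelInputError("CI bounds out of order")
    return eq_range.contains(lo, hi)


@dataclass(frozen=True)
class ComparisonVerdict:
    """Full per-block comparison: difference, significance, KS, equivalence."""

    block: int
    metric: str
    median_x: float
    median_y: float
    n_x: int
    n_y: int
    diff: BootstrapCI            # absolute difference, reporting form
    diff_percent: BootstrapCI | None  # percent-of-y-median form (SI only)
    ks_p: float
    difference_significant_95: bool
    significant_after_bonferroni: bool
    equivalence_half_width: float
    equivalent: bool

    def __post_init__(self):
        if self.significant_after_bonferroni and not self.difference_significant_95:
            raise ModelInputError(
                "Bonferroni significance without 95% significance is inconsistent")


def _excludes_zero(ci: tuple[float, float]) -> bool:
    return ci[0] > 0 or ci[1] < 0


def compare_block(x: BlockSample, y: BlockSample, eq_range: EquivalenceRange,
                  n_boot: int = N_BOOT_DEFAULT, seed=None) -> ComparisonVerdict:
    """Assemble bootstrap CIs, KS p and both verdicts for one block.

    ``x`` and ``y`` are the same block/metric for the two outcome groups.
    For the SI metric the equivalence test uses the percent-of-y-median CI;
    for %dSI the absolute CI is already in percent units.
    """
    if x.block != y.block or x.metric != y.metric:
        raise ModelInputError("block samples are not comparable")
    if x.n == 0 or y.n == 0:
        raise ModelInputError(f"block {x.block}: empty sample")
    rng, seed_val = _resolve_rng(seed)
    state = rng.bit_generator.state
    diff_abs = bootstrap_median_diff(x.values, y.values, n_boot=n_boot,
                                     seed=rng, mode="absolute")
    if x.metric == "si":
        rng.bit_generator.state = state  # same resampling stream for both forms
        diff_pct = bootstrap_median_diff(x.values, y.values, n_boot=n_boot,
                                         seed=rng, mode="percent")
        equiv_ci = diff_pct.ci95
    else:
        diff_pct = None
        equiv_ci = diff_abs.ci95
    sig95 = _excludes_zero(diff_abs.ci95)
    sig_bonf = sig95 and _excludes_zero(diff_abs.ci996)
    return ComparisonVerdict(
        block=x.block, metric=x.metric,
        median_x=x.median, median_y=y.median, n_x=x.n, n_y=y.n,
        diff=diff_abs, diff_percent=diff_pct,
        ks_p=ks_two_sample(x.values, y.values),
        difference_significant_95=sig95,
        significant_after_bonferroni=sig_bonf,
        equivalence_half_width=eq_range.half_width,
        equivalent=equivalence_verdict(equiv_ci, eq_range),
    )
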