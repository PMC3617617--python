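"""Data-quality screening of AAR datasets.

Compromised analyses (contaminated, degraded or mis-run samples) are
identified from the covariance structure that closed-system protein
diagenesis imposes on the data, while natural variability is retained. Four
screens are applied in a fixed order:

1. a robust pre-cull of gross deviants in the Asx–Glx THAA concentration
   plane (they would otherwise wreck the regression-based tests),
2. three covariance tests — (i) FAA Asx D/L vs THAA Asx D/L (power law,
   dual-axis regression), (ii) THAA Asx vs Glx concentration (linear,
   orthogonal distance regression), (iii) THAA Asx D/L vs THAA Glx D/L
   (power law, dual-axis) — flagging points whose standardised residuals
   exceed a cutoff (default 2.5 sd),
3. a 4-sd screen on the differences between analytical duplicates, and
4. a 2-sd screen on total THAA concentration.

Because both variables of each covariance test carry error, non-linear
relations are tested twice with the axes swapped (a point must be an
outlier in *both* orientations), and the linear concentration test uses
orthogonal distance regression directly.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import odr as _odr
from scipy import optimize as _optimize
from scipy import stats as _stats

from .core import AMINO_ACIDS, Analysis, Dataset

# Reason codes for exclusions.
PRECULL = "PRECULL"
COVAR_FAA_THAA_ASX = "COVAR_FAA_THAA_ASX"
COVAR_CONC_ASX_GLX = "COVAR_CONC_ASX_GLX"
COVAR_DL_ASX_GLX = "COVAR_DL_ASX_GLX"
DUPLICATE_4SD = "DUPLICATE_4SD"
CONC_EXTREME_2SD = "CONC_EXTREME_2SD"

Family = Literal["linear", "power"]
ResidualMode = Literal["vertical", "orthogonal"]


class FitError(RuntimeError):
    """A regression failed to converge; carries solver diagnostics."""


class NoValidModelError(RuntimeError):
    """Every candidate family was rejected (e.g. negative gradient)."""


@dataclass
class RegressionFit:
    """A fitted regression line/curve with residuals in the fitted mode.

    ``params`` is ``(a, b)`` for the power family ``y = a * x**b`` and
    ``(intercept, slope)`` for the linear family.
    """

    family: Family
    params: tuple[float, float]
    adjusted_r2: float
    aic: float
    residuals: np.ndarray
    residual_mode: ResidualMode
    n: int
    f_stat_vs_mean: float = float("nan")
    yscale: float = 1.0  # data magnitude, for degeneracy detection

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.family == "power":
            a, b = self.params
            return a * np.power(x, b)
        b0, b1 = self.params
        return b0 + b1 * x

    def gradient(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.family == "power":
            a, b = self.params
            return a * b * np.power(x, b - 1.0)
        return np.full_like(x, self.params[1])

    def summary(self) -> dict:
        return {
            "family": self.family,
            "params": [float(p) for p in self.params],
            "adjusted_r2": float(self.adjusted_r2),
            "aic": float(self.aic),
            "residual_mode": self.residual_mode,
            "n": int(self.n),
        }


class StandardisedResiduals(NamedTuple):
    values: np.ndarray
    degenerate: bool


@dataclass
class OutlierReport:
    """Accumulated outcome of the screening pipeline.

    ``excluded`` maps analysis ids to the set of reason codes that removed
    the whole analysis; ``value_removals`` lists (analysis_id, amino_acid,
    reason) for single-amino-acid removals from the duplicate screen.
    """

    cutoff: float
    excluded: dict[str, set[str]] = field(default_factory=dict)
    value_removals: list[tuple[str, str, str]] = field(default_factory=list)
    fits: dict[str, dict] = field(default_factory=dict)

    def add(self, analysis_id: str, reason: str) -> None:
        self.excluded.setdefault(analysis_id, set()).add(reason)

    @property
    def flagged_ids(self) -> set[str]:
        """Ids touched by any screen, whole-analysis or value-level."""
        return set(self.excluded) | {aid for aid, _, _ in self.value_removals}

    def to_json(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "excluded": {k: sorted(v) for k, v in sorted(
                self.excluded.items())},
            "value_removals": [list(t) for t in self.value_removals],
            "fits": self.fits,
        }


@dataclass
class ScreeningConfig:
    """Tunable screening thresholds (defaults follow standard practice)."""

    cutoff: float = 2.5            # stdev multiple for covariance tests
    precull_threshold: float = 10  # robust-distance multiple (x MAD)
    duplicate_k: float = 4.0       # stdev multiple for duplicate screen
    concentration_k: float = 2.0   # stdev multiple for THAA conc screen
    concentration_total: bool = True  # sum over amino acids (else per-AA)


# ---------------------------------------------------------------------------
# Regression machinery
# ---------------------------------------------------------------------------

def fit_regression(x, y, family: Family = "linear",
                   residual_mode: ResidualMode = "vertical") -> RegressionFit:
    """Least-squares fit of a linear or power curve in the requested mode.

    Vertical mode minimises squared y-residuals; orthogonal mode minimises
    perpendicular point-to-curve distances (error in both variables).
    Residuals are reported in the fitted mode (signed by the y-residual).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need >= 5 paired points")
    if family == "power" and np.any(x <= 0):
        raise ValueError("power family requires x > 0 on all points")

    if residual_mode == "orthogonal":
        params, resid = _fit_orthogonal(x, y, family)
    elif family == "linear":
        b1, b0 = np.polyfit(x, y, 1)
        params = (float(b0), float(b1))
        resid = y - (b0 + b1 * x)
    else:
        params = _fit_power_vertical(x, y)
        resid = y - params[0] * np.power(x, params[1])

    fit = RegressionFit(family, params, float("nan"), float("nan"),
                        np.asarray(resid, dtype=float), residual_mode,
                        int(x.size))
    _attach_criteria(fit, x, y)
    return fit


def _fit_power_vertical(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    mask = y > 0
    if mask.sum() >= 2:
        b, loga = np.polyfit(np.log(x[mask]), np.log(y[mask]), 1)
        p0 = (math.exp(loga), b)
    else:
        p0 = (1.0, 1.0)
    try:
        popt, _ = _optimize.curve_fit(
            lambda t, a, b: a * np.power(t, b), x, y, p0=p0, maxfev=20000)
    except (RuntimeError, _optimize.OptimizeWarning) as exc:
        raise FitError(f"power fit did not converge: {exc}") from exc
    return (float(popt[0]), float(popt[1]))


def _fit_orthogonal(x: np.ndarray, y: np.ndarray,
                    family: Family) -> tuple[tuple[float, float], np.ndarray]:
    if family == "linear":
        b1, b0 = np.polyfit(x, y, 1)
        model = _odr.Model(lambda beta, t: beta[0] + beta[1] * t)
        beta0 = [b0, b1]
    else:
        a0, b0p = _fit_power_vertical(x, y)
        model = _odr.Model(lambda beta, t: beta[0] * np.power(t, beta[1]))
        beta0 = [a0, b0p]
    out = _odr.ODR(_odr.RealData(x, y), model, beta0=beta0).run()
    # ones digit 1-3 = converged; tens digits carry benign rank warnings
    if not (out.info % 10 in (1, 2, 3) and out.info < 50000):
        raise FitError(f"ODR did not converge: {out.stopreason}")
    # signed perpendicular distance: magnitude from the (delta, eps)
    # adjustments, sign from the vertical residual
    delta = np.atleast_1d(np.asarray(out.delta, dtype=float))
    eps = np.asarray(out.eps, dtype=float)
    dist = np.hypot(delta, eps) * np.sign(np.where(eps == 0, 1.0, eps))
    if family == "linear":
        params = (float(out.beta[0]), float(out.beta[1]))
    else:
        params = (float(out.beta[0]), float(out.beta[1]))
    return params, dist


def _attach_criteria(fit: RegressionFit, x: np.ndarray,
                     y: np.ndarray) -> None:
    """Adjusted R^2, AIC and an F statistic, from vertical residuals.

    Goodness-of-fit criteria are conventionally quoted on the response
    scale, so they are computed from vertical residuals of the fitted curve
    regardless of the fitting mode.
    """
    n = x.size
    k = 2  # both families have two parameters
    fit.yscale = float(np.max(np.abs(y))) or 1.0
    resid_v = y - fit.predict(x)
    ss_res = float(resid_v @ resid_v)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        r2 = 1.0 if ss_res == 0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    fit.adjusted_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    if ss_res > 0:
        fit.aic = n * math.log(ss_res / n) + 2 * (k + 1)
        fit.f_stat_vs_mean = ((ss_tot - ss_res) / (k - 1 + 1)) / (
            ss_res / (n - k))
    else:
        fit.aic = -math.inf
        fit.f_stat_vs_mean = math.inf


def select_function(x, y, candidates: Sequence[Family] = ("linear", "power"),
                    residual_mode: ResidualMode = "vertical") -> RegressionFit:
    """Fit each candidate family and pick one.

    A candidate whose fitted curve has a negative gradient anywhere on the
    observed x-range is rejected — racemization must progress with time, so
    a decreasing best-fit relation contradicts the reaction taking place.
    Among survivors the fit with the best adjusted R^2 wins (AIC and an F
    statistic are recorded on the fit for inspection). If every candidate
    is rejected a :class:`NoValidModelError` is raised, never a silent
    fallback.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    x = np.asarray(x, dtype=float)
    survivors: list[RegressionFit] = []
    for fam in candidates:
        try:
            fit = fit_regression(x, y, fam, residual_mode)
        except FitError:
            continue
        grid = np.linspace(x.min(), x.max(), 201)
        if fam == "power":
            grid = grid[grid > 0]
        if np.any(fit.gradient(grid) < 0):
            continue
        survivors.append(fit)
    if not survivors:
        raise NoValidModelError(
            "no candidate family yields a monotone non-decreasing fit on "
            f"the observed range (candidates: {list(candidates)})"
        )
    return max(survivors, key=lambda f: f.adjusted_r2)


def standardised_residuals(fit: RegressionFit) -> StandardisedResiduals:
    """Residuals divided by their sample standard deviation (ddof=1).

    Zero residual variance is degenerate (perfect fit): all-zero output
    with the ``degenerate`` flag set.
    """
    r = np.asarray(fit.residuals, dtype=float)
    if r.size < 3:
        raise ValueError("need >= 3 residuals")
    sd = float(np.std(r, ddof=1))
    # residual spread at machine precision relative to the data magnitude is
    # a perfect fit, not a population to standardise against
    if sd <= 1e-9 * fit.yscale:
        return StandardisedResiduals(np.zeros_like(r), True)
    return StandardisedResiduals(r / sd, False)


# ---------------------------------------------------------------------------
# Outlier flagging
# ---------------------------------------------------------------------------

def flag_outliers_dual_axis(ids, x, y, family: Family = "power",
                            cutoff: float = 2.5) -> set:
    """Dual-axis outlier test for non-linear relations.

    The relation is fitted twice with the dependent variable swapped
    (y ~ x and x ~ y, vertical residuals); a point is flagged only if its
    absolute standardised residual exceeds ``cutoff`` in *both*
    orientations, acknowledging error in both variables.
    """
    ids = list(ids)
    z_yx = standardised_residuals(fit_regression(x, y, family,
                                                 "vertical")).values
    z_xy = standardised_residuals(fit_regression(y, x, family,
                                                 "vertical")).values
    mask = (np.abs(z_yx) > cutoff) & (np.abs(z_xy) > cutoff)
    return {ids[i] for i in np.flatnonzero(mask)}


def flag_outliers_odr(ids, x, y, cutoff: float = 2.5) -> set:
    """Orthogonal-regression outlier test for linear relations.

    A single orthogonal linear fit; points whose standardised perpendicular
    residual exceeds ``cutoff`` are flagged. Symmetric in x and y.
    """
    ids = list(ids)
    fit = fit_regression(x, y, "linear", "orthogonal")
    z = standardised_residuals(fit).values
    return {ids[i] for i in np.flatnonzero(np.abs(z) > cutoff)}


def precull(ids, x, y, threshold: float = 10.0) -> set:
    """Robust pre-cull of gross deviants before any regression.

    Fits a median-slope (Theil–Sen) line and flags points whose orthogonal
    distance from it exceeds ``threshold`` × the median absolute deviation
    of all distances. Replaces the visual removal of points that would
    severely compromise the regression-based tests with a deterministic
    robust rule.
    """
    ids = list(ids)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slope = _stats.theilslopes(y, x)[0]
    intercept = float(np.median(y - slope * x))  # robust intercept
    dist = np.abs(y - (intercept + slope * x)) / math.hypot(1.0, slope)
    mad = float(np.median(np.abs(dist - np.median(dist))))
    # floor at machine precision relative to data magnitude so a perfectly
    # collinear cloud does not flag its own floating-point noise
    scale = float(np.max(np.abs(np.concatenate([x, y])), initial=1.0))
    cut = max(threshold * mad, 1e-9 * scale)
    return {ids[i] for i in np.flatnonzero(dist > cut)}


# ---------------------------------------------------------------------------
# Dataset-level screens
# ---------------------------------------------------------------------------

def _duplicate_pairs(analyses: list[Analysis]):
    """Yield duplicate pairs keyed by (core, assigned_year, fraction)."""
    groups: dict[tuple, list[Analysis]] = defaultdict(list)
    for a in analyses:
        groups[(a.core_code, a.assigned_year, a.fraction)].append(a)
    for key, members in groups.items():
        members = sorted(members, key=lambda a: a.replicate_id)
        if len(members) == 2 and members[0].replicate_id != \
                members[1].replicate_id:
            yield key, members[0], members[1]


def screen_duplicates(dataset: Dataset, k: float = 4.0,
                      report: OutlierReport | None = None) -> OutlierReport:
    """Flag analytical duplicate pairs that replicate poorly.

    For each amino acid and fraction, the population of signed D/L
    differences between duplicates is collected over the whole dataset and
    its standard deviation (ddof=1, including any candidate pair) computed.
    A pair whose absolute difference exceeds ``k``·sd is flagged. If only
    one amino acid trips, that amino acid's values are removed from both
    duplicates; if more than one trips, both analyses are excluded
    entirely. Unpaired replicates pass this screen by default.
    """
    if report is None:
        report = OutlierReport(cutoff=k)
    pairs = list(_duplicate_pairs(dataset.analyses))
    # population sd of signed differences per (amino acid, fraction)
    sds: dict[tuple[str, str], float] = {}
    diffs: dict[tuple[str, str], list[float]] = defaultdict(list)
    for (_, _, fraction), a1, a2 in pairs:
        for aa in AMINO_ACIDS:
            if aa in a1.dl and aa in a2.dl:
                diffs[(aa, fraction)].append(a1.dl[aa] - a2.dl[aa])
    for key, vals in diffs.items():
        if len(vals) >= 2:
            sds[key] = float(np.std(vals, ddof=1))
    for (_, _, fraction), a1, a2 in pairs:
        tripped = [aa for aa in AMINO_ACIDS
                   if aa in a1.dl and aa in a2.dl
                   and sds.get((aa, fraction), 0.0) > 0
                   and abs(a1.dl[aa] - a2.dl[aa]) >
                   k * sds[(aa, fraction)]]
        if len(tripped) == 1:
            for a in (a1, a2):
                report.value_removals.append(
                    (a.analysis_id, tripped[0], DUPLICATE_4SD))
        elif len(tripped) > 1:
            for a in (a1, a2):
                report.add(a.analysis_id, DUPLICATE_4SD)
    return report


def screen_concentration_extremes(dataset: Dataset, k: float = 2.0,
                                  total: bool = True,
                                  report: OutlierReport | None = None
                                  ) -> OutlierReport:
    """Flag THAA analyses with extreme high/low concentrations.

    With ``total=True`` (default) the screen uses the total THAA
    concentration summed over the routinely analysed amino acids; analyses
    more than ``k`` sd from the full-dataset mean are flagged. With
    ``total=False`` each amino acid is screened separately.
    """
    if report is None:
        report = OutlierReport(cutoff=k)
    thaa = [a for a in dataset.analyses if a.fraction == "THAA" and a.conc]
    if len(thaa) < 3:
        return report
    if total:
        metrics = {a.analysis_id: sum(a.conc.values()) for a in thaa}
        _flag_extremes(metrics, k, report)
    else:
        for aa in AMINO_ACIDS:
            metrics = {a.analysis_id: a.conc[aa] for a in thaa
                       if aa in a.conc}
            if len(metrics) >= 3:
                _flag_extremes(metrics, k, report)
    return report


def _flag_extremes(metrics: dict[str, float], k: float,
                   report: OutlierReport) -> None:
    vals = np.array(list(metrics.values()), dtype=float)
    mean, sd = float(vals.mean()), float(vals.std(ddof=1))
    if sd == 0:
        return
    for aid, v in metrics.items():
        if abs(v - mean) > k * sd:
            report.add(aid, CONC_EXTREME_2SD)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def _active(dataset: Dataset, report: OutlierReport) -> list[Analysis]:
    return [a for a in dataset.analyses if a.analysis_id not in
            report.excluded]


def _replicate_pairs_across_fractions(analyses: list[Analysis]):
    """Pair the THAA and FAA analyses of each (core, year, replicate)."""
    groups: dict[tuple, dict[str, Analysis]] = defaultdict(dict)
    for a in analyses:
        groups[(a.core_code, a.assigned_year, a.replicate_id)][a.fraction] = a
    for key, d in groups.items():
        if "THAA" in d and "FAA" in d:
            yield key, d["THAA"], d["FAA"]


def run_screening(dataset: Dataset,
                  config: ScreeningConfig | None = None
                  ) -> tuple[Dataset, OutlierReport]:
    """Apply all screens in order and return the filtered dataset + report.

    Order: robust pre-cull (concentration plane) → covariance test (i)
    FAA vs THAA Asx D/L (power, dual-axis) → test (ii) THAA Asx vs Glx
    concentration (linear, ODR) → test (iii) THAA Asx vs Glx D/L (power,
    dual-axis) → analytical-duplicate screen → concentration-extreme
    screen. Exclusions from earlier screens are removed before later fits;
    reason codes accumulate per analysis.
    """
    if config is None:
        config = ScreeningConfig()
    report = OutlierReport(cutoff=config.cutoff)
    work = dataset.copy()

    # --- pre-cull on the THAA Asx/Glx concentration plane
    ids, x, y = _conc_points(_active(work, report))
    if len(ids) >= 5:
        for aid in precull(ids, x, y, config.precull_threshold):
            report.add(aid, PRECULL)

    # --- test (i): FAA Asx D/L vs THAA Asx D/L, power, dual-axis
    pairs = [(key, a_t, a_f) for key, a_t, a_f in
             _replicate_pairs_across_fractions(_active(work, report))
             if "Asx" in a_t.dl and "Asx" in a_f.dl
             and a_t.dl["Asx"] > 0]
    if len(pairs) >= 5:
        ids_i = [(a_t.analysis_id, a_f.analysis_id) for _, a_t, a_f in pairs]
        x = [a_t.dl["Asx"] for _, a_t, _ in pairs]
        y = [a_f.dl["Asx"] for _, _, a_f in pairs]
        fit = select_function(x, y, ("linear", "power"))
        report.fits["faa_vs_thaa_asx_dl"] = fit.summary()
        flagged = flag_outliers_dual_axis(ids_i, x, y, "power", config.cutoff)
        for aid_t, aid_f in flagged:
            report.add(aid_t, COVAR_FAA_THAA_ASX)
            report.add(aid_f, COVAR_FAA_THAA_ASX)

    # --- test (ii): THAA Asx conc vs THAA Glx conc, linear, ODR
    ids, x, y = _conc_points(_active(work, report))
    if len(ids) >= 5:
        fit = fit_regression(x, y, "linear", "orthogonal")
        report.fits["thaa_conc_asx_vs_glx"] = fit.summary()
        for aid in flag_outliers_odr(ids, x, y, config.cutoff):
            report.add(aid, COVAR_CONC_ASX_GLX)

    # --- test (iii): THAA Asx D/L vs THAA Glx D/L, power, dual-axis.
    # A D/L-covariance break marks the subsample's protein as disturbed,
    # so the same-replicate FAA analysis is removed along with the THAA.
    active = _active(work, report)
    partner = {(a.core_code, a.assigned_year, a.replicate_id): a
               for a in active if a.fraction == "FAA"}
    thaa = [a for a in active if a.fraction == "THAA"
            and "Asx" in a.dl and "Glx" in a.dl and a.dl["Asx"] > 0
            and a.dl["Glx"] > 0]
    if len(thaa) >= 5:
        by_id = {a.analysis_id: a for a in thaa}
        ids3 = [a.analysis_id for a in thaa]
        x = [a.dl["Asx"] for a in thaa]
        y = [a.dl["Glx"] for a in thaa]
        fit = select_function(x, y, ("linear", "power"))
        report.fits["thaa_dl_asx_vs_glx"] = fit.summary()
        for aid in flag_outliers_dual_axis(ids3, x, y, "power",
                                           config.cutoff):
            report.add(aid, COVAR_DL_ASX_GLX)
            a = by_id[aid]
            mate = partner.get((a.core_code, a.assigned_year,
                                a.replicate_id))
            if mate is not None:
                report.add(mate.analysis_id, COVAR_DL_ASX_GLX)

    # --- duplicate and concentration screens; their reference statistics
    # (sd of duplicate differences, mean/sd of THAA concentration) are
    # computed on the whole population, not just survivors
    screen_duplicates(work, config.duplicate_k, report)
    screen_concentration_extremes(work, config.concentration_k,
                                  config.concentration_total, report)

    # --- build the filtered dataset
    removals: dict[str, set[str]] = defaultdict(set)
    for aid, aa, _ in report.value_removals:
        removals[aid].add(aa)
    filtered: list[Analysis] = []
    for a in work.analyses:
        if a.analysis_id in report.excluded:
            continue
        a = a.copy()
        for aa in removals.get(a.analysis_id, ()):
            a.dl.pop(aa, None)
            a.conc.pop(aa, None)
            a.exclusion_flags.add(f"{DUPLICATE_4SD}:{aa}")
        filtered.append(a)
    return Dataset(filtered, work.cores), report


def _conc_points(analyses: list[Analysis]):
    thaa = [a for a in analyses if a.fraction == "THAA"
            and "Asx" in a.conc and "Glx" in a.conc]
    ids = [a.analysis_id for a in thaa]
    x = np.array([a.conc["Asx"] for a in thaa], dtype=float)
    y = np.array([a.conc["Glx"] for a in thaa], dtype=float)
    return ids, x, y
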