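"""Synthetic multi-colony AAR datasets with known ground truth.

Emulates the measurement structure of a multi-core coral AAR study:
stratigraphically increasing D/L with age, per-colony rate multipliers,
linearly declining THAA concentrations, %FAA rising toward the closed-
system asymptote, paired analytical duplicates with independent noise, and
a small fraction of compromised analyses planted in three styles — one per
screening pathway:

* ``dl_shift``   — a single amino acid's D/L displaced in both duplicates of
  one subsample-fraction (a compromised preparation affects both runs),
  breaking the covariance structure the regression screens test;
* ``conc_spike`` — all concentrations of a THAA subsample scaled by a large
  factor (high or low), caught by the concentration screens;
* ``dup_discord`` — one amino acid's D/L displaced in *one* duplicate,
  caught by the 4-sd duplicate screen. Both members of the discordant pair
  carry the truth label, because the pair is unusable.

Kinetic trajectories come in two forms: a power law ``d0 + a*age**b``
(mirroring the empirical fits used in screening) and reverse first-order
kinetics with equilibrium constant 1, ``tanh(k*age + artanh(d0))``. Default
exponents are shared across amino acids within a fraction and the per-colony
rate multiplier is shared across amino acids and fractions, which keeps the
between-amino-acid covariance tight — the structure real screening relies
on.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Analysis, CoreMeta, Dataset

OUTLIER_STYLES = ("dl_shift", "conc_spike", "dup_discord")


@dataclass(frozen=True)
class KineticParams:
    """Parameters of one amino acid x fraction trajectory.

    Power form uses (d0, a, b); reverse first-order uses (d0, k). d0 is the
    D/L at age 0 (hydrolysis-induced racemization of living tissue).
    """

    d0: float
    a: float = 0.0
    b: float = 1.0
    k: float = 0.0


def _default_kinetics() -> dict[tuple[str, str], KineticParams]:
    # Exponents shared across amino acids and fractions: FAA and THAA D/L
    # are driven by the same diagenesis clock, with the free pool showing
    # twice the apparent extent (faster apparent racemization of the free
    # fraction). A shared per-colony rate multiplier then cancels exactly
    # in every between-variable covariance plane, which is the structure
    # the screening tests rely on. Amplitudes chosen so THAA Asx D/L spans
    # ~0.05-0.35 and FAA Asx ~0.1-0.7 over 500 years.
    thaa_b, faa_b = 0.45, 0.45
    out: dict[tuple[str, str], KineticParams] = {}
    for aa, a_thaa, d0_thaa, a_faa, d0_faa in (
            ("Asx", 0.0183, 0.05, 0.0366, 0.10),
            ("Glx", 0.0075, 0.03, 0.0150, 0.06),
            ("Ala", 0.0061, 0.025, 0.0122, 0.05),
            ("Ser", 0.0110, 0.06, 0.0220, 0.12)):
        out[(aa, "THAA")] = KineticParams(d0=d0_thaa, a=a_thaa, b=thaa_b,
                                          k=a_thaa / 10.0)
        out[(aa, "FAA")] = KineticParams(d0=d0_faa, a=a_faa, b=faa_b,
                                         k=a_faa / 10.0)
    return out


@dataclass
class SynthConfig:
    """Full specification of a simulated multi-colony dataset.

    Defaults emulate an eight-colony coral study sampled in 5-year growth
    increments with duplicate FAA and THAA analyses per subsample. The
    kinetic amplitudes are conveniences tuned to realistic D/L spans, not
    claims of fidelity to any particular reef.
    """

    n_colonies: int = 8
    ages: tuple[float, ...] = tuple(range(10, 490, 30))
    collection_year: int = 1990
    amino_acids: tuple[str, ...] = ("Asx", "Glx", "Ala", "Ser")
    kinetics_form: str = "power"            # "power" | "reverse-first-order"
    kinetics: dict[tuple[str, str], KineticParams] = field(
        default_factory=_default_kinetics)
    colony_rate_sd: float = 0.1             # lognormal sd of rate multiplier
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"THAA": 0.005, "FAA": 0.010})
    conc0: dict[str, float] = field(
        default_factory=lambda: {"Asx": 2000.0, "Glx": 1000.0,
                                 "Ala": 700.0, "Ser": 500.0})
    conc_decline: dict[str, float] = field(
        default_factory=lambda: {"Asx": 2.0, "Glx": 1.0,
                                 "Ala": 0.7, "Ser": 0.5})  # units / year
    conc_noise_rel: float = 0.05            # common per-run factor (mass,
                                            # injection volume: all AAs move
                                            # together)
    conc_noise_aa: float = 0.02             # independent per-AA noise
    k_h: float = 0.001                      # per-year FAA generation rate
    faa_floor: float = 2.0                  # %FAA at age 0
    outlier_fraction: float = 0.05
    outlier_magnitude: float = 12.0         # displacement in noise-sd units
    conc_spike_factor: float = 5.0
    outlier_styles: tuple[str, ...] = OUTLIER_STYLES
    style_weights: tuple[float, ...] = (0.4, 0.4, 0.2)
    n_replicates: int = 2
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must lie in [0, 1)")
        if self.colony_rate_sd < 0 or self.k_h < 0:
            raise ValueError("rates and sds must be >= 0")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise sds must be >= 0")
        if self.conc_noise_rel < 0 or self.conc_noise_aa < 0:
            raise ValueError("concentration noise sds must be >= 0")
        if self.kinetics_form not in ("power", "reverse-first-order"):
            raise ValueError(f"unknown kinetics form {self.kinetics_form!r}")
        if set(self.outlier_styles) - set(OUTLIER_STYLES):
            raise ValueError(f"unknown outlier style in "
                             f"{self.outlier_styles}")
        if len(self.style_weights) != len(self.outlier_styles):
            raise ValueError("style_weights must match outlier_styles")
        for key in [(aa, fr) for aa in self.amino_acids
                    for fr in ("FAA", "THAA")]:
            if key not in self.kinetics:
                raise ValueError(f"kinetics missing for {key}")
            trajectory_dl(0.0, self.kinetics[key], self.kinetics_form)

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)


def trajectory_dl(age, params: KineticParams, form: str = "power"):
    """Noiseless D/L at a given age.

    power: ``d0 + a * age**b`` (a, b > 0 so the trajectory is
    non-decreasing). reverse-first-order (equilibrium constant 1):
    ``tanh(k*age + artanh(d0))``, the solution of
    d(D/L)/dt = k * (1 - (D/L)^2); always below 1.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    if form == "power":
        if params.a < 0 or params.b <= 0 or params.d0 < 0:
            raise ValueError(
                "power form needs a >= 0, b > 0, d0 >= 0 for a "
                "non-decreasing trajectory")
        out = params.d0 + params.a * np.power(age, params.b)
    elif form == "reverse-first-order":
        if params.k < 0 or not 0 <= params.d0 < 1:
            raise ValueError(
                "reverse first-order form needs k >= 0 and 0 <= d0 < 1")
        out = np.tanh(params.k * age + math.atanh(params.d0))
    else:
        raise ValueError(f"unknown kinetics form {form!r}")
    return out if out.ndim else float(out)


def percent_free_truth(age, k_h: float, floor: float = 0.0):
    """Noiseless %FAA at a given age in a closed system.

    ``floor + (100 - floor) * (1 - exp(-k_h * age))``: strictly increasing
    for k_h > 0 with asymptote 100 — nothing leaves the intra-crystalline
    pool, so the free share can only grow toward the total.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < 0) or k_h < 0:
        raise ValueError("age and k_h must be >= 0")
    out = floor + (100.0 - floor) * (-np.expm1(-k_h * age))
    return out if out.ndim else float(out)


def _style_coverage(config: SynthConfig) -> dict[str, int]:
    """How many of a subsample's analyses each corruption style touches."""
    return {"dl_shift": 2 * config.n_replicates,   # both fractions
            "conc_spike": config.n_replicates,     # THAA pair
            "dup_discord": config.n_replicates}    # one fraction's pair


def subsample_event_probability(config: SynthConfig) -> float:
    """Per-subsample corruption probability matching ``outlier_fraction``.

    Corruption events are drawn once per subsample; a style touching
    ``cov`` of the subsample's ``2 * n_replicates`` analyses labels that
    many, so the event probability is scaled to make the expected labelled
    *analysis* fraction equal ``outlier_fraction``.
    """
    cov = _style_coverage(config)
    mean_cov = sum(w * cov[s] for s, w in zip(config.outlier_styles,
                                              config.style_weights))
    mean_cov /= sum(config.style_weights)
    return min(config.outlier_fraction * 2 * config.n_replicates / mean_cov,
               1.0)


def generate_dataset(config: SynthConfig) -> tuple[Dataset, pd.DataFrame]:
    """Generate a dataset plus its truth table. Deterministic given seed.

    The truth table has one row per analysis: true age, colony rate
    multiplier, noiseless D/L per amino acid (``<AA>_dl_true``), the
    outlier flag and style. One Bernoulli corruption draw is made per
    physical subsample (see :func:`subsample_event_probability`); every
    analysis a corruption touches carries the truth label.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    analyses: list[Analysis] = []
    truth_rows: list[dict] = []
    cores: dict[str, CoreMeta] = {}
    collection = dt.date(config.collection_year, 6, 1)
    p_event = subsample_event_probability(config)
    weights = np.asarray(config.style_weights, dtype=float)
    weights = weights / weights.sum()

    for c in range(config.n_colonies):
        code = f"SIM{c + 1:02d}"
        cores[code] = CoreMeta(code, collection, latitude=-18.0 - 0.1 * c,
                               longitude=146.0 + 0.1 * c,
                               mean_annual_sst=26.2, seasonal_range=6.0,
                               shelf_position="synthetic")
        multiplier = float(rng.lognormal(0.0, config.colony_rate_sd)) \
            if config.colony_rate_sd > 0 else 1.0
        for age in config.ages:
            assigned_year = config.collection_year - age
            truth_dl: dict[tuple[str, str], float] = {}
            truth_conc: dict[tuple[str, str], float] = {}
            pf = percent_free_truth(age, config.k_h, config.faa_floor)
            for fraction in ("THAA", "FAA"):
                for aa in config.amino_acids:
                    p = config.kinetics[(aa, fraction)]
                    scaled = dataclasses.replace(
                        p, a=p.a * multiplier, k=p.k * multiplier)
                    truth_dl[(aa, fraction)] = float(
                        trajectory_dl(age, scaled, config.kinetics_form))
                    thaa_c = max(config.conc0[aa]
                                 - config.conc_decline[aa] * age, 0.0)
                    truth_conc[(aa, fraction)] = thaa_c \
                        if fraction == "THAA" else thaa_c * pf / 100.0

            # one corruption event per physical subsample
            style = ""
            if rng.random() < p_event:
                style = str(rng.choice(list(config.outlier_styles),
                                       p=weights))
            dl_shifts: dict[tuple[str, str], float] = {}
            spike, spike_aa = 1.0, ""
            discord_fraction, discord_aa, discord_shift = "", "", 0.0
            if style == "dl_shift":
                # compromised subsample: a contaminant displaces every
                # amino acid's D/L in both fractions, independently
                for fraction in ("THAA", "FAA"):
                    for aa in config.amino_acids:
                        dl_shifts[(aa, fraction)] = (
                            config.outlier_magnitude
                            * config.noise_sd[fraction]
                            * float(rng.choice([-1.0, 1.0]))
                            * float(rng.uniform(0.75, 1.25)))
            elif style == "conc_spike":
                spike = config.conc_spike_factor \
                    if rng.random() < 0.5 else 1.0 / config.conc_spike_factor
                if rng.random() < 0.5:  # single-AA spike: breaks the
                    # Asx-Glx concentration covariance
                    spike_aa = str(rng.choice(
                        [aa for aa in ("Asx", "Glx")
                         if aa in config.amino_acids] or
                        list(config.amino_acids)))
            elif style == "dup_discord":
                discord_fraction = str(rng.choice(["THAA", "FAA"]))
                discord_aa = str(rng.choice(config.amino_acids))
                discord_shift = (config.outlier_magnitude
                                 * config.noise_sd[discord_fraction]
                                 * float(rng.choice([-1.0, 1.0])))

            for fraction in ("THAA", "FAA"):
                if style == "dl_shift":
                    labelled = True
                elif style == "conc_spike":
                    labelled = fraction == "THAA"
                elif style == "dup_discord":
                    labelled = fraction == discord_fraction
                else:
                    labelled = False
                for r in range(1, config.n_replicates + 1):
                    dl_obs, conc_obs = {}, {}
                    run_factor = float(rng.lognormal(
                        0.0, config.conc_noise_rel)) \
                        if config.conc_noise_rel > 0 else 1.0
                    for aa in config.amino_acids:
                        v = truth_dl[(aa, fraction)] + float(
                            rng.normal(0.0, config.noise_sd[fraction]))
                        v += dl_shifts.get((aa, fraction), 0.0)
                        if style == "dup_discord" and aa == discord_aa \
                                and fraction == discord_fraction \
                                and r == config.n_replicates:
                            v += discord_shift
                        dl_obs[aa] = float(np.clip(v, 0.0, 1.09))
                        cval = truth_conc[(aa, fraction)] * run_factor \
                            * (1.0 + float(rng.normal(
                                0.0, config.conc_noise_aa)))
                        if style == "conc_spike" and fraction == "THAA" \
                                and (not spike_aa or aa == spike_aa):
                            cval *= spike
                        conc_obs[aa] = max(cval, 0.0)
                    aid = f"{code}-{age:g}-{fraction}-{r}"
                    analyses.append(Analysis(
                        aid, code, float(assigned_year), str(r), fraction,
                        dl_obs, conc_obs))
                    truth_rows.append({
                        "analysis_id": aid, "core_code": code,
                        "age": float(age), "fraction": fraction,
                        "replicate_id": str(r),
                        "colony_multiplier": multiplier,
                        "is_outlier": labelled,
                        "outlier_style": style if labelled else "",
                        **{f"{aa}_dl_true": truth_dl[(aa, fraction)]
                           for aa in config.amino_acids},
                    })
    dataset = Dataset(analyses, cores)
    dataset.validate()
    return dataset, pd.DataFrame(truth_rows)
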