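"""Synthetic study generator.

Emulates the statistical structure of a diel rice transcriptome study:

* the growth-chamber (GC) factorial design — photoperiods 0L/24D, 8L/16D,
  12L/12D, 16L/8D, 24L/0D crossed with light temperatures {20..40} degC and
  dark temperatures {15..35} degC, equal light/dark temperatures excluded,
  giving 73 conditions;
* field meteorology in which temperature and irradiance are diel-correlated
  (a phenomenological sinusoid + AR(1) model, not a weather reanalysis);
* gene expression generated from known ground-truth models (clock-only,
  temperature-driven, or radiation-driven genes) via the forward model of
  :mod:`fieldfit.fitcore` plus Gaussian noise on the log2 scale, clipped at 0
  to stay in the observable log2(rpm+1) range;
* QC fixtures: plate-level annotation swaps and cultivar-specific SNP call
  tables.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fitcore
from .data import EnvSeries, EnvStack, SampleSet, ExpressionStudy, LOOKBACK_H
from .fitcore import GeneModelFit, LinearCoefs, NonlinearParams

LIGHT_HOURS = (0, 8, 12, 16, 24)
LIGHT_TEMPS = (20, 25, 30, 35, 40)
DARK_TEMPS = (15, 20, 25, 30, 35)

#: 3-h sampling cadence starting 1.5 h after lights-on, 8 samplings per day
SAMPLING_CLOCKS = tuple(1.5 + 3.0 * k for k in range(8))

#: plant age (days) at GC sampling: 14 d preculture + 2 d acclimation + day 3
GC_SAMPLING_AGE_DAYS = 17.0


@dataclass(frozen=True)
class ConditionSpec:
    """One growth-chamber condition (photoperiod and light/dark temperatures)."""

    condition_id: str
    light_hours: int
    light_temp: float | None
    dark_temp: float | None

    def __post_init__(self):
        if self.light_hours not in LIGHT_HOURS:
            raise ValueError(f"light_hours must be one of {LIGHT_HOURS}")
        if (self.light_temp is None) != (self.light_hours == 0):
            raise ValueError("light_temp must be absent iff the photoperiod is 0L")
        if (self.dark_temp is None) != (self.light_hours == 24):
            raise ValueError("dark_temp must be absent iff the photoperiod is 24L")
        if self.light_temp is not None and self.light_temp not in LIGHT_TEMPS:
            raise ValueError(f"light_temp must be one of {LIGHT_TEMPS}")
        if self.dark_temp is not None and self.dark_temp not in DARK_TEMPS:
            raise ValueError(f"dark_temp must be one of {DARK_TEMPS}")
        if (
            self.light_temp is not None
            and self.dark_temp is not None
            and self.light_temp == self.dark_temp
        ):
            raise ValueError("equal light and dark temperatures are excluded")

    def temperature_at(self, clock_time: float) -> float:
        if (clock_time % 24.0) < self.light_hours:
            return float(self.light_temp)
        return float(self.dark_temp)


def _condition_id(light_hours, light_temp, dark_temp) -> str:
    lt = "-" if light_temp is None else f"{int(light_temp)}"
    dk = "-" if dark_temp is None else f"{int(dark_temp)}"
    return f"{light_hours}L{24 - light_hours}D_L{lt}_D{dk}"


def enumerate_conditions() -> list[ConditionSpec]:
    """All 73 conditions of the factorial design, deterministically ordered.

    Order: photoperiod ascending, then light temperature, then dark
    temperature.  0L/24D has one condition per dark temperature and 24L/0D
    one per light temperature; for the three mixed photoperiods every
    light/dark pair with unequal temperatures is present.
    """
    out: list[ConditionSpec] = []
    for lh in LIGHT_HOURS:
        if lh == 0:
            for dk in DARK_TEMPS:
                out.append(ConditionSpec(_condition_id(lh, None, dk), lh, None, dk))
        elif lh == 24:
            for lt in LIGHT_TEMPS:
                out.append(ConditionSpec(_condition_id(lh, lt, None), lh, lt, None))
        else:
            for lt, dk in itertools.product(LIGHT_TEMPS, DARK_TEMPS):
                if lt == dk:
                    continue
                out.append(ConditionSpec(_condition_id(lh, lt, dk), lh, lt, dk))
    return out


def gc_env_series(cond: ConditionSpec, days: int = 4, dt: float = 0.5,
                  light_irradiance: float = 1.0) -> EnvSeries:
    """Square-wave chamber trace: lights on at clock 0 for ``light_hours``.

    ``days`` must be at least 4 so that samples on the final day retain the
    full 72-h look-back window.
    """
    if days < 4:
        raise ValueError("need at least 4 days (acclimation + look-back window)")
    if dt <= 0 or abs(24.0 / dt - round(24.0 / dt)) > 1e-9:
        raise ValueError(f"grid step dt={dt} must divide 24 h")
    t = np.arange(0.0, days * 24.0, dt)
    clock = t % 24.0
    light = clock < cond.light_hours
    if cond.light_hours == 0:
        temp = np.full_like(t, float(cond.dark_temp))
        irr = np.zeros_like(t)
    elif cond.light_hours == 24:
        temp = np.full_like(t, float(cond.light_temp))
        irr = np.full_like(t, light_irradiance)
    else:
        temp = np.where(light, float(cond.light_temp), float(cond.dark_temp))
        irr = np.where(light, light_irradiance, 0.0)
    return EnvSeries(t, temp, irr, clock0=0.0)


@dataclass(frozen=True)
class FieldEnvParams:
    """Phenomenological field-weather model (mid-season paddy defaults).

    Irradiance is a half-sinusoid over daylight scaled by a lognormal
    day-to-day weather factor (sunny vs overcast days).  Temperature is a
    seasonal mean plus a diel sinusoid peaking in early afternoon plus AR(1)
    noise, and the *same* daily weather factor scales the diel temperature
    swing: sunshine drives daytime heating (and clear nights cool further),
    so the two variables share their forcing at both the diel and the
    day-to-day scale — the coupling that makes them hard to disentangle from
    field data alone.
    """

    mean_temp: float = 26.0
    diel_amp: float = 4.0
    peak_clock: float = 14.0
    ar_rho: float = 0.95
    ar_sd: float = 0.4  # stationary s.d. of the non-solar AR(1) component, degC
    weather_temp_gain: float = 3.0  # degC shift of daily mean per unit day-factor anomaly
    sunrise: float = 5.0
    sunset: float = 19.0
    max_irradiance: float = 1.0
    weather_sigma: float = 0.4  # lognormal sigma of the day factor


def field_env_series(days: int, dt: float = 0.5, seed: int = 0,
                     params: FieldEnvParams | None = None) -> EnvSeries:
    """Synthetic field meteorology with positively correlated temp/irradiance."""
    if days < 4:
        raise ValueError("need at least 4 days for the 72-h look-back window")
    p = params or FieldEnvParams()
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, days * 24.0, dt)
    clock = t % 24.0
    day_idx = (t // 24.0).astype(int)

    day_factor = np.exp(rng.normal(0.0, p.weather_sigma, days)) if p.weather_sigma > 0 \
        else np.ones(days)
    f_mean = math.exp(p.weather_sigma**2 / 2.0)
    diel = (p.diel_amp * day_factor[day_idx]
            * np.cos(2.0 * np.pi * (clock - p.peak_clock) / 24.0)
            + p.weather_temp_gain * (day_factor[day_idx] - f_mean))
    innov_sd = p.ar_sd * math.sqrt(max(1.0 - p.ar_rho**2, 1e-12))
    noise = np.empty(len(t))
    noise[0] = rng.normal(0.0, p.ar_sd) if p.ar_sd > 0 else 0.0
    eps = rng.normal(0.0, 1.0, len(t)) * innov_sd
    for i in range(1, len(t)):
        noise[i] = p.ar_rho * noise[i - 1] + eps[i]
    temp = p.mean_temp + diel + noise

    daylen = p.sunset - p.sunrise
    frac = (clock - p.sunrise) / daylen
    shape = np.where((frac > 0) & (frac < 1), np.sin(np.pi * np.clip(frac, 0, 1)), 0.0)
    irr = np.maximum(0.0, p.max_irradiance * shape * day_factor[day_idx])
    return EnvSeries(t, temp, irr, clock0=0.0)


# ---------------------------------------------------------------------------
# ground-truth genes and forward simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthGene:
    """Ground truth for one simulated gene."""

    gene_id: str
    driver: str  # temperature | radiation | neither
    true_params: NonlinearParams
    true_coefs: LinearCoefs
    noise_sd: float

    def __post_init__(self):
        if self.driver not in ("temperature", "radiation", "neither"):
            raise ValueError(f"unknown driver {self.driver!r}")
        if self.driver == "neither" and np.any(self.true_coefs.env_group != 0):
            raise ValueError("neither-gene must have zero environmental coefficients")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def as_fit(self) -> GeneModelFit:
        return GeneModelFit(self.gene_id, self.driver, self.true_params,
                            self.true_coefs, float("nan"), 0)


def simulate_expression(truth, env: EnvSeries, sample_times, seed: int = 0,
                        sample_ids=None, meta_extra=None) -> ExpressionStudy:
    """Forward-simulate an expression matrix over one environmental trace.

    ``sample_times`` is a list of ``(time_h, age_days)`` pairs; ``time_h`` is
    hours into ``env`` and must leave the full 72-h look-back (otherwise the
    earliest valid time is named in the error).  Each gene's values are the
    forward model of its ground truth plus N(0, noise_sd^2) noise, clipped at
    0 to mirror the log2(rpm+1) scale.
    """
    st = np.asarray(sample_times, dtype=float).reshape(-1, 2)
    if np.any(st[:, 0] < LOOKBACK_H):
        raise ValueError(
            f"samples before the 72-h look-back; earliest valid time is {LOOKBACK_H:.1f} h"
        )
    stack = EnvStack([env])
    clock = (env.clock0 + st[:, 0]) % 24.0
    samples = SampleSet(stack, np.zeros(len(st), dtype=np.int64),
                        st[:, 0], clock, st[:, 1])
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = [f"s{i:04d}" for i in range(len(st))]
    rows = {}
    for tg in truth:
        mu = fitcore.predict(tg.as_fit(), stack, samples)
        if tg.noise_sd > 0:
            mu = mu + rng.normal(0.0, tg.noise_sd, len(mu))
        rows[tg.gene_id] = np.maximum(mu, 0.0)
    matrix = pd.DataFrame(rows, index=sample_ids).T
    matrix.index.name = "gene_id"
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cultivar": "A",
            "condition_id": "trace",
            "plate_id": "P1",
            "clock_time_h": clock,
            "age_days": st[:, 1],
            "sampling_time_index": np.arange(len(st)),
        }
    )
    if meta_extra:
        for k, v in meta_extra.items():
            meta[k] = v
    return ExpressionStudy(matrix, meta)


def make_truth_genes(n_temperature: int, n_radiation: int, n_neither: int,
                     reference: SampleSet | None = None, seed: int = 0,
                     noise_sd: float = 0.3, target_snr: float = 6.0,
                     age_slope_range=(0.01, 0.03)) -> list[TruthGene]:
    """Draw ground-truth genes with environmental effects scaled to a target SNR.

    SNR is defined as sd(environment-driven component across ``reference``
    samples) / noise_sd; when ``reference`` is omitted the effect size is set
    from nominal variable scales instead (7 degC for temperature, 0.35 flux
    units for gated irradiance).
    """
    rng = np.random.default_rng(seed)
    out: list[TruthGene] = []
    drivers = (["temperature"] * n_temperature + ["radiation"] * n_radiation
               + ["neither"] * n_neither)
    for i, drv in enumerate(drivers):
        T = float(rng.choice([3.0, 6.0, 12.0, 24.0]))
        if drv == "neither":
            phi = float(rng.uniform(0.0, 24.0))  # inert for clock-only genes
        else:
            # environmental responsiveness gates to the photoperiod (light- and
            # heat-response pathways peak around midday)
            phi = float(rng.normal(13.0, 3.0)) % 24.0
        gamma = 1.0 if rng.random() < 0.7 else 0.0
        theta = (-50.0, 50.0) if drv != "radiation" else (-10.0, 10.0)
        nl = NonlinearParams(T, 0.0, phi, gamma, 2.0, *theta)
        b0 = float(rng.uniform(7.0, 10.0))
        b_age = float(rng.choice([-1.0, 1.0]) * rng.uniform(*age_slope_range))
        b_cos = float(rng.normal(0.0, 0.5))
        b_sin = float(rng.normal(0.0, 0.5))
        if drv == "neither":
            coefs = LinearCoefs(b0, b_age, b_cos, b_sin, 0.0, 0.0, 0.0, 0.0)
        else:
            if reference is not None:
                x = fitcore.sample_env_inputs(reference, nl, drv)
                scale = float(np.std(x))
                center = float(np.mean(x))
            else:
                # nominal scales: ~7 degC temperature spread; gated square-wave
                # irradiance; gate mean is 3/8 for gamma=1, w=2
                gmean = (1.0 - gamma) + gamma * 0.375
                scale = 7.0 * gmean if drv == "temperature" else 0.35 * gmean
                center = 27.0 * gmean if drv == "temperature" else 0.5 * gmean
            scale = max(scale, 1e-6)
            sign = float(rng.choice([-1.0, 1.0]))
            # environmental signal s.d. on the log2 scale; a unit signal for
            # noise-free genes, where SNR is otherwise undefined
            signal_sd = target_snr * noise_sd if noise_sd > 0 else 1.0
            b_e = sign * signal_sd / scale
            # keep the baseline at b0 by absorbing the mean environmental input,
            # so negative effects don't push expression below the observable 0
            b0 -= b_e * center
            coefs = LinearCoefs(b0, b_age, b_cos, b_sin, b_e, 0.0, 0.0, 0.0)
        out.append(TruthGene(f"gene{i:03d}", drv, nl, coefs, noise_sd))
    return out


# ---------------------------------------------------------------------------
# study assembly
# ---------------------------------------------------------------------------

def make_study_samples(conditions, timepoints_per_condition: int = 8,
                       cultivars: int = 2) -> pd.DataFrame:
    """Full-factorial sample plan: conditions x time points x cultivars."""
    clocks = [SAMPLING_CLOCKS[k % 8] + 24.0 * (k // 8)
              for k in range(timepoints_per_condition)]
    cvs = [chr(ord("A") + i) for i in range(cultivars)]
    rows = []
    for cond in conditions:
        for cv in cvs:
            for k, ck in enumerate(clocks):
                rows.append(
                    {
                        "condition_id": cond.condition_id,
                        "cultivar": cv,
                        "sampling_time_index": k,
                        "clock_time_h": ck % 24.0,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class StudyBundle:
    """A simulated study plus the machinery needed to refit it."""

    study: ExpressionStudy
    samples: SampleSet
    envs: list[EnvSeries]
    truth: list[TruthGene]
    source: str = "gc"

    @property
    def expr(self) -> pd.DataFrame:
        return self.study.matrix


def _plate_ids(n_samples: int, samples_per_plate: int = 96) -> list[str]:
    return [f"P{1 + i // samples_per_plate:02d}" for i in range(n_samples)]


def simulate_gc_study(conditions, truth, seed: int = 0, days: int = 4,
                      dt: float = 0.5, light_irradiance: float = 1.0,
                      cultivars: int = 1, samples_per_plate: int = 96,
                      cultivar_shift: dict | None = None,
                      batch_effect_sd: float = 0.3) -> StudyBundle:
    """Simulate a growth-chamber study across ``conditions``.

    One trace per condition; sampling on the final day at the 3-h cadence.
    Plates are filled in sample order (``samples_per_plate`` per plate) so a
    plate groups neighbouring conditions — the layout that makes plate swaps
    detectable from temperature-responsive expression.

    ``batch_effect_sd`` adds a per-(gene, chamber run) random offset shared
    by all samples of a condition, mirroring the batch covariance of samples
    grown and harvested together (one plant per time point, no replicates).
    """
    conditions = list(conditions)
    envs = [gc_env_series(c, days=days, dt=dt, light_irradiance=light_irradiance)
            for c in conditions]
    stack = EnvStack(envs)
    base_h = (days - 1) * 24.0
    cvs = [chr(ord("A") + i) for i in range(cultivars)]
    trace, time_h, clock, age, meta_rows = [], [], [], [], []
    for ci, cond in enumerate(conditions):
        for cv in cvs:
            for k, ck in enumerate(SAMPLING_CLOCKS):
                trace.append(ci)
                time_h.append(base_h + ck)
                clock.append(ck)
                age.append(GC_SAMPLING_AGE_DAYS)
                meta_rows.append(
                    {
                        "cultivar": cv,
                        "condition_id": cond.condition_id,
                        "clock_time_h": ck,
                        "age_days": GC_SAMPLING_AGE_DAYS,
                        "sampling_time_index": k,
                        "nominal_temp_C": cond.temperature_at(ck),
                    }
                )
    samples = SampleSet(stack, trace, time_h, clock, age)
    n = len(samples)
    sample_ids = [f"gc{i:04d}" for i in range(n)]
    meta = pd.DataFrame(meta_rows)
    meta.insert(0, "sample_id", sample_ids)
    meta["plate_id"] = _plate_ids(n, samples_per_plate)

    rng = np.random.default_rng(seed)
    cond_idx = np.asarray(trace)
    rows = {}
    for tg in truth:
        mu = fitcore.predict(tg.as_fit(), stack, samples)
        if cultivar_shift and tg.gene_id in cultivar_shift:
            shift = np.array([cultivar_shift[tg.gene_id].get(cv, 0.0)
                              for cv in meta["cultivar"]])
            mu = mu + shift
        if batch_effect_sd > 0:
            mu = mu + rng.normal(0.0, batch_effect_sd, len(conditions))[cond_idx]
        if tg.noise_sd > 0:
            mu = mu + rng.normal(0.0, tg.noise_sd, n)
        rows[tg.gene_id] = np.maximum(mu, 0.0)
    matrix = pd.DataFrame(rows, index=sample_ids).T
    matrix.index.name = "gene_id"
    truth_meta = pd.DataFrame(
        {"sample_id": sample_ids, "true_temp_C": meta["nominal_temp_C"].to_numpy()}
    ).set_index("sample_id")
    study = ExpressionStudy(matrix, meta, truth=truth_meta)
    return StudyBundle(study, samples, envs, list(truth), source="gc")


def simulate_field_study(truth, n_samples: int = 805, seed: int = 0,
                         dt: float = 0.5, params: FieldEnvParams | None = None,
                         sample_clocks=None, age_start: float = 25.0,
                         batch_effect_sd: float = 0.5) -> StudyBundle:
    """Simulate a field study over one synthetic meteorological season.

    Samples run from day 4 (so the look-back is always covered) at a fixed
    set of clock times per day; plant age advances one day per day so the
    pool spans a range of developmental stages, unlike the GC pool.

    ``batch_effect_sd`` adds a per-(gene, sampling day) random offset shared
    by all samples of a day — the day-level covariance of field series where
    each time point is a single plant harvested in one outing.
    """
    if sample_clocks is None:
        sample_clocks = tuple(np.arange(1.0, 24.0, 2.0))  # 12 per day
    per_day = len(sample_clocks)
    days = 4 + math.ceil(n_samples / per_day) + 1
    env = field_env_series(days, dt=dt, seed=seed, params=params)
    stack = EnvStack([env])
    time_h, clock, age = [], [], []
    d, k = 3, 0
    while len(time_h) < n_samples:
        ck = sample_clocks[k]
        time_h.append(d * 24.0 + ck)
        clock.append(ck)
        age.append(age_start + d)
        k += 1
        if k == per_day:
            k = 0
            d += 1
    samples = SampleSet(stack, np.zeros(n_samples, dtype=np.int64),
                        time_h, clock, age)
    rng = np.random.default_rng(seed + 1)
    sample_ids = [f"fd{i:04d}" for i in range(n_samples)]
    sample_day = (np.asarray(time_h) // 24.0).astype(int)
    rows = {}
    for tg in truth:
        mu = fitcore.predict(tg.as_fit(), stack, samples)
        if batch_effect_sd > 0:
            mu = mu + rng.normal(0.0, batch_effect_sd, days)[sample_day]
        if tg.noise_sd > 0:
            mu = mu + rng.normal(0.0, tg.noise_sd, n_samples)
        rows[tg.gene_id] = np.maximum(mu, 0.0)
    matrix = pd.DataFrame(rows, index=sample_ids).T
    matrix.index.name = "gene_id"
    pos = samples.pos
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cultivar": "A",
            "condition_id": "field",
            "plate_id": _plate_ids(n_samples),
            "clock_time_h": clock,
            "age_days": age,
            "sampling_time_index": np.arange(n_samples),
            "nominal_temp_C": env.temperature[pos],
        }
    )
    truth_meta = pd.DataFrame(
        {"sample_id": sample_ids, "true_temp_C": env.temperature[pos]}
    ).set_index("sample_id")
    study = ExpressionStudy(matrix, meta, truth=truth_meta)
    return StudyBundle(study, samples, [env], list(truth), source="field")


# ---------------------------------------------------------------------------
# QC fixtures
# ---------------------------------------------------------------------------

_SWAPPABLE = ["cultivar", "condition_id", "clock_time_h", "age_days",
              "sampling_time_index", "nominal_temp_C"]


def inject_plate_swap(study: ExpressionStudy, plate_a: str, plate_b: str) -> ExpressionStudy:
    """Exchange the metadata annotations of two plates (matrix untouched).

    Samples are paired positionally within each plate, mimicking two 96-well
    plates being physically exchanged during library processing: the data
    columns stay where they are but their biological annotations now lie.
    Applying the same swap twice restores the original study.
    """
    out = study.copy()
    meta = out.meta
    ids_a = meta.index[meta["plate_id"] == plate_a]
    ids_b = meta.index[meta["plate_id"] == plate_b]
    if len(ids_a) == 0:
        raise ValueError(f"unknown plate {plate_a!r}")
    if len(ids_b) == 0:
        raise ValueError(f"unknown plate {plate_b!r}")
    if plate_a == plate_b:
        return out
    if len(ids_a) != len(ids_b):
        raise ValueError("plates must have equal sample counts to be swapped")
    cols = [c for c in _SWAPPABLE if c in meta.columns]
    block_a = meta.loc[ids_a, cols].to_numpy()
    block_b = meta.loc[ids_b, cols].to_numpy()
    meta.loc[ids_a, cols] = block_b
    meta.loc[ids_b, cols] = block_a
    out.swap_log.append((plate_a, plate_b))
    return out


def make_snp_fixture(n_loci: int, n_samples: int, true_cultivars,
                     error_rate: float = 0.0, dropout_rate: float = 0.0,
                     seed: int = 0) -> pd.DataFrame:
    """Cultivar-specific SNP call table (tidy: sample_id, locus_id, call).

    Per sample x locus the true cultivar's allele is emitted with probability
    1 - error - dropout, an erroneous call (the other allele or "unknown",
    half/half) with probability error, and "none" (no sequence) with
    probability dropout.  ``true_cultivars`` entries are "A", "B" or "mix"
    (a 50/50 allele mixture, emulating a contaminated sample).
    """
    if not 0 <= error_rate <= 1 or not 0 <= dropout_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    if error_rate + dropout_rate > 1:
        raise ValueError("error_rate + dropout_rate must not exceed 1")
    rng = np.random.default_rng(seed)
    rows = []
    loci = [f"L{j:05d}" for j in range(n_loci)]
    for i, cv in enumerate(true_cultivars):
        if cv not in ("A", "B", "mix"):
            raise ValueError(f"true cultivar must be A, B or mix, got {cv!r}")
        sid = f"s{i:03d}"
        u = rng.random(n_loci)
        sub = rng.random(n_loci)
        if cv == "mix":
            alleles = np.where(rng.random(n_loci) < 0.5, "A", "B")
        else:
            alleles = np.full(n_loci, cv, dtype=object)
        other = np.where(alleles == "A", "B", "A")
        call = np.where(
            u < dropout_rate, "none",
            np.where(
                u < dropout_rate + error_rate,
                np.where(sub < 0.5, other, "unknown"),
                alleles,
            ),
        )
        for j in range(n_loci):
            rows.append({"sample_id": sid, "locus_id": loci[j], "call": call[j]})
    return pd.DataFrame(rows)


def make_qc_study(n_responders: int = 60, n_neutral: int = 20,
                  n_plates: int = 12, conds_per_plate: int = 2,
                  seed: int = 0, noise_sd: float = 0.3) -> StudyBundle:
    """GC study fixture tailored to plate-swap QC.

    The expression truth is dominated by fast temperature responders
    (sub-hour to 3-h windows, no lag, ungated — heat-shock-like genes that
    make growth temperature recoverable from the transcriptome).  Conditions
    are assigned to plates so that the last four plates hold mid-range but
    mutually distinct temperature blocks (cooler on plates n-3/n-2, warmer
    on n-1/n, roughly 8 degC apart) while the design extremes stay on the
    other plates: swapping a cooler against a warmer plate then produces a
    clear annotation-temperature mismatch without destroying the training
    range of the leave-one-plate-out regression.
    """
    rng = np.random.default_rng(seed)
    conds = enumerate_conditions()

    def mean_temp(c: ConditionSpec) -> float:
        lt = c.light_temp if c.light_temp is not None else c.dark_temp
        dk = c.dark_temp if c.dark_temp is not None else c.light_temp
        return (lt * c.light_hours + dk * (24 - c.light_hours)) / 24.0

    ordered = sorted(conds, key=mean_temp)
    need = n_plates * conds_per_plate
    take = [ordered[int(round(i))] for i in np.linspace(0, len(ordered) - 1, need)]
    k = 2 * conds_per_plate
    lo = (need - 2 * k) // 3          # cooler mid-range block start
    hi = need - k - lo                # warmer mid-range block start
    cooler = take[lo:lo + k]
    warmer = take[hi:hi + k]
    rest = take[:lo] + take[lo + k:hi] + take[hi + k:]
    arranged = rest + cooler + warmer  # cooler on plates n-3/n-2, warmer on n-1/n

    truth = []
    for i in range(n_responders):
        b_e = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.2, 0.5))
        T = float(rng.choice([0.5, 1.5, 3.0]))
        truth.append(TruthGene(
            f"t{i:03d}", "temperature",
            NonlinearParams(T, 0.0, 0.0, 0.0, 2.0, -50.0, 50.0),
            LinearCoefs(9.0 - b_e * 27.0, 0.0, float(rng.normal(0, 0.3)),
                        float(rng.normal(0, 0.3)), b_e, 0.0, 0.0, 0.0),
            noise_sd,
        ))
    for i in range(n_neutral):
        truth.append(TruthGene(
            f"n{i:03d}", "neither",
            NonlinearParams(3.0, 0.0, 0.0, 0.0, 2.0, -50.0, 50.0),
            LinearCoefs(6.0, 0.0, float(rng.normal(0, 0.5)),
                        float(rng.normal(0, 0.5)), 0.0, 0.0, 0.0, 0.0),
            noise_sd,
        ))
    return simulate_gc_study(arranged, truth, seed=seed + 1,
                             samples_per_plate=conds_per_plate * len(SAMPLING_CLOCKS))


# ---------------------------------------------------------------------------
# cluster-membership fixture (exemplar genes -> member genes)
# ---------------------------------------------------------------------------

def make_cluster_table(n_exemplars: int = 466, total_members: int = 15907,
                       n_singletons: int = 66) -> pd.DataFrame:
    """Deterministic exemplar -> member table with a controllable size mix.

    The default mirrors the scale of a representative-gene analysis (466
    co-expression clusters covering 15,907 genes).  Sizes are a mix of
    singletons and near-equal larger clusters so that arbitrary member
    counts can be realized exactly by greedy exemplar selection.
    """
    if n_singletons >= n_exemplars:
        raise ValueError("need at least one non-singleton cluster")
    n_big = n_exemplars - n_singletons
    rem = total_members - n_singletons
    base = rem // n_big
    sizes = [1] * n_singletons + [base] * (n_big - 1) + [rem - base * (n_big - 1)]
    if min(sizes) < 1:
        raise ValueError("infeasible cluster-size construction")
    rows = []
    g = 0
    for ci, size in enumerate(sizes):
        members = [f"g{g + j:05d}" for j in range(size)]
        g += size
        for m in members:
            rows.append({"exemplar_gene_id": f"ex{ci:03d}", "member_gene_id": m})
    return pd.DataFrame(rows)


def select_exemplars_for_count(cluster_table: pd.DataFrame, target: int) -> list[str]:
    """Greedy exemplar selection whose clusters cover exactly ``target`` genes."""
    sizes = cluster_table.groupby("exemplar_gene_id").size().sort_values(ascending=False)
    chosen, acc = [], 0
    for ex, size in sizes.items():
        if acc + size <= target:
            chosen.append(ex)
            acc += int(size)
        if acc == target:
            return chosen
    raise ValueError(f"cannot realize member count {target} with this cluster table")
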