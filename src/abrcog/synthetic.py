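"""Synthetic cohorts and ABR epoch sets with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes for a three-age-group adult cohort (young 18–30, middle-aged 31–59,
elderly 60–92; default sizes 26/26/66):

* ages uniform within each group's range;
* pure-tone average (PTA) and ABR wave V latency/amplitude linear in age
  with Gaussian residuals, calibrated to the printed group summaries
  (young wave V latency ~5.95 ms rising to ~6.11 ms in the elderly, wave V
  amplitude falling 0.30 -> 0.19 µV, PTA rising ~1.4 -> ~24 dB HL);
* wave I latency/amplitude age-independent (latency normal, amplitude
  lognormal so it stays positive);
* a latent cognitive composite on the z scale driven by age
  (-0.021 z/year) and by the age-independent components of the wave V
  features, calibrated so that age-adjusted regressions of the recomputed
  composite on z-scored wave V amplitude/latency recover +0.110 / -0.101;
* ten domain measures sharing that single latent factor plus independent
  noise, affinely anchored to realistic raw scales (time measures inverted),
  so that re-standardising and averaging them reconstructs the composite.

Raw ABR epochs are sums of biphasic Gaussian wavelets (one per wave) in
white noise; a configurable fraction of sweeps additionally carries a large
square-pulse artifact exceeding the 23.8 µV rejection threshold. The
generator records which sweeps got artifacts and the planted wave features,
so artifact rejection and peak picking have exact oracles.

Everything is driven by ``numpy.random.default_rng(seed)``: identical
(params, seed) give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .schema import COGNITIVE_MEASURES, LOWER_IS_BETTER, ParameterError

# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearAgeModel:
    """value = intercept + slope * age + N(0, resid_sd)."""

    intercept: float
    slope: float
    resid_sd: float


@dataclass(frozen=True)
class WaveIModel:
    """Age-independent wave I parameters (amplitude drawn lognormal)."""

    latency_mean: float  # ms
    latency_sd: float
    amplitude_mean: float  # µV
    amplitude_sd: float


@dataclass(frozen=True)
class CognitionModel:
    """Latent composite on the z scale.

    composite = intercept + age_slope*(age - mean_age)
                + latency_slope_z * (scaled latent latency residual)
                + amplitude_slope_z * (scaled latent amplitude residual)
                + N(0, resid_sd)

    ``latency_slope`` / ``amplitude_slope`` are the *target* age-adjusted
    regression slopes per z of the wave feature; the generator internally
    rescales them by the residual/marginal SD ratio of the feature so that
    the fitted slopes converge to these targets.
    """

    intercept: float
    age_slope: float  # z per year
    latency_slope: float  # z per z of wave V latency (age-adjusted)
    amplitude_slope: float  # z per z of wave V amplitude (age-adjusted)
    resid_sd: float


@dataclass(frozen=True)
class CohortParams:
    group_sizes: tuple[int, int, int]
    age_ranges: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    pta_model: LinearAgeModel
    wave_v_latency_model: LinearAgeModel
    wave_v_amplitude_model: LinearAgeModel
    wave_i_model: WaveIModel
    cognition_model: CognitionModel
    domain_noise_sd: float  # unique per-measure noise, z scale
    female_fraction: float = 0.559
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name, model in (
            ("pta_model", self.pta_model),
            ("wave_v_latency_model", self.wave_v_latency_model),
            ("wave_v_amplitude_model", self.wave_v_amplitude_model),
        ):
            if model.resid_sd < 0:
                raise ParameterError(f"{name}.resid_sd must be >= 0")
        if self.wave_i_model.latency_sd < 0 or self.wave_i_model.amplitude_sd < 0:
            raise ParameterError("wave_i_model SDs must be >= 0")
        if self.cognition_model.resid_sd < 0:
            raise ParameterError("cognition_model.resid_sd must be >= 0")
        if self.domain_noise_sd < 0:
            raise ParameterError("domain_noise_sd must be >= 0")
        if any(n < 1 for n in self.group_sizes):
            raise ParameterError("group_sizes must all be >= 1")
        if len(self.group_sizes) != len(self.age_ranges):
            raise ParameterError("group_sizes and age_ranges must have equal length")
        prev_hi = -np.inf
        for lo, hi in self.age_ranges:
            if lo > hi:
                raise ParameterError(f"age_ranges entry ({lo}, {hi}) must be ordered")
            if lo <= prev_hi:
                raise ParameterError("age_ranges must be non-overlapping and increasing")
            prev_hi = hi
        if not 0.0 <= self.missing_rate < 1.0:
            raise ParameterError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ParameterError("female_fraction must be in [0, 1]")

    # --- analytic age-distribution moments of the group mixture ------------
    def age_moments(self) -> tuple[float, float]:
        """Population mean and SD of age under the uniform-mixture design."""
        sizes = np.asarray(self.group_sizes, dtype=float)
        w = sizes / sizes.sum()
        lo = np.array([r[0] for r in self.age_ranges])
        hi = np.array([r[1] for r in self.age_ranges])
        means = (lo + hi) / 2.0
        variances = (hi - lo) ** 2 / 12.0
        mu = float(w @ means)
        var = float(w @ (variances + means**2) - mu**2)
        return mu, np.sqrt(var)


@dataclass(frozen=True)
class SyntheticTruth:
    """Generator-side ground truth for one realized cohort."""

    params: CohortParams
    latent_composite: np.ndarray  # per participant, z scale
    mean_age: float  # population mean age used for centering
    # effective latent coefficients actually applied (after SD-ratio scaling)
    latency_coef: float
    amplitude_coef: float


@dataclass(frozen=True)
class EpochParams:
    """Raw ABR epoch simulation parameters.

    ``waves`` entries are (center latency ms, peak-to-trough amplitude µV,
    width ms ~ FWHM of the positive lobe).
    """

    sampling_rate: float = 24000.0  # Hz; 3 kHz filter corner needs margin
    epoch_duration: float = 10.66  # ms
    waves: tuple[tuple[float, float, float], ...] = (
        (1.8, 0.10, 0.3),  # wave I
        (6.0, 0.23, 0.5),  # wave V
    )
    noise_sd: float = 5.0  # µV per single sweep
    artifact_rate: float = 0.05
    artifact_amplitude: float = 40.0  # µV, must exceed the 23.8 µV threshold
    artifact_duration: float = 2.0  # ms (square pulse)
    n_sweeps: int = 2400
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        if self.epoch_duration <= 0:
            raise ParameterError("epoch_duration must be positive")
        if self.n_sweeps < 1:
            raise ParameterError("n_sweeps must be >= 1")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ParameterError("artifact_rate must be in [0, 1]")
        if self.artifact_rate > 0 and self.artifact_amplitude <= 23.8:
            raise ParameterError(
                "artifact_amplitude must exceed the 23.8 uV rejection threshold"
            )
        for center, amp, width in self.waves:
            if width <= 0 or amp < 0 or center < 0:
                raise ParameterError(f"invalid wave spec ({center}, {amp}, {width})")


# ---------------------------------------------------------------------------
# defaults
# ---------------------------------------------------------------------------

#: Target SD of the recomputed cognitive composite (mean of 10 sample-z
#: measures). 0.64 implies a mean inter-measure correlation of ~0.34.
_COMPOSITE_SD_TARGET = 0.64

#: Raw anchor scales for the ten measures: (mean, SD) in native units.
DOMAIN_SCALES: dict[str, tuple[float, float]] = {
    "word_learning": (22.10, 3.59),
    "delayed_recall": (7.08, 2.01),
    "word_recognition": (19.52, 1.31),
    "animal_fluency": (22.81, 5.65),
    "tmt_a_seconds": (26.77, 8.84),
    "tmt_b_seconds": (66.65, 27.33),
    "four_mountains_accuracy": (10.10, 2.87),
    "four_mountains_rt_ms": (8150.77, 2221.63),
    "visual_discrimination": (15.97, 1.82),
    "sdmt": (52.42, 11.63),
}

#: Instrument score limits: draws are clipped here, reproducing the ceiling
#: effects real test batteries show (e.g. word recognition saturates at 20).
DOMAIN_BOUNDS: dict[str, tuple[float, float]] = {
    "word_learning": (0.0, 30.0),
    "delayed_recall": (0.0, 10.0),
    "word_recognition": (0.0, 20.0),
    "animal_fluency": (0.0, 80.0),
    "tmt_a_seconds": (5.0, 600.0),
    "tmt_b_seconds": (10.0, 600.0),
    "four_mountains_accuracy": (0.0, 15.0),
    "four_mountains_rt_ms": (500.0, 60000.0),
    "visual_discrimination": (0.0, 18.0),
    "sdmt": (0.0, 120.0),
}

#: audiometer limits for the pure-tone average
PTA_BOUNDS = (-10.0, 120.0)


def _resid_to_marginal_ratio(model: LinearAgeModel, age_sd: float) -> float:
    """resid SD / marginal SD of a linear-in-age feature (0 when no residual)."""
    if model.resid_sd == 0:
        return 0.0
    marginal = float(np.hypot(model.slope * age_sd, model.resid_sd))
    return model.resid_sd / marginal


def default_params(n_total: int | None = None, seed: int = 0) -> CohortParams:
    """Paper-calibrated default cohort parameters.

    Group sizes 26/26/66 (scaled proportionally when ``n_total`` is given),
    age ranges 18–30 / 31–59 / 60–92, composite age slope −0.021 z/year and
    age-adjusted wave V slopes −0.101 (latency) / +0.110 (amplitude) per z.
    The latent residual SD is solved in closed form so the recomputed
    composite has SD ≈ 0.64 on the default design.
    """
    sizes = (26, 26, 66)
    if n_total is not None:
        if n_total < 3:
            raise ParameterError("n_total must be >= 3")
        raw = np.array(sizes, dtype=float) * n_total / sum(sizes)
        scaled = np.maximum(np.round(raw).astype(int), 1)
        # fix rounding drift on the largest group
        scaled[2] += n_total - int(scaled.sum())
        if scaled[2] < 1:
            raise ParameterError("n_total too small to populate three groups")
        sizes = tuple(int(x) for x in scaled)

    params = CohortParams(
        group_sizes=sizes,
        age_ranges=((18.0, 30.0), (31.0, 59.0), (60.0, 92.0)),
        pta_model=LinearAgeModel(intercept=-9.2, slope=0.44, resid_sd=8.0),
        wave_v_latency_model=LinearAgeModel(intercept=5.871, slope=0.0033, resid_sd=0.28),
        wave_v_amplitude_model=LinearAgeModel(intercept=0.355, slope=-0.0023, resid_sd=0.095),
        wave_i_model=WaveIModel(
            latency_mean=1.80, latency_sd=0.26, amplitude_mean=0.10, amplitude_sd=0.09
        ),
        cognition_model=CognitionModel(
            intercept=0.0,
            age_slope=-0.021,
            latency_slope=-0.101,
            amplitude_slope=0.110,
            resid_sd=0.0,  # placeholder, solved below
        ),
        domain_noise_sd=0.0,  # placeholder, solved below
        seed=seed,
    )

    # Per-measure unique noise w: each z-scored measure has variance ~1 =
    # shared + w^2, and the composite (mean of 10) has variance
    # shared + w^2/10 = target^2  =>  w^2 = (1 - target^2) / 0.9.
    w = float(np.sqrt((1.0 - _COMPOSITE_SD_TARGET**2) / 0.9))
    shared_var = 1.0 - w**2

    # Shared-factor variance budget: age term + wave couplings + residual.
    _, age_sd = params.age_moments()
    cog = params.cognition_model
    rho_lat = _resid_to_marginal_ratio(params.wave_v_latency_model, age_sd)
    rho_amp = _resid_to_marginal_ratio(params.wave_v_amplitude_model, age_sd)
    explained = (
        (cog.age_slope * age_sd) ** 2
        + (cog.latency_slope * rho_lat) ** 2
        + (cog.amplitude_slope * rho_amp) ** 2
    )
    if explained >= shared_var:
        raise ParameterError(
            "calibration infeasible: explained latent variance exceeds the shared-factor target"
        )
    resid_sd = float(np.sqrt(shared_var - explained))

    return replace(
        params,
        cognition_model=replace(cog, resid_sd=resid_sd),
        domain_noise_sd=w,
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(params: CohortParams) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw one cohort table plus its ground truth.

    Returns the canonical cohort DataFrame (one row per participant) and a
    :class:`SyntheticTruth` holding the latent composite. Deterministic in
    ``params`` (including ``params.seed``).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    ages_parts = []
    groups = []
    for gi, (n_g, (lo, hi)) in enumerate(zip(params.group_sizes, params.age_ranges)):
        ages_parts.append(rng.uniform(lo, hi, size=n_g))
        groups.extend([gi] * n_g)
    age = np.concatenate(ages_parts)
    n = age.size

    sex = np.where(rng.random(n) < params.female_fraction, "F", "M")

    def draw_linear(model: LinearAgeModel) -> tuple[np.ndarray, np.ndarray]:
        eta = rng.standard_normal(n)
        return model.intercept + model.slope * age + model.resid_sd * eta, eta

    pta, _ = draw_linear(params.pta_model)
    pta = np.clip(pta, *PTA_BOUNDS)  # audiometer floor/ceiling
    wave_v_lat, eta_lat = draw_linear(params.wave_v_latency_model)
    wave_v_amp, eta_amp = draw_linear(params.wave_v_amplitude_model)

    wi = params.wave_i_model
    wave_i_lat = wi.latency_mean + wi.latency_sd * rng.standard_normal(n)
    if wi.amplitude_sd > 0 and wi.amplitude_mean > 0:
        # moment-matched lognormal keeps amplitudes positive
        s2 = np.log1p((wi.amplitude_sd / wi.amplitude_mean) ** 2)
        mu = np.log(wi.amplitude_mean) - s2 / 2.0
        wave_i_amp = rng.lognormal(mu, np.sqrt(s2), size=n)
    else:
        wave_i_amp = np.full(n, wi.amplitude_mean)

    mean_age, age_sd = params.age_moments()
    cog = params.cognition_model
    rho_lat = _resid_to_marginal_ratio(params.wave_v_latency_model, age_sd)
    rho_amp = _resid_to_marginal_ratio(params.wave_v_amplitude_model, age_sd)
    lat_coef = cog.latency_slope * rho_lat
    amp_coef = cog.amplitude_slope * rho_amp
    composite = (
        cog.intercept
        + cog.age_slope * (age - mean_age)
        + lat_coef * eta_lat
        + amp_coef * eta_amp
        + cog.resid_sd * rng.standard_normal(n)
    )

    data: dict[str, np.ndarray] = {
        "participant_id": np.array([f"S{i + 1:03d}" for i in range(n)]),
        "age": age,
        "sex": sex,
        "pta": pta,
        "wave_i_latency": wave_i_lat,
        "wave_i_amplitude": wave_i_amp,
        "wave_v_latency": wave_v_lat,
        "wave_v_amplitude": wave_v_amp,
        "iv_latency_difference": wave_v_lat - wave_i_lat,
    }
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            (wave_i_amp > 0) & (wave_v_amp > 0), wave_v_amp / np.abs(wave_i_amp), np.nan
        )
        data["log_vi_amplitude_ratio"] = np.log(ratio)

    for measure in COGNITIVE_MEASURES:
        latent = composite + params.domain_noise_sd * rng.standard_normal(n)
        mean_m, sd_m = DOMAIN_SCALES[measure]
        direction = -1.0 if measure in LOWER_IS_BETTER else 1.0
        raw = mean_m + sd_m * direction * latent
        # instrument floor/ceiling effects (e.g. recognition saturates at 20)
        data[measure] = np.clip(raw, *DOMAIN_BOUNDS[measure])

    table = pd.DataFrame(data)

    if params.missing_rate > 0:
        miss = rng.random((n, len(COGNITIVE_MEASURES))) < params.missing_rate
        for j, measure in enumerate(COGNITIVE_MEASURES):
            table.loc[miss[:, j], measure] = np.nan

    truth = SyntheticTruth(
        params=params,
        latent_composite=composite,
        mean_age=mean_age,
        latency_coef=lat_coef,
        amplitude_coef=amp_coef,
    )
    return table, truth


# ---------------------------------------------------------------------------
# epoch generation
# ---------------------------------------------------------------------------


def wave_template(
    times_ms: np.ndarray, center: float, amplitude: float, width: float
) -> np.ndarray:
    """Biphasic wavelet: positive Gaussian lobe plus a delayed negative lobe.

    Rescaled so the peak-to-following-trough of the clean template equals
    ``amplitude`` exactly — that value is the planted truth for peak picking.
    """
    sig_p = width / 2.355  # width is the positive lobe's FWHM
    sig_n = 1.5 * sig_p
    shape = np.exp(-((times_ms - center) ** 2) / (2 * sig_p**2)) - 0.6 * np.exp(
        -((times_ms - center - 2 * width) ** 2) / (2 * sig_n**2)
    )
    if amplitude == 0:
        return np.zeros_like(shape)
    i_peak = int(np.argmax(shape))
    p2t = shape[i_peak] - shape[i_peak:].min()
    return shape * (amplitude / p2t)


def generate_epoch_set(params: EpochParams):
    """Simulate a sweeps x samples ABR epoch matrix.

    Clean sweeps are the wave template plus white Gaussian noise; a seeded
    Bernoulli(artifact_rate) subset additionally receives a square pulse of
    ``artifact_amplitude`` µV lasting ``artifact_duration`` ms at a random
    position, guaranteeing rejection at the 23.8 µV threshold. ``meta``
    records the artifact mask, the clean template and the planted features.
    """
    from .abr import EpochSet  # local import to avoid a cycle at import time

    params.validate()
    rng = np.random.default_rng(params.seed)
    n_samples = int(round(params.epoch_duration / 1000.0 * params.sampling_rate))
    times = np.arange(n_samples) / params.sampling_rate * 1000.0

    template = np.zeros(n_samples)
    for center, amp, width in params.waves:
        template += wave_template(times, center, amp, width)

    data = template + params.noise_sd * rng.standard_normal((params.n_sweeps, n_samples))

    artifact_mask = rng.random(params.n_sweeps) < params.artifact_rate
    if artifact_mask.any():
        pulse_len = max(int(round(params.artifact_duration / 1000.0 * params.sampling_rate)), 1)
        pulse_len = min(pulse_len, n_samples)
        starts = rng.integers(0, n_samples - pulse_len + 1, size=int(artifact_mask.sum()))
        signs = rng.choice([-1.0, 1.0], size=starts.size)
        for row, start, sign in zip(np.flatnonzero(artifact_mask), starts, signs):
            data[row, start : start + pulse_len] += sign * params.artifact_amplitude

    return EpochSet(
        data=data,
        sampling_rate=params.sampling_rate,
        onset_time=0.0,
        meta={
            "seed": params.seed,
            "artifact_mask": artifact_mask,
            "template": template,
            "planted_waves": tuple(params.waves),
            "params": params,
        },
    )


def generate_epoch_sets_for_cohort(
    cohort: pd.DataFrame,
    base_params: EpochParams | None = None,
    seed: int = 0,
    wave_columns: Sequence[str] = ("wave_i_latency", "wave_i_amplitude", "wave_v_latency", "wave_v_amplitude"),
):
    """Yield (participant_id, EpochSet) pairs planting each row's wave features."""
    base = base_params or EpochParams()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(cohort))
    for child, (_, row) in zip(children, cohort.iterrows()):
        il, ia, vl, va = (float(row[c]) for c in wave_columns)
        p = replace(
            base,
            waves=((il, max(ia, 0.0), 0.3), (vl, max(va, 0.0), 0.5)),
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        yield row["participant_id"], generate_epoch_set(p)
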