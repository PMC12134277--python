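"""Synthetic EIS cohort generation.

Real clinical impedance spectra for this problem are confidential, so every
downstream stage of the pipeline is exercised on synthetic cohorts.  Spectra
follow a single-dispersion Cole model,

    Z(omega) = R_inf + (R0 - R_inf) / (1 + (j * omega * tau) ** alpha),

the simplest standard parametric form for biological tissue impedance that
reproduces the qualitative behaviour of mucosal EIS: a monotone-decreasing
real part from R0 (DC limit) to R_inf (high-frequency limit) and a
single-peaked reactive part centred near omega = 1/tau.  Disease is encoded
chiefly as a reduced low-frequency resistance R0 and a shifted time constant
tau, i.e. lesion spectra leave the healthy band most visibly at low
frequency.

Stored spectra follow the convention Z = Z_Re - j * Z_Im, so the reported
imaginary part Z_Im is the negated mathematical imaginary component and is
non-negative for a passive capacitive tissue.

Cohort structure mirrors the study design this package emulates: a human
cohort of healthy volunteers plus WHO-graded lesion subjects (readings
nested within subjects), and a porcine proof-of-concept cohort of normal
versus acid-treated mucosa.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._exceptions import InvalidArgumentError
from .data import EISDataset, EISReading, assign_binary_label

__all__ = [
    "FrequencyGrid",
    "ColeParameters",
    "TissueClassSpec",
    "CohortConfig",
    "build_frequency_grid",
    "simulate_spectrum",
    "sample_subject",
    "generate_cohort",
    "default_human_config",
    "default_pig_config",
    "null_calibration_config",
    "human_class_specs",
    "pig_class_specs",
    "null_class_specs",
]


@dataclass(frozen=True)
class FrequencyGrid:
    """Measurement frequencies: ``n_steps`` binary (doubling) steps from ``f_min``."""

    f_min: float
    n_steps: int
    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.frequencies[0] != self.f_min:
            raise InvalidArgumentError("grid must start at f_min")

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies (rad/s)."""
        return 2.0 * np.pi * np.asarray(self.frequencies)


def build_frequency_grid(f_min: float = 76.0, n_steps: int = 14) -> FrequencyGrid:
    """Build the doubling frequency grid f_k = f_min * 2**k, k = 0..n_steps-1.

    The default grid spans 76 Hz to 622,592 Hz (nominally 625 kHz) in 14
    binary steps, the sweep of the hand-held EIS probe this pipeline targets.
    """
    if f_min <= 0:
        raise InvalidArgumentError(f"f_min must be positive, got {f_min}")
    if n_steps < 1:
        raise InvalidArgumentError(f"n_steps must be >= 1, got {n_steps}")
    freqs = tuple(float(f_min) * 2.0**k for k in range(int(n_steps)))
    return FrequencyGrid(f_min=float(f_min), n_steps=int(n_steps), frequencies=freqs)


@dataclass(frozen=True)
class ColeParameters:
    """Single-dispersion Cole model parameters.

    R0 and R_inf are the low- and high-frequency resistance limits (Ohm),
    tau the characteristic time constant (s), and alpha in (0, 1] the
    dispersion broadening exponent (alpha = 1 recovers a Debye dispersion).
    """

    R0: float
    R_inf: float
    tau: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not (self.R0 > self.R_inf > 0):
            raise InvalidArgumentError(
                f"require R0 > R_inf > 0, got R0={self.R0}, R_inf={self.R_inf}"
            )
        if self.tau <= 0:
            raise InvalidArgumentError(f"tau must be positive, got {self.tau}")
        if not (0 < self.alpha <= 1):
            raise InvalidArgumentError(f"alpha must lie in (0, 1], got {self.alpha}")


@dataclass(frozen=True)
class TissueClassSpec:
    """Sampling distribution for one tissue class.

    Between-subject variation is multiplicative log-normal on each Cole
    parameter (keeping them positive); reading-level measurement noise is
    i.i.d. Gaussian with SD ``reading_sd`` times the local signal magnitude,
    applied independently to the real and reactive parts.
    """

    class_label: str
    mean_params: ColeParameters
    subject_sd: float = 0.10
    reading_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.subject_sd < 0 or self.reading_sd < 0:
            raise InvalidArgumentError("SDs must be non-negative")


@dataclass(frozen=True)
class ClassCount:
    """Subject/reading bookkeeping for one class in a cohort config."""

    n_subjects: int
    n_readings: int
    #: Optional explicit readings-per-subject pattern (len == n_subjects, sums
    #: to n_readings).  When None, readings are spread as evenly as possible.
    reading_pattern: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 0 or self.n_readings < 0:
            raise InvalidArgumentError("counts must be non-negative")
        if self.n_subjects > 0 and self.n_readings < self.n_subjects:
            raise InvalidArgumentError("need at least one reading per subject")
        if self.reading_pattern is not None:
            if len(self.reading_pattern) != self.n_subjects:
                raise InvalidArgumentError("reading_pattern length != n_subjects")
            if sum(self.reading_pattern) != self.n_readings:
                raise InvalidArgumentError("reading_pattern does not sum to n_readings")
            if any(r < 1 for r in self.reading_pattern):
                raise InvalidArgumentError("reading_pattern entries must be >= 1")

    def per_subject(self) -> list[int]:
        if self.reading_pattern is not None:
            return list(self.reading_pattern)
        if self.n_subjects == 0:
            return []
        base, extra = divmod(self.n_readings, self.n_subjects)
        return [base + (1 if i < extra else 0) for i in range(self.n_subjects)]


@dataclass(frozen=True)
class CohortConfig:
    """Per-class subject/reading counts plus label-assignment settings."""

    counts: dict[str, ClassCount]
    moderate_to_highrisk_fraction: float = 2.0 / 3.0
    #: When set, moderate-dysplasia subjects with these (sorted descending)
    #: positions in the per-subject reading pattern are assigned high-risk
    #: deterministically; used by the default human config to pin the cohort
    #: table's 2/3 low-risk vs 9/18 high-risk split exactly.
    moderate_highrisk_subjects: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.moderate_to_highrisk_fraction <= 1.0):
            raise InvalidArgumentError("fraction must lie in [0, 1]")


def simulate_spectrum(
    params: ColeParameters,
    grid: FrequencyGrid,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Evaluate the Cole model on a frequency grid, optionally with noise.

    Returns a complex array in the storage convention Z = Z_Re - j*Z_Im with
    Z_Im >= 0 in the noiseless case; i.e. ``-result.imag`` is the reported
    reactive part.  Noise is multiplicative Gaussian with SD ``noise_sd``
    (fraction of signal), independent per frequency and per component.
    """
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be non-negative")
    omega = grid.omega
    z = params.R_inf + (params.R0 - params.R_inf) / (
        1.0 + (1j * omega * params.tau) ** params.alpha
    )
    if noise_sd > 0:
        if rng is None:
            raise InvalidArgumentError("rng required when noise_sd > 0")
        re = z.real * (1.0 + noise_sd * rng.standard_normal(z.shape))
        im = z.imag * (1.0 + noise_sd * rng.standard_normal(z.shape))
        z = re + 1j * im
    return z


def _sample_params(spec: TissueClassSpec, rng: np.random.Generator) -> ColeParameters:
    m = spec.mean_params
    if spec.subject_sd == 0:
        return m
    factors = np.exp(spec.subject_sd * rng.standard_normal(4))
    alpha = min(1.0, m.alpha * factors[3])
    r_inf = m.R_inf * factors[1]
    r0 = max(m.R0 * factors[0], r_inf * 1.01)  # keep R0 > R_inf
    return ColeParameters(R0=r0, R_inf=r_inf, tau=m.tau * factors[2], alpha=alpha)


def sample_subject(
    spec: TissueClassSpec,
    grid: FrequencyGrid,
    n_readings: int,
    subject_id: str,
    rng: np.random.Generator,
    site: str = "VT",
) -> list[EISReading]:
    """Draw one subject: latent per-subject Cole parameters, then noisy readings.

    All readings of the subject share the latent parameters; reading-level
    noise is independent across readings.
    """
    params = _sample_params(spec, rng)
    readings = []
    for k in range(n_readings):
        z = simulate_spectrum(params, grid, noise_sd=spec.reading_sd, rng=rng)
        readings.append(
            EISReading(
                reading_id=f"{subject_id}_r{k:02d}",
                subject_id=subject_id,
                site=site,
                z_re=tuple(z.real.tolist()),
                z_im=tuple((-z.imag).tolist()),
                who_grade=spec.class_label,
                binary_label="",  # assigned at cohort level
            )
        )
    return readings


# ---------------------------------------------------------------------------
# Default presets.
#
# The study publishes no numeric spectra, so class means are free presets
# calibrated only to the qualitative picture of the published spectra plots:
# diseased tissue leaves the healthy mean +- SD band chiefly at low frequency
# (reduced R0), with severity ordering the departure.  Magnitudes are in the
# kilo-ohm range typical of tetrapolar mucosal probes.
# ---------------------------------------------------------------------------

_HEALTHY = ColeParameters(R0=4000.0, R_inf=300.0, tau=1.6e-5, alpha=0.85)

_HUMAN_MEANS: dict[str, ColeParameters] = {
    "healthy": _HEALTHY,
    "non_dysplastic": ColeParameters(R0=3600.0, R_inf=300.0, tau=1.5e-5, alpha=0.85),
    "mild": ColeParameters(R0=3200.0, R_inf=310.0, tau=1.3e-5, alpha=0.84),
    "moderate": ColeParameters(R0=2500.0, R_inf=320.0, tau=1.0e-5, alpha=0.82),
    "severe": ColeParameters(R0=2000.0, R_inf=330.0, tau=8.0e-6, alpha=0.80),
    "cancer": ColeParameters(R0=1500.0, R_inf=350.0, tau=6.0e-6, alpha=0.78),
}

_PIG_MEANS: dict[str, ColeParameters] = {
    "healthy": ColeParameters(R0=4000.0, R_inf=300.0, tau=1.6e-5, alpha=0.85),
    "treated": ColeParameters(R0=1800.0, R_inf=340.0, tau=7.0e-6, alpha=0.80),
}


def human_class_specs(
    subject_sd: float = 0.10, reading_sd: float = 0.03
) -> dict[str, TissueClassSpec]:
    """Default per-class sampling specs for the human cohort."""
    return {
        label: TissueClassSpec(label, mean, subject_sd=subject_sd, reading_sd=reading_sd)
        for label, mean in _HUMAN_MEANS.items()
    }


def pig_class_specs(
    subject_sd: float = 0.10, reading_sd: float = 0.03
) -> dict[str, TissueClassSpec]:
    """Default per-class sampling specs for the porcine cohort."""
    return {
        label: TissueClassSpec(label, mean, subject_sd=subject_sd, reading_sd=reading_sd)
        for label, mean in _PIG_MEANS.items()
    }


def null_class_specs(
    labels: list[str] | None = None, reading_sd: float = 0.03
) -> dict[str, TissueClassSpec]:
    """Zero-class-effect specs: every class shares the healthy mean parameters.

    Labels then carry no spectral information, so any downstream classifier
    should sit at chance — the calibration null for the pipeline.  Between-
    subject variation is also zeroed so that readings are exchangeable at
    the reading level: with only a handful of lesion subjects in the cohort,
    latent per-subject spectra would otherwise dominate the chance-level
    band and the calibration would measure the subject lottery of one small
    cohort draw instead of pipeline bias.
    """
    specs = {}
    for label in labels or list(_HUMAN_MEANS):
        specs[label] = TissueClassSpec(
            label, _HEALTHY, subject_sd=0.0, reading_sd=reading_sd
        )
    return specs


def default_human_config(seed: int = 0) -> CohortConfig:
    """Human cohort matching the study's combined VT/FM table exactly.

    51 healthy subjects / 102 readings; lesion subjects: 5 cancer / 10
    readings, 1 mild / 2, 3 moderate / 4, 2 severe / 5.  The moderate
    reading pattern is pinned to (2, 1, 1) with the first two subjects
    assigned high-risk, reproducing the table's binary split of 2 low-risk
    subjects / 3 readings versus 9 high-risk subjects / 18 readings.
    """
    return CohortConfig(
        counts={
            "healthy": ClassCount(51, 102),
            "cancer": ClassCount(5, 10),
            "mild": ClassCount(1, 2),
            "moderate": ClassCount(3, 4, reading_pattern=(2, 1, 1)),
            "severe": ClassCount(2, 5, reading_pattern=(2, 3)),
        },
        moderate_highrisk_subjects=(0, 1),
        seed=seed,
    )


def null_calibration_config(seed: int = 0) -> CohortConfig:
    """Binary zero-effect cohort used to calibrate the pipeline at chance.

    Sized (150 low-risk subjects / 300 readings, 30 high-risk subjects / 60
    readings) so that a pooled test AUC has a standard error of ~0.04 under
    the null: the tiny clinical-table cohort pins the pooled AUC to a
    handful of fixed readings and cannot resolve the chance band.  Pair
    with :func:`null_class_specs`.
    """
    return CohortConfig(
        counts={
            "non_dysplastic": ClassCount(150, 300),
            "cancer": ClassCount(30, 60),
        },
        seed=seed,
    )


def default_pig_config(seed: int = 0) -> CohortConfig:
    """Porcine cohort: 15 normal heads / 220 readings, 3 treated heads / 80."""
    return CohortConfig(
        counts={
            "healthy": ClassCount(15, 220),
            "treated": ClassCount(3, 80),
        },
        seed=seed,
    )


def generate_cohort(
    config: CohortConfig,
    class_specs: dict[str, TissueClassSpec],
    grid: FrequencyGrid | None = None,
) -> EISDataset:
    """Generate a full cohort dataset from per-class counts and specs.

    Binary labels are derived from the WHO grade: deterministic for all
    grades except moderate dysplasia, which goes high-risk with probability
    ``moderate_to_highrisk_fraction`` (or per the pinned subject list when
    ``moderate_highrisk_subjects`` is set).
    """
    grid = grid or build_frequency_grid()
    rng = np.random.default_rng(config.seed)
    readings: list[EISReading] = []
    for label in sorted(config.counts):
        count = config.counts[label]
        if label not in class_specs and count.n_subjects > 0:
            raise InvalidArgumentError(f"no TissueClassSpec for class {label!r}")
        for s_idx, n_read in enumerate(count.per_subject()):
            subject_id = f"{label}_s{s_idx:03d}"
            site = "VT" if rng.random() < 0.5 else "FM"
            subj_readings = sample_subject(
                class_specs[label], grid, n_read, subject_id, rng, site=site
            )
            if label == "moderate" and config.moderate_highrisk_subjects is not None:
                binary = (
                    "high_risk"
                    if s_idx in config.moderate_highrisk_subjects
                    else "low_risk"
                )
            else:
                binary = assign_binary_label(
                    label, rng.random(), config.moderate_to_highrisk_fraction
                )
            subj_readings = [replace(r, binary_label=binary) for r in subj_readings]
            readings.extend(subj_readings)
    provenance = {"generator": "eisrisk.synth", "seed": config.seed}
    return EISDataset(readings=readings, grid=grid, provenance=provenance)
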