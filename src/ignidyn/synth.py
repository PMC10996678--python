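"""Synthetic cohorts with analytically known ignition statistics.

Real resting-state cohorts are not redistributable, so the test bed is a
generative model chosen for *tractability*: global ignition events occur at
Poisson-thinned TRs; each event recruits a random fraction of regions drawn
from a Beta distribution; recruited regions co-activate at that single TR.
Because co-active regions form a clique, the integration of an event equals
the recruited fraction, and node-metastability has a closed form — the
standard deviation of the (size-biased) recruitment fraction plus a binomial
sampling correction.  A *severity* parameter shrinks the recruitment fraction
toward its mean, lowering integration variance (the quantity
node-metastability measures) without moving the mean, which emulates the
progressive loss of dynamical complexity along the Alzheimer's continuum
(healthy controls > mild cognitive impairment > Alzheimer's disease).

A BOLD mode convolves the event trains with a canonical two-gamma
haemodynamic kernel and adds Gaussian noise, so the full band-pass /
threshold pipeline can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .ignition import EventRaster, IgnitionProfile, ParcelTimeSeries

__all__ = [
    "SyntheticSpec",
    "BurdenCoefficients",
    "GroundTruth",
    "generate_event_raster",
    "raster_to_bold",
    "generate_burden_tables",
    "generate_cohort",
    "clique_metastability_target",
    "event_integration_sd_target",
    "hrf_kernel",
    "COHORT_SEVERITY",
    "COHORT_SIZES",
    "BURDEN_MEANS",
]

# Severity of recruitment-variability shrinkage per diagnostic group.  The
# MCI and AD values are the complements of the printed whole-brain group-mean
# metastability ratios (0.087/0.094 and 0.070/0.094), so cohort means scale
# the way the three stages do.
COHORT_SEVERITY: dict[str, float] = {"HC": 0.0, "MCI": 0.074, "AD": 0.255}

# Group sizes of the study cohort (17 HC, 9 MCI, 10 AD).
COHORT_SIZES: dict[str, int] = {"HC": 17, "MCI": 9, "AD": 10}

# Cohort-mean SUVR levels per group (amyloid-beta, tau), matching the
# demographics table of the study population.
BURDEN_MEANS: dict[str, tuple[float, float]] = {
    "HC": (1.31, 1.53),
    "MCI": (1.52, 1.80),
    "AD": (2.01, 2.46),
}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic subject's event raster.

    event_rate is the per-TR probability of a global ignition event;
    recruit_alpha/recruit_beta shape the Beta recruitment-fraction law;
    severity in [0, 1] shrinks each fraction toward the Beta mean
    (f' = mean + (1 - severity)·(f - mean)); noise_sd is the Gaussian
    noise added in BOLD mode, in units of the unit-peak haemodynamic kernel.
    """

    n_regions: int = 100
    n_timepoints: int = 197
    tr_seconds: float = 3.0
    event_rate: float = 0.15
    recruit_alpha: float = 2.0
    recruit_beta: float = 2.0
    noise_sd: float = 0.1
    severity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.recruit_alpha <= 0 or self.recruit_beta <= 0:
            raise ParameterError("recruit_alpha and recruit_beta must be positive")
        if not 0.0 <= self.severity <= 1.0:
            raise ParameterError(f"severity must lie in [0, 1], got {self.severity}")
        if self.n_regions < 2 or self.n_timepoints < 2:
            raise ParameterError("need at least 2 regions and 2 timepoints")
        if not 0.0 < self.event_rate <= 1.0:
            raise ParameterError("event_rate must lie in (0, 1]")
        if self.event_rate * self.n_timepoints < 10:
            raise ParameterError(
                "event_rate·n_timepoints < 10: too few events for usable statistics"
            )


@dataclass
class BurdenCoefficients:
    """True mixed-model coefficients linking burden to node-metastability."""

    intercept: float = 0.10
    beta_abeta: float = -0.002
    beta_tau: float = -0.002
    beta_interaction: float = 0.0
    random_intercept_sd: float = 0.003
    residual_sd: float = 0.005


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    event_times: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    recruit_fractions: np.ndarray = field(default_factory=lambda: np.empty(0))
    drivers: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    coefficients: BurdenCoefficients | None = None
    random_intercepts: dict[str, float] = field(default_factory=dict)


def generate_event_raster(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[EventRaster, GroundTruth]:
    """Draw one subject's clique event raster.

    Each TR is independently a global event with probability ``event_rate``.
    Per event, a recruitment fraction ``f ~ Beta(recruit_alpha, recruit_beta)``
    is drawn and shrunk toward its mean by ``severity``; each region is then
    independently active with probability ``f``, with one uniformly chosen
    nominal driver always active.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    is_event = rng.random(spec.n_timepoints) < spec.event_rate
    event_times = np.flatnonzero(is_event)
    n_events = event_times.size
    mean_f = spec.recruit_alpha / (spec.recruit_alpha + spec.recruit_beta)
    f_raw = rng.beta(spec.recruit_alpha, spec.recruit_beta, size=n_events)
    f = mean_f + (1.0 - spec.severity) * (f_raw - mean_f)
    drivers = rng.integers(0, spec.n_regions, size=n_events)
    events = np.zeros((spec.n_regions, spec.n_timepoints), dtype=np.uint8)
    if n_events:
        active = rng.random((n_events, spec.n_regions)) < f[:, None]
        active[np.arange(n_events), drivers] = True
        events[:, event_times] = active.T
    raster = EventRaster(events=events, theta=np.nan)
    truth = GroundTruth(event_times=event_times, recruit_fractions=f, drivers=drivers)
    return raster, truth


def hrf_kernel(
    tr_seconds: float,
    duration_s: float = 32.0,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical two-gamma haemodynamic response sampled at the TR.

    Gamma shapes are chosen so the analytic mode of the positive lobe falls
    at ``peak_s`` and of the undershoot at ``undershoot_s`` (rate 1/s); the
    kernel is scaled to unit peak so noise_sd is expressed relative to the
    event response amplitude.
    """
    t = np.arange(0.0, duration_s + tr_seconds / 2, tr_seconds)
    peak = stats.gamma.pdf(t, a=peak_s + 1.0, scale=1.0)
    under = stats.gamma.pdf(t, a=undershoot_s + 1.0, scale=1.0)
    h = peak - undershoot_ratio * under
    return h / h.max()


def raster_to_bold(
    raster: EventRaster,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    subject_id: str = "synthetic",
) -> ParcelTimeSeries:
    """Convolve event trains with the haemodynamic kernel and add noise."""
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    h = hrf_kernel(spec.tr_seconds)
    n_regions, n_time = raster.events.shape
    bold = np.empty((n_regions, n_time))
    trains = raster.events.astype(float)
    for i in range(n_regions):
        bold[i] = np.convolve(trains[i], h)[:n_time]
    if spec.noise_sd > 0:
        bold += rng.normal(0.0, spec.noise_sd, size=bold.shape)
    return ParcelTimeSeries(subject_id, bold, spec.tr_seconds)


def _shrunk_beta_moments(alpha: float, beta: float, severity: float) -> tuple[float, float, float]:
    """First three raw moments of the severity-shrunk recruitment fraction."""
    mu = alpha / (alpha + beta)
    var = alpha * beta / ((alpha + beta) ** 2 * (alpha + beta + 1))
    skew = (
        2 * (beta - alpha) * np.sqrt(alpha + beta + 1)
        / ((alpha + beta + 2) * np.sqrt(alpha * beta))
    )
    mu3 = skew * var**1.5  # third central moment
    c = 1.0 - severity
    m1 = mu
    m2 = mu**2 + c**2 * var
    m3 = mu**3 + 3 * mu * c**2 * var + c**3 * mu3
    return m1, m2, m3


def clique_metastability_target(
    alpha: float, beta: float, n_regions: int, severity: float = 0.0
) -> float:
    """Closed-form node-metastability of the clique generator.

    A region records an event only when it is itself recruited, which
    size-biases the recruitment density by a factor f/E[f] (for severity 0
    and Beta(a, b) recruitment this is exactly Beta(a+1, b)).  Conditional on
    the fraction f, the observed integration is (1 + Binomial(N-1, f))/N, so

        Var = ((N-1)/N)^2 · Var_sb(f) + (N-1)/N^2 · E_sb[f(1-f)]

    with moments under the size-biased law.  Driver forcing adds an O(1/N)
    perturbation that is neglected here (and covered by test tolerances).
    """
    m1, m2, m3 = _shrunk_beta_moments(alpha, beta, severity)
    # size-biased raw moments: E_sb[f^k] = E[f^(k+1)] / E[f]
    s1, s2 = m2 / m1, m3 / m1
    var_sb = s2 - s1**2
    e_f1mf = s1 - s2
    n = n_regions
    var = ((n - 1) / n) ** 2 * var_sb + (n - 1) / n**2 * e_f1mf
    return float(np.sqrt(var))


def event_integration_sd_target(
    alpha: float, beta: float, n_regions: int, severity: float = 0.0
) -> float:
    """Closed-form sd of integration over *all* events (no size bias)."""
    m1, m2, _ = _shrunk_beta_moments(alpha, beta, severity)
    var_f = m2 - m1**2
    e_f1mf = m1 - m2
    n = n_regions
    return float(np.sqrt(var_f + e_f1mf / n))


def generate_burden_tables(
    profiles: list[IgnitionProfile],
    coefficients: BurdenCoefficients,
    groups: dict[str, str] | None = None,
    rng: np.random.Generator | None = None,
    suvr_sigma: float = 0.25,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, GroundTruth]:
    """Per-subject burden tables plus metastability targets with known coefficients.

    For every subject×region, amyloid-beta and tau SUVR are drawn log-normally
    around the subject group's cohort mean (``BURDEN_MEANS``; ``suvr_sigma``
    is the log-scale sd), and a node-metastability *target* is regenerated as

        intercept + β_Aβ·Aβ + β_tau·tau + β_int·Aβ·tau
        + subject random intercept + residual

    so a mixed-effects fit has exact ground truth to recover.  ``groups``
    maps subject id to HC/MCI/AD; subjects absent from it use the HC means.

    Returns (burden tables keyed by subject, long metastability-target table,
    ground truth with coefficients and drawn random intercepts).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    groups = groups or {}
    burdens: dict[str, pd.DataFrame] = {}
    rows = []
    rand_intercepts: dict[str, float] = {}
    for prof in profiles:
        sid = prof.subject_id or f"S{len(burdens):03d}"
        ab_mean, tau_mean = BURDEN_MEANS.get(groups.get(sid, "HC"), BURDEN_MEANS["HC"])
        n = len(prof.region_ids)
        abeta = rng.lognormal(np.log(ab_mean) - suvr_sigma**2 / 2, suvr_sigma, n)
        tau = rng.lognormal(np.log(tau_mean) - suvr_sigma**2 / 2, suvr_sigma, n)
        b0 = rng.normal(0.0, coefficients.random_intercept_sd)
        rand_intercepts[sid] = b0
        meta = (
            coefficients.intercept
            + coefficients.beta_abeta * abeta
            + coefficients.beta_tau * tau
            + coefficients.beta_interaction * abeta * tau
            + b0
            + rng.normal(0.0, coefficients.residual_sd, n)
        )
        burdens[sid] = pd.DataFrame(
            {"region_id": prof.region_ids, "abeta_suvr": abeta, "tau_suvr": tau}
        )
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "region_id": prof.region_ids,
                    "metastability": meta,
                }
            )
        )
    truth = GroundTruth(coefficients=coefficients, random_intercepts=rand_intercepts)
    return burdens, pd.concat(rows, ignore_index=True), truth


def generate_cohort(
    base_spec: SyntheticSpec | None = None,
    severities: dict[str, float] | None = None,
    sizes: dict[str, int] | None = None,
    seed: int = 0,
    bold: bool = False,
) -> tuple[dict[str, EventRaster | ParcelTimeSeries], dict[str, str], dict[str, GroundTruth]]:
    """Generate a three-group cohort of synthetic subjects.

    Returns (per-subject raster or BOLD series, subject→group map, per-subject
    ground truth).  Group severities default to ``COHORT_SEVERITY`` and sizes
    to ``COHORT_SIZES``; every subject draws from an independent substream of
    ``seed``.
    """
    base_spec = base_spec or SyntheticSpec()
    severities = severities if severities is not None else COHORT_SEVERITY
    sizes = sizes if sizes is not None else COHORT_SIZES
    master = np.random.SeedSequence(seed)
    subjects: dict[str, EventRaster | ParcelTimeSeries] = {}
    groups: dict[str, str] = {}
    truths: dict[str, GroundTruth] = {}
    streams = iter(master.spawn(sum(sizes.values())))
    for group, n in sizes.items():
        for j in range(n):
            sid = f"{group}{j:02d}"
            rng = np.random.default_rng(next(streams))
            spec = replace(base_spec, severity=severities[group])
            raster, truth = generate_event_raster(spec, rng)
            raster.region_ids = [f"R{i:03d}" for i in range(spec.n_regions)]
            if bold:
                subjects[sid] = raster_to_bold(raster, spec, rng, subject_id=sid)
            else:
                subjects[sid] = raster
            groups[sid] = group
            truths[sid] = truth
    return subjects, groups, truths
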