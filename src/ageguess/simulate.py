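"""Synthetic 450k/EPIC-like methylome generator with planted ground truth.

The generator emulates the shape of whole-blood methylation array studies:
hundreds of samples with uniformly distributed adult ages, thousands to
hundreds of thousands of CpG probes whose beta values sit in a bimodal
(mostly un/fully methylated) baseline, a small planted set of probes whose
mean beta drifts linearly with age, optional probes informative in one sex
only, and a fraction of probes annotated to the sex chromosomes (always
drawn from the uninformative pool, so excluding them never removes
signal).  Every draw is reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import sqrt, pi
from pathlib import Path

import numpy as np

from .datamodel import FeatureAnnotation, MethylomeMatrix, SampleMetadata
from .errors import ValidationError

#: beta values are clamped into this open interval to avoid boundary
#: pathologies in downstream standardisation
CLAMP_LO, CLAMP_HI = 0.001, 0.999


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults emulate a mid-sized 450k blood study."""

    n_samples: int = 300
    n_features: int = 2000
    n_informative: int = 20
    n_gender_specific: int = 0  # split evenly male/female
    age_min: float = 19.0
    age_max: float = 101.0
    slope_min: float = 0.002  # beta units per year, sign randomised
    slope_max: float = 0.008
    gender_effect: float = 0.05  # additive beta offset in the target sex
    noise_sd: float = 0.01  # beta units
    sex_chrom_fraction: float = 0.02
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative + self.n_gender_specific > self.n_features:
            raise ValidationError("planted probes exceed n_features")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        for r in (self.sex_chrom_fraction, self.missing_rate):
            if not (0.0 <= r <= 1.0):
                raise ValidationError(f"rate {r} outside [0, 1]")
        if not (0 < self.age_min < self.age_max):
            raise ValidationError("need 0 < age_min < age_max")
        if not (0 < self.slope_min <= self.slope_max):
            raise ValidationError("need 0 < slope_min <= slope_max")


@dataclass
class PlantedProbe:
    probe_id: str
    slope: float  # beta units per year (signed)
    intercept: float  # beta at age 0
    target_sex: str | None = None  # None: informative in everyone
    gender_effect: float = 0.0


@dataclass
class GroundTruth:
    """What was planted: probes with their linear models, plus the samples."""

    informative: list[PlantedProbe] = field(default_factory=list)
    gender_specific: list[PlantedProbe] = field(default_factory=list)
    ages: list[float] = field(default_factory=list)
    sexes: list[str] = field(default_factory=list)

    @property
    def informative_ids(self) -> list[str]:
        return [p.probe_id for p in self.informative]

    @property
    def gender_ids(self) -> list[str]:
        return [p.probe_id for p in self.gender_specific]

    def gender_ids_for(self, sex: str) -> list[str]:
        return [p.probe_id for p in self.gender_specific if p.target_sex == sex]

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "informative": [asdict(p) for p in self.informative],
            "gender_specific": [asdict(p) for p in self.gender_specific],
            "ages": self.ages,
            "sexes": self.sexes,
        }
        text = json.dumps(d, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, "utf-8")
        return text


def simulate_methylome(
    config: SyntheticConfig,
) -> tuple[MethylomeMatrix, list[SampleMetadata], list[FeatureAnnotation], GroundTruth]:
    """Draw a synthetic methylome with planted age-associated probes.

    Informative probes follow ``beta = b0 + b1 * age + noise`` with the
    intercept chosen so the noiseless mean stays inside [0.05, 0.95] over
    the whole age range (clamping then almost never distorts the signal).
    Gender-specific probes carry their age slope and an additive offset in
    the target sex only and are baseline noise in the other sex.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_features
    ages = rng.uniform(config.age_min, config.age_max, size=n)
    sexes = np.where(rng.random(n) < 0.5, "male", "female")

    probe_ids = [f"cg{i:08d}" for i in range(p)]
    sample_ids = [f"s{j:04d}" for j in range(n)]

    n_planted = config.n_informative + config.n_gender_specific
    planted_pos = rng.choice(p, size=n_planted, replace=False)
    info_pos = planted_pos[: config.n_informative]
    gender_pos = planted_pos[config.n_informative :]

    values = _baseline(rng, p, n, config.noise_sd)

    truth = GroundTruth(ages=[float(a) for a in ages], sexes=[str(s) for s in sexes])
    male_mask = sexes == "male"

    for pos in info_pos:
        probe = _plant(rng, config, probe_ids[int(pos)], target_sex=None)
        mean = probe.intercept + probe.slope * ages
        values[pos] = mean + rng.normal(0.0, config.noise_sd, size=n)
        truth.informative.append(probe)

    for k, pos in enumerate(gender_pos):
        sex = "male" if k % 2 == 0 else "female"
        probe = _plant(rng, config, probe_ids[int(pos)], target_sex=sex)
        match = male_mask if sex == "male" else ~male_mask
        mean = np.where(
            match,
            probe.intercept + probe.slope * ages + probe.gender_effect,
            probe.intercept + (config.age_min + config.age_max) / 2 * probe.slope,
        )
        values[pos] = mean + rng.normal(0.0, config.noise_sd, size=n)
        truth.gender_specific.append(probe)

    np.clip(values, CLAMP_LO, CLAMP_HI, out=values)

    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values[mask] = np.nan

    annotation = _annotate(rng, probe_ids, set(int(i) for i in planted_pos), config)
    matrix = MethylomeMatrix(probe_ids, sample_ids, values)
    metadata = [
        SampleMetadata(sample_ids[j], float(ages[j]), str(sexes[j])) for j in range(n)
    ]
    return matrix, metadata, annotation, truth


def _plant(
    rng: np.random.Generator, config: SyntheticConfig, probe_id: str, target_sex
) -> PlantedProbe:
    slope = rng.uniform(config.slope_min, config.slope_max)
    if rng.random() < 0.5:
        slope = -slope
    offset = config.gender_effect if target_sex is not None else 0.0
    # keep the noiseless mean (including any sex offset) inside [0.05, 0.95]
    lo_m, hi_m = 0.05, 0.95 - offset
    ends = (slope * config.age_min, slope * config.age_max)
    b0_lo = lo_m - min(ends)
    b0_hi = hi_m - max(ends)
    if b0_hi <= b0_lo:
        raise ValidationError(
            f"slope {slope:.4g} too steep for the age range at probe {probe_id}"
        )
    intercept = rng.uniform(b0_lo, b0_hi)
    return PlantedProbe(probe_id, float(slope), float(intercept), target_sex, offset)


def _baseline(
    rng: np.random.Generator, p: int, n: int, noise_sd: float
) -> np.ndarray:
    """Bimodal age-independent background: per-probe mean near 0.1 or 0.9."""
    low_mode = rng.random(p) < 0.5
    means = np.where(low_mode, rng.beta(8, 72, size=p), rng.beta(72, 8, size=p))
    return means[:, None] + rng.normal(0.0, noise_sd, size=(p, n))


def _annotate(
    rng: np.random.Generator,
    probe_ids: list[str],
    planted: set[int],
    config: SyntheticConfig,
) -> list[FeatureAnnotation]:
    p = len(probe_ids)
    candidates = np.array([i for i in range(p) if i not in planted])
    n_sex = int(round(config.sex_chrom_fraction * p))
    n_sex = min(n_sex, candidates.size)
    sex_pos = set(int(i) for i in rng.choice(candidates, size=n_sex, replace=False))
    annotation = []
    for i, pid in enumerate(probe_ids):
        if i in sex_pos:
            chrom = "X" if rng.random() < 0.5 else "Y"
        else:
            chrom = str(int(rng.integers(1, 23)))
        gene = f"GENE{i % 997}" if rng.random() < 0.6 else None
        annotation.append(FeatureAnnotation(pid, chrom, gene))
    return annotation


def oracle_mad(config: SyntheticConfig) -> float:
    """Noise-limited MAD (years) of the true linear model.

    Each planted probe read at a known age carries Gaussian beta noise, so
    inverting its linear model yields an age estimate with standard
    deviation noise_sd/|slope|.  Combining the ``n_informative``
    independent probes by inverse variance gives residual age noise
    sigma_age = noise_sd / sqrt(sum slope_j^2); with slopes drawn uniformly
    from [slope_min, slope_max] the expected squared slope is
    (lo^2 + lo*hi + hi^2)/3.  The MAD of centred Gaussian error is
    sigma * sqrt(2/pi).
    """
    if config.n_informative < 1:
        raise ValidationError("oracle_mad requires at least one informative probe")
    lo, hi = config.slope_min, config.slope_max
    ms_slope = (lo * lo + lo * hi + hi * hi) / 3.0
    sigma_age = config.noise_sd / sqrt(config.n_informative * ms_slope)
    return sigma_age * sqrt(2.0 / pi)
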