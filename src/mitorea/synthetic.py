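"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator plants, per subject, a haplogroup marker backbone plus
gene-length-proportional Poisson counts of homoplasmic mutations
(group-specific per-gene multipliers let tests create e.g. an ND5
enrichment in the maternal group), heteroplasmic mutations with
minor-allele fractions uniform on [0.2, 0.5], and sub-threshold low-level
variants with fractions uniform on [0.01, 0.15].  Probe intensities follow
a two-level signal model: a channel carrying allele share ``s`` has mean
``mu_lo + (mu_hi - mu_lo) * s``, absent channels sit at the background
``mu_lo``, and every channel gets independent multiplicative lognormal
noise; strands are i.i.d.  qPCR Ct values are generated so that the
``2^(Ct_nDNA - Ct_mtDNA)`` formula recovers the planted copy-number
factor in expectation.

Seeding is hierarchical: a *structure* seed fixes who carries which
variants and a separate *noise* seed fixes the intensity/Ct noise, so
recovery tests can redraw noise while holding the truth ledger fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .arraydata import (
    BASES,
    SENSE,
    ANTISENSE,
    SubjectIntensities,
    SubjectMeta,
    IntensityRecord,
    write_intensities,
    write_metadata,
)
from .cohortstats import load_marker_table
from .reference import BASE_INDEX, ReferenceGenome, load_reference

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass
class SimConfig:
    """Study-condition parameters for a simulated cohort.

    Default rates give roughly 25-30 homoplasmic and a handful of
    heteroplasmic mutations per subject, matching the per-subject burden
    scale of blood resequencing-array cohorts.
    """

    groups: dict[str, int] = field(
        default_factory=lambda: {"CTRL": 10, "non-maternal": 10, "maternal": 10}
    )
    sample_type: str = "WB"
    structure_seed: int = 0
    noise_seed: int = 1

    haplogroup_probs: dict[str, float] = field(
        default_factory=lambda: {"H": 0.50, "J": 0.15, "T": 0.12, "U": 0.12,
                                 "K": 0.11}
    )
    hom_rate_per_kb: float = 1.5
    hom_gene_multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    het_rate_per_kb: float = 0.2
    het_gene_multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    het_fraction_range: tuple[float, float] = (0.2, 0.5)
    lowlevel_rate: float = 0.001
    lowlevel_fraction_range: tuple[float, float] = (0.01, 0.15)
    ts_tv_odds: float = 10.0  # transition : transversion odds per variant

    mu_hi: float = 1000.0
    mu_lo: float = 50.0
    sigma: float = 0.1  # sd of the multiplicative lognormal noise (natural log)

    ct_baseline_b2m: float = 25.0
    ct_sd: float = 0.15
    cn_factor: float = 150.0
    cn_group_multipliers: dict[str, float] = field(default_factory=dict)
    n_ct_replicates: int = 3
    covariate_missing_prob: float = 0.2

    def __post_init__(self) -> None:
        for name in ("hom_rate_per_kb", "het_rate_per_kb", "lowlevel_rate",
                     "sigma", "ts_tv_odds"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (self.mu_hi > self.mu_lo > 0):
            raise ConfigError("need mu_hi > mu_lo > 0")
        lo, hi = self.het_fraction_range
        if not (0.2 <= lo <= hi <= 0.5):
            raise ConfigError("het fractions must stay inside [0.2, 0.5]")
        llo, lhi = self.lowlevel_fraction_range
        if not (0 < llo <= lhi < 0.2):
            raise ConfigError("low-level fractions must stay inside (0, 0.2)")
        if abs(sum(self.haplogroup_probs.values()) - 1.0) > 1e-6:
            raise ConfigError("haplogroup probabilities must sum to 1")
        if any(n < 0 for n in self.groups.values()):
            raise ConfigError("group sizes must be >= 0")


@dataclass(frozen=True)
class PlantedVariant:
    position: int
    mutation_class: str  # homoplasmic | heteroplasmic | low-level
    alt: str
    fraction: float | None  # non-reference allele fraction; None if homoplasmic


@dataclass
class SubjectTruth:
    subject_id: str
    group: str
    sample_type: str
    haplogroup: str
    variants: list[PlantedVariant]
    cn_factor: float

    def positions(self) -> set[int]:
        return {v.position for v in self.variants}

    def count(self, mutation_class: str) -> int:
        return sum(v.mutation_class == mutation_class for v in self.variants)


@dataclass
class SyntheticTruth:
    subjects: list[SubjectTruth]

    def validate(self, genome: ReferenceGenome) -> None:
        callable_set = set(genome.callable_positions.tolist())
        for s in self.subjects:
            pos = [v.position for v in s.variants]
            if len(pos) != len(set(pos)):
                raise ConfigError(f"{s.subject_id}: duplicate planted positions")
            if not set(pos) <= callable_set:
                raise ConfigError(f"{s.subject_id}: planted variant off the array")
            for v in s.variants:
                if v.mutation_class == "heteroplasmic" and not (
                        0.2 <= v.fraction <= 0.5):
                    raise ConfigError(f"{s.subject_id}: het fraction {v.fraction}")
                if v.mutation_class == "low-level" and not (
                        0 < v.fraction < 0.2):
                    raise ConfigError(
                        f"{s.subject_id}: low-level fraction {v.fraction}")

    def by_subject(self) -> dict[str, SubjectTruth]:
        return {s.subject_id: s for s in self.subjects}


@dataclass
class CohortData:
    meta: list[SubjectMeta]
    intensities: dict[str, SubjectIntensities]
    truth: SyntheticTruth
    config: SimConfig

    def grouping(self) -> dict[str, str]:
        return {m.subject_id: m.group for m in self.meta}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_metadata(self.meta, outdir / "metadata.tsv")
        for sid, sub in self.intensities.items():
            write_intensities(sub, outdir / f"{sid}.intensities.tsv")
        write_truth(self.truth, outdir / "truth.tsv")


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    lines = ["subject_id\tgroup\thaplogroup\tposition\tclass\talt\tfraction"
             "\tcn_factor"]
    for s in truth.subjects:
        for v in s.variants:
            frac = "" if v.fraction is None else f"{v.fraction:.6g}"
            lines.append(
                f"{s.subject_id}\t{s.group}\t{s.haplogroup}\t{v.position}\t"
                f"{v.mutation_class}\t{v.alt}\t{frac}\t{s.cn_factor:.6g}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _draw_alt(ref: str, rng: np.random.Generator, ts_tv_odds: float) -> str:
    if rng.random() < ts_tv_odds / (ts_tv_odds + 1):
        return _TRANSITION[ref]
    tv = [b for b in BASES if b != ref and b != _TRANSITION[ref]]
    return tv[int(rng.integers(len(tv)))]


def _gene_callable(genome: ReferenceGenome) -> dict[str, np.ndarray]:
    callable_pos = genome.callable_positions
    out = {}
    for g in genome.genes:
        mask = np.zeros(callable_pos.size, dtype=bool)
        for start, end in g.arcs:
            mask |= (callable_pos >= start) & (callable_pos <= end)
        out[g.name] = callable_pos[mask]
    return out


def _simulate_structure(
    config: SimConfig, genome: ReferenceGenome
) -> SyntheticTruth:
    markers = load_marker_table()
    gene_pos = _gene_callable(genome)
    callable_pos = genome.callable_positions
    hg_names = list(config.haplogroup_probs)
    hg_p = np.array([config.haplogroup_probs[h] for h in hg_names])

    subjects = []
    idx = 0
    prefix = {"CTRL": "C", "non-maternal": "N", "maternal": "M"}
    for group, n in config.groups.items():
        for k in range(n):
            rng = np.random.default_rng([config.structure_seed, idx])
            sid = f"{prefix.get(group, group[:1])}{k + 1:03d}"
            hg = hg_names[int(rng.choice(len(hg_names), p=hg_p))]

            used: set[int] = set()
            variants: list[PlantedVariant] = []
            # a label absent from the marker table (e.g. "rCRS") plants no
            # backbone variants
            for pos, alt in markers.get(hg, []):
                if pos in set(callable_pos.tolist()) and pos not in used:
                    used.add(pos)
                    variants.append(PlantedVariant(pos, "homoplasmic", alt, None))

            hom_mult = config.hom_gene_multipliers.get(group, {})
            het_mult = config.het_gene_multipliers.get(group, {})
            for cls, base_rate, mults, frange in (
                ("homoplasmic", config.hom_rate_per_kb, hom_mult, None),
                ("heteroplasmic", config.het_rate_per_kb, het_mult,
                 config.het_fraction_range),
            ):
                for gname, positions in gene_pos.items():
                    lam = base_rate * positions.size / 1000.0 * mults.get(gname, 1.0)
                    count = int(rng.poisson(lam))
                    if count == 0:
                        continue
                    free = positions[~np.isin(positions, list(used))]
                    if free.size < count:
                        raise ConfigError(
                            f"{sid}: more planted variants than free positions "
                            f"in {gname}"
                        )
                    chosen = rng.choice(free, size=count, replace=False)
                    for pos in np.sort(chosen):
                        pos = int(pos)
                        used.add(pos)
                        ref = genome.base_at(pos)
                        alt = _draw_alt(ref, rng, config.ts_tv_odds)
                        frac = (None if frange is None
                                else float(rng.uniform(*frange)))
                        variants.append(PlantedVariant(pos, cls, alt, frac))

            if config.lowlevel_rate > 0:
                mask = rng.random(callable_pos.size) < config.lowlevel_rate
                for pos in callable_pos[mask]:
                    pos = int(pos)
                    if pos in used:
                        continue
                    used.add(pos)
                    ref = genome.base_at(pos)
                    alt = _draw_alt(ref, rng, config.ts_tv_odds)
                    frac = float(rng.uniform(*config.lowlevel_fraction_range))
                    variants.append(PlantedVariant(pos, "low-level", alt, frac))

            cn = config.cn_factor * config.cn_group_multipliers.get(group, 1.0)
            subjects.append(SubjectTruth(sid, group, config.sample_type, hg,
                                         variants, cn))
            idx += 1
    truth = SyntheticTruth(subjects)
    truth.validate(genome)
    return truth


def _channel_means(
    config: SimConfig,
    genome: ReferenceGenome,
    truth: SubjectTruth,
) -> np.ndarray:
    """(n_callable, 4) expected channel intensities in sense-base space."""
    callable_pos = genome.callable_positions
    n = callable_pos.size
    share = np.zeros((n, 4))
    ref_idx = np.array([BASE_INDEX[genome.base_at(int(p))] for p in callable_pos])
    share[np.arange(n), ref_idx] = 1.0
    pos_index = {int(p): i for i, p in enumerate(callable_pos)}
    for v in truth.variants:
        i = pos_index[v.position]
        share[i, :] = 0.0
        alt_i = BASE_INDEX[v.alt]
        if v.mutation_class == "homoplasmic":
            share[i, alt_i] = 1.0
        else:
            share[i, alt_i] = v.fraction
            share[i, ref_idx[i]] = 1.0 - v.fraction
    return config.mu_lo + (config.mu_hi - config.mu_lo) * share


def simulate_subject_intensities(
    config: SimConfig,
    genome: ReferenceGenome,
    truth: SubjectTruth,
    rng: np.random.Generator,
) -> SubjectIntensities:
    means = _channel_means(config, genome, truth)  # (n, 4)
    n = means.shape[0]
    noise = np.exp(config.sigma * rng.standard_normal((n, 2, 4)))
    values = means[:, None, :] * noise
    return SubjectIntensities(
        subject_id=truth.subject_id,
        sample_type=truth.sample_type,
        positions=genome.callable_positions,
        values=values,
    )


def simulate_position(
    genotype: Sequence[str],
    fraction: float | None,
    config: SimConfig,
    rng: np.random.Generator,
    position: int = 1,
) -> tuple[IntensityRecord, IntensityRecord]:
    """Simulate the eight channels of one position (both strands i.i.d.).

    ``genotype`` has one or two bases; ``fraction`` is the minor-allele
    share and must be given exactly when the genotype is a pair.
    """
    genotype = tuple(genotype)
    if len(genotype) not in (1, 2) or any(b not in BASES for b in genotype):
        raise ValueError(f"genotype must be 1-2 bases from {BASES}")
    share = np.zeros(4)
    if len(genotype) == 1:
        if fraction is not None:
            raise ValueError("fraction must be None for a single-allele genotype")
        share[BASE_INDEX[genotype[0]]] = 1.0
    else:
        if fraction is None or not (0 < fraction <= 0.5):
            raise ValueError("a two-allele genotype needs a fraction in (0, 0.5]")
        major, minor = genotype
        share[BASE_INDEX[major]] = 1.0 - fraction
        share[BASE_INDEX[minor]] = fraction
    means = config.mu_lo + (config.mu_hi - config.mu_lo) * share
    noise = np.exp(config.sigma * rng.standard_normal((2, 4)))
    vals = means[None, :] * noise
    sense = IntensityRecord(position, SENSE, dict(zip(BASES, vals[0].tolist())))
    anti = IntensityRecord(position, ANTISENSE, dict(zip(BASES, vals[1].tolist())))
    return sense, anti


def _simulate_meta(
    config: SimConfig,
    truth: SubjectTruth,
    rng: np.random.Generator,
) -> SubjectMeta:
    is_als = truth.group != "CTRL"
    onset = "unknown"
    alsfrs = age = duration = None
    if is_als:
        onset = "bulbar" if rng.random() < 0.3 else "spinal"
        if rng.random() > config.covariate_missing_prob:
            alsfrs = float(np.round(max(0.05, rng.normal(0.9, 0.4)), 3))
        if rng.random() > config.covariate_missing_prob:
            age = float(np.round(rng.normal(60, 10), 1))
        if rng.random() > config.covariate_missing_prob:
            duration = float(np.round(max(1.0, rng.normal(24, 10)), 1))

    reps = config.n_ct_replicates
    ct_dloop_center = config.ct_baseline_b2m - np.log2(truth.cn_factor)
    ct_dloop = tuple(
        float(np.round(ct_dloop_center + rng.normal(0, config.ct_sd), 4))
        for _ in range(reps)
    )
    if config.sample_type == "PLT":
        ct_b2m = None  # platelets carry no nuclear DNA
    else:
        ct_b2m = tuple(
            float(np.round(config.ct_baseline_b2m + rng.normal(0, config.ct_sd), 4))
            for _ in range(reps)
        )
    return SubjectMeta(
        subject_id=truth.subject_id,
        group=truth.group,
        sample_type=truth.sample_type,
        onset_site=onset,
        alsfrs_decline_per_month=alsfrs,
        age_at_onset=age,
        disease_duration=duration,
        ct_b2m=ct_b2m,
        ct_dloop=ct_dloop,
    )


def simulate_cohort(
    config: SimConfig,
    genome: ReferenceGenome | None = None,
) -> CohortData:
    """Generate a full cohort: metadata, intensities and the truth ledger.

    Fully reproducible: the structure seed fixes the planted variants and
    group structure, the noise seed fixes intensity/Ct noise.
    """
    genome = genome or load_reference()
    truth = _simulate_structure(config, genome)
    meta = []
    intensities = {}
    for i, st in enumerate(truth.subjects):
        rng_noise = np.random.default_rng([config.noise_seed, i])
        intensities[st.subject_id] = simulate_subject_intensities(
            config, genome, st, rng_noise
        )
        meta.append(_simulate_meta(config, st, rng_noise))
    return CohortData(meta=meta, intensities=intensities, truth=truth,
                      config=config)
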