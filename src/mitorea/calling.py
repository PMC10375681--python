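"""Diploid-model base calling from eight-channel probe intensities.

Each interrogated position yields eight fluorescence values (2 strands x 4
bases, indexed in sense-base space).  The caller scores ten genotype
hypotheses — four single-base models and six unordered base pairs — with a
two-level template on the log10 intensities: channels of present alleles
share a fitted level ``mu_hi``, absent channels share ``mu_lo`` (both by
least squares, per position per model).  The model log-score is
``-RSS / (2 sigma^2)`` with a noise scale pooled per subject, and the call
quality is the log10-scale score gap between the best and second-best
model.  Positions whose quality falls below the threshold (default 3, the
value used for resequencing-array analysis) become no-calls.

Calls against the reference are classified as:

* ``reference`` — best model is the single reference base;
* ``homoplasmic`` — best model is a single non-reference base;
* ``heteroplasmic`` — best model is a base pair whose minor-allele
  fraction lies in the detectable range, by default 20-50% (fractions
  above 50% are impossible by the minor-allele definition);
* below 20% the pair collapses to the major allele's single-base state:
  that low-level regime is deliberately not a call class and is assessed
  by the REA index instead (:mod:`mitorea.rea`).

The exact likelihood of the vendor's resequencing algorithm is
unpublished; this two-level template caller is a fully specified surrogate
reproducing its documented behaviour (diploid heteroplasmy detection,
quality-threshold no-calls).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .arraydata import BASES, IntensityRecord, SubjectIntensities
from .reference import BASE_INDEX, ReferenceGenome

logger = logging.getLogger(__name__)

REFERENCE, HOMOPLASMIC, HETEROPLASMIC, NO_CALL = (
    "reference", "homoplasmic", "heteroplasmic", "no-call",
)

# model order is the deterministic tie-break: singles first, then pairs
MODELS: tuple[tuple[str, ...], ...] = tuple(
    [(b,) for b in BASES] + [tuple(p) for p in combinations(BASES, 2)]
)
_N_MODELS = len(MODELS)

# (10, 8) present-channel masks over [sense A,C,G,T, antisense A,C,G,T]
_MASKS = np.zeros((_N_MODELS, 8), dtype=bool)
for _m, _alleles in enumerate(MODELS):
    for _b in _alleles:
        _MASKS[_m, BASE_INDEX[_b]] = True
        _MASKS[_m, 4 + BASE_INDEX[_b]] = True

_LN10 = np.log(10.0)

#: default noise scale (sd of log10-intensity residuals) for single-position
#: fits outside a subject context; per-subject calling pools its own estimate
DEFAULT_SIGMA = 0.05
_SIGMA_FLOOR = 0.01


class DegenerateInputError(ValueError):
    """Raised when intensities carry no usable signal (e.g. all zero)."""


@dataclass
class CallParams:
    """Tunable calling parameters; defaults mirror the published settings."""

    quality_threshold: float = 3.0
    het_range: tuple[float, float] = (0.2, 0.5)
    intensity_floor: float = 1.0  # arbitrary units, applied before logs
    sigma: float | None = None  # None -> pooled per subject


@dataclass
class ModelFit:
    """Scores of the ten genotype hypotheses at one position."""

    position: int
    rss: dict[tuple[str, ...], float]
    scores: dict[tuple[str, ...], float]
    best_model: tuple[str, ...]
    second_model: tuple[str, ...]
    quality: float
    sense: IntensityRecord
    antisense: IntensityRecord


@dataclass(frozen=True)
class BaseCall:
    position: int
    state: str
    called_alleles: tuple[str, ...]
    minor_fraction: float | None
    quality: float


_STATE_CODES = (REFERENCE, HOMOPLASMIC, HETEROPLASMIC, NO_CALL)


class CallSet:
    """One call per callable position for a subject, array-backed."""

    def __init__(
        self,
        subject_id: str,
        positions: np.ndarray,
        states: np.ndarray,
        allele1: np.ndarray,
        allele2: np.ndarray,
        minor_fraction: np.ndarray,
        quality: np.ndarray,
    ) -> None:
        self.subject_id = subject_id
        self.positions = positions
        self.states = states
        self.allele1 = allele1
        self.allele2 = allele2
        self.minor_fraction = minor_fraction
        self.quality = quality
        self.n_homoplasmic = int(np.sum(states == 1))
        self.n_heteroplasmic = int(np.sum(states == 2))

    def __len__(self) -> int:
        return self.positions.size

    def recount(self) -> tuple[int, int]:
        return int(np.sum(self.states == 1)), int(np.sum(self.states == 2))

    def call_at(self, position: int) -> BaseCall:
        i = int(np.searchsorted(self.positions, position))
        if i >= len(self.positions) or self.positions[i] != position:
            raise KeyError(f"np {position} is not a callable position")
        return self._call(i)

    def _call(self, i: int) -> BaseCall:
        alleles = tuple(
            BASES[a] for a in (self.allele1[i], self.allele2[i]) if a >= 0
        )
        mf = self.minor_fraction[i]
        return BaseCall(
            position=int(self.positions[i]),
            state=_STATE_CODES[self.states[i]],
            called_alleles=alleles,
            minor_fraction=None if np.isnan(mf) else float(mf),
            quality=float(self.quality[i]),
        )

    def calls(self) -> list[BaseCall]:
        return [self._call(i) for i in range(len(self))]

    def variants(self, state: str) -> list[BaseCall]:
        """Calls of a mutation class ('homoplasmic' or 'heteroplasmic')."""
        code = _STATE_CODES.index(state)
        return [self._call(i) for i in np.nonzero(self.states == code)[0]]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CallSet)
            and self.subject_id == other.subject_id
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.states, other.states)
            and np.array_equal(self.allele1, other.allele1)
            and np.array_equal(self.allele2, other.allele2)
            and np.array_equal(self.minor_fraction, other.minor_fraction,
                               equal_nan=True)
            and np.array_equal(self.quality, other.quality)
        )


def _log_channels(sense: IntensityRecord, antisense: IntensityRecord,
                  floor: float) -> np.ndarray:
    x = np.concatenate([sense.as_array(), antisense.as_array()])
    if np.all(x == 0):
        raise DegenerateInputError(
            f"np {sense.position}: all eight intensities are zero"
        )
    return np.log10(np.maximum(x, floor))


def _rss_all_models(x8: np.ndarray) -> np.ndarray:
    """RSS of the two-level template for all 10 models; x8 is (n, 8) log10.

    The fit is constrained to ``mu_hi >= mu_lo`` (present alleles cannot be
    dimmer than absent ones); when the unconstrained levels invert, the
    constrained least-squares solution collapses both to the grand mean.
    Without the constraint a pair model and its complementary pair would
    partition the channels identically and be indistinguishable.
    """
    n = x8.shape[0]
    rss = np.empty((n, _N_MODELS))
    grand = x8.mean(axis=1, keepdims=True)
    total_ss = ((x8 - grand) ** 2).sum(axis=1)
    for m in range(_N_MODELS):
        hi = x8[:, _MASKS[m]]
        lo = x8[:, ~_MASKS[m]]
        hi_mean = hi.mean(axis=1)
        lo_mean = lo.mean(axis=1)
        free = (
            ((hi - hi_mean[:, None]) ** 2).sum(axis=1)
            + ((lo - lo_mean[:, None]) ** 2).sum(axis=1)
        )
        rss[:, m] = np.where(hi_mean >= lo_mean, free, total_ss)
    return rss


def fit_genotype(
    sense: IntensityRecord,
    antisense: IntensityRecord,
    sigma: float = DEFAULT_SIGMA,
    intensity_floor: float = 1.0,
) -> ModelFit:
    """Score all ten genotype models at one position.

    ``sigma`` is the assumed sd of log10-intensity residuals; within
    :func:`call_subject` it is instead pooled across the subject's
    positions.
    """
    if sense.position != antisense.position:
        raise ValueError("sense/antisense records are for different positions")
    x8 = _log_channels(sense, antisense, intensity_floor)[None, :]
    rss = _rss_all_models(x8)[0]
    order = np.argsort(rss, kind="stable")
    best, second = int(order[0]), int(order[1])
    sigma = max(sigma, _SIGMA_FLOOR)
    scores = -rss / (2 * sigma**2)
    quality = float((rss[second] - rss[best]) / (2 * sigma**2 * _LN10))
    return ModelFit(
        position=sense.position,
        rss={MODELS[m]: float(rss[m]) for m in range(_N_MODELS)},
        scores={MODELS[m]: float(scores[m]) for m in range(_N_MODELS)},
        best_model=MODELS[best],
        second_model=MODELS[second],
        quality=quality,
        sense=sense,
        antisense=antisense,
    )


def _background_subtracted(sense: np.ndarray, antisense: np.ndarray) -> np.ndarray:
    """Per-channel strand-averaged intensities after background subtraction.

    Background per strand = mean of that strand's two lowest channels,
    floored at zero after subtraction (a simple deterministic
    cross-hybridisation correction).
    """
    out = np.zeros(4)
    for strand in (sense, antisense):
        bg = np.mean(np.sort(strand)[:2])
        out += np.maximum(strand - bg, 0.0)
    return out / 2.0


def minor_allele_fraction(
    sense: IntensityRecord,
    antisense: IntensityRecord,
    pair: Sequence[str],
) -> float:
    """Minor-allele fraction of a base pair, in [0, 0.5] by construction.

    ``f = I_minor / (I_major + I_minor)`` on background-subtracted,
    strand-averaged channel intensities.
    """
    a, b = pair
    if a == b:
        raise ValueError("pair must contain two distinct bases")
    chan = _background_subtracted(sense.as_array(), antisense.as_array())
    ia, ib = chan[BASE_INDEX[a]], chan[BASE_INDEX[b]]
    denom = ia + ib
    if denom <= 0:
        raise DegenerateInputError(
            f"np {sense.position}: no signal left in {a}/{b} channels "
            "after background subtraction"
        )
    return float(min(ia, ib) / denom)


def call_position(
    fit: ModelFit,
    ref_base: str,
    quality_threshold: float = 3.0,
    het_range: tuple[float, float] = (0.2, 0.5),
) -> BaseCall:
    """Classify one position from its model fit.

    Below-threshold quality gives a no-call; a winning pair model whose
    minor fraction falls below the heteroplasmy range collapses to the
    major allele's single-base state (the low-level regime is left to the
    REA index).
    """
    if ref_base not in BASES:
        raise ValueError(
            f"np {fit.position}: reference base {ref_base!r} — the position "
            "should already be excluded from calling"
        )
    if fit.quality < quality_threshold:
        return BaseCall(fit.position, NO_CALL, (), None, fit.quality)
    best = fit.best_model
    if len(best) == 1:
        state = REFERENCE if best[0] == ref_base else HOMOPLASMIC
        return BaseCall(fit.position, state, best, None, fit.quality)

    f = minor_allele_fraction(fit.sense, fit.antisense, best)
    chan = _background_subtracted(fit.sense.as_array(), fit.antisense.as_array())
    major, minor = sorted(best, key=lambda b: -chan[BASE_INDEX[b]])
    lo, hi = het_range
    eps = 1e-9
    if lo - eps <= f <= hi + eps:
        return BaseCall(fit.position, HETEROPLASMIC, (major, minor),
                        min(f, 0.5), fit.quality)
    # low-level regime: collapse to the major allele
    state = REFERENCE if major == ref_base else HOMOPLASMIC
    return BaseCall(fit.position, state, (major,), None, fit.quality)


def call_subject(
    intensities: SubjectIntensities,
    genome: ReferenceGenome,
    params: CallParams | None = None,
) -> CallSet:
    """Call every callable position of a subject (deterministic).

    The noise scale is pooled across the subject's best-model residuals
    unless ``params.sigma`` overrides it.  Per-position degeneracies are
    downgraded to no-calls with a logged warning rather than aborting the
    subject.
    """
    params = params or CallParams()
    intensities.validate_against(genome)
    n = intensities.positions.size

    x = np.maximum(intensities.values, params.intensity_floor)
    x8 = np.log10(x).reshape(n, 8)
    degenerate = np.all(intensities.values == 0, axis=(1, 2))

    rss = _rss_all_models(x8)
    order = np.argsort(rss, axis=1, kind="stable")
    best = order[:, 0]
    second = order[:, 1]
    rss_best = rss[np.arange(n), best]
    rss_second = rss[np.arange(n), second]

    if params.sigma is not None:
        sigma = max(params.sigma, _SIGMA_FLOOR)
    else:
        sigma = max(np.sqrt(rss_best.sum() / (6 * n)), _SIGMA_FLOOR)
    quality = (rss_second - rss_best) / (2 * sigma**2 * _LN10)
    quality[degenerate] = 0.0
    if degenerate.any():
        logger.warning(
            "subject %s: %d all-zero positions downgraded to no-call",
            intensities.subject_id, int(degenerate.sum()),
        )

    ref_idx = np.array(
        [BASE_INDEX[genome.base_at(int(p))] for p in intensities.positions]
    )
    states = np.zeros(n, dtype=np.int8)
    allele1 = np.full(n, -1, dtype=np.int8)
    allele2 = np.full(n, -1, dtype=np.int8)
    fractions = np.full(n, np.nan)

    no_call = (quality < params.quality_threshold) | degenerate
    states[no_call] = 3

    is_single = best < 4
    ok = ~no_call
    single_ok = ok & is_single
    allele1[single_ok] = best[single_ok]
    states[single_ok & (best != ref_idx)] = 1  # homoplasmic
    # single_ok & best == ref stays 0 (reference)

    lo, hi = params.het_range
    eps = 1e-9
    for i in np.nonzero(ok & ~is_single)[0]:
        pair = MODELS[best[i]]
        try:
            chan = _background_subtracted(
                intensities.values[i, 0], intensities.values[i, 1]
            )
            a, b = pair
            ia, ib = chan[BASE_INDEX[a]], chan[BASE_INDEX[b]]
            if ia + ib <= 0:
                raise DegenerateInputError("no signal after background subtraction")
            f = min(ia, ib) / (ia + ib)
        except DegenerateInputError as exc:
            logger.warning("subject %s np %d: %s -> no-call",
                           intensities.subject_id, intensities.positions[i], exc)
            states[i] = 3
            continue
        major_i, minor_i = sorted((BASE_INDEX[a], BASE_INDEX[b]),
                                  key=lambda k: -chan[k])
        if lo - eps <= f <= hi + eps:
            states[i] = 2
            allele1[i], allele2[i] = major_i, minor_i
            fractions[i] = min(f, 0.5)
        else:
            allele1[i] = major_i
            if major_i != ref_idx[i]:
                states[i] = 1

    return CallSet(
        subject_id=intensities.subject_id,
        positions=intensities.positions.copy(),
        states=states,
        allele1=allele1,
        allele2=allele2,
        minor_fraction=fractions,
        quality=quality,
    )


def write_snp_view(callset: CallSet, path: str | Path) -> None:
    """Export calls as a 'SNP view' TSV (position, state, alleles, fraction, quality)."""
    rows = {
        "position": callset.positions,
        "state": [_STATE_CODES[s] for s in callset.states],
        "alleles": [
            "".join(BASES[a] for a in (a1, a2) if a >= 0)
            for a1, a2 in zip(callset.allele1, callset.allele2)
        ],
        "minor_fraction": callset.minor_fraction,
        "quality": callset.quality,
    }
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.4g", lineterminator="\n")


def write_vcf(callset: CallSet, genome: ReferenceGenome, path: str | Path) -> None:
    """Export non-reference calls as minimal VCF v4.2 on contig chrM.

    Heteroplasmic calls carry the non-reference allele fraction in the AF
    info field; homoplasmic calls have AF=1.
    """
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chrM,length=16569>",
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Non-reference allele fraction">',
        '##INFO=<ID=HET,Number=0,Type=Flag,Description="Heteroplasmic call">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for call in callset.calls():
        if call.state not in (HOMOPLASMIC, HETEROPLASMIC):
            continue
        ref = genome.base_at(call.position)
        alts = [b for b in call.called_alleles if b != ref]
        if not alts:
            continue
        if call.state == HOMOPLASMIC:
            afs, info_extra = ["1"], ""
        else:
            afs = []
            for b in alts:
                # minor allele carries minor_fraction, major the complement
                is_minor = b == call.called_alleles[-1]
                af = call.minor_fraction if is_minor else 1 - call.minor_fraction
                afs.append(f"{af:.4g}")
            info_extra = ";HET"
        lines.append(
            f"chrM\t{call.position}\t.\t{ref}\t{','.join(alts)}\t"
            f"{call.quality:.1f}\tPASS\tAF={','.join(afs)}{info_extra}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
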