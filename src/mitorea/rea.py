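"""REA (Ratio of Expected Allele) index and the genome-wide group scan.

Base calling only reports heteroplasmy down to a 20% minor-allele
fraction.  Below that, low-level heteroplasmy is assessed per position by
the REA index: the log ratio of the reference nucleotide's fluorescence
intensity to the mean intensity of the other three nucleotides, pooled
over both strands.  A high REA means the reference allele dominates; a
planted low-level variant moves fluorescence mass from the reference
channel to an alternate channel and strictly lowers REA at its position.

The group scan compares two groups of subjects position by position: a
Shapiro-Wilk normality gate on each group decides between a two-sample t
test (both normal) and a Mann-Whitney test, with per-position two-sided
p-values thresholded at alpha = 0.001 and no multiple-testing correction
(the fixed per-test threshold is the documented convention for this
analysis).  The logarithm base only rescales REA by a positive constant
and cannot change any scan p-value or direction (t and rank statistics
are scale-invariant); log10 is used for readability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .arraydata import IntensityRecord, SubjectIntensities
from .reference import BASE_INDEX, BASES, ReferenceGenome


class EmptySignificantSetError(ValueError):
    """No significant positions: a direction summary is undefined, not 0."""


@dataclass(frozen=True)
class REAProfile:
    """One REA value per callable position for one subject."""

    subject_id: str
    positions: np.ndarray  # 1-based np, ascending
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.positions.shape:
            raise ValueError("positions/values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("REA values must all be finite")

    def __len__(self) -> int:
        return self.values.size

    def value_at(self, position: int) -> float:
        i = int(np.searchsorted(self.positions, position))
        if i >= self.positions.size or self.positions[i] != position:
            raise KeyError(f"np {position} not in profile")
        return float(self.values[i])


def rea_value(
    sense: IntensityRecord,
    antisense: IntensityRecord,
    ref_base: str,
    intensity_floor: float = 1.0,
    log_base: float = 10.0,
) -> float:
    """REA at one position: log of ref-channel mean over the 6-alternate mean."""
    if ref_base not in BASES:
        raise ValueError(
            f"np {sense.position}: reference base {ref_base!r} — position "
            "should be excluded from the callable set"
        )
    s = np.maximum(sense.as_array(), intensity_floor)
    a = np.maximum(antisense.as_array(), intensity_floor)
    r = BASE_INDEX[ref_base]
    ref_mean = (s[r] + a[r]) / 2.0
    alt_mask = np.arange(4) != r
    alt_mean = (s[alt_mask].sum() + a[alt_mask].sum()) / 6.0
    return float(np.log(ref_mean / alt_mean) / np.log(log_base))


def rea_profile(
    intensities: SubjectIntensities,
    genome: ReferenceGenome,
    intensity_floor: float = 1.0,
    log_base: float = 10.0,
) -> REAProfile:
    """REA at every callable position, regardless of the position's call state."""
    intensities.validate_against(genome)
    x = np.maximum(intensities.values, intensity_floor)  # (n, 2, 4)
    ref_idx = np.array(
        [BASE_INDEX[genome.base_at(int(p))] for p in intensities.positions]
    )
    n = intensities.positions.size
    rows = np.arange(n)
    ref_mean = x[rows, :, ref_idx].mean(axis=1)
    total = x.sum(axis=(1, 2))
    alt_mean = (total - x[rows, 0, ref_idx] - x[rows, 1, ref_idx]) / 6.0
    values = np.log(ref_mean / alt_mean) / np.log(log_base)
    return REAProfile(
        subject_id=intensities.subject_id,
        positions=intensities.positions.copy(),
        values=values,
    )


@dataclass
class ScanResult:
    """Per-position outcome of the two-group REA scan."""

    group_names: tuple[str, str]
    alpha: float
    table: pd.DataFrame  # index np; mean_<g1>, mean_<g2>, normal_gate, test,
    #                      p, direction, significant, degenerate

    @property
    def significant_positions(self) -> np.ndarray:
        return self.table.index[self.table["significant"]].to_numpy()

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def significant_fraction(self) -> float:
        return self.n_significant / len(self.table)


def _stack(profiles: list[REAProfile]) -> tuple[np.ndarray, np.ndarray]:
    positions = profiles[0].positions
    for p in profiles[1:]:
        if not np.array_equal(p.positions, positions):
            raise ValueError("profiles cover different position sets")
    return positions, np.vstack([p.values for p in profiles])


def rea_scan(
    profiles_by_group: dict[str, list[REAProfile]],
    alpha: float = 0.001,
    normality_alpha: float = 0.05,
) -> ScanResult:
    """Position-wise two-group comparison of REA profiles.

    Both groups normal by Shapiro-Wilk (p > ``normality_alpha``) -> Welch t
    test, otherwise Mann-Whitney; two-sided p, flagged significant at
    ``p <= alpha``.  Positions where both groups are constant get p = 1 and
    a degenerate flag.
    """
    if len(profiles_by_group) != 2:
        raise ValueError("the scan compares exactly two groups")
    (g1, p1), (g2, p2) = profiles_by_group.items()
    if len(p1) < 3 or len(p2) < 3:
        raise ValueError("need at least 3 subjects per group")
    positions, x1 = _stack(p1)
    pos2, x2 = _stack(p2)
    if not np.array_equal(positions, pos2):
        raise ValueError("groups cover different position sets")

    n = positions.size
    mean1, mean2 = x1.mean(axis=0), x2.mean(axis=0)
    degenerate = (np.ptp(x1, axis=0) == 0) & (np.ptp(x2, axis=0) == 0)

    normal = np.zeros(n, dtype=bool)
    with np.errstate(all="ignore"):
        for j in range(n):
            if degenerate[j]:
                continue
            # Shapiro-Wilk needs within-group variation
            if np.ptp(x1[:, j]) == 0 or np.ptp(x2[:, j]) == 0:
                continue
            if (stats.shapiro(x1[:, j]).pvalue > normality_alpha
                    and stats.shapiro(x2[:, j]).pvalue > normality_alpha):
                normal[j] = True

    pvals = np.ones(n)
    use_t = normal & ~degenerate
    use_mw = ~normal & ~degenerate
    if use_t.any():
        res = stats.ttest_ind(x1[:, use_t], x2[:, use_t], equal_var=False, axis=0)
        pvals[use_t] = res.pvalue
    if use_mw.any():
        res = stats.mannwhitneyu(
            x1[:, use_mw], x2[:, use_mw], alternative="two-sided",
            method="asymptotic", axis=0,
        )
        pvals[use_mw] = res.pvalue
    pvals = np.nan_to_num(pvals, nan=1.0)

    direction = np.where(mean1 >= mean2, g1, g2)
    table = pd.DataFrame(
        {
            f"mean_{g1}": mean1,
            f"mean_{g2}": mean2,
            "normal_gate": normal,
            "test": np.where(degenerate, "none", np.where(normal, "t", "mannwhitney")),
            "p": pvals,
            "direction": direction,
            "significant": (pvals <= alpha) & ~degenerate,
            "degenerate": degenerate,
        },
        index=pd.Index(positions, name="position"),
    )
    return ScanResult(group_names=(g1, g2), alpha=alpha, table=table)


def direction_summary(result: ScanResult, focus_group: str) -> float:
    """Fraction of significant positions where ``focus_group`` has higher mean REA."""
    if focus_group not in result.group_names:
        raise ValueError(f"{focus_group!r} is not one of {result.group_names}")
    sig = result.table[result.table["significant"]]
    if sig.empty:
        raise EmptySignificantSetError(
            "no significant positions: direction summary is undefined"
        )
    return float((sig["direction"] == focus_group).mean())


def write_scan(result: ScanResult, path) -> None:
    result.table.to_csv(path, sep="\t", float_format="%.6g", lineterminator="\n")
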