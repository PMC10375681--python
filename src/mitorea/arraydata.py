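"""Per-subject probe-intensity data and subject metadata: model and TSV I/O.

The array reports, for every interrogated nucleotide position, four
fluorescence channels (one per base) on each of the two strands — eight
values per position.  On disk the antisense channels are indexed by the
probe base actually hybridised on that strand; at read time they are
re-indexed by the Watson-Crick complement so that in memory *all* channels
are indexed by the base as read on the sense strand.  Every downstream
formula (base calling, minor-allele fraction, REA) is therefore
strand-symmetric and works in a single sense-base space.

Intensity TSV dialect (a minimal surrogate for the vendor "Probe Intensity
File"): one header line ``position  strand  int_A  int_C  int_G  int_T``,
UTF-8, tab-separated, rows ordered by position with sense before antisense.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .reference import BASE_INDEX, BASES, ReferenceGenome

SENSE, ANTISENSE = "sense", "antisense"
STRANDS = (SENSE, ANTISENSE)

GROUPS = ("CTRL", "non-maternal", "maternal")
SAMPLE_TYPES = ("WB", "WBC", "PLT")
ONSET_SITES = ("bulbar", "spinal", "unknown")

# channel permutation taking probe-base indexing to sense-base indexing
# (A<->T, C<->G); it is its own inverse
_COMPLEMENT_PERM = np.array([3, 2, 1, 0])

_INT_COLS = [f"int_{b}" for b in BASES]


class ValidationError(ValueError):
    """Structurally invalid intensity or metadata input."""


@dataclass(frozen=True)
class IntensityRecord:
    """Four fluorescence channels for one (position, strand), sense-base indexed."""

    position: int
    strand: str
    intensities: dict[str, float]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"unknown strand {self.strand!r}")
        if sorted(self.intensities) != list(BASES):
            raise ValidationError(
                f"np {self.position}: need exactly channels {BASES}, "
                f"got {sorted(self.intensities)}"
            )
        for b, v in self.intensities.items():
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"np {self.position} strand {self.strand}: "
                    f"channel {b} intensity {v} not finite and >= 0"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.intensities[b] for b in BASES], dtype=float)


class SubjectIntensities:
    """All probe intensities for one subject, array-backed.

    ``values`` has shape (n_positions, 2, 4): axis 1 is strand
    (0 = sense, 1 = antisense), axis 2 the channel in sense-base order
    A, C, G, T.  One record per (callable position, strand).
    """

    def __init__(
        self,
        subject_id: str,
        sample_type: str,
        positions: Sequence[int] | np.ndarray,
        values: np.ndarray,
    ) -> None:
        if sample_type not in SAMPLE_TYPES:
            raise ValidationError(f"unknown sample type {sample_type!r}")
        positions = np.asarray(positions, dtype=int)
        values = np.asarray(values, dtype=float)
        if positions.ndim != 1 or positions.size == 0:
            raise ValidationError("empty position set")
        if np.any(np.diff(positions) <= 0):
            dup = positions[1:][np.diff(positions) == 0]
            raise ValidationError(
                f"positions must be strictly increasing; duplicates/disorder at "
                f"{np.unique(dup)[:10].tolist() or 'unsorted input'}"
            )
        if values.shape != (positions.size, 2, 4):
            raise ValidationError(
                f"values shape {values.shape} != {(positions.size, 2, 4)}"
            )
        bad = ~np.isfinite(values) | (values < 0)
        if np.any(bad):
            rows = positions[np.unique(np.nonzero(bad)[0])]
            raise ValidationError(
                f"non-finite or negative intensities at np {rows[:10].tolist()}"
            )
        self.subject_id = subject_id
        self.sample_type = sample_type
        self.positions = positions
        self.values = values
        self._pos_index = {int(p): i for i, p in enumerate(positions)}

    @property
    def n_records(self) -> int:
        return self.positions.size * 2

    def record(self, position: int, strand: str) -> IntensityRecord:
        if strand not in STRANDS:
            raise ValidationError(f"unknown strand {strand!r}")
        try:
            i = self._pos_index[int(position)]
        except KeyError:
            raise ValidationError(f"np {position} not present for subject") from None
        row = self.values[i, STRANDS.index(strand)]
        return IntensityRecord(
            position=int(position),
            strand=strand,
            intensities=dict(zip(BASES, row.tolist())),
        )

    def iter_records(self) -> Iterator[IntensityRecord]:
        for p in self.positions:
            yield self.record(int(p), SENSE)
            yield self.record(int(p), ANTISENSE)

    def validate_against(self, genome: ReferenceGenome) -> None:
        """Check this subject covers exactly the genome's callable positions."""
        expected = genome.callable_positions
        if self.positions.size != expected.size or np.any(self.positions != expected):
            missing = np.setdiff1d(expected, self.positions)
            extra = np.setdiff1d(self.positions, expected)
            raise ValidationError(
                f"subject {self.subject_id}: positions do not match the callable "
                f"set (missing {missing[:10].tolist()}, "
                f"unexpected {extra[:10].tolist()})"
            )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SubjectIntensities)
            and self.subject_id == other.subject_id
            and self.sample_type == other.sample_type
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.values, other.values)
        )


def read_intensities(
    path: str | Path,
    subject_id: str | None = None,
    sample_type: str = "WB",
    genome: ReferenceGenome | None = None,
) -> SubjectIntensities:
    """Read one subject's intensity TSV, re-indexing antisense channels.

    If ``genome`` is given the file must cover exactly its callable
    positions; structural problems raise :class:`ValidationError` naming
    the offending rows.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    expected_cols = ["position", "strand", *_INT_COLS]
    if list(df.columns) != expected_cols:
        raise ValidationError(f"{path.name}: columns {list(df.columns)} "
                              f"!= {expected_cols}")
    bad_strand = ~df["strand"].isin(STRANDS)
    if bad_strand.any():
        raise ValidationError(
            f"{path.name}: unknown strand codes "
            f"{df.loc[bad_strand, 'strand'].unique().tolist()}"
        )
    dup = df.duplicated(subset=["position", "strand"])
    if dup.any():
        raise ValidationError(
            f"{path.name}: duplicate (position, strand) rows at np "
            f"{df.loc[dup, 'position'].unique()[:10].tolist()}"
        )
    counts = df.groupby("position")["strand"].count()
    incomplete = counts.index[counts != 2]
    if len(incomplete):
        raise ValidationError(
            f"{path.name}: positions without both strands: "
            f"{incomplete[:10].tolist()}"
        )

    positions = np.sort(df["position"].unique())
    n = positions.size
    pos_idx = {int(p): i for i, p in enumerate(positions)}
    values = np.empty((n, 2, 4), dtype=float)
    for s_i, strand in enumerate(STRANDS):
        sub = df[df["strand"] == strand].sort_values("position")
        vals = sub[_INT_COLS].to_numpy(dtype=float)
        if strand == ANTISENSE:
            vals = vals[:, _COMPLEMENT_PERM]  # probe-base -> sense-base space
        idx = [pos_idx[int(p)] for p in sub["position"]]
        values[idx, s_i, :] = vals

    subject = SubjectIntensities(
        subject_id=subject_id or path.stem,
        sample_type=sample_type,
        positions=positions,
        values=values,
    )
    if genome is not None:
        subject.validate_against(genome)
    return subject


def write_intensities(data: SubjectIntensities, path: str | Path) -> None:
    """Write the intensity TSV deterministically (position asc, sense first)."""
    n = data.positions.size
    rows = np.empty((2 * n, 4), dtype=float)
    sense = data.values[:, 0, :]
    anti = data.values[:, 1, :][:, _COMPLEMENT_PERM]  # back to probe-base space
    rows[0::2] = sense
    rows[1::2] = anti
    df = pd.DataFrame(rows, columns=_INT_COLS)
    df.insert(0, "strand", np.tile(np.array(STRANDS, dtype=object), n))
    df.insert(0, "position", np.repeat(data.positions, 2))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


@dataclass
class SubjectMeta:
    """Group labels, clinical covariates and qPCR Ct triplicates for a subject."""

    subject_id: str
    group: str
    sample_type: str
    onset_site: str = "unknown"
    alsfrs_decline_per_month: float | None = None
    age_at_onset: float | None = None
    disease_duration: float | None = None
    ct_b2m: tuple[float, ...] | None = None
    ct_dloop: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"{self.subject_id}: unknown group {self.group!r}")
        if self.sample_type not in SAMPLE_TYPES:
            raise ValidationError(
                f"{self.subject_id}: unknown sample type {self.sample_type!r}"
            )
        if self.onset_site not in ONSET_SITES:
            raise ValidationError(
                f"{self.subject_id}: unknown onset site {self.onset_site!r}"
            )
        for name in ("ct_b2m", "ct_dloop"):
            ct = getattr(self, name)
            if ct is not None and any(
                not math.isfinite(v) or v <= 0 for v in ct
            ):
                raise ValidationError(f"{self.subject_id}: {name} must be positive")


_META_COLS = [f.name for f in fields(SubjectMeta)]


def _fmt_ct(ct: tuple[float, ...] | None) -> str:
    return "" if ct is None else ",".join(f"{v:.6g}" for v in ct)


def _parse_ct(cell) -> tuple[float, ...] | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return None
    return tuple(float(v) for v in str(cell).split(","))


def read_metadata(path: str | Path) -> list[SubjectMeta]:
    """Read subject metadata TSV; clinical covariates may be missing."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = set(_META_COLS) - set(df.columns)
    if missing:
        raise ValidationError(f"metadata missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for col in _META_COLS:
            v = getattr(row, col)
            if col in ("ct_b2m", "ct_dloop"):
                kwargs[col] = _parse_ct(v)
            elif col in ("alsfrs_decline_per_month", "age_at_onset",
                         "disease_duration"):
                kwargs[col] = None if pd.isna(v) else float(v)
            elif col == "onset_site":
                kwargs[col] = "unknown" if pd.isna(v) else str(v)
            else:
                kwargs[col] = str(v)
        out.append(SubjectMeta(**kwargs))
    return out


def write_metadata(meta: Sequence[SubjectMeta], path: str | Path) -> None:
    rows = []
    for m in meta:
        row = {c: getattr(m, c) for c in _META_COLS}
        row["ct_b2m"] = _fmt_ct(m.ct_b2m)
        row["ct_dloop"] = _fmt_ct(m.ct_dloop)
        rows.append(row)
    pd.DataFrame(rows, columns=_META_COLS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
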