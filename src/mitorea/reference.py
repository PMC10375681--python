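"""Mitochondrial reference model: sequence, circularity, gene annotation.

All coordinates on the public interface are 1-based inclusive nucleotide
positions (np) on the 16,569-base revised Cambridge Reference Sequence
frame, matching standard mtDNA variant nomenclature.  The packaged FASTA is
a synthetic rCRS-equivalent (same length, 'N' placeholder at np 3107,
realistic base composition); the gene annotation table is the standard
rCRS feature set (13 protein-coding genes, 22 tRNAs, 2 rRNAs and the
control region / D-loop, represented as a single feature with two arcs
joined across the origin).

Of the 16,569 positions, 25 are not interrogated by the resequencing
array, leaving 16,544 callable positions.  The packaged exclusion list is
a documented surrogate (the array design file is not public) and can be
replaced per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

MT_LENGTH = 16_569
N_CALLABLE = 16_544

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class ReferenceError(Exception):
    """Raised for corrupt fixtures or out-of-range coordinates."""


def complement(base: str) -> str:
    """Watson-Crick complement of a single base (an involution on {A,C,G,T})."""
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise ReferenceError(f"cannot complement non-ACGT base {base!r}") from None


@dataclass(frozen=True)
class GeneInterval:
    """An annotated mtDNA feature; two arcs only for the origin-spanning D-loop."""

    name: str
    arcs: tuple[tuple[int, int], ...]  # 1-based inclusive (start, end) per arc
    feature_class: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.arcs:
            raise ReferenceError(f"gene {self.name} has no arcs")
        for start, end in self.arcs:
            if not (1 <= start <= end <= MT_LENGTH):
                raise ReferenceError(
                    f"gene {self.name} arc ({start},{end}) outside [1,{MT_LENGTH}]"
                )

    def contains(self, position: int) -> bool:
        return any(start <= position <= end for start, end in self.arcs)

    @property
    def length(self) -> int:
        return sum(end - start + 1 for start, end in self.arcs)


@dataclass(frozen=True)
class ReferenceGenome:
    """The circular mitochondrial reference plus array-callability metadata."""

    sequence: str
    genes: tuple[GeneInterval, ...]
    excluded_positions: frozenset[int]
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) != MT_LENGTH:
            raise ReferenceError(
                f"reference length {len(self.sequence)} != {MT_LENGTH}"
            )
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ReferenceError(f"non-ACGTN characters in reference: {bad}")
        n_pos = {i + 1 for i, b in enumerate(self.sequence) if b == "N"}
        if not n_pos <= self.excluded_positions:
            raise ReferenceError("every 'N' position must be excluded from calling")
        if not all(1 <= p <= MT_LENGTH for p in self.excluded_positions):
            raise ReferenceError("excluded position outside [1, 16569]")

    @property
    def length(self) -> int:
        return MT_LENGTH

    @property
    def callable_positions(self) -> np.ndarray:
        """Sorted 1-based positions interrogated by the array."""
        mask = np.ones(MT_LENGTH, dtype=bool)
        mask[[p - 1 for p in self.excluded_positions]] = False
        return np.nonzero(mask)[0] + 1

    @property
    def n_callable(self) -> int:
        return MT_LENGTH - len(self.excluded_positions)

    def base_at(self, position: int) -> str:
        _check_position(position)
        return self.sequence[position - 1]

    def gene_by_name(self, name: str) -> GeneInterval:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]


def _check_position(position: int) -> None:
    if not 1 <= int(position) <= MT_LENGTH:
        raise ReferenceError(f"position {position} outside [1, {MT_LENGTH}]")


def gene_at(genome: ReferenceGenome, position: int) -> list[str]:
    """Names of every annotated feature whose arcs contain ``position``.

    Returns [] for intergenic positions and may return two names in overlap
    regions (e.g. ATP8/ATP6); a mutation at an overlap position is attributed
    to every overlapping feature.
    """
    _check_position(position)
    return [g.name for g in genome.genes if g.contains(position)]


def base_composition(genome: ReferenceGenome) -> dict[str, int]:
    """Counts of A/C/G/T (and N) in the reference; they partition its length."""
    return {b: genome.sequence.count(b) for b in ("A", "C", "G", "T", "N")}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("mitorea").joinpath("data", name)))


def _read_excluded(path: Path) -> frozenset[int]:
    out = set()
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.add(int(line))
    return frozenset(out)


def _read_genes(path: Path) -> tuple[GeneInterval, ...]:
    arcs: dict[str, list[tuple[int, int]]] = {}
    cls: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().split()
        if header != ["name", "start", "end", "feature_class"]:
            raise ReferenceError(f"unexpected gene table header {header}")
        for line in fh:
            name, start, end, fclass = line.split()
            arcs.setdefault(name, []).append((int(start), int(end)))
            cls[name] = fclass
    return tuple(
        GeneInterval(name=n, arcs=tuple(a), feature_class=cls[n])
        for n, a in arcs.items()
    )


def load_reference(
    fasta: str | Path | None = None,
    genes: str | Path | None = None,
    excluded: Iterable[int] | str | Path | None = None,
) -> ReferenceGenome:
    """Load the packaged reference genome (or substitute any of its parts).

    ``excluded`` may be an iterable of 1-based positions or a path to a text
    file with one position per line ('#' comments allowed).
    """
    fasta = _data_path("rcrs_synthetic.fasta") if fasta is None else Path(fasta)
    genes_path = _data_path("genes.tsv") if genes is None else Path(genes)
    if excluded is None:
        excluded_set = _read_excluded(_data_path("excluded_positions.txt"))
    elif isinstance(excluded, (str, Path)):
        excluded_set = _read_excluded(Path(excluded))
    else:
        excluded_set = frozenset(int(p) for p in excluded)

    try:
        record = next(SeqIO.parse(str(fasta), "fasta"))
    except (StopIteration, FileNotFoundError) as exc:
        raise ReferenceError(f"cannot read reference FASTA {fasta}") from exc
    return ReferenceGenome(
        sequence=str(record.seq).upper(),
        genes=_read_genes(genes_path),
        excluded_positions=excluded_set,
    )
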