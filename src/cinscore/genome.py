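"""Genome coordinate model: builds, segments and per-sample copy-number profiles.

All coordinates inside the package are 0-based, half-open.  Chromosome names
are canonicalised by stripping a leading ``chr`` prefix, so ``chr1`` and ``1``
refer to the same chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence


class ValidationError(ValueError):
    """An input violates a structural invariant (overlap, duplicate id, ...)."""


def canonical_chrom(name: str) -> str:
    """Canonical chromosome label: ``chr1`` -> ``1``, ``chrX`` -> ``X``."""
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    return name.upper() if name.lower() in ("x", "y") else name


@dataclass(frozen=True)
class GenomeBuild:
    """An ordered set of named chromosomes with lengths in base pairs.

    The default build (:func:`default_build`) holds the 22 human autosomes of
    GRCh37; every fraction-of-chromosome computation in the scoring module is
    carried out in this coordinate frame.
    """

    chromosomes: tuple  # tuple[(name, length), ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in build")
        for n, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {n} has non-positive length")

    @property
    def names(self) -> tuple:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> dict:
        return {n: l for n, l in self.chromosomes}

    def __contains__(self, name: str) -> bool:
        return canonical_chrom(name) in self.lengths

    def __len__(self) -> int:
        return len(self.chromosomes)

    def index(self, name: str) -> int:
        return self.names.index(canonical_chrom(name))

    def length(self, name: str) -> int:
        return self.lengths[canonical_chrom(name)]

    def scaled(self, factor: float) -> "GenomeBuild":
        """A proportionally shrunken copy (used for fast exhaustive checks)."""
        return GenomeBuild(
            tuple((n, max(1, int(round(l * factor)))) for n, l in self.chromosomes)
        )


# GRCh37 autosome lengths (bp)
_GRCH37_AUTOSOMES = (
    ("1", 249250621), ("2", 243199373), ("3", 198022430), ("4", 191154276),
    ("5", 180915260), ("6", 171115067), ("7", 159138663), ("8", 146364022),
    ("9", 141213431), ("10", 135534747), ("11", 135006516), ("12", 133851895),
    ("13", 115169878), ("14", 107349540), ("15", 102531392), ("16", 90354753),
    ("17", 81195210), ("18", 78077248), ("19", 59128983), ("20", 63025520),
    ("21", 48129895), ("22", 51304566),
)


def default_build() -> GenomeBuild:
    """The 22 GRCh37 human autosomes — the frame all scores are defined on."""
    return GenomeBuild(_GRCH37_AUTOSOMES)


@dataclass
class Segment:
    """A copy-number segment in internal 0-based half-open coordinates."""

    chromosome: str
    start: int
    end: int
    copy_number: float

    def __post_init__(self) -> None:
        self.chromosome = canonical_chrom(self.chromosome)
        if not self.start < self.end:
            raise ValidationError(
                f"segment {self.chromosome}:{self.start}-{self.end} has start >= end"
            )
        if self.copy_number < 0:
            raise ValidationError(
                f"segment {self.chromosome}:{self.start}-{self.end} "
                f"has negative copy number {self.copy_number}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SampleProfile:
    """One sample's segments plus externally estimated ploidy and WGD status.

    Ploidy is the average genome copy number per cell, an input here (it comes
    from an ABSOLUTE-style caller); ``wgd`` flags whole-genome doubling.
    Segments must be non-overlapping within each chromosome; they are kept
    sorted by (chromosome order of appearance, start).
    """

    sample_id: str
    segments: list = field(default_factory=list)
    ploidy: Optional[float] = None
    wgd: Optional[bool] = None
    cohort: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ploidy is not None and not self.ploidy > 0:
            raise ValidationError(f"sample {self.sample_id}: ploidy must be > 0")
        self.segments = sorted(
            self.segments, key=lambda s: (s.chromosome, s.start)
        )
        self._check_overlap()

    def _check_overlap(self) -> None:
        prev = None
        for seg in self.segments:
            if (
                prev is not None
                and seg.chromosome == prev.chromosome
                and seg.start < prev.end
            ):
                raise ValidationError(
                    f"sample {self.sample_id}: overlapping segments on "
                    f"chromosome {seg.chromosome} "
                    f"({prev.start}-{prev.end} and {seg.start}-{seg.end})"
                )
            prev = seg

    def segments_on(self, chromosome: str) -> list:
        c = canonical_chrom(chromosome)
        return [s for s in self.segments if s.chromosome == c]

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)
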