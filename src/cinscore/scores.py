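"""Karyotypic complexity scores: NCS, SCS and WGII.

Three per-sample surrogate measures of chromosomal instability, all computed
from integer-rounded segmented copy numbers over the 22 autosomes:

* NCS (numerical complexity score) — the number of autosomes whose integer
  copy number differs from the sample's integer ploidy over at least 75% of
  the covered length: a count of whole-chromosome gains/losses (W-CIN).
* SCS (structural complexity score) — the number of merged segments of at
  least 1 Mb whose integer copy number deviates from the chromosome's
  length-weighted modal copy number: a count of structural aberrations
  (S-CIN).  Ploidy is not part of the definition.
* WGII (weighted genome instability index) — the mean, over autosomes, of
  the fraction of covered length whose integer copy number differs from the
  integer ploidy; a ploidy-relative fraction in [0, 1].

Because NCS and WGII are relative to the sample's own integer ploidy, a pure
whole-genome doubling (every copy number doubled along with the ploidy)
leaves both unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .genome import GenomeBuild, SampleProfile, Segment, default_build

NCS_THRESHOLD = 0.75
SCS_MIN_LENGTH = 1_000_000


class PloidyMissingError(ValueError):
    """NCS/WGII need a sample ploidy; none was provided."""


def round_half_away(x):
    """Nearest integer with .5 ties rounded away from zero (vectorised)."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


@dataclass
class RoundedProfile:
    """Integer-rounded, merge-normalised profile in array form.

    Segments are sorted by (build chromosome order, start); contiguous
    segments with equal integer copy number have been merged, so counting a
    merged segment is independent of the segmentation granularity upstream.
    """

    sample_id: str
    chrom_idx: np.ndarray   # index into build.names
    start: np.ndarray
    end: np.ndarray
    copy_number: np.ndarray  # integer
    ploidy: Optional[int]
    build: GenomeBuild
    wgd: Optional[bool] = None
    cohort: Optional[str] = None

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def segments(self) -> List[Segment]:
        names = self.build.names
        return [
            Segment(names[c], int(s), int(e), float(cn))
            for c, s, e, cn in zip(
                self.chrom_idx, self.start, self.end, self.copy_number
            )
        ]


@dataclass
class ChromosomeCall:
    """Per-chromosome summary backing the NCS/WGII fractions and SCS mode."""

    chromosome: str
    covered_length: int
    changed_length: int
    changed_fraction: float
    modal_cn: Optional[int]
    is_whole_change: bool


def round_profile(profile: SampleProfile, build: Optional[GenomeBuild] = None) -> RoundedProfile:
    """Round ploidy and segment copy numbers to nearest integers and merge.

    Ties at .5 round half away from zero.  Contiguous same-chromosome
    segments whose integer copy numbers agree are merged into one segment.
    Chromosomes absent from the build are ignored.
    """
    build = build or default_build()
    index = {name: i for i, name in enumerate(build.names)}
    rows = [
        (index[s.chromosome], s.start, s.end, s.copy_number)
        for s in profile.segments
        if s.chromosome in index
    ]
    if not rows:
        empty = np.empty(0, dtype=np.int64)
        return RoundedProfile(
            profile.sample_id, empty, empty.copy(), empty.copy(), empty.copy(),
            None if profile.ploidy is None else int(round_half_away(profile.ploidy)),
            build, profile.wgd, profile.cohort,
        )
    arr = np.asarray(rows, dtype=float)
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    arr = arr[order]
    chrom = arr[:, 0].astype(np.int64)
    start = arr[:, 1].astype(np.int64)
    end = arr[:, 2].astype(np.int64)
    cn = round_half_away(arr[:, 3])

    # merge runs of contiguous, equal-CN segments on the same chromosome
    new_run = np.ones(len(cn), dtype=bool)
    same = (
        (chrom[1:] == chrom[:-1]) & (cn[1:] == cn[:-1]) & (start[1:] == end[:-1])
    )
    new_run[1:] = ~same
    run_id = np.cumsum(new_run) - 1
    n_runs = run_id[-1] + 1
    first = np.flatnonzero(new_run)
    last = np.append(first[1:] - 1, len(cn) - 1)
    ploidy = None if profile.ploidy is None else int(round_half_away(profile.ploidy))
    return RoundedProfile(
        profile.sample_id,
        chrom[first], start[first], end[last], cn[first],
        ploidy, build, profile.wgd, profile.cohort,
    )


def _as_rounded(profile, build: Optional[GenomeBuild]) -> RoundedProfile:
    if isinstance(profile, RoundedProfile):
        return profile
    return round_profile(profile, build)


def _modal_copy_numbers(r: RoundedProfile) -> np.ndarray:
    """Length-weighted modal CN per build chromosome (-1 where uncovered).

    Ties between equally weighted copy-number states break toward the integer
    ploidy when available (so the ploidy backbone is never called aberrant on
    a tie), otherwise toward the smaller copy number.
    """
    n = len(r.build)
    modal = np.full(n, -1, dtype=np.int64)
    lengths = r.lengths
    for c in np.unique(r.chrom_idx):
        mask = r.chrom_idx == c
        states, inv = np.unique(r.copy_number[mask], return_inverse=True)
        weight = np.bincount(inv, weights=lengths[mask])
        best = weight == weight.max()
        cands = states[best]
        if r.ploidy is not None:
            modal[c] = min(cands, key=lambda v: (abs(v - r.ploidy), v))
        else:
            modal[c] = cands.min()
    return modal


def chromosome_calls(
    profile, build: Optional[GenomeBuild] = None, threshold: float = NCS_THRESHOLD
) -> List[ChromosomeCall]:
    """Per-autosome covered/changed lengths, fractions and modal CN."""
    r = _as_rounded(profile, build)
    if r.ploidy is None:
        raise PloidyMissingError(f"sample {r.sample_id}: ploidy required")
    n = len(r.build)
    lengths = r.lengths
    covered = np.bincount(r.chrom_idx, weights=lengths, minlength=n)
    dev = r.copy_number != r.ploidy
    changed = np.bincount(
        r.chrom_idx[dev], weights=lengths[dev], minlength=n
    )
    modal = _modal_copy_numbers(r)
    calls = []
    for i, name in enumerate(r.build.names):
        cov = int(covered[i])
        chg = int(changed[i])
        frac = chg / cov if cov else 0.0
        calls.append(
            ChromosomeCall(
                chromosome=name,
                covered_length=cov,
                changed_length=chg,
                changed_fraction=frac,
                modal_cn=None if modal[i] < 0 else int(modal[i]),
                is_whole_change=bool(cov > 0 and frac >= threshold),
            )
        )
    return calls


def compute_ncs(
    profile, build: Optional[GenomeBuild] = None, threshold: float = NCS_THRESHOLD
) -> Tuple[int, List[ChromosomeCall]]:
    """Numerical complexity score: count of whole-chromosome changes.

    A chromosome counts when at least ``threshold`` (default 75%) of its
    covered length has integer copy number differing from the integer ploidy.
    Chromosomes with zero coverage are never counted.
    """
    calls = chromosome_calls(profile, build, threshold)
    return sum(c.is_whole_change for c in calls), calls


def compute_scs(
    profile,
    build: Optional[GenomeBuild] = None,
    min_length: int = SCS_MIN_LENGTH,
) -> Tuple[int, List[Segment]]:
    """Structural complexity score: count of long segments off the modal CN.

    Each merged segment of length >= ``min_length`` (default 1 Mb) whose
    integer copy number differs from its chromosome's length-weighted modal
    copy number contributes one; the total over autosomes is the SCS.  Sample
    ploidy enters only as a tie-break for the mode.
    """
    r = _as_rounded(profile, build)
    if len(r.chrom_idx) == 0:
        return 0, []
    modal = _modal_copy_numbers(r)
    counted_mask = (
        (r.lengths >= min_length) & (r.copy_number != modal[r.chrom_idx])
    )
    names = r.build.names
    counted = [
        Segment(names[c], int(s), int(e), float(cn))
        for c, s, e, cn in zip(
            r.chrom_idx[counted_mask], r.start[counted_mask],
            r.end[counted_mask], r.copy_number[counted_mask],
        )
    ]
    return int(counted_mask.sum()), counted


def compute_wgii(profile, build: Optional[GenomeBuild] = None) -> float:
    """Weighted genome instability index: mean ploidy-deviating fraction.

    Per autosome, the fraction of covered length whose integer copy number
    differs from the integer ploidy; the WGII is the unweighted mean over
    autosomes with nonzero coverage, a fraction in [0, 1].
    """
    calls = chromosome_calls(profile, build)
    fracs = [c.changed_fraction for c in calls if c.covered_length > 0]
    return float(np.mean(fracs)) if fracs else float("nan")


@dataclass
class CinScores:
    """The per-sample (NCS, SCS, WGII) triple."""

    sample_id: str
    ncs: Optional[int]
    scs: int
    wgii: Optional[float]


def score_sample(
    profile,
    build: Optional[GenomeBuild] = None,
    threshold: float = NCS_THRESHOLD,
    min_length: int = SCS_MIN_LENGTH,
) -> CinScores:
    """All three scores for one sample; NCS/WGII are missing without ploidy."""
    r = _as_rounded(profile, build)
    scs, _ = compute_scs(r, build, min_length)
    if r.ploidy is None:
        return CinScores(r.sample_id, None, scs, None)
    ncs, calls = compute_ncs(r, build, threshold)
    fracs = [c.changed_fraction for c in calls if c.covered_length > 0]
    wgii = float(np.mean(fracs)) if fracs else float("nan")
    return CinScores(r.sample_id, ncs, scs, wgii)


def score_cohort(
    profiles: Iterable[SampleProfile],
    build: Optional[GenomeBuild] = None,
    threshold: float = NCS_THRESHOLD,
    min_length: int = SCS_MIN_LENGTH,
) -> pd.DataFrame:
    """Score every profile; one row per sample.

    Samples without ploidy get NaN NCS/WGII but a valid SCS.  Columns:
    sample_id, ncs, scs, wgii, ploidy, wgd, cohort.
    """
    build = build or default_build()
    rows = []
    for p in profiles:
        s = score_sample(p, build, threshold, min_length)
        rows.append(
            (
                s.sample_id,
                np.nan if s.ncs is None else s.ncs,
                s.scs,
                np.nan if s.wgii is None else s.wgii,
                np.nan if p.ploidy is None else p.ploidy,
                p.wgd,
                p.cohort,
            )
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "ncs", "scs", "wgii", "ploidy", "wgd", "cohort"]
    )
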