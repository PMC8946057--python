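"""Independent brute-force scorer: tallies the integer copy number of every
single base of every chromosome and recomputes NCS, SCS and WGII from first
principles.  Deliberately naive — no merging, no interval arithmetic — so it
shares no code path with the package implementation.  Practical on shrunken
genome builds (tens to hundreds of kilobases per chromosome)."""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from cinscore.genome import GenomeBuild, SampleProfile, Segment


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def brute_force_scores(
    profile: SampleProfile,
    build: GenomeBuild,
    threshold: float = 0.75,
    min_length: int = 1_000_000,
) -> Tuple[Optional[int], int, Optional[float]]:
    """Per-base recomputation of (NCS, SCS, WGII); NCS/WGII None w/o ploidy."""
    ploidy = None if profile.ploidy is None else _round_half_away(profile.ploidy)

    fracs = []
    ncs = 0
    scs = 0
    for name, length in build.chromosomes:
        arr = np.full(length, -1, dtype=np.int64)  # -1 marks uncovered bases
        for seg in profile.segments_on(name):
            arr[seg.start: seg.end] = _round_half_away(seg.copy_number)
        covered = arr >= 0
        n_cov = int(covered.sum())

        if ploidy is not None and n_cov > 0:
            frac = float((covered & (arr != ploidy)).sum()) / n_cov
            fracs.append(frac)
            if frac >= threshold:
                ncs += 1

        if n_cov > 0:
            # length-weighted modal copy number; ties toward ploidy, then
            # toward the smaller state
            states, counts = np.unique(arr[covered], return_counts=True)
            best = states[counts == counts.max()]
            if ploidy is not None:
                modal = min(best, key=lambda v: (abs(v - ploidy), v))
            else:
                modal = best.min()
            # runs of identical value (uncovered bases split runs)
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [length]))
            for s, e in zip(starts, ends):
                if arr[s] >= 0 and arr[s] != modal and (e - s) >= min_length:
                    scs += 1

    wgii = float(np.mean(fracs)) if (ploidy is not None and fracs) else None
    if ploidy is None:
        return None, scs, None
    return ncs, scs, wgii


def random_profiles(
    rng: np.random.Generator,
    build: GenomeBuild,
    n: int,
    p_gap: float = 0.15,
    p_tie: float = 0.05,
) -> list:
    """Random stress-test profiles: ragged segmentation, coverage gaps,
    occasional exact .5 copy numbers, random real-valued ploidy."""
    profiles = []
    for i in range(n):
        ploidy = float(rng.uniform(1.6, 4.4))
        segs = []
        for name, length in build.chromosomes:
            n_seg = int(rng.integers(1, 9))
            cuts = np.sort(rng.choice(np.arange(1, length), size=n_seg - 1,
                                      replace=False)) if n_seg > 1 else np.array([], int)
            bounds = np.concatenate(([0], cuts, [length]))
            for s, e in zip(bounds[:-1], bounds[1:]):
                if rng.random() < p_gap:
                    continue  # uncovered stretch
                if rng.random() < p_tie:
                    cn = float(int(rng.integers(0, 6)) + 0.5)  # exact tie case
                else:
                    cn = max(0.0, ploidy + float(rng.normal(0, 1.2)))
                segs.append(Segment(name, int(s), int(e), cn))
        profiles.append(
            SampleProfile(sample_id=f"R{i:03d}", segments=segs, ploidy=ploidy)
        )
    return profiles
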