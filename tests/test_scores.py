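"""NCS / SCS / WGII scoring rules, rounding, merging and invariances."""

import numpy as np
import pytest

from cinscore.genome import GenomeBuild, SampleProfile, Segment
from cinscore.scores import (
    PloidyMissingError, compute_ncs, compute_scs, compute_wgii,
    round_half_away, round_profile, score_cohort, score_sample,
)
from tests.conftest import flat_profile
from tests.oracle import brute_force_scores, random_profiles

MB = 1_000_000


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected",
        [(2.7, 3), (2.1, 2), (2.5, 3), (3.5, 4), (0.5, 1), (0.49, 0), (2.0, 2)],
    )
    def test_nearest_integer_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected

    def test_round_profile_rounds_cn_and_ploidy(self, build):
        p = flat_profile(build, ploidy=2.1, cn=2.7)
        r = round_profile(p, build)
        assert r.ploidy == 2
        assert set(r.copy_number) == {3}

    def test_adjacent_equal_integer_segments_merge(self, build):
        segs = [Segment("1", 0, MB, 3.2), Segment("1", MB, 2 * MB, 2.8)]
        r = round_profile(SampleProfile(sample_id="S", segments=segs, ploidy=2),
                          build)
        assert len(r.start) == 1
        assert (r.start[0], r.end[0], r.copy_number[0]) == (0, 2 * MB, 3)

    def test_gap_separated_segments_do_not_merge(self, build):
        segs = [Segment("1", 0, MB, 3.0), Segment("1", 2 * MB, 3 * MB, 3.0)]
        r = round_profile(SampleProfile(sample_id="S", segments=segs, ploidy=2),
                          build)
        assert len(r.start) == 2


class TestNcs:
    def test_profile_at_ploidy_scores_zero(self, build):
        ncs, _ = compute_ncs(flat_profile(build, ploidy=2.0, cn=2.0), build)
        assert ncs == 0

    def test_exactly_75_percent_counts(self, build):
        """'At least 75%' is inclusive: a chromosome at the threshold counts.

        Chromosome 20's length is divisible by 4, so the 75% point is exact.
        """
        L = build.length("20")
        assert L % 4 == 0
        cut = 3 * L // 4
        segs = [
            Segment(name, 0, ln, 2.0)
            for name, ln in build.chromosomes if name != "20"
        ] + [Segment("20", 0, cut, 3.0), Segment("20", cut, L, 2.0)]
        p = SampleProfile(sample_id="S1", segments=segs, ploidy=2.0)
        ncs, calls = compute_ncs(p, build)
        idx = build.index("20")
        assert calls[idx].changed_fraction == 0.75
        assert ncs == 1

    def test_five_trisomic_plus_one_partial(self, build, small_build):
        """Five fully trisomic autosomes count; a 60% trisomic one does not."""

        def make(b):
            segs = []
            for i, (name, L) in enumerate(b.chromosomes):
                if i < 5:
                    segs.append(Segment(name, 0, L, 3.0))
                elif i == 5:
                    cut = int(0.6 * L)
                    segs += [Segment(name, 0, cut, 3.0),
                             Segment(name, cut, L, 2.0)]
                else:
                    segs.append(Segment(name, 0, L, 2.0))
            return SampleProfile(sample_id="S", segments=segs, ploidy=2.0)

        ncs, _ = compute_ncs(make(build), build)
        assert ncs == 5
        # independent per-base tally agrees (on the shrunken build)
        assert brute_force_scores(make(small_build), small_build)[0] == 5

    def test_ploidy_required(self, build):
        p = flat_profile(build, cn=2.0)
        p.ploidy = None
        with pytest.raises(PloidyMissingError):
            compute_ncs(p, build)

    def test_uncovered_chromosome_not_counted(self, build):
        segs = [Segment("1", 0, build.length("1"), 3.0)]
        p = SampleProfile(sample_id="S", segments=segs, ploidy=2.0)
        ncs, calls = compute_ncs(p, build)
        assert ncs == 1
        assert sum(c.covered_length > 0 for c in calls) == 1


class TestScs:
    def test_uniform_chromosome_contributes_zero(self, build):
        scs, counted = compute_scs(flat_profile(build, cn=3.0), build)
        assert scs == 0 and counted == []

    def test_sub_megabase_deviation_not_counted(self, build):
        """1.0 Mb off-modal counts; 0.9 Mb fails the length rule."""
        L = build.length("1")
        segs = [
            Segment("1", 0, 10 * MB, 2.0),
            Segment("1", 10 * MB, 11 * MB, 3.0),          # exactly 1.0 Mb
            Segment("1", 11 * MB, 20 * MB, 2.0),
            Segment("1", 20 * MB, 20 * MB + 900_000, 1.0),  # 0.9 Mb
            Segment("1", 20 * MB + 900_000, L, 2.0),
        ]
        p = SampleProfile(sample_id="S", segments=segs, ploidy=2.0)
        scs, counted = compute_scs(p, build)
        assert scs == 1
        assert counted[0].copy_number == 3.0

    def test_scs_without_ploidy(self, build):
        L = build.length("2")
        segs = [Segment("2", 0, L - 2 * MB, 2.0), Segment("2", L - 2 * MB, L, 4.0)]
        p = SampleProfile(sample_id="S", segments=segs)
        scs, _ = compute_scs(p, build)
        assert scs == 1

    def test_split_representation_invariance(self, build, rng):
        """Splitting a counted segment into equal-CN pieces leaves SCS fixed."""
        L = build.length("3")
        segs = [Segment("3", 0, L - 5 * MB, 2.0), Segment("3", L - 5 * MB, L, 3.0)]
        whole = SampleProfile(sample_id="S", segments=segs, ploidy=2.0)
        split_segs = [
            Segment("3", 0, L - 5 * MB, 2.0),
            Segment("3", L - 5 * MB, L - 2 * MB, 3.0),
            Segment("3", L - 2 * MB, L, 3.0),
        ]
        split = SampleProfile(sample_id="S", segments=split_segs, ploidy=2.0)
        assert compute_scs(whole, build)[0] == compute_scs(split, build)[0] == 1

    def test_modal_tie_breaks_toward_ploidy(self, build):
        # exactly half the covered length at CN 2 (=ploidy), half at CN 3:
        # backbone must win the tie, so the CN-3 half is the aberration
        L = 10 * MB
        segs = [Segment("1", 0, L, 2.0), Segment("1", L, 2 * L, 3.0)]
        p = SampleProfile(sample_id="S", segments=segs, ploidy=2.0)
        scs, counted = compute_scs(p, build)
        assert scs == 1 and counted[0].copy_number == 3.0


class TestWgii:
    def test_all_at_ploidy_is_zero(self, build):
        assert compute_wgii(flat_profile(build, cn=2.0), build) == 0.0

    def test_every_autosome_fully_deviating_is_one(self, build):
        assert compute_wgii(flat_profile(build, ploidy=2.0, cn=3.0), build) == 1.0

    def test_forty_percent_everywhere_gives_040(self, build):
        segs = []
        for name, L in build.chromosomes:
            cut = int(round(0.4 * L))
            segs += [Segment(name, 0, cut, 3.0), Segment(name, cut, L, 2.0)]
        p = SampleProfile(sample_id="S", segments=segs, ploidy=2.0)
        expected = np.mean(
            [int(round(0.4 * L)) / L for _, L in build.chromosomes]
        )
        assert compute_wgii(p, build) == pytest.approx(expected, abs=1e-12)


class TestInvariances:
    def test_wgd_doubling_leaves_ncs_and_wgii_unchanged(self, small_build, rng):
        for p in random_profiles(rng, small_build, 20):
            doubled = SampleProfile(
                sample_id=p.sample_id,
                segments=[Segment(s.chromosome, s.start, s.end,
                                  2 * round(s.copy_number)) for s in p.segments],
                ploidy=2.0 * round(p.ploidy),
            )
            base = SampleProfile(
                sample_id=p.sample_id,
                segments=[Segment(s.chromosome, s.start, s.end,
                                  round(s.copy_number)) for s in p.segments],
                ploidy=float(round(p.ploidy)),
            )
            assert compute_ncs(doubled, small_build)[0] == \
                   compute_ncs(base, small_build)[0]
            assert compute_wgii(doubled, small_build) == \
                   pytest.approx(compute_wgii(base, small_build), abs=1e-12)

    def test_whole_chromosome_gain_adds_one_ncs(self, small_build, rng):
        for p in random_profiles(rng, small_build, 10):
            covered = {s.chromosome for s in p.segments}
            empty = [n for n, _ in small_build.chromosomes if n not in covered]
            if not empty:
                continue
            name = empty[0]
            L = small_build.length(name)
            gained = SampleProfile(
                sample_id=p.sample_id,
                segments=p.segments + [
                    Segment(name, 0, L, round(p.ploidy) + 1.0)
                ],
                ploidy=p.ploidy,
            )
            assert compute_ncs(gained, small_build)[0] == \
                   compute_ncs(p, small_build)[0] + 1
            assert compute_wgii(gained, small_build) >= \
                   compute_wgii(p, small_build) - 1e-12


class TestScoreCohort:
    def test_empty_cohort(self, build):
        assert score_cohort([], build).empty

    def test_missing_ploidy_gives_scs_only(self, build):
        L = build.length("1")
        segs = [Segment("1", 0, L - 2 * MB, 2.0), Segment("1", L - 2 * MB, L, 4.0)]
        p = SampleProfile(sample_id="S", segments=segs)
        row = score_cohort([p], build).iloc[0]
        assert row["scs"] == 1
        assert np.isnan(row["ncs"]) and np.isnan(row["wgii"])

    def test_matches_brute_force_oracle(self, small_build, rng):
        profiles = random_profiles(rng, small_build, 40)
        table = score_cohort(profiles, small_build, min_length=1000)
        for p, (_, row) in zip(profiles, table.iterrows()):
            ncs, scs, wgii = brute_force_scores(p, small_build, min_length=1000)
            assert row["ncs"] == ncs and row["scs"] == scs
            assert abs(row["wgii"] - wgii) < 1e-12
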