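"""Score two hand-built copy-number profiles.

Builds a near-diploid sample with one trisomy and one focal amplification,
plus a genome-doubled sample, and prints their NCS / SCS / WGII.
"""

from cinscore import SampleProfile, Segment, default_build, score_sample

build = default_build()
MB = 1_000_000


def full_chromosomes(cn, skip=()):
    return [
        Segment(name, 0, length, cn)
        for name, length in build.chromosomes
        if name not in skip
    ]


# Sample A: diploid backbone, trisomy 7, one 5 Mb amplification on 1p
chr1 = build.length("1")
sample_a = SampleProfile(
    sample_id="A",
    segments=full_chromosomes(2.05, skip=("1", "7"))
    + [
        Segment("1", 0, 20 * MB, 2.1),
        Segment("1", 20 * MB, 25 * MB, 4.2),   # 5 Mb focal gain
        Segment("1", 25 * MB, chr1, 1.95),
        Segment("7", 0, build.length("7"), 3.1),  # whole-chromosome gain
    ],
    ploidy=2.1,
)

# Sample B: whole-genome doubled (ploidy ~4), one chromosome lost back to 3
sample_b = SampleProfile(
    sample_id="B",
    segments=full_chromosomes(3.9, skip=("13",))
    + [Segment("13", 0, build.length("13"), 3.0)],
    ploidy=3.95,
)

for sample in (sample_a, sample_b):
    s = score_sample(sample, build)
    print(f"sample {s.sample_id}: NCS={s.ncs}  SCS={s.scs}  WGII={s.wgii:.4f}")

print(
    "\nNCS counts autosomes deviating from integer ploidy over >=75% of their"
    "\ncovered length (the trisomy in A; the single lost chromosome in B --"
    "\nthe doubling itself is invisible because scores are ploidy-relative)."
    "\nSCS counts >=1 Mb segments off the chromosome's modal copy number"
    "\n(the 5 Mb gain in A).  WGII is the mean deviating fraction per autosome."
)
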