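"""Readers and writers for SEG tables, ploidy calls, annotations and matrices.

Files are plain tab-delimited text throughout.  Coordinate conventions differ
between SEG dialects (TCGA writes 1-based inclusive intervals); a
:class:`SegDialect` declares the convention at the boundary and everything is
normalised to the internal 0-based half-open frame on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .genome import (
    GenomeBuild,
    SampleProfile,
    Segment,
    ValidationError,
    canonical_chrom,
    default_build,
)

logger = logging.getLogger("cinscore")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


@dataclass(frozen=True)
class SegDialect:
    """Coordinate and value convention of a SEG file.

    ``based`` is the index of the first base (0 or 1); ``end_inclusive`` says
    whether the end coordinate is part of the segment.  ``log2_ratio`` marks
    files carrying log2 copy-ratio values instead of absolute copy numbers;
    conversion to absolute copy number (CN = ploidy * 2**ratio) then requires
    per-sample ploidy at read time.
    """

    based: int = 1
    end_inclusive: bool = True
    log2_ratio: bool = False

    def to_internal(self, start: int, end: int) -> Tuple[int, int]:
        return start - self.based, end - self.based + (1 if self.end_inclusive else 0)

    def from_internal(self, start: int, end: int) -> Tuple[int, int]:
        return start + self.based, end + self.based - (1 if self.end_inclusive else 0)


DIALECTS: Dict[str, SegDialect] = {
    "tcga": SegDialect(based=1, end_inclusive=True),
    "bed": SegDialect(based=0, end_inclusive=False),
    "tcga-log2": SegDialect(based=1, end_inclusive=True, log2_ratio=True),
}

_SAMPLE_COLS = ("sample", "sample_id", "id", "ccle_name", "array", "name")
_CHROM_COLS = ("chromosome", "chrom", "chr")
_START_COLS = ("start", "loc.start", "chromstart")
_END_COLS = ("end", "loc.end", "chromend", "stop")
_CN_COLS = (
    "copy_number", "cn", "segment_mean", "seg.mean", "modal_total_cn",
    "mean", "value", "tcn",
)
_PLOIDY_COLS = ("ploidy",)
_WGD_COLS = ("wgd", "genome_doublings", "genome doublings", "doublings")


def _find_col(columns: Iterable[str], candidates: Tuple[str, ...], what: str) -> str:
    lower = {str(c).strip().lower(): c for c in columns}
    for cand in candidates:
        if cand in lower:
            return lower[cand]
    raise ParseError(f"no {what} column found; looked for any of {candidates}")


def _resolve_dialect(dialect) -> SegDialect:
    if isinstance(dialect, SegDialect):
        return dialect
    try:
        return DIALECTS[str(dialect).lower()]
    except KeyError:
        raise ParseError(
            f"unknown SEG dialect {dialect!r}; known: {sorted(DIALECTS)}"
        ) from None


def read_seg(
    path,
    build: Optional[GenomeBuild] = None,
    dialect="tcga",
    ploidy_map: Optional[Mapping[str, float]] = None,
) -> List[SampleProfile]:
    """Read a SEG file into per-sample profiles (segments only, no ploidy).

    Chromosomes absent from ``build`` (sex chromosomes against the default
    autosome build, typically) are dropped with a logged count, as are rows
    with missing copy number.  Overlapping segments within a sample and
    chromosome raise :class:`~cinscore.genome.ValidationError`.
    """
    build = build or default_build()
    dia = _resolve_dialect(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    s_col = _find_col(df.columns, _SAMPLE_COLS, "sample")
    c_col = _find_col(df.columns, _CHROM_COLS, "chromosome")
    b_col = _find_col(df.columns, _START_COLS, "start")
    e_col = _find_col(df.columns, _END_COLS, "end")
    v_col = _find_col(df.columns, _CN_COLS, "copy-number")

    profiles: Dict[str, List[Segment]] = {}
    n_dropped_chrom = 0
    n_dropped_missing = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        rec = dict(zip(df.columns, row))
        chrom = canonical_chrom(rec[c_col])
        raw_cn = rec[v_col]
        if raw_cn is None or (isinstance(raw_cn, float) and np.isnan(raw_cn)) \
                or str(raw_cn).strip() in ("", "NA", "nan", "NaN"):
            n_dropped_missing += 1
            continue
        try:
            start = int(float(rec[b_col]))
            end = int(float(rec[e_col]))
            value = float(raw_cn)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: malformed row at line {i}: {exc}") from None
        if chrom not in build:
            n_dropped_chrom += 1
            continue
        start, end = dia.to_internal(start, end)
        sample = str(rec[s_col]).strip()
        if dia.log2_ratio:
            if ploidy_map is None or sample not in ploidy_map:
                raise ParseError(
                    f"{path}: log2-ratio dialect requires ploidy for sample {sample}"
                )
            value = ploidy_map[sample] * 2.0 ** value
        if value < 0:
            value = 0.0
        try:
            seg = Segment(chrom, start, end, value)
        except ValidationError as exc:
            raise ParseError(f"{path}: invalid segment at line {i}: {exc}") from None
        profiles.setdefault(sample, []).append(seg)

    if n_dropped_chrom:
        logger.warning(
            "read_seg(%s): dropped %d segment(s) on chromosomes outside the build",
            path, n_dropped_chrom,
        )
    if n_dropped_missing:
        logger.warning(
            "read_seg(%s): dropped %d segment(s) with missing copy number",
            path, n_dropped_missing,
        )
    return [SampleProfile(sample_id=s, segments=segs) for s, segs in profiles.items()]


def write_seg(profiles: Iterable[SampleProfile], path, dialect="tcga") -> None:
    """Write profiles as a SEG file in the given dialect (absolute CN values)."""
    dia = _resolve_dialect(dialect)
    if dia.log2_ratio:
        raise ValueError("writing log2-ratio SEG files is not supported")
    rows = []
    for p in profiles:
        for seg in p.segments:
            start, end = dia.from_internal(seg.start, seg.end)
            rows.append((p.sample_id, seg.chromosome, start, end, seg.copy_number))
    out = pd.DataFrame(
        rows, columns=["sample", "chromosome", "start", "end", "copy_number"]
    )
    # shortest-repr floats: read(write(profiles)) restores copy numbers exactly
    out.to_csv(path, sep="\t", index=False)


def read_ploidy_table(path) -> Dict[str, Tuple[float, Optional[bool]]]:
    """Read a per-sample ploidy (and optional WGD-status) table.

    Returns ``{sample_id: (ploidy, wgd_or_None)}``.  WGD columns holding
    genome-doubling counts (ABSOLUTE style) are interpreted as doubled iff the
    count is positive.  Duplicate sample ids are an error.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")
    s_col = _find_col(df.columns, _SAMPLE_COLS, "sample")
    p_col = _find_col(df.columns, _PLOIDY_COLS, "ploidy")
    try:
        w_col = _find_col(df.columns, _WGD_COLS, "wgd")
    except ParseError:
        w_col = None

    out: Dict[str, Tuple[float, Optional[bool]]] = {}
    for i, row in df.iterrows():
        sample = str(row[s_col]).strip()
        if sample in out:
            raise ValidationError(f"{path}: duplicate sample id {sample}")
        try:
            ploidy = float(row[p_col])
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: non-numeric ploidy {row[p_col]!r} for sample {sample} "
                f"(line {i + 2})"
            ) from None
        wgd: Optional[bool] = None
        if w_col is not None and not pd.isna(row[w_col]):
            raw = str(row[w_col]).strip().lower()
            if raw in ("true", "false"):
                wgd = raw == "true"
            else:
                wgd = float(raw) > 0
        out[sample] = (ploidy, wgd)
    return out


def read_annotations(path) -> pd.DataFrame:
    """Sample annotation table (cohort, endpoints, indices), sample_id index."""
    df = pd.read_csv(path, sep="\t", comment="#")
    s_col = _find_col(df.columns, _SAMPLE_COLS, "sample")
    df = df.rename(columns={s_col: "sample_id"})
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids in annotations")
    return df.set_index("sample_id")


def read_feature_matrix(path, transpose: bool = False) -> pd.DataFrame:
    """Samples x features real or binary matrix from TSV (first column = id).

    ``transpose=True`` reads a features-in-rows file (the common layout of
    pathway-activity exports) and flips it to samples-in-rows.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if transpose:
        df = df.T
    df.index = df.index.map(str)
    return df


def read_drug_screen(path, transpose: bool = False) -> pd.DataFrame:
    """Compound x cell-line AUC matrix from TSV; missing values allowed."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if transpose:
        df = df.T
    df.index = df.index.map(str)
    if np.isinf(df.to_numpy(dtype=float, na_value=np.nan)).any():
        raise ValidationError(f"{path}: non-finite AUC values present")
    return df


def load_build(path) -> GenomeBuild:
    """Read a genome build as a two-column (name, length) TSV."""
    df = pd.read_csv(path, sep="\t", comment="#")
    name_col, len_col = df.columns[:2]
    return GenomeBuild(
        tuple(
            (canonical_chrom(r[name_col]), int(r[len_col]))
            for _, r in df.iterrows()
        )
    )


@dataclass
class CohortDataset:
    """Profiles with ploidy attached, joined with annotations on sample id."""

    profiles: List[SampleProfile]
    annotations: Optional[pd.DataFrame] = None

    @property
    def sample_ids(self) -> List[str]:
        return [p.sample_id for p in self.profiles]


def join_cohort(
    profiles: Iterable[SampleProfile],
    ploidy_map: Mapping[str, Tuple[float, Optional[bool]]],
    annotations: Optional[pd.DataFrame] = None,
) -> CohortDataset:
    """Inner-join segment profiles with ploidy calls (and annotations).

    Samples missing from the ploidy table are dropped (a logged count), since
    ploidy-relative scores cannot be computed for them.  An empty intersection
    is an error.
    """
    profiles = list(profiles)
    kept: List[SampleProfile] = []
    for p in profiles:
        if p.sample_id not in ploidy_map:
            continue
        ploidy, wgd = ploidy_map[p.sample_id]
        cohort = p.cohort
        if annotations is not None and p.sample_id in annotations.index \
                and "cohort" in annotations.columns:
            cohort = annotations.loc[p.sample_id, "cohort"]
        kept.append(
            SampleProfile(
                sample_id=p.sample_id, segments=p.segments,
                ploidy=ploidy, wgd=wgd, cohort=cohort,
            )
        )
    n_dropped = len(profiles) - len(kept)
    if n_dropped:
        logger.info("join_cohort: dropped %d sample(s) lacking ploidy", n_dropped)
    if not kept:
        raise ValidationError("join_cohort: no samples shared between inputs")
    ann = None
    if annotations is not None:
        ids = [p.sample_id for p in kept]
        ann = annotations.loc[annotations.index.intersection(ids)]
    return CohortDataset(profiles=kept, annotations=ann)
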