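"""Synthetic multi-cohort copy-number datasets with known ground truth.

The generator emulates the statistical structure a pan-cancer chromosomal
instability analysis rests on, while keeping every planted quantity exactly
recoverable:

* a whole-genome-doubling (WGD) mixture — doubled samples start from ploidy
  4 and draw many more whole-chromosome changes, producing the bimodal
  ploidy-relative NCS distribution seen across tumour cohorts;
* a right-skewed structural burden (negative-binomial event counts, focal
  event lengths log-uniform down to sub-megabase scale);
* clinical endpoints whose hazard depends on the sample's CIN group, an HRD
  covariate tracking structural burden, and an aneuploidy score tracking
  whole-chromosome burden;
* expression/pathway features with planted per-cohort score correlations, a
  binary alteration matrix whose carriers draw elevated event rates (a
  TP53-like gene by default), and a compound x cell-line AUC matrix with
  planted sensitivity slopes.

Noise added to segment copy numbers is a Gaussian clipped to (-0.499, 0.499)
so that rounding to the nearest integer always restores the planted state:
the generator models residual segment-mean jitter, never state flips.  All
randomness flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import GenomeBuild, SampleProfile, Segment, default_build
from .scores import SCS_MIN_LENGTH, score_cohort

NOISE_CLIP = 0.499


class PlacementError(RuntimeError):
    """Structural-event placement failed after bounded retries."""


@dataclass
class GeneratorConfig:
    """Defaults define the study conditions for all downstream checks."""

    seed: int = 0
    n_cohorts: int = 22
    samples_per_cohort: int = 30
    p_wgd: Optional[Sequence[float]] = None  # default: linspace(0.05, 0.75)

    # whole-chromosome change rates (Poisson means; capped at 20 so that a
    # couple of autosomes always remain available for structural events)
    lambda_whole: float = 1.0
    lambda_whole_wgd: float = 6.0

    # structural events: negative-binomial count (right-skewed), log-uniform
    # focal lengths spanning sub-1 Mb to 20 Mb
    struct_mean: float = 5.0
    struct_dispersion: float = 1.2
    focal_length_range: Tuple[float, float] = (3e5, 2e7)
    event_gap: int = 100_000
    max_event_coverage: float = 0.4

    # fixed event counts override the random draws (exact planted designs)
    fixed_whole: Optional[int] = None
    fixed_struct: Optional[int] = None
    strict_placement: bool = False

    noise_sd: float = 0.2
    ploidy_jitter_sd: float = 0.04

    # survival model: exponential with hazard h0 * exp(beta * 1[high CIN]),
    # independent uniform censoring; times in days
    survival_score: str = "ncs"
    baseline_hazard: float = 3e-4
    log_hazard_high: float = float(np.log(2.0))
    censor_max: float = 3650.0

    # therapy response: P(responder) = sigmoid(a0 + a1 * z(score))
    response_intercept: float = 0.0
    response_slope: float = -0.8
    response_missing: float = 0.1

    # instability covariates
    hrd_slope: float = 0.6
    hrd_noise_sd: float = 2.0
    aneuploidy_slope: float = 1.5
    aneuploidy_noise_sd: float = 1.5
    p_min_flag: float = 0.1

    # feature matrix: (name, score kind, rho, n active cohorts)
    n_null_features: int = 40
    planted_features: Sequence[Tuple[str, str, float, int]] = (
        ("PW_NCS_BROAD", "ncs", 0.5, 10),
        ("PW_NCS_SPARSE", "ncs", 0.5, 3),
    )

    # binary alterations: (gene, delta ncs, delta scs, carrier probability)
    n_null_genes: int = 15
    null_carrier_p: float = 0.3
    planted_alterations: Sequence[Tuple[str, float, float, float]] = (
        ("TP53", 4.0, 11.0, 0.35),
    )

    # drug screen: (compound, baseline AUC, slope of AUC vs z(score))
    drug_score: str = "ncs"
    n_null_compounds: int = 20
    planted_compounds: Sequence[Tuple[str, float, float]] = (
        ("POTENT-POS", 0.25, 0.12),
        ("WEAK-POS", 0.85, 0.12),
    )
    drug_noise_sd: float = 0.05

    def wgd_probabilities(self) -> np.ndarray:
        if self.p_wgd is not None:
            p = np.asarray(self.p_wgd, dtype=float)
            if len(p) != self.n_cohorts:
                raise ValueError("p_wgd must have one entry per cohort")
        else:
            p = np.linspace(0.05, 0.75, self.n_cohorts)
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p_wgd entries must lie in [0, 1]")
        return p

    @property
    def n_samples(self) -> int:
        return self.n_cohorts * self.samples_per_cohort


def sample_ids(config: GeneratorConfig) -> Tuple[List[str], List[str]]:
    """Deterministic sample ids and cohort labels, cohort-major order."""
    ids, cohorts = [], []
    for ci in range(config.n_cohorts):
        cohort = f"C{ci + 1:02d}"
        for si in range(config.samples_per_cohort):
            ids.append(f"{cohort}-S{si + 1:03d}")
            cohorts.append(cohort)
    return ids, cohorts


def _clipped_noise(rng: np.random.Generator, sd: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.zeros(size)
    return np.clip(rng.normal(0.0, sd, size), -NOISE_CLIP, NOISE_CLIP)


def _feasible_starts(
    occupied: List[Tuple[int, int]], L: int, ev_len: int, gap: int
) -> List[Tuple[int, int]]:
    """Slots of admissible start positions given occupied intervals + gap."""
    slots = []
    pos = 0
    for s, e in sorted(occupied) + [(L + gap, L + gap)]:
        hi = s - gap - ev_len  # last admissible start before this interval
        if hi >= pos:
            slots.append((pos, min(hi, L - ev_len)))
        pos = e + gap
        if pos > L - ev_len:
            break
    return [(a, b) for a, b in slots if b >= a]


def _place_events(
    rng: np.random.Generator,
    build: GenomeBuild,
    free_chroms: np.ndarray,
    lengths: Sequence[int],
    gap: int,
    max_cov: float,
    strict: bool = False,
) -> List[Tuple[int, int, int]]:
    """Place events (chrom_idx, start, end) without overlap on free autosomes.

    Events are placed largest-first; each draws a chromosome with probability
    proportional to its remaining admissible start positions, then a start
    uniformly among them, so placement succeeds whenever room exists.  An
    event with no room anywhere is dropped (or raises when ``strict``); the
    returned list holds realised events only, and ground truth is recorded
    from it.
    """
    occupied: Dict[int, List[Tuple[int, int]]] = {int(c): [] for c in free_chroms}
    occ_len: Dict[int, int] = {int(c): 0 for c in free_chroms}
    placed: List[Tuple[int, int, int]] = []
    for ev_len in sorted(lengths, reverse=True):
        options = []
        totals = []
        for c in occupied:
            L = build.chromosomes[c][1]
            if occ_len[c] + ev_len > max_cov * L:
                continue
            slots = _feasible_starts(occupied[c], L, ev_len, gap)
            total = sum(b - a + 1 for a, b in slots)
            if total > 0:
                options.append((c, slots))
                totals.append(total)
        if not options:
            if strict:
                raise PlacementError(f"no room left for a {ev_len} bp event")
            continue  # tail case: drop the event; truth tracks placed events
        weights = np.asarray(totals, dtype=float)
        idx = int(rng.choice(len(options), p=weights / weights.sum()))
        c, slots = options[idx]
        offset = int(rng.integers(0, int(weights[idx])))
        for a, b in slots:
            width = b - a + 1
            if offset < width:
                start = a + offset
                break
            offset -= width
        end = start + ev_len
        occupied[c].append((start, end))
        occ_len[c] += ev_len
        placed.append((c, start, end))
    return placed


def generate_profiles(
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
    build: Optional[GenomeBuild] = None,
    ncs_rate_shift: Optional[np.ndarray] = None,
    scs_mean_shift: Optional[np.ndarray] = None,
) -> Tuple[List[SampleProfile], pd.DataFrame]:
    """Draw one profile per sample; return profiles and per-sample truth.

    ``ncs_rate_shift``/``scs_mean_shift`` are optional per-sample additive
    shifts of the whole-change rate and structural-event mean; the alteration
    generator uses them to realise carrier effects before profiles exist.

    Truth columns: sample_id, cohort, wgd, base_ploidy, n_whole (planted
    whole-chromosome changes), n_struct (realised structural events),
    n_struct_ge_min (realised events of at least the SCS minimum length —
    the exact SCS ground truth).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    build = build or default_build()
    ids, cohorts = sample_ids(config)
    p_wgd = config.wgd_probabilities()
    n_chrom = len(build)
    cap_whole = max(0, n_chrom - 2)
    lo, hi = config.focal_length_range
    # fraction of drawn events long enough to count toward the SCS; planted
    # structural shifts are stated in SCS units, so the event-rate shift is
    # inflated by 1/p_long to land on the intended score difference
    if lo >= SCS_MIN_LENGTH:
        p_long = 1.0
    elif hi <= SCS_MIN_LENGTH:
        p_long = 0.0
    else:
        p_long = (np.log(hi) - np.log(SCS_MIN_LENGTH)) / (np.log(hi) - np.log(lo))

    profiles: List[SampleProfile] = []
    truth_rows = []
    for i, (sid, cohort) in enumerate(zip(ids, cohorts)):
        ci = i // config.samples_per_cohort
        wgd = bool(rng.random() < p_wgd[ci])
        base_ploidy = 4 if wgd else 2
        lam = config.lambda_whole_wgd if wgd else config.lambda_whole
        if ncs_rate_shift is not None:
            lam = max(0.0, lam + float(ncs_rate_shift[i]))
        if config.fixed_whole is not None:
            k = int(min(config.fixed_whole, cap_whole))
        else:
            k = int(min(rng.poisson(lam), cap_whole))
        whole = rng.choice(n_chrom, size=k, replace=False) if k else np.empty(0, int)
        whole_cn = {
            int(c): base_ploidy + (1 if rng.random() < 0.5 else -1) for c in whole
        }

        mean_m = config.struct_mean
        if scs_mean_shift is not None and scs_mean_shift[i] != 0:
            if p_long == 0.0:
                raise ValueError(
                    "planted structural effects need focal lengths that can "
                    "reach the SCS minimum length"
                )
            mean_m = max(0.0, mean_m + float(scs_mean_shift[i]) / p_long)
        disp = config.struct_dispersion
        if config.fixed_struct is not None:
            m = int(config.fixed_struct)
        else:
            m = int(rng.negative_binomial(disp, disp / (disp + mean_m))) if mean_m > 0 else 0
        ev_lengths = [
            int(round(np.exp(rng.uniform(np.log(lo), np.log(hi))))) for _ in range(m)
        ]
        free = np.setdiff1d(np.arange(n_chrom), whole)
        placed = _place_events(
            rng, build, free, ev_lengths, config.event_gap,
            config.max_event_coverage, strict=config.strict_placement,
        ) if m else []
        deltas = rng.choice([-2, -1, 1, 2], size=len(placed), p=[0.15, 0.35, 0.35, 0.15])

        events: Dict[int, List[Tuple[int, int, int]]] = {}
        for (c, s, e), d in zip(placed, deltas):
            events.setdefault(c, []).append((s, e, max(base_ploidy + int(d), 0)))

        segs: List[Segment] = []
        raw: List[Tuple[int, int, int, int]] = []  # chrom, start, end, int CN
        for c in range(n_chrom):
            L = build.chromosomes[c][1]
            if c in whole_cn:
                raw.append((c, 0, L, whole_cn[c]))
                continue
            pos = 0
            for s, e, cn in sorted(events.get(c, [])):
                if s > pos:
                    raw.append((c, pos, s, base_ploidy))
                raw.append((c, s, e, cn))
                pos = e
            if pos < L:
                raw.append((c, pos, L, base_ploidy))
        noise = _clipped_noise(rng, config.noise_sd, len(raw))
        names = build.names
        for (c, s, e, cn), eps in zip(raw, noise):
            segs.append(Segment(names[c], s, e, max(cn + eps, 0.0)))

        ploidy = base_ploidy + float(
            np.clip(rng.normal(0, config.ploidy_jitter_sd), -0.45, 0.45)
        )
        profiles.append(
            SampleProfile(sample_id=sid, segments=segs, ploidy=ploidy,
                          wgd=wgd, cohort=cohort)
        )
        placed_lengths = [e - s for _, s, e in placed]
        n_ge = sum(1 for l in placed_lengths if l >= SCS_MIN_LENGTH)
        truth_rows.append(
            (sid, cohort, wgd, base_ploidy, k, len(placed), n_ge)
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "cohort", "wgd", "base_ploidy",
                 "n_whole", "n_struct", "n_struct_ge_min"],
    )
    return profiles, truth


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_clinical(
    config: GeneratorConfig,
    scores: pd.DataFrame,
    rng: np.random.Generator,
    truth: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Clinical annotations: survival endpoints, response, instability indices.

    Survival is exponential with hazard h0*exp(beta) for samples above their
    cohort's median score; censoring is uniform on (0, censor_max).  HRD
    tracks the structural-event truth and the aneuploidy score (AS) the
    whole-chromosome truth; SMR/NSMR/ITH/proliferation are independent noise.
    """
    s = scores.set_index("sample_id")
    score = s[config.survival_score].astype(float)
    med = score.groupby(s["cohort"]).transform("median")
    high = (score > med).to_numpy().astype(int)
    n = len(s)

    rows: Dict[str, np.ndarray] = {}
    hazard = config.baseline_hazard * np.exp(config.log_hazard_high * high)
    for ep in ("os", "dfs", "pfs"):
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.uniform(0, config.censor_max, n)
        rows[f"{ep}_time"] = np.minimum(t_event, t_cens)
        rows[f"{ep}_event"] = (t_event <= t_cens).astype(int)

    z = _zscore(score.to_numpy())
    p_resp = 1.0 / (1.0 + np.exp(-(config.response_intercept + config.response_slope * z)))
    resp = np.where(rng.random(n) < p_resp, "responder", "non-responder").astype(object)
    resp[rng.random(n) < config.response_missing] = np.nan

    if truth is not None:
        t = truth.set_index("sample_id").loc[s.index]
        scs_t = t["n_struct_ge_min"].to_numpy(float)
        ncs_t = t["n_whole"].to_numpy(float)
    else:
        scs_t = s["scs"].to_numpy(float)
        ncs_t = s["ncs"].to_numpy(float)

    ann = pd.DataFrame(
        {
            "cohort": s["cohort"].to_numpy(),
            **rows,
            "response": resp,
            "AS": config.aneuploidy_slope * ncs_t
            + rng.normal(0, config.aneuploidy_noise_sd, n),
            "HRD": config.hrd_slope * scs_t + rng.normal(0, config.hrd_noise_sd, n),
            "SMR": rng.normal(0, 1, n),
            "NSMR": rng.normal(0, 1, n),
            "ITH": rng.normal(0, 1, n),
            "MIN": rng.normal(0, 1, n),
            "proliferation": rng.normal(0, 1, n),
            "min_flag": rng.random(n) < config.p_min_flag,
        },
        index=s.index,
    )
    ann.index.name = "sample_id"
    return ann


def generate_features(
    config: GeneratorConfig,
    scores: pd.DataFrame,
    rng: np.random.Generator,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Real-valued feature matrix with planted per-cohort score correlations.

    A planted feature equals rho*z + sqrt(1-rho^2)*noise within its active
    cohorts (z = within-cohort standardised score) and pure noise elsewhere;
    null features are independent standard normals.
    """
    s = scores.set_index("sample_id")
    cohorts = s["cohort"]
    cohort_order = sorted(cohorts.unique())
    n = len(s)
    cols: Dict[str, np.ndarray] = {}
    truth_rows = []
    for name, kind, rho, n_active in config.planted_features:
        active = set(cohort_order[:n_active])
        z = (
            s[kind].astype(float)
            .groupby(cohorts)
            .transform(lambda v: _zscore(v.to_numpy()))
            .to_numpy()
        )
        eps = rng.normal(0, 1, n)
        in_active = cohorts.isin(active).to_numpy()
        x = np.where(in_active, rho * z + np.sqrt(1 - rho**2) * eps, eps)
        cols[name] = x
        truth_rows.append((name, kind, rho, n_active))
    for j in range(config.n_null_features):
        name = f"NULL_F{j:02d}"
        cols[name] = rng.normal(0, 1, n)
        truth_rows.append((name, config.survival_score, 0.0, 0))
    feats = pd.DataFrame(cols, index=s.index)
    feats.index.name = "sample_id"
    truth = pd.DataFrame(
        truth_rows, columns=["feature", "score", "rho", "n_cohorts_active"]
    )
    return feats, truth


def generate_alterations(
    config: GeneratorConfig,
    ids: Sequence[str],
    rng: np.random.Generator,
) -> Tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]:
    """Binary alteration matrix plus the per-sample event-rate shifts.

    Carrier status is drawn before profile realisation; a carrier of a gene
    with planted (delta_ncs, delta_scs) has its whole-change rate and
    structural-event mean shifted by those amounts, so the regression
    coefficient of score on carrier status recovers the planted delta.
    Returns (matrix, truth, ncs_rate_shift, scs_mean_shift).
    """
    n = len(ids)
    cols: Dict[str, np.ndarray] = {}
    truth_rows = []
    d_ncs = np.zeros(n)
    d_scs = np.zeros(n)
    for gene, dn, ds, p in config.planted_alterations:
        carrier = (rng.random(n) < p).astype(int)
        cols[gene] = carrier
        d_ncs += dn * carrier
        d_scs += ds * carrier
        truth_rows.append((gene, dn, ds, p))
    for j in range(config.n_null_genes):
        gene = f"NULL_G{j:02d}"
        cols[gene] = (rng.random(n) < config.null_carrier_p).astype(int)
        truth_rows.append((gene, 0.0, 0.0, config.null_carrier_p))
    mat = pd.DataFrame(cols, index=pd.Index(ids, name="sample_id"))
    truth = pd.DataFrame(
        truth_rows, columns=["gene", "delta_ncs", "delta_scs", "carrier_p"]
    )
    return mat, truth, d_ncs, d_scs


def generate_drug_screen(
    config: GeneratorConfig,
    scores: pd.DataFrame,
    rng: np.random.Generator,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Compound x cell-line AUC matrix with planted sensitivity slopes.

    AUC = baseline - slope * z(score) + noise, clipped at zero; a positive
    slope makes high-CIN lines more sensitive (lower AUC).  The default
    planted pair is one potent compound (low baseline AUC, hence high median
    sensitivity) and one weak compound (high baseline), both positively
    score-correlated.
    """
    s = scores.set_index("sample_id")
    z = _zscore(s[config.drug_score].astype(float).to_numpy())
    n = len(s)
    rows: Dict[str, np.ndarray] = {}
    truth_rows = []
    for name, baseline, slope in config.planted_compounds:
        rows[name] = np.maximum(
            baseline - slope * z + rng.normal(0, config.drug_noise_sd, n), 0.0
        )
        truth_rows.append((name, baseline, slope))
    for j in range(config.n_null_compounds):
        name = f"CMPD-N{j:02d}"
        baseline = rng.uniform(0.35, 0.8)
        rows[name] = np.maximum(
            baseline + rng.normal(0, config.drug_noise_sd, n), 0.0
        )
        truth_rows.append((name, baseline, 0.0))
    auc = pd.DataFrame(rows, index=s.index).T
    auc.index.name = "compound"
    truth = pd.DataFrame(truth_rows, columns=["compound", "baseline_auc", "slope"])
    return auc, truth


@dataclass
class SyntheticDataset:
    """Everything one seeded draw of the generator produces."""

    config: GeneratorConfig
    profiles: List[SampleProfile]
    truth: pd.DataFrame
    scores: pd.DataFrame
    annotations: pd.DataFrame
    features: pd.DataFrame
    feature_truth: pd.DataFrame
    alterations: pd.DataFrame
    alteration_truth: pd.DataFrame
    auc: pd.DataFrame
    drug_truth: pd.DataFrame


def simulate_cohort(
    config: Optional[GeneratorConfig] = None,
    seed: Optional[int] = None,
    build: Optional[GenomeBuild] = None,
) -> SyntheticDataset:
    """Run the full generator: profiles, scores, clinical, features, drugs."""
    config = config or GeneratorConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    build = build or default_build()
    ids, _ = sample_ids(config)
    alterations, alt_truth, d_ncs, d_scs = generate_alterations(config, ids, rng)
    profiles, truth = generate_profiles(
        config, rng, build, ncs_rate_shift=d_ncs, scs_mean_shift=d_scs
    )
    scores = score_cohort(profiles, build)
    annotations = generate_clinical(config, scores, rng, truth)
    features, feature_truth = generate_features(config, scores, rng)
    auc, drug_truth = generate_drug_screen(config, scores, rng)
    return SyntheticDataset(
        config=config, profiles=profiles, truth=truth, scores=scores,
        annotations=annotations, features=features, feature_truth=feature_truth,
        alterations=alterations, alteration_truth=alt_truth,
        auc=auc, drug_truth=drug_truth,
    )
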