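"""Synthetic cohort generator for the full pipeline.

Emulates, at desk scale, the statistical structure the analysis assumes in a
tumor/adjacent-normal small RNA-seq cohort:

* per-miRNA distinct-isoform counts drawn from a zero-truncated Poisson whose
  mean differs between groups for a planted set of "signal" miRNAs (lower
  diversity in tumors, and lower again in unfavorable-histology tumors, by the
  configured fold change);
* negative-binomial read counts with library-size scaling, 5' offsets
  concentrated at zero and 3' offsets dispersed, with the 3'+1 isoform
  optionally the most abundant;
* censored survival times from an exponential (or Weibull) hazard that depends
  on the diversity group and histology;
* precursor hairpins with annotated mature arms, and UTR sequences carrying a
  manifest-recorded number of exact and one-mismatch seed-complementary sites.

Everything flows from one seeded generator: the same config and seed give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .diversity import IsomirCountTable
from .io import COUNT_KEY_COLUMNS

__all__ = [
    "SimConfig",
    "ConfigError",
    "generate_count_table",
    "generate_clinical",
    "generate_sequences",
    "plant_site_comparison_utr",
    "zero_truncated_poisson_rate",
]

_RNA = np.array(list("ACGU"))
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# isoform catalogue in abundance-rank order: 5' offsets concentrated at 0,
# 3' offsets dispersed
_OFFSET_CATALOG: list[tuple[int, int]] = [
    (0, 0), (0, 1), (0, -1), (0, 2), (0, -2), (0, 3), (-1, 1), (1, 0),
    (-1, 0), (0, 4), (1, 1), (-1, 2), (0, -3), (1, -1), (0, 5), (-1, -1),
]


class ConfigError(ValueError):
    """Raised when a simulation parameter is out of range; names the field."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the analyzed cohort where it pins them: 127 tumor and 5
    adjacent normal samples at a mean depth of 8.9 million reads.  The planted
    diversity fold change defaults to 3 — comfortably beyond the 2-fold
    selection threshold, as the reported hits were — with signal miRNAs at a
    high base diversity (mean 8 isoforms in normals) so the median->=3
    eligibility gate keeps them in play in every stratum.
    """

    n_tumor: int = 127
    n_normal: int = 5
    n_mirnas: int = 50
    n_signal: int = 2
    depth_mean: float = 8.9e6
    depth_sd: float = 7e5
    nb_dispersion: float = 0.1
    diversity_fc: float = 3.0
    abundance_fc: float = 2.0
    hr_diversity: float = 2.0
    hr_histology: float = 3.0
    censor_rate: float = 0.3
    p_unfavorable: float = 0.35
    signal_mean_isoforms: float = 8.0
    noise_mean_isoforms: tuple[float, float] = (2.5, 6.0)
    abundance_decay: float = 0.7
    dominant_3p1: bool = True
    baseline_median_days: float = 2000.0
    survival_model: str = "exponential"
    weibull_shape: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "n_tumor", "n_normal", "n_mirnas", "depth_mean", "depth_sd",
            "nb_dispersion", "hr_diversity", "hr_histology",
            "signal_mean_isoforms", "baseline_median_days", "weibull_shape",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_signal < 0 or self.n_signal > self.n_mirnas:
            raise ConfigError(f"n_signal must be in [0, n_mirnas], got {self.n_signal}")
        if self.diversity_fc < 1:
            raise ConfigError(f"diversity_fc must be >= 1, got {self.diversity_fc}")
        if self.abundance_fc <= 0:
            raise ConfigError(f"abundance_fc must be > 0, got {self.abundance_fc}")
        if not (0 <= self.censor_rate < 1):
            raise ConfigError(f"censor_rate must be in [0, 1), got {self.censor_rate}")
        if not (0 < self.p_unfavorable < 1):
            raise ConfigError(f"p_unfavorable must be in (0, 1), got {self.p_unfavorable}")
        if not (0 < self.abundance_decay < 1):
            raise ConfigError(f"abundance_decay must be in (0, 1), got {self.abundance_decay}")
        if self.survival_model not in ("exponential", "weibull"):
            raise ConfigError(f"survival_model must be exponential|weibull, got {self.survival_model}")
        # the zero-truncated Poisson needs every stratum mean above 1; the
        # smallest is the unfavorable-tumor mean m_f / fc (see _isoform_means)
        fc, p = self.diversity_fc, self.p_unfavorable
        m_f = (self.signal_mean_isoforms / fc) / ((1 - p) + p / fc)
        if self.n_signal > 0 and m_f / fc <= 1.0 + 1e-9:
            raise ConfigError(
                "signal_mean_isoforms too small: the unfavorable-stratum mean "
                f"isoform count {m_f / fc:.3f} must exceed 1"
            )


def zero_truncated_poisson_rate(mean: float) -> float:
    """Poisson rate lambda whose zero-truncated mean lambda/(1-e^-lambda) equals ``mean``."""
    if mean <= 1:
        raise ValueError(f"zero-truncated Poisson mean must be > 1, got {mean}")
    f = lambda lam: lam / (1.0 - np.exp(-lam)) - mean
    return float(optimize.brentq(f, 1e-12, mean))


def _sample_ztp(lam: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-truncated Poisson draws by inverse transform."""
    p0 = np.exp(-lam)
    u = rng.uniform(0.0, 1.0, size=size)
    return stats.poisson.ppf(p0 + u * (1.0 - p0), lam).astype(int)


def _nb_draw(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    n = 1.0 / dispersion
    p = n / (n + np.clip(mean, 1e-12, None))
    return rng.negative_binomial(n, p)


def _sample_frame(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample ids, tissue, histology and gender for the cohort."""
    ids = [f"T{i + 1:03d}" for i in range(config.n_tumor)] + [
        f"N{i + 1:03d}" for i in range(config.n_normal)
    ]
    tissue = ["tumor"] * config.n_tumor + ["normal"] * config.n_normal
    hist = np.where(
        rng.uniform(size=config.n_tumor) < config.p_unfavorable,
        "unfavorable",
        "favorable",
    ).tolist() + ["NA"] * config.n_normal
    gender = np.where(rng.uniform(size=len(ids)) < 0.5, "male", "female").tolist()
    return pd.DataFrame(
        {"tissue": tissue, "histology": hist, "gender": gender},
        index=pd.Index(ids, name="sample_id"),
    )


def _isoform_means(config: SimConfig) -> pd.DataFrame:
    """Per-miRNA mean isoform count by stratum (normal / favorable / unfavorable).

    Signal miRNAs: normal mean is ``signal_mean_isoforms``; the tumor strata
    are scaled so that both the tumor/normal and the unfavorable/favorable
    mean ratios equal ``diversity_fc`` exactly.
    """
    names = [f"mir-{i + 1:03d}" for i in range(config.n_mirnas)]
    base = np.linspace(*config.noise_mean_isoforms, config.n_mirnas)
    df = pd.DataFrame(
        {"normal": base, "favorable": base, "unfavorable": base},
        index=pd.Index(names, name="mirna"),
    )
    fc, p = config.diversity_fc, config.p_unfavorable
    m_hi = config.signal_mean_isoforms
    # favorable mean m_f solves (1-p) m_f + p m_f/fc = m_hi/fc
    m_f = (m_hi / fc) / ((1 - p) + p / fc)
    for i in range(config.n_signal):
        name = names[i]
        df.loc[name, "normal"] = m_hi
        df.loc[name, "favorable"] = m_f
        df.loc[name, "unfavorable"] = m_f / fc
    return df


def signal_mirnas(config: SimConfig) -> list[str]:
    """Names of the planted diversity-signal miRNAs."""
    return [f"mir-{i + 1:03d}" for i in range(config.n_signal)]


def generate_count_table(config: SimConfig) -> IsomirCountTable:
    """Simulate the isomiR x sample raw read-count table.

    Per sample and miRNA, the number of distinct isoforms present is a
    zero-truncated Poisson draw with a stratum-dependent mean; the isoforms
    present are the top-k of a fixed catalogue ranked by abundance
    (geometric decay, 3'+1 isoform first when ``dominant_3p1``).  Reads for
    present isoforms are negative binomial with means scaled to a per-sample
    library depth drawn around ``depth_mean``.
    """
    rng = np.random.default_rng(config.seed)
    samples = _sample_frame(config, rng)
    means = _isoform_means(config)
    n_iso = len(_OFFSET_CATALOG)
    names = list(means.index)
    sig = set(signal_mirnas(config))

    # per-miRNA expression share (fixed across samples), moderate spread
    share = np.exp(rng.normal(0.0, 0.5, size=config.n_mirnas))
    share /= share.sum()

    # abundance-rank weights; optionally the (0,1) isoform outranks the archetype
    order = list(range(n_iso))
    if config.dominant_3p1:
        order[0], order[1] = order[1], order[0]  # catalogue[1] == (0, 1) gets rank 0
    rank_of = np.empty(n_iso, dtype=int)
    for rank, idx in enumerate(order):
        rank_of[idx] = rank
    iso_w = config.abundance_decay ** rank_of.astype(float)

    depths = np.clip(
        rng.normal(config.depth_mean, config.depth_sd, size=len(samples)),
        config.depth_mean * 0.1,
        None,
    )

    stratum = np.where(
        samples["tissue"] == "normal", "normal", samples["histology"]
    )
    is_tumor = (samples["tissue"] == "tumor").to_numpy()

    # draw isoform presence k per (miRNA, sample)
    k = np.zeros((config.n_mirnas, len(samples)), dtype=int)
    for mi, name in enumerate(names):
        for strat in ("normal", "favorable", "unfavorable"):
            cols = np.flatnonzero(stratum == strat)
            if cols.size == 0:
                continue
            lam = zero_truncated_poisson_rate(means.loc[name, strat])
            k[mi, cols] = np.minimum(_sample_ztp(lam, cols.size, rng), n_iso)

    # expected read mass per (miRNA, isoform, sample)
    expr = np.tile(share[:, None], (1, len(samples)))
    for mi, name in enumerate(names):
        if name in sig:
            expr[mi, is_tumor] *= config.abundance_fc

    # an isoform is present iff its abundance rank is below the sample's k
    present = rank_of[None, :, None] < k[:, None, :]
    w = iso_w[None, :, None] * present
    w /= w.sum(axis=1, keepdims=True)  # per-miRNA weights over present isoforms
    mean_mass = w * expr[:, None, :]
    # normalise each sample column so the expected depth is exactly depths[s]
    mean_mass *= depths[None, None, :] / mean_mass.sum(axis=(0, 1), keepdims=True)

    counts = _nb_draw(mean_mass, config.nb_dispersion, rng)
    counts[mean_mass == 0] = 0  # absent isoforms stay absent

    index = pd.MultiIndex.from_tuples(
        [(name, o5, o3) for name in names for (o5, o3) in _OFFSET_CATALOG],
        names=COUNT_KEY_COLUMNS,
    )
    mat = counts.reshape(config.n_mirnas * n_iso, len(samples))
    df = pd.DataFrame(mat, index=index, columns=samples.index)
    # drop isoforms never observed anywhere (they were never drawn present)
    df = df.loc[df.sum(axis=1) > 0]
    return IsomirCountTable(df, samples)


def generate_clinical(
    config: SimConfig,
    diversity_groups: Mapping[str, str] | pd.Series,
    samples: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate censored event-free survival for the tumor samples.

    ``diversity_groups`` maps every tumor sample to "more"/"less"; the hazard
    is baseline x hr_diversity^[less] x hr_histology^[unfavorable].  With an
    exponential model the baseline rate is log(2)/baseline_median_days; the
    Weibull option shares the same median.  A record is censored with
    probability ``censor_rate``, at a uniform time before its event.

    ``samples`` supplies histology/gender/tissue annotations (as produced by
    :func:`generate_count_table`); if omitted they are re-drawn from the seed.
    """
    groups = pd.Series(diversity_groups)
    rng = np.random.default_rng((config.seed, 1))
    if samples is None:
        # re-draw the cohort frame exactly as generate_count_table does
        samples = _sample_frame(config, np.random.default_rng(config.seed))
    tumor_ids = [s for s in samples.index if samples.loc[s, "tissue"] == "tumor"]
    missing = [s for s in tumor_ids if s not in groups.index]
    if missing:
        raise ValueError(f"diversity labels missing for samples: {missing}")
    bad = set(groups.loc[tumor_ids]) - {"more", "less"}
    if bad:
        raise ValueError(f"diversity labels must be 'more'/'less', got {sorted(bad)}")

    lam0 = np.log(2.0) / config.baseline_median_days
    rows = []
    for s in tumor_ids:
        hr = 1.0
        if groups[s] == "less":
            hr *= config.hr_diversity
        if samples.loc[s, "histology"] == "unfavorable":
            hr *= config.hr_histology
        if config.survival_model == "exponential":
            t_event = rng.exponential(1.0 / (lam0 * hr))
        else:
            # Weibull with shape a and the same median as the exponential baseline
            a = config.weibull_shape
            scale = config.baseline_median_days / (np.log(2.0) ** (1.0 / a))
            t_event = scale * (rng.exponential(1.0) / hr) ** (1.0 / a)
        censored = rng.uniform() < config.censor_rate
        if censored:
            t = rng.uniform(0.0, t_event)
            t = max(t, 1e-6)
            rows.append((s, t, 0))
        else:
            rows.append((s, max(t_event, 1e-6), 1))
    clin = pd.DataFrame(rows, columns=["sample_id", "time_days", "event"]).set_index(
        "sample_id"
    )
    clin["histology"] = samples.loc[clin.index, "histology"]
    clin["gender"] = samples.loc[clin.index, "gender"]
    clin["tissue"] = "tumor"
    clin["diversity_group"] = groups.loc[clin.index]
    return clin


def _random_rna(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_RNA, size=length))


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def _count_seed_windows(utr: str, seed: str, max_mismatch: int) -> int:
    """Brute-force count of UTR windows matching revcomp(seed) with <= max_mismatch."""
    target = _revcomp(seed)
    k = len(target)
    n = 0
    for i in range(len(utr) - k + 1):
        mm = sum(1 for a, b in zip(utr[i : i + k], target) if a != b)
        if mm <= max_mismatch:
            n += 1
    return n


def _utr_with_planted_sites(
    seed7: str, n_exact: int, n_mm1: int, length: int, rng: np.random.Generator
) -> str:
    """A UTR with exactly ``n_exact`` exact and ``n_mm1`` one-mismatch seed sites.

    Assembled by inserting site sequences into site-free background and
    re-checked by brute force; rejected and re-drawn on accidental extras.
    """
    target = _revcomp(seed7)
    for _ in range(200):
        utr = _random_rna(length, rng)
        # carve non-overlapping slots, 10 nt apart
        n_sites = n_exact + n_mm1
        slot_width = len(target) + 10
        if n_sites * slot_width > length - 20:
            raise ValueError("UTR too short for the requested sites")
        starts = 10 + np.arange(n_sites) * slot_width
        starts = starts + rng.integers(0, 5, size=n_sites)
        pieces = list(utr)
        for j, st in enumerate(starts):
            site = list(target)
            if j >= n_exact:  # one-mismatch site: break one seed pairing
                pos = int(rng.integers(0, len(site)))
                site[pos] = seed7[len(site) - 1 - pos]  # identity never pairs
            pieces[st : st + len(site)] = site
        cand = "".join(pieces)
        if (
            _count_seed_windows(cand, seed7, 0) == n_exact
            and _count_seed_windows(cand, seed7, 1) == n_exact + n_mm1
        ):
            return cand
    raise RuntimeError("could not assemble a UTR with the requested planted sites")


def generate_sequences(
    config: SimConfig,
    n_precursors: int = 5,
    utr_length: int = 400,
    seed_positions: tuple[int, int] = (2, 8),
) -> tuple[dict[str, str], pd.DataFrame, dict[str, str], dict[str, str]]:
    """Generate precursors, mature annotations, UTRs and a planted-site manifest.

    For the first ``n_precursors`` simulated miRNAs: a random 70-nt hairpin
    with the 22-nt mature arm annotated at positions 9-30, and one UTR per
    miRNA carrying a manifest-recorded number of exact and one-mismatch
    seed-complementary sites.

    Returns (precursor FASTA dict, mature annotation table, UTR FASTA dict,
    manifest dict).  Manifest keys: ``<utr_id>:<mirna>:exact`` and
    ``...:mm1``.
    """
    rng = np.random.default_rng((config.seed, 2))
    n_precursors = min(n_precursors, config.n_mirnas)
    precursors: dict[str, str] = {}
    utrs: dict[str, str] = {}
    manifest: dict[str, str] = {}
    ann_rows = []
    lo, hi = seed_positions
    for i in range(n_precursors):
        mirna = f"mir-{i + 1:03d}"
        prec_id = f"pre-{mirna}"
        hairpin = _random_rna(70, rng)
        precursors[prec_id] = hairpin
        ann_rows.append((prec_id, mirna, 9, 30))
        mature = hairpin[8:30]
        seed7 = mature[lo - 1 : hi]
        n_exact = int(rng.integers(1, 4))
        n_mm1 = int(rng.integers(0, 3))
        utr_id = f"utr-{mirna}"
        utrs[utr_id] = _utr_with_planted_sites(seed7, n_exact, n_mm1, utr_length, rng)
        manifest[f"{utr_id}:{mirna}:exact"] = str(n_exact)
        manifest[f"{utr_id}:{mirna}:mm1"] = str(n_mm1)
    annotations = pd.DataFrame(
        ann_rows, columns=["precursor_id", "mirna", "start", "end"]
    )
    return precursors, annotations, utrs, manifest


def plant_site_comparison_utr(
    archetype_seq: str,
    isoform_seq: str,
    rng: np.random.Generator,
    n_shared: int = 4,
    n_isoform_only: int = 1,
    length: int = 600,
    seed_positions: tuple[int, int] = (2, 8),
    mismatch_positions: tuple[int, int] = (12, 14),
) -> tuple[str, float]:
    """Build a UTR where the isoform gains effective sites over its archetype.

    The isoform must be a pure 3' extension of the archetype (identical seed).
    ``n_shared`` sites are perfect complements of the full isoform (effective
    for both sequences); each of the ``n_isoform_only`` sites breaks two
    non-seed archetype pairings while the isoform's 3' extension still pairs,
    so only the isoform's relative pairing score clears the returned
    ``min_score_frac`` threshold.  All sites are exact seed matches, so raw
    seed-hit counts are equal for both sequences.

    Returns (utr, min_score_frac) for use with
    :func:`isomirdiv.targetscan.compare_site_counts`.
    """
    arch = archetype_seq.strip().upper().replace("T", "U")
    iso = isoform_seq.strip().upper().replace("T", "U")
    if not iso.startswith(arch) or len(iso) <= len(arch):
        raise ValueError("isoform must be a strict 3' extension of the archetype")
    lo, hi = seed_positions
    seed7 = arch[lo - 1 : hi]
    la, li = len(arch), len(iso)
    n_mut = len(mismatch_positions)
    for p in mismatch_positions:
        if lo <= p <= hi or p > la:
            raise ValueError("mismatch positions must be outside the seed and inside the archetype")
    # relative-score threshold separating (la - n_mut)/la from (li - n_mut)/li
    frac_lo = (la - n_mut) / la   # archetype at a weakened site: must fail
    frac_hi = (li - n_mut) / li   # isoform at the same site: must pass
    if frac_lo >= frac_hi:
        raise ValueError("isoform extension too short to separate the scores")
    min_score_frac = (frac_lo + frac_hi) / 2.0

    perfect = _revcomp(iso)  # site perfectly pairing the whole isoform
    n_sites = n_shared + n_isoform_only
    slot = li + 12
    if n_sites * slot + 40 > length:
        length = n_sites * slot + 40
    for _ in range(200):
        utr = list(_random_rna(length, rng))
        starts = 20 + np.arange(n_sites) * slot + rng.integers(0, 6, size=n_sites)
        for j, st in enumerate(starts):
            site = list(perfect)
            if j >= n_shared:
                # break archetype pairings at the chosen miRNA positions:
                # miRNA position p pairs site index (li - p); identity never pairs
                for p in mismatch_positions:
                    site[li - p] = iso[p - 1]
            utr[st : st + li] = site
        cand = "".join(utr)
        if _count_seed_windows(cand, seed7, 0) == n_sites:
            return cand, float(min_score_frac)
    raise RuntimeError("could not assemble the site-comparison UTR")
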