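"""Seed-register scanning of 3'UTRs and duplex complementarity scoring.

A candidate site is a UTR window whose sense-strand sequence is the reverse
complement of the miRNA seed (positions 2-8 by default) with at most
``max_mismatch`` mismatches; G:U wobble counts as a mismatch inside the seed.
Each hit also carries an extended-duplex pairing score over the full miRNA
length (Watson-Crick +1, G:U wobble +0.5, else 0), which is what separates
isoforms whose seed is unchanged — e.g. a pure 3'-extension isomiR has exactly
the archetype's seed hits, and any difference in "effective" site counts must
come from the extended 3' pairing.

The pairing score is an in-house complementarity heuristic, not a
thermodynamic model: it counts paired positions rather than folding energy.
An empirical null for calling sites "effective" is provided via
dinucleotide-preserving UTR shuffles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SeedSiteHit",
    "SiteComparison",
    "normalize_rna",
    "seed_sites",
    "pairing_score",
    "compare_site_counts",
    "expression_correlation",
    "dinucleotide_shuffle",
    "effective_score_threshold",
]

_RNA_ALPHABET = set("ACGU")
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {("G", "U"), ("U", "G")}


def normalize_rna(seq: str, what: str = "sequence") -> str:
    """Uppercase and convert DNA T to RNA U; reject anything outside ACGU."""
    out = seq.strip().upper().replace("T", "U")
    for i, ch in enumerate(out):
        if ch not in _RNA_ALPHABET:
            raise ValueError(f"invalid symbol {ch!r} at position {i + 1} in {what}")
    return out


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


@dataclass(frozen=True)
class SeedSiteHit:
    """A seed-complementary site on a UTR.

    ``start`` is the 1-based UTR position of the first seed-paired base (the
    5'-most base of the seed match on the UTR sense strand).
    """

    utr_id: str
    start: int
    seed_span: tuple[int, int]
    mismatches: int
    pairing_score: float

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("site start must be >= 1")


@dataclass(frozen=True)
class SiteComparison:
    """Archetype-vs-isoform site counts on one UTR."""

    gene_id: str
    sites_archetype: int
    sites_isoform: int
    seed_sites_archetype: int
    seed_sites_isoform: int

    @property
    def delta(self) -> int:
        return self.sites_isoform - self.sites_archetype


def pairing_score(mirna_seq: str, utr_window: str) -> tuple[float, str]:
    """Score an antiparallel duplex position by position.

    The window is the UTR sense strand, same length as the miRNA; miRNA
    position 1 (5') pairs the window's 3'-most base.  Watson-Crick pairs score
    1, G:U wobble 0.5, all else 0.  Returns (score, pairing string) where the
    pairing string uses ``|`` for WC, ``:`` for wobble and ``.`` for none,
    ordered 5'->3' along the miRNA.
    """
    mirna = normalize_rna(mirna_seq, "miRNA")
    window = normalize_rna(utr_window, "UTR window")
    if len(window) != len(mirna):
        raise ValueError(
            f"window length {len(window)} != miRNA length {len(mirna)}"
        )
    score = 0.0
    marks = []
    n = len(mirna)
    for i in range(n):
        m, u = mirna[i], window[n - 1 - i]
        if _COMPLEMENT[m] == u:
            score += 1.0
            marks.append("|")
        elif (m, u) in _WOBBLE:
            score += 0.5
            marks.append(":")
        else:
            marks.append(".")
    return score, "".join(marks)


def _window_score(mirna: str, utr: str, seed_start_utr0: int, seed_len: int,
                  seed_positions: tuple[int, int]) -> float:
    """Extended-duplex score for a seed hit at 0-based UTR position, clipping at UTR ends."""
    n = len(mirna)
    # miRNA position p (1-based) pairs UTR index seed_start_utr0 + seed_len - 1 + (seed_positions[0] - p)
    anchor = seed_start_utr0 + seed_len - 1 + seed_positions[0]
    score = 0.0
    for p in range(1, n + 1):
        j = anchor - p
        if 0 <= j < len(utr):
            m, u = mirna[p - 1], utr[j]
            if _COMPLEMENT[m] == u:
                score += 1.0
            elif (m, u) in _WOBBLE:
                score += 0.5
    return score


def seed_sites(
    mirna_seq: str,
    utr_seq: str,
    seed_positions: tuple[int, int] = (2, 8),
    max_mismatch: int = 1,
    utr_id: str = "utr",
) -> list[SeedSiteHit]:
    """Find all UTR windows seed-complementary to a miRNA.

    Every window whose reverse complement matches miRNA positions
    ``seed_positions`` (1-based inclusive) with at most ``max_mismatch``
    mismatches is reported, 5'->3' on the UTR sense strand; overlapping hits
    are all kept.  G:U wobble counts as a mismatch within the seed.
    """
    mirna = normalize_rna(mirna_seq, "miRNA")
    utr = normalize_rna(utr_seq, "UTR")
    lo, hi = seed_positions
    if not (1 <= lo <= hi <= len(mirna)):
        raise ValueError(
            f"seed positions {seed_positions} do not fit miRNA of length {len(mirna)}"
        )
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    seed = mirna[lo - 1 : hi]
    target = _revcomp(seed)  # what a perfect site reads on the UTR sense strand
    k = len(target)
    if len(utr) < k:
        raise ValueError(f"UTR shorter ({len(utr)}) than seed match length ({k})")
    hits: list[SeedSiteHit] = []
    for i in range(len(utr) - k + 1):
        mm = sum(1 for a, b in zip(utr[i : i + k], target) if a != b)
        if mm <= max_mismatch:
            score = _window_score(mirna, utr, i, k, seed_positions)
            hits.append(
                SeedSiteHit(utr_id, i + 1, seed_positions, mm, score)
            )
    return hits


def compare_site_counts(
    archetype_seq: str,
    isoform_seq: str,
    utr_seq: str,
    gene_id: str = "gene",
    seed_positions: tuple[int, int] = (2, 8),
    max_mismatch: int = 1,
    min_score_frac: float | None = None,
) -> SiteComparison:
    """Count target sites for an archetype and one of its isoforms on a UTR.

    Reports both raw seed-hit counts and "effective" counts.  When
    ``min_score_frac`` is given, a hit is effective if its extended-duplex
    pairing score is at least ``min_score_frac`` times the sequence's own
    maximum (its length); otherwise effective counts equal the seed counts.
    For isoforms that only extend the 3' end the seed hits are identical to
    the archetype's, so any non-zero delta under a score threshold is driven
    entirely by 3'-supplementary pairing.
    """
    hits_a = seed_sites(archetype_seq, utr_seq, seed_positions, max_mismatch, gene_id)
    hits_i = seed_sites(isoform_seq, utr_seq, seed_positions, max_mismatch, gene_id)
    if min_score_frac is None:
        eff_a, eff_i = len(hits_a), len(hits_i)
    else:
        la = len(normalize_rna(archetype_seq))
        li = len(normalize_rna(isoform_seq))
        eff_a = sum(1 for h in hits_a if h.pairing_score >= min_score_frac * la)
        eff_i = sum(1 for h in hits_i if h.pairing_score >= min_score_frac * li)
    return SiteComparison(
        gene_id=gene_id,
        sites_archetype=eff_a,
        sites_isoform=eff_i,
        seed_sites_archetype=len(hits_a),
        seed_sites_isoform=len(hits_i),
    )


def expression_correlation(
    mirna_expr: Sequence[float], gene_expr: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between a miRNA's and a gene's per-sample expression."""
    x = np.asarray(mirna_expr, dtype=float)
    y = np.asarray(gene_expr, dtype=float)
    if x.shape != y.shape:
        raise ValueError("expression vectors must cover the same samples")
    if x.size < 3:
        raise ValueError("need at least 3 samples for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance expression vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Altschul-Erikson shuffle: treat each dinucleotide as a directed edge in a
    multigraph over the 4 bases and draw a uniform random Eulerian path with
    the original start and end vertices.  The first and last base and every
    dinucleotide count are preserved.
    """
    s = normalize_rna(seq)
    if len(s) <= 2:
        return s
    vertices = sorted(set(s))
    edges: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    last = s[-1]
    # pick, for each non-terminal vertex, a "last exit" edge so the chosen
    # exits form a tree pointing to the terminal vertex (guarantees an
    # Eulerian path exists through the shuffled edge lists)
    while True:
        last_exit: dict[str, str] = {}
        for v in vertices:
            if v != last and edges[v]:
                last_exit[v] = edges[v][rng.integers(len(edges[v]))]
        # check connectivity: following last exits from each vertex reaches `last`
        ok = True
        for v in last_exit:
            seen = {v}
            cur = v
            while cur != last:
                if cur not in last_exit:
                    ok = False
                    break
                cur = last_exit[cur]
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v in last_exit:
            pool.remove(last_exit[v])
        rng.shuffle(pool)
        if v in last_exit:
            pool.append(last_exit[v])
        shuffled[v] = pool
    out = [s[0]]
    cur = s[0]
    ptr = {v: 0 for v in vertices}
    for _ in range(len(s) - 1):
        nxt = shuffled[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def effective_score_threshold(
    mirna_seq: str,
    utr_seq: str,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    seed_positions: tuple[int, int] = (2, 8),
    max_mismatch: int = 1,
    rng: np.random.Generator | None = None,
) -> float:
    """Empirical pairing-score threshold for "effective" sites.

    Scans ``n_shuffles`` dinucleotide-preserving shuffles of the UTR and
    returns the (1 - alpha) quantile of the best per-shuffle hit score; an
    observed site scoring at or above it has empirical p <= alpha under the
    shuffle null.  Shuffles with no seed hit contribute a best score of 0.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    best: list[float] = []
    for _ in range(n_shuffles):
        shuf = dinucleotide_shuffle(utr_seq, rng)
        hits = seed_sites(mirna_seq, shuf, seed_positions, max_mismatch)
        best.append(max((h.pairing_score for h in hits), default=0.0))
    return float(np.quantile(best, 1.0 - alpha))
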