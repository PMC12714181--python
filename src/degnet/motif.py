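"""Position-weight-matrix promoter scanning and binding-core mutant design.

Promoters are TSS-anchored: a window of length L occupies TSS-relative
coordinates [-L, 0), half-open, with the last base of the sequence at
position -1. All site coordinates are reported on the forward axis
regardless of strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

ALPHABET = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as integer codes (A=0..T=3, N=4)."""
    seq = seq.upper()
    try:
        return np.fromiter((_CODE[b] for b in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise ValidationError(f"sequence contains non-ACGTN character {exc.args[0]!r}") from None


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix: base counts, rows in A,C,G,T order."""

    counts: np.ndarray  # (4, w) non-negative
    motif_id: str = "motif"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValidationError("PFM counts must be a 4 x w matrix")
        if counts.shape[1] < 4:
            raise ValidationError("PFM width must be >= 4")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValidationError("PFM counts must be finite and non-negative")
        if np.any(counts.sum(axis=0) <= 0):
            raise ValidationError("every PFM column needs at least one positive count")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.counts, axis=0))


@dataclass(frozen=True)
class PWM:
    """Log-odds matrix (log2 vs background) with its score range."""

    log_odds: np.ndarray  # (4, w)
    background: np.ndarray  # (4,), sums to 1
    motif_id: str = "motif"
    max_score: float = field(init=False, default=0.0)
    min_score: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        lo = np.asarray(self.log_odds, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "log_odds", lo)
        object.__setattr__(self, "background", bg)
        object.__setattr__(self, "max_score", float(lo.max(axis=0).sum()))
        object.__setattr__(self, "min_score", float(lo.min(axis=0).sum()))
        if not self.max_score > self.min_score:
            raise ValidationError("degenerate PWM: max score equals min score")

    @property
    def width(self) -> int:
        return self.log_odds.shape[1]

    def rel_score(self, score: float | np.ndarray) -> float | np.ndarray:
        return (score - self.min_score) / (self.max_score - self.min_score)


@dataclass(frozen=True)
class MotifSite:
    gene: str
    tss_start: int  # TSS-relative, half-open [tss_start, tss_end), tss_end <= 0
    tss_end: int
    strand: str  # '+' or '-'
    score: float
    rel_score: float

    def __post_init__(self) -> None:
        if self.tss_start >= self.tss_end:
            raise ValidationError(f"site start {self.tss_start} >= end {self.tss_end}")
        if self.strand not in "+-":
            raise ValidationError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class PromoterFragment:
    label: str  # P1 / P2 / P3
    tss_start: int
    tss_end: int
    sequence: str


def pfm_to_pwm(
    pfm: PFM,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 0.25,
) -> PWM:
    """Convert counts to a log2-odds PWM.

    Column probabilities are (count + pseudocount) / (total + 4*pseudocount).
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0):
        raise ValidationError("background must be 4 strictly positive probabilities")
    if abs(bg.sum() - 1.0) > 1e-9:
        raise ValidationError("background probabilities must sum to 1")
    totals = pfm.counts.sum(axis=0)
    probs = (pfm.counts + pseudocount) / (totals + 4.0 * pseudocount)
    if np.any(probs <= 0):
        raise ValidationError("zero count with zero pseudocount gives -inf log-odds; use pseudocount > 0")
    log_odds = np.log2(probs / bg[:, None])
    return PWM(log_odds=log_odds, background=bg, motif_id=pfm.motif_id)


def pwm_reverse_complement(pwm: PWM) -> PWM:
    """PWM scoring the reverse complement: rows A<->T, C<->G, columns reversed."""
    lo = pwm.log_odds[::-1, ::-1]
    return PWM(log_odds=lo, background=pwm.background[::-1], motif_id=pwm.motif_id)


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of every window plus a validity mask (windows with N are invalid)."""
    w = log_odds.shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = ~(windows == 4).any(axis=1)
    safe = np.where(windows == 4, 0, windows)
    scores = log_odds[safe, np.arange(w)].sum(axis=1)
    return scores, valid


def scan_promoter(
    seq: str,
    pwm: PWM,
    rel_threshold: float = 0.85,
    both_strands: bool = True,
    gene: str = "promoter",
) -> list[MotifSite]:
    """Report every window whose relative score reaches the threshold.

    Coordinates are TSS-relative on the forward axis for both strands;
    overlapping opposite-strand sites are both reported. Windows containing
    N are skipped.
    """
    if not 0 < rel_threshold <= 1:
        raise ValidationError("rel_threshold must lie in (0, 1]")
    L = len(seq)
    w = pwm.width
    if L < w:
        return []
    codes = encode(seq)
    span = pwm.max_score - pwm.min_score
    sites: list[MotifSite] = []
    strands = [("+", pwm.log_odds)]
    if both_strands:
        strands.append(("-", pwm_reverse_complement(pwm).log_odds))
    for strand, lo in strands:
        scores, valid = _window_scores(codes, lo)
        rel = (scores - pwm.min_score) / span
        for i in np.flatnonzero(valid & (rel >= rel_threshold)):
            sites.append(
                MotifSite(
                    gene=gene,
                    tss_start=int(i) - L,
                    tss_end=int(i) - L + w,
                    strand=strand,
                    score=float(scores[i]),
                    rel_score=float(rel[i]),
                )
            )
    sites.sort(key=lambda s: (s.tss_start, s.strand))
    return sites


def rank_genes_by_motif(
    promoters: Mapping[str, str],
    pwm: PWM,
    rel_threshold: float = 0.85,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Rank genes by their best promoter window score.

    Returns a table (gene, best_rel_score, site_count) sorted by best score
    descending, ties broken by site count then gene symbol. Genes whose
    promoter yields no scorable window get best_rel_score 0.
    """
    if not promoters:
        raise ValidationError("no promoter sequences supplied")
    rows = []
    span = pwm.max_score - pwm.min_score
    rc = pwm_reverse_complement(pwm)
    for gene, seq in promoters.items():
        best = 0.0
        count = 0
        if len(seq) >= pwm.width:
            codes = encode(seq)
            for lo in ([pwm.log_odds, rc.log_odds] if both_strands else [pwm.log_odds]):
                scores, valid = _window_scores(codes, lo)
                if valid.any():
                    rel = (scores[valid] - pwm.min_score) / span
                    best = max(best, float(rel.max()))
                    count += int((rel >= rel_threshold).sum())
        rows.append((gene, best, count))
    table = pd.DataFrame(rows, columns=["gene", "best_rel_score", "site_count"])
    table = table.sort_values(
        ["best_rel_score", "site_count", "gene"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table


_FRAGMENTS = (("P1", -2000, -1500), ("P2", -1500, -1000), ("P3", -1000, 0))


def partition_promoter(seq: str) -> tuple[PromoterFragment, PromoterFragment, PromoterFragment]:
    """Split a 2000-nt promoter into the three reporter fragments.

    P1 = [-2000, -1500), P2 = [-1500, -1000), P3 = [-1000, 0); the closed
    printed ranges are mapped to half-open intervals so the fragments tile
    the window without double-counting boundary bases.
    """
    if len(seq) != 2000:
        raise ValidationError(f"promoter partition requires exactly 2000 nt, got {len(seq)}")
    out = []
    for label, start, end in _FRAGMENTS:
        out.append(PromoterFragment(label, start, end, seq[start + 2000 : end + 2000]))
    return tuple(out)  # type: ignore[return-value]


def _column_information(pwm: PWM) -> np.ndarray:
    probs = pwm.background[:, None] * np.exp2(pwm.log_odds)
    probs = probs / probs.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(probs > 0, probs * np.log2(probs / pwm.background[:, None]), 0.0)
    return terms.sum(axis=0)


def design_motif_mutants(
    seq: str,
    sites: Iterable[MotifSite],
    pwm: PWM,
    n_core_positions: int = 3,
    rel_threshold: float = 0.85,
) -> tuple[str, list[tuple[int, str, str]]]:
    """Ablate each binding site by substituting its highest-information cores.

    For each site, the ``n_core_positions`` PWM columns with the highest
    information content are rewritten to that column's minimum-log-odds base
    (on the site's strand, written back as forward-strand bases). If the
    rescanned site still reaches ``rel_threshold``, more columns are added
    until it drops below; exhausting all columns raises. Substitutions can
    create a novel above-threshold match overlapping the mutated window
    (e.g. on the opposite strand); such matches are ablated iteratively so
    no residual site overlaps a substituted position. Returns the mutant
    sequence and the substitutions as (tss_position, ref_base, alt_base)
    relative to the original sequence.
    """
    sites = sorted(sites, key=lambda s: (s.tss_start, s.strand))
    w = pwm.width
    L = len(seq)
    if n_core_positions > w:
        raise ValidationError("n_core_positions exceeds motif width")
    original = seq.upper()
    current = list(original)
    info_order = np.argsort(-_column_information(pwm), kind="mergesort")
    min_base = [ALPHABET[int(b)] for b in np.argmin(pwm.log_odds, axis=0)]
    span = pwm.max_score - pwm.min_score

    def site_rel(chars: list[str], site: MotifSite) -> float:
        start = site.tss_start + L
        window = "".join(chars[start : start + w])
        if site.strand == "-":
            window = reverse_complement(window)
        codes = encode(window)
        score = float(pwm.log_odds[codes, np.arange(w)].sum())
        return (score - pwm.min_score) / span

    def ablate(site: MotifSite) -> None:
        nonlocal current
        if site.tss_start + L < 0 or site.tss_end + L > L:
            raise ValidationError(f"site {site.tss_start}..{site.tss_end} outside sequence")
        for k in range(n_core_positions, w + 1):
            trial = list(current)
            for col in info_order[:k]:
                col = int(col)
                if site.strand == "+":
                    pos = site.tss_start + L + col
                    alt = min_base[col]
                else:
                    pos = site.tss_start + L + (w - 1 - col)
                    alt = _COMPLEMENT[min_base[col]]
                trial[pos] = alt
            if site_rel(trial, site) < rel_threshold:
                current = trial
                return
        raise ValidationError(
            f"degenerate PWM: site at {site.tss_start} cannot be driven below "
            f"rel_threshold {rel_threshold} even with all {w} columns substituted"
        )

    for site in sites:
        ablate(site)
    # substitutions may create a fresh match overlapping a mutated window
    # (typically on the opposite strand); ablate those until none remain
    for _ in range(10):
        changed = {i for i in range(L) if current[i] != original[i]}
        residual = [
            s
            for s in scan_promoter("".join(current), pwm, rel_threshold, gene=sites[0].gene if sites else "promoter")
            if set(range(s.tss_start + L, s.tss_end + L)) & changed
        ]
        if not residual:
            break
        for site in residual:
            ablate(site)
    else:
        raise ValidationError("mutation did not converge: substitutions keep creating new matches")
    for site in sites:
        if site_rel(current, site) >= rel_threshold:
            raise ValidationError(f"mutation verification failed for site at {site.tss_start}")
    substitutions = [
        (i - L, original[i], current[i]) for i in range(L) if current[i] != original[i]
    ]
    return "".join(current), substitutions


def background_hit_probability(pwm: PWM, rel_threshold: float, granularity: float = 1e-4) -> float:
    """P(one window on one strand scores >= threshold) under the background.

    Exact up to score discretization at ``granularity``, computed by dynamic
    programming (column-wise convolution of the discretized score
    distribution under the background base frequencies).
    """
    if not 0 < rel_threshold <= 1:
        raise ValidationError("rel_threshold must lie in (0, 1]")
    thr = pwm.min_score + rel_threshold * (pwm.max_score - pwm.min_score)
    # shift each column to non-negative integers
    shifted = pwm.log_odds - pwm.log_odds.min(axis=0, keepdims=True)
    ints = np.rint(shifted / granularity).astype(np.int64)
    dist = np.array([1.0])
    for col in range(pwm.width):
        col_dist = np.zeros(int(ints[:, col].max()) + 1)
        for b in range(4):
            col_dist[ints[b, col]] += pwm.background[b]
        dist = np.convolve(dist, col_dist)
    thr_int = (thr - pwm.min_score) / granularity
    # rounding guard: accept anything within half a grid step of the threshold
    cutoff = int(np.ceil(thr_int - 0.5))
    return float(dist[max(cutoff, 0):].sum())


def default_cebpb_pfm(counts_per_position: int = 100) -> PFM:
    """Bundled stand-in PFM for the palindromic C/EBP consensus TTGCGCAA.

    Synthetic: built from the consensus string alone (count mass on the
    consensus base at every column); supply a curated PFM for real scans.
    """
    consensus = "TTGCGCAA"
    counts = np.zeros((4, len(consensus)))
    for j, base in enumerate(consensus):
        counts[_CODE[base], j] = counts_per_position
    return PFM(counts=counts, motif_id="CEBP_consensus")
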