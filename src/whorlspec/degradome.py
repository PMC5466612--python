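"""Degradome (PARE) supported miRNA target identification.

A miRNA is aligned antiparallel against transcript windows with position-
weighted penalties in the style of the classical plant-target rules:
mismatch 1.0, G:U wobble 0.5, single-nucleotide gap 1.0, each doubled at
miRNA positions 2-13 counted from the 5' end; a perfect complement scores
0 and candidate sites are those scoring at or below a cutoff (default 5).
The slice site is the transcript base paired to miRNA position 10, the
canonical AGO cleavage register.  Sites are then categorized against the
degradome 5'-end pileup (0: unique maximum read count on the transcript;
1: tied maximum; 2: above the median; 3: below; 4: a single read), and an
empirical p-value is attached by re-scanning mononucleotide-shuffled
miRNAs.

Alignment bookkeeping: at most one bulge per site.  A bulged miRNA base
(site one base shorter) is penalized at its own position weight; a bulged
transcript base (site one base longer) between miRNA positions g and g+1
is penalized with the seed weight whenever it touches positions 2-13.
Alignments that would place the cleavage register (position 10) in a gap
are not reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from statistics import median

import numpy as np

log = logging.getLogger(__name__)

SCORE_CUTOFF = 5.0
N_SHUFFLES = 99
SEED_START, SEED_END = 2, 13  # doubled-penalty region, 1-based miRNA positions

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

# penalty[miRNA base, transcript base]
_PEN = np.ones((4, 4))
for _m, _t in ((0, 3), (3, 0), (1, 2), (2, 1)):  # Watson-Crick
    _PEN[_m, _t] = 0.0
_PEN[2, 3] = 0.5  # G:U wobble
_PEN[3, 2] = 0.5  # U:G wobble


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    bad = set(seq) - set(_CODE)
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    return np.fromiter((_CODE[c] for c in seq), dtype=np.int8, count=len(seq))


def _weights(length: int) -> np.ndarray:
    w = np.ones(length)
    w[SEED_START - 1:SEED_END] = 2.0
    return w


def validate_mirna(seq: str) -> str:
    """Check a mature miRNA sequence (RNA alphabet, 18-30 nt)."""
    _encode(seq)
    if not 18 <= len(seq) <= 30:
        raise ValueError(f"mature miRNA length {len(seq)} outside 18-30 nt")
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class SiteHit:
    """A candidate (or supported) miRNA target site on a transcript."""

    mirna_id: str
    transcript_id: str
    slice_pos: int          # 1-based transcript coordinate paired to miRNA pos 10
    score: float
    start: int              # 1-based inclusive site span on the transcript
    end: int
    gap: str = "none"       # none | mirna_bulge | target_bulge
    category: int | None = None
    pvalue: float | None = None


# -- pairwise site scoring -----------------------------------------------------

def align_mirna_target(mirna: str, site: str) -> float:
    """Best penalty score of a miRNA against one candidate site.

    The site length may differ from the miRNA length by at most 1 (one
    bulge).  Returns the minimum score over the allowed gap placements.
    """
    m = _encode(mirna)
    t = _encode(site)
    L = len(m)
    if abs(len(t) - L) > 1:
        raise ValueError("site length must be within 1 of the miRNA length")
    w = _weights(L)
    configs = _alignment_scores(m, t, w)
    return float(min(configs))


def _alignment_scores(m: np.ndarray, t: np.ndarray, w: np.ndarray) -> list[float]:
    L, N = len(m), len(t)
    pen = _PEN[m]  # (L, 4): penalty of miRNA index k vs each target base
    scores: list[float] = []
    if N == L:  # ungapped: miRNA k pairs t[L-1-k]
        scores.append(float(sum(w[k] * pen[k, t[L - 1 - k]] for k in range(L))))
    elif N == L - 1:  # one bulged miRNA base at position g
        for g in range(1, L + 1):
            s = w[g - 1] * 1.0
            for k in range(L):
                if k == g - 1:
                    continue
                tx = N - k if k >= g else (N - 1) - k  # antiparallel with skip
                s += w[k] * pen[k, t[tx]]
            scores.append(float(s))
    else:  # N == L + 1: one bulged transcript base between positions g, g+1
        for g in range(1, L):
            gap_w = 2.0 if g <= SEED_END else 1.0
            s = gap_w * 1.0
            for k in range(L):
                tx = (L - 1 - k) if k >= g else (L - k)
                s += w[k] * pen[k, t[tx]]
            scores.append(float(s))
    return scores


# -- vectorized transcript scanning -------------------------------------------

def _scan_codes(m: np.ndarray, tx: np.ndarray, cutoff: float,
                allow_gaps: bool = True) -> list[tuple[float, int, int, str, int]]:
    """All candidate alignments of one miRNA along one transcript.

    Returns (score, start0, site_len, gap_kind, slice_pos 1-based) tuples for
    every configuration scoring <= cutoff; deduplication happens later.
    """
    L, N = len(m), len(tx)
    if N < L:
        return []
    w = _weights(L)
    win = np.lib.stride_tricks.sliding_window_view(tx, L)      # (N-L+1, L)
    winr = win[:, ::-1]                                        # k pairs tx[s+L-1-k]
    P0 = _PEN[m[None, :], winr]                                # (n_off, L)
    WP = P0 * w[None, :]
    C = WP.cumsum(axis=1)                                      # C[s,k] = sum_{j<=k}
    tot = C[:, -1]
    out: list[tuple[float, int, int, str, int]] = []

    hits = np.nonzero(tot <= cutoff)[0]
    for s in hits:
        out.append((float(tot[s]), int(s), L, "none", int(s + L - 9)))

    if not allow_gaps or N < L + 1:
        return out

    n_off = C.shape[0]
    # miRNA bulge at 1-based position g; site [s, s+L-2], needs s >= 1
    if n_off >= 2:
        for g in range(1, L + 1):
            if g == 10:
                continue  # cleavage register would be unpaired
            suffix = tot - (C[:, g - 1] if g >= 1 else 0.0)
            s_idx = np.arange(1, n_off)
            sc = suffix[s_idx] + w[g - 1]
            if g >= 2:
                sc = sc + C[s_idx - 1, g - 2]
            ok = np.nonzero(sc <= cutoff)[0]
            for i in ok:
                s = int(s_idx[i])
                slice_pos = s + L - 9 if g < 10 else s + L - 10
                out.append((float(sc[i]), s, L - 1, "mirna_bulge", slice_pos))
    # transcript bulge between positions g and g+1; site [s, s+L], s <= N-L-1
    if N >= L + 1 and n_off >= 2:
        for g in range(1, L):
            gap_w = 2.0 if g <= SEED_END else 1.0
            s_idx = np.arange(0, n_off - 1)
            sc = (tot[s_idx] - C[s_idx, g - 1]) + gap_w + C[s_idx + 1, g - 1]
            ok = np.nonzero(sc <= cutoff)[0]
            for i in ok:
                s = int(s_idx[i])
                slice_pos = s + L - 9 if g <= 9 else s + L - 8
                out.append((float(sc[i]), s, L + 1, "target_bulge", slice_pos))
    return out


def _dedupe(cands: list[tuple[float, int, int, str, int]]):
    """Keep the best-scoring candidate among overlapping spans (ties: the
    leftmost, then the ungapped configuration)."""
    order = sorted(cands, key=lambda c: (c[0], c[1], c[3] != "none"))
    taken: list[tuple[int, int]] = []
    kept = []
    for score, s, length, gap, slice_pos in order:
        span = (s, s + length - 1)
        if any(span[0] <= e and span[1] >= b for b, e in taken):
            continue
        taken.append(span)
        kept.append((score, s, length, gap, slice_pos))
    kept.sort(key=lambda c: c[1])
    return kept


def scan_targets(mirnas: dict[str, str], transcripts: dict[str, str],
                 score_cutoff: float = SCORE_CUTOFF,
                 allow_gaps: bool = True) -> list[SiteHit]:
    """Scan every miRNA against every transcript.

    Reports each non-overlapping candidate site with score <= cutoff,
    keeping the best score among overlapping configurations.
    """
    if not transcripts:
        raise ValueError("no transcripts to scan")
    tx_codes = {tid: _encode(seq) for tid, seq in transcripts.items()}
    hits: list[SiteHit] = []
    for mid in sorted(mirnas):
        m = _encode(validate_mirna(mirnas[mid]))
        for tid in sorted(tx_codes):
            cands = _scan_codes(m, tx_codes[tid], score_cutoff, allow_gaps)
            for score, s, length, gap, slice_pos in _dedupe(cands):
                hits.append(SiteHit(
                    mirna_id=mid, transcript_id=tid, slice_pos=slice_pos,
                    score=score, start=s + 1, end=s + length, gap=gap))
    return hits


# -- degradome support ---------------------------------------------------------

def categorize_site(profile: dict[str, dict[int, int]], transcript: str,
                    position: int, length: int | None = None) -> int | None:
    """Degradome category of a position: 4 if its count is exactly 1; else 0
    for the unique transcript-wide maximum, 1 for a tied maximum, 2 above the
    per-position median, 3 otherwise; None when no read starts there."""
    tx = profile.get(transcript, {})
    if position < 1 or (length is not None and position > length):
        raise ValueError(f"position {position} outside transcript {transcript}")
    count = tx.get(position, 0)
    if count == 0:
        return None
    if count == 1:
        return 4
    counts = list(tx.values())
    mx = max(counts)
    if count == mx:
        return 0 if counts.count(mx) == 1 else 1
    return 2 if count > median(counts) else 3


def categorize_hits(hits: list[SiteHit],
                    profile: dict[str, dict[int, int]]) -> list[SiteHit]:
    """Attach degradome categories; hits without a supporting read keep None."""
    return [replace(h, category=categorize_site(profile, h.transcript_id,
                                                h.slice_pos)) for h in hits]


class _ProfileStats:
    """Per-transcript pileup summaries reused across many shuffle scans."""

    def __init__(self, profile: dict[str, dict[int, int]]):
        self.stats = {}
        for tid, counts in profile.items():
            vals = list(counts.values())
            mx = max(vals)
            self.stats[tid] = (counts, mx, vals.count(mx), median(vals))

    def category(self, tid: str, pos: int) -> int | None:
        if tid not in self.stats:
            return None
        counts, mx, n_at_max, med = self.stats[tid]
        c = counts.get(pos, 0)
        if c == 0:
            return None
        if c == 1:
            return 4
        if c == mx:
            return 0 if n_at_max == 1 else 1
        return 2 if c > med else 3


def site_pvalue(hit: SiteHit, mirna: str, transcripts: dict[str, str],
                profile: dict[str, dict[int, int]],
                n_shuffles: int = N_SHUFFLES, seed: int = 0,
                allow_gaps: bool = True) -> float:
    """Empirical significance of a categorized hit.

    Each of ``n_shuffles`` mononucleotide shuffles of the miRNA is scanned
    over the whole transcript set; a shuffle succeeds when it finds any site
    with score <= the observed score whose slice position has degradome
    category <= the observed category.  p = (1 + successes) / (1 + shuffles).
    """
    if n_shuffles < 19:
        raise ValueError("need at least 19 shuffles for p-value resolution at 0.05")
    if hit.category is None:
        raise ValueError("hit has no degradome category; cannot assign a p-value")
    rng = np.random.default_rng(seed)
    m = _encode(validate_mirna(mirna))
    tx_codes = {tid: _encode(seq) for tid, seq in transcripts.items()}
    stats = _ProfileStats(profile)
    successes = 0
    for _ in range(n_shuffles):
        shuf = rng.permutation(m)
        found = False
        for tid, codes in tx_codes.items():
            for score, s, length, gap, slice_pos in _scan_codes(
                    shuf, codes, hit.score, allow_gaps):
                cat = stats.category(tid, slice_pos)
                if cat is not None and cat <= hit.category:
                    found = True
                    break
            if found:
                break
        successes += found
    return (1 + successes) / (1 + n_shuffles)


def annotate_pvalues(hits: list[SiteHit], mirnas: dict[str, str],
                     transcripts: dict[str, str],
                     profile: dict[str, dict[int, int]],
                     n_shuffles: int = N_SHUFFLES, seed: int = 0) -> list[SiteHit]:
    """site_pvalue over a hit list (hits without a category are passed through)."""
    out = []
    for i, h in enumerate(hits):
        if h.category is None:
            out.append(h)
            continue
        p = site_pvalue(h, mirnas[h.mirna_id], transcripts, profile,
                        n_shuffles=n_shuffles, seed=seed + i)
        out.append(replace(h, pvalue=p))
    return out


# -- reporting -----------------------------------------------------------------

def tplot_table(transcript_id: str, profile: dict[str, dict[int, int]],
                hits: list[SiteHit]):
    """Long-form T-plot table: one row per position with reads, plus one
    slice-site flag column per hit on this transcript."""
    import pandas as pd

    counts = profile.get(transcript_id, {})
    tx_hits = [h for h in hits if h.transcript_id == transcript_id]
    rows = []
    for pos in sorted(counts):
        row = {"position": pos, "count": counts[pos]}
        for h in tx_hits:
            row[f"{h.mirna_id}@{h.slice_pos}"] = int(pos == h.slice_pos)
        rows.append(row)
    cols = ["position", "count"] + [f"{h.mirna_id}@{h.slice_pos}" for h in tx_hits]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class MergedLibraries:
    per_library: dict[str, list[SiteHit]]
    merged: list[SiteHit]
    overlap: dict[str, int]  # venn region -> count, keys like "shoot&merged"


def merge_profiles(profiles: dict[str, dict[str, dict[int, int]]]
                   ) -> dict[str, dict[int, int]]:
    """Position-wise sum of several degradome pileups."""
    merged: dict[str, dict[int, int]] = {}
    for prof in profiles.values():
        for tid, counts in prof.items():
            dst = merged.setdefault(tid, {})
            for pos, c in counts.items():
                dst[pos] = dst.get(pos, 0) + c
    return merged


def merge_library_hits(mirnas: dict[str, str], transcripts: dict[str, str],
                       profiles: dict[str, dict[str, dict[int, int]]],
                       score_cutoff: float = SCORE_CUTOFF) -> MergedLibraries:
    """Per-library and merged-library supported sites with their venn overlap.

    Each library's pileup is categorized independently; the merged profile is
    the position-wise sum, rescanned and recategorized.  A site is "supported"
    when it has a degradome category.  Overlap counts are keyed by the sorted
    '&'-joined member names of each venn region.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 libraries to merge")
    base_hits = scan_targets(mirnas, transcripts, score_cutoff)
    per_library = {
        lib: [h for h in categorize_hits(base_hits, prof) if h.category is not None]
        for lib, prof in profiles.items()
    }
    merged_profile = merge_profiles(profiles)
    merged = [h for h in categorize_hits(base_hits, merged_profile)
              if h.category is not None]

    def key(h: SiteHit):
        return (h.mirna_id, h.transcript_id, h.slice_pos)

    sets = {lib: {key(h) for h in hs} for lib, hs in per_library.items()}
    sets["merged"] = {key(h) for h in merged}
    names = sorted(sets)
    union = set().union(*sets.values())
    overlap: dict[str, int] = {}
    for site in union:
        members = tuple(n for n in names if site in sets[n])
        label = "&".join(members)
        overlap[label] = overlap.get(label, 0) + 1
    return MergedLibraries(per_library=per_library, merged=merged, overlap=overlap)
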