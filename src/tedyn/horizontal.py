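"""Horizontal-transfer screening: near-identity search across species and
the synonymous-rate (dS) contrast.

A TE family found at >= 99.5% identity over >= 90% of its canonical
length in a species diverged by millions of years is a horizontal-
transfer (HT) candidate: vertical inheritance would have let it drift
apart at least as fast as the synonymous sites of orthologous genes.
The contrast is made explicit by comparing the dS distribution of TE
ORFs against that of single-copy orthologues with a Mann-Whitney U test,
FDR-corrected across families.

dS uses the Nei-Gojobori (1986) counting method: synonymous/
nonsynonymous sites averaged per codon, differences averaged over
shortest substitution pathways (stop-crossing paths excluded), with the
Jukes-Cantor correction dS = -3/4 ln(1 - 4/3 pS).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import bh_fdr, mann_whitney, revcomp

__all__ = [
    "HTCandidate",
    "DsEstimate",
    "SearchHit",
    "search_te_in_genome",
    "screen_ht",
    "ds_ng86",
    "compare_ds",
    "compare_ds_table",
]

_CODON_TABLE = {}
_BASES = "TCAG"
_AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_a, _b, _c) in enumerate(itertools.product(_BASES, _BASES, _BASES)):
    _CODON_TABLE[_a + _b + _c] = _AMINO[_i]


@dataclass(frozen=True)
class SearchHit:
    family: str
    species: str
    identity: float        # percent
    coverage: float        # percent of canonical length
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str


@dataclass(frozen=True)
class HTCandidate:
    family: str
    species: str
    best_identity: float
    query_coverage: float
    is_candidate: bool


@dataclass(frozen=True)
class DsEstimate:
    pair_id: str
    S: float     # synonymous sites (codon-averaged)
    N: float     # nonsynonymous sites
    Sd: float    # synonymous differences
    Nd: float
    pS: float
    dS: float


# ---------------------------------------------------------------------------
# seed-and-extend search

def _banded_edit_distance(a: str, b: str, band: int) -> int:
    """Global (Needleman-Wunsch) edit distance restricted to a diagonal band.

    Unit costs; the band is widened by the length difference so the
    optimum stays reachable.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return max(n, m)
    w = band + abs(n - m)
    ea = np.frombuffer(a.encode(), dtype=np.uint8)
    eb = np.frombuffer(b.encode(), dtype=np.uint8)
    inf = n + m + 1
    prev = np.full(m + 1, inf, dtype=np.int32)
    lo_prev = 0
    hi_prev = min(m, w)
    prev[lo_prev : hi_prev + 1] = np.arange(lo_prev, hi_prev + 1)
    for i in range(1, n + 1):
        lo = max(0, i - w)
        hi = min(m, i + w)
        cur = np.full(m + 1, inf, dtype=np.int32)
        js = np.arange(lo, hi + 1)
        # substitution / match
        sub = np.full(js.size, inf, dtype=np.int32)
        valid = js >= 1
        sub[valid] = prev[js[valid] - 1] + (eb[js[valid] - 1] != ea[i - 1])
        # deletion from a (vertical)
        dele = prev[js] + 1
        best = np.minimum(sub, dele)
        # insertion (horizontal): cur[j] = min_{j'<=j} best[j'] + (j - j')
        cur[js] = js + np.minimum.accumulate(best - js)
        prev = cur
    return int(prev[m])


def _best_diagonal_chain(query: str, target: str, k: int, band: int):
    """Anchor k-mer matches, cluster by diagonal, keep the cluster covering
    the most query bases.  Returns (q_lo, q_hi, t_lo, t_hi) or None."""
    index: dict[str, list[int]] = {}
    for q in range(len(query) - k + 1):
        index.setdefault(query[q : q + k], []).append(q)
    anchors: list[tuple[int, int]] = []  # (diag, q)
    step = 1
    for t in range(0, len(target) - k + 1, step):
        for q in index.get(target[t : t + k], ()):
            anchors.append((t - q, q))
    if not anchors:
        return None
    diags = np.array([a[0] for a in sorted(anchors)])
    qpos = np.array([a[1] for a in sorted(anchors)])
    # sliding window over diagonals within the band; score = query span covered
    best = None
    j = 0
    for i in range(len(diags)):
        if i and diags[i] == diags[i - 1] and j >= i:
            continue
        while j < len(diags) and diags[j] - diags[i] <= band:
            j += 1
        qs = qpos[i:j]
        q_lo, q_hi = int(qs.min()), int(qs.max()) + k
        if best is None or q_hi - q_lo > best[0]:
            best = (q_hi - q_lo, q_lo, q_hi, int(diags[i]))
    _, q_lo, q_hi, diag = best
    t_lo = max(q_lo + diag, 0)
    t_hi = min(q_hi + diag, len(target))
    return q_lo, q_hi, t_lo, t_hi


def search_te_in_genome(
    consensus: str,
    genome: str,
    kmer: int = 15,
    band: int = 16,
    family: str = "",
    species: str = "",
    search_revcomp: bool = True,
) -> SearchHit | None:
    """Best local placement of a consensus in a genome by seed-and-extend.

    Exact k-mer anchors are chained on a common diagonal; the chained
    query span is extended to the full consensus where the genome
    allows, and aligned with a banded global alignment.  Identity =
    (columns - edit distance) / columns; coverage = aligned consensus
    span / canonical length.  No anchors -> no hit (None).
    """
    if len(consensus) < kmer:
        raise ValueError("consensus shorter than k-mer size")
    best: SearchHit | None = None
    for strand, target in (("+", genome), ("-", revcomp(genome)) if search_revcomp else (("+", genome),)):
        chain = _best_diagonal_chain(consensus, target, kmer, band)
        if chain is None:
            continue
        q_lo, q_hi, t_lo, t_hi = chain
        # extend to the whole consensus where the target allows
        ext_left = min(q_lo, t_lo)
        ext_right = min(len(consensus) - q_hi, len(target) - t_hi)
        q_lo -= ext_left
        t_lo -= ext_left
        q_hi += ext_right
        t_hi += ext_right
        a = consensus[q_lo:q_hi]
        b = target[t_lo:t_hi]
        dist = _banded_edit_distance(a, b, band)
        cols = max(len(a), len(b))
        identity = 100.0 * (cols - dist) / cols
        coverage = 100.0 * (q_hi - q_lo) / len(consensus)
        hit = SearchHit(family, species, identity, coverage, q_lo, q_hi, t_lo, t_hi, strand)
        if best is None or hit.identity * hit.coverage > best.identity * best.coverage:
            best = hit
    return best


def screen_ht(
    hits: list[SearchHit] | pd.DataFrame,
    min_identity: float = 99.5,
    min_coverage: float = 90.0,
) -> pd.DataFrame:
    """Flag per-family per-species HT candidates at the identity/coverage
    thresholds (boundary inclusive)."""
    if isinstance(hits, list):
        df = pd.DataFrame(
            [
                {"family": h.family, "species": h.species, "best_identity": h.identity,
                 "query_coverage": h.coverage}
                for h in hits
            ]
        )
    else:
        df = hits.copy()
    df["is_candidate"] = (df["best_identity"] >= min_identity) & (df["query_coverage"] >= min_coverage)
    return df


# ---------------------------------------------------------------------------
# NG86 dS

def _syn_fraction(codon: str, pos: int) -> float:
    aa = _CODON_TABLE[codon]
    syn = 0
    for base in "ACGT":
        if base == codon[pos]:
            continue
        alt = codon[:pos] + base + codon[pos + 1 :]
        if _CODON_TABLE[alt] == aa:  # changes to stops count as nonsynonymous
            syn += 1
    return syn / 3.0


def _codon_sites(codon: str) -> tuple[float, float]:
    s = sum(_syn_fraction(codon, p) for p in range(3))
    return s, 3.0 - s


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous differences over shortest
    substitution pathways between two codons; pathways through stop
    codons are excluded (all-blocked falls back to all pathways)."""
    positions = [p for p in range(3) if c1[p] != c2[p]]
    if not positions:
        return 0.0, 0.0

    def walk(order) -> tuple[float, float] | None:
        cur = c1
        sd = nd = 0.0
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if _CODON_TABLE[nxt] == "*" and nxt != c2:
                return None
            if _CODON_TABLE[cur] == "*" or _CODON_TABLE[nxt] == "*":
                nd += 1.0  # involves a stop codon: count as nonsynonymous
            elif _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    paths = [walk(order) for order in itertools.permutations(positions)]
    valid = [p for p in paths if p is not None]
    if not valid:
        valid = [(0.0, float(len(positions)))]  # every path crosses a stop: count as nonsynonymous
    sd = float(np.mean([v[0] for v in valid]))
    nd = float(np.mean([v[1] for v in valid]))
    return sd, nd


def ds_ng86(seq_a: str, seq_b: str, pair_id: str = "") -> DsEstimate:
    """Nei-Gojobori dS with Jukes-Cantor correction for an aligned coding
    pair (length divisible by 3, no internal stops in the reference
    frame; codons with gaps or ambiguity are skipped)."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    if len(seq_a) % 3:
        raise ValueError("alignment length must be divisible by 3")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    S = N = Sd = Nd = 0.0
    n_codons = len(seq_a) // 3
    for i in range(n_codons):
        ca = seq_a[3 * i : 3 * i + 3]
        cb = seq_b[3 * i : 3 * i + 3]
        if any(ch not in "ACGT" for ch in ca + cb):
            continue
        if _CODON_TABLE[ca] == "*" or _CODON_TABLE[cb] == "*":
            if i == n_codons - 1:
                continue  # terminal stop: not a coding site
            raise ValueError(f"internal stop codon at codon {i}")
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _pathway_diffs(ca, cb)
        Sd += sd
        Nd += nd
    if S == 0:
        raise ValueError("no synonymous sites in alignment")
    pS = Sd / S
    if pS >= 0.75:
        raise ValueError(f"synonymous saturation: pS = {pS:.3f} >= 3/4")
    dS = -0.75 * np.log(1.0 - 4.0 * pS / 3.0)
    return DsEstimate(pair_id=pair_id, S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, dS=float(dS))


# ---------------------------------------------------------------------------
# dS contrast

def compare_ds(te_ds, gene_ds) -> tuple[float, float]:
    """Two-sided Mann-Whitney U of TE dS values against the orthologue
    background (exact for small samples, normal + tie correction
    otherwise).  Returns (U, p)."""
    return mann_whitney(te_ds, gene_ds, exact_max=8)


def compare_ds_table(te_ds_by_family: dict[str, list[float]], gene_ds: list[float]) -> pd.DataFrame:
    """Per-family dS contrast with Benjamini-Hochberg correction across
    families."""
    rows = []
    for fam, values in te_ds_by_family.items():
        u, p = compare_ds(values, gene_ds)
        rows.append({"family": fam, "n_te": len(values), "U": u, "p": p,
                     "median_te_ds": float(np.median(values))})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_fdr(df["p"])
    return df
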