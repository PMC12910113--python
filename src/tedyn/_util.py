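"""Shared low-level helpers: sequence codecs, RNG derivation, rank statistics."""

from __future__ import annotations

import numpy as np
from scipy import stats

# A,C,G,T -> 0,1,2,3
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def encode_seq(seq: str) -> np.ndarray:
    """Encode an ACGT string to a uint8 array (A=0,C=1,G=2,T=3).

    Raises ValueError on any other character.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    enc = _CODE[raw]
    if (enc == 255).any():
        bad = chr(raw[enc == 255][0])
        raise ValueError(f"non-ACGT character in sequence: {bad!r}")
    return enc


def decode_seq(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def rng_for(seed: int, *tags: int) -> np.random.Generator:
    """Deterministic child generator for (seed, tags).

    Keeps every derived stream reproducible and independent of call order.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *map(int, tags)]))


def mann_whitney(x, y, exact_max: int = 20) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact null distribution when both samples are small (<= exact_max),
    normal approximation with tie correction otherwise.  Fully tied data
    returns p = 1 by contract.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return x.size * y.size / 2.0, 1.0
    exact = min(x.size, y.size) <= exact_max and max(x.size, y.size) <= 1000
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return stats.false_discovery_control(p, method="bh")
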