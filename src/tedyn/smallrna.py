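"""piRNA selection, exact consensus mapping, nucleotide biases and the
ping-pong signature.

Reads of 23-29 nt are treated as piRNAs and mapped to TE family
consensus sequences requiring a perfect match (an exact substring of the
consensus for sense reads, of its reverse complement for antisense).
The ping-pong amplification loop leaves an excess of sense/antisense
read pairs whose 5' ends overlap by exactly 10 nt; its strength is
summarized as Z10, the 10-nt overlap pair count standardized against the
background offsets (1-20 nt excluding 10, sample standard deviation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import revcomp

__all__ = [
    "PingPongResult",
    "filter_and_map",
    "nucleotide_bias",
    "ping_pong_signature",
    "rpm_normalize",
]

DEFAULT_BACKGROUND = tuple(o for o in range(1, 21) if o != 10)


@dataclass
class PingPongResult:
    family: str
    overlap_histogram: dict[int, float]
    z10: float | None
    frac_1U_sense: float | None
    frac_1U_antisense: float | None
    frac_10A_sense: float | None
    sense_rpm: float | None = None
    antisense_rpm: float | None = None


def filter_and_map(
    reads: pd.DataFrame,
    library: dict[str, str],
    min_len: int = 23,
    max_len: int = 29,
) -> pd.DataFrame:
    """Keep 23-29-nt reads and map them exactly to consensus sequences.

    ``reads`` needs columns ``sequence`` and ``count`` (multiplicity).
    A read maps to a family iff it occurs verbatim in the consensus
    (sense) or in its reverse complement (antisense); a multi-family
    mapper is recorded once per family.  Returns one row per (read,
    family) with the 0-based consensus coordinate of the 5' end.
    """
    if not library:
        raise ValueError("empty consensus library")
    seqs = {
        fam: (cons.sequence if hasattr(cons, "sequence") else cons)
        for fam, cons in library.items()
    }
    rows = []
    for read in reads.itertuples():
        seq = read.sequence
        n = len(seq)
        if not (min_len <= n <= max_len):
            continue
        count = int(getattr(read, "count", 1))
        rc = revcomp(seq)
        for fam, cons in seqs.items():
            i = cons.find(seq)
            if i >= 0:
                rows.append((seq, count, fam, "sense", i, n))
                continue  # a read matching both orientations is pathological; first wins
            j = cons.find(rc)
            if j >= 0:
                # antisense: 5' end sits at the downstream end on consensus coords
                rows.append((seq, count, fam, "antisense", j + n - 1, n))
    return pd.DataFrame(rows, columns=["sequence", "count", "family", "strand", "pos5", "length"])


def nucleotide_bias(reads: pd.DataFrame) -> tuple[float | None, float | None]:
    """Multiplicity-weighted fraction of reads with U (T) at position 1
    and A at position 10, in read orientation.

    Empty input yields (None, None) -- missing, not zero.
    """
    if len(reads) == 0:
        return None, None
    w = reads["count"].to_numpy(float)
    first = reads["sequence"].str[0].to_numpy()
    frac_1u = float(w[first == "T"].sum() / w.sum())
    long_enough = reads["sequence"].str.len() >= 10
    if not long_enough.any():
        return frac_1u, None
    w10 = w[long_enough.to_numpy()]
    tenth = reads.loc[long_enough, "sequence"].str[9].to_numpy()
    frac_10a = float(w10[tenth == "A"].sum() / w10.sum())
    return frac_1u, frac_10a


def _pair_counts(sense: pd.DataFrame, antisense: pd.DataFrame, max_overlap: int) -> dict[int, float]:
    """Multiplicity-weighted (sense, antisense) pair counts by 5'-5' overlap.

    An overlap of o nt means the antisense 5' end lies at sense 5' + o - 1
    on consensus coordinates; for o <= 20 < read length the read intervals
    necessarily intersect.
    """
    if sense.empty or antisense.empty:
        return {o: 0.0 for o in range(1, max_overlap + 1)}
    size = int(max(sense["pos5"].max(), antisense["pos5"].max())) + 2
    ws = np.zeros(size)
    wa = np.zeros(size)
    np.add.at(ws, sense["pos5"].to_numpy(int), sense["count"].to_numpy(float))
    np.add.at(wa, antisense["pos5"].to_numpy(int), antisense["count"].to_numpy(float))
    out = {}
    for o in range(1, max_overlap + 1):
        shift = o - 1
        if shift >= size:
            out[o] = 0.0
            continue
        # 5'-5' separation of opposite-strand reads, symmetric in strand labels
        n = float(np.dot(ws[: size - shift], wa[shift:]))
        if shift > 0:
            n += float(np.dot(wa[: size - shift], ws[shift:]))
        out[o] = n
    return out


def ping_pong_signature(
    mapped: pd.DataFrame,
    family: str | None = None,
    background_offsets: tuple[int, ...] = DEFAULT_BACKGROUND,
    max_overlap: int = 20,
    total_mapped_reads: float | None = None,
) -> PingPongResult:
    """Overlap histogram, Z10 and nucleotide biases for one family.

    Z10 = (n10 - mean(background)) / sample-sd(background).  A zero
    background sd yields Z10 = 0 when the histogram is flat, +inf when
    n10 exceeds the background.  No opposite-strand pairs at any offset
    -> Z10 is None (undefined).
    """
    df = mapped if family is None else mapped[mapped["family"] == family]
    fam = family or (df["family"].iloc[0] if len(df) else "NA")
    sense = df[df["strand"] == "sense"]
    anti = df[df["strand"] == "antisense"]
    hist = _pair_counts(sense, anti, max_overlap)
    bg = np.array([hist[o] for o in background_offsets if o in hist], dtype=float)
    n10 = hist.get(10, 0.0)
    if sum(hist.values()) == 0:
        z10 = None
    else:
        sd = bg.std(ddof=1) if bg.size > 1 else 0.0
        if sd == 0:
            z10 = 0.0 if n10 == bg.mean() else math.inf
        else:
            z10 = float((n10 - bg.mean()) / sd)
    s1u, s10a = nucleotide_bias(sense)
    a1u, _ = nucleotide_bias(anti)
    sense_rpm = antisense_rpm = None
    if total_mapped_reads:
        sense_rpm = rpm_normalize(float(sense["count"].sum()), total_mapped_reads)
        antisense_rpm = rpm_normalize(float(anti["count"].sum()), total_mapped_reads)
    return PingPongResult(
        family=fam,
        overlap_histogram=hist,
        z10=z10,
        frac_1U_sense=s1u,
        frac_1U_antisense=a1u,
        frac_10A_sense=s10a,
        sense_rpm=sense_rpm,
        antisense_rpm=antisense_rpm,
    )


def rpm_normalize(count: float, total_mapped_reads: float) -> float:
    """Reads per million mapped reads."""
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be > 0")
    return count * 1e6 / total_mapped_reads
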