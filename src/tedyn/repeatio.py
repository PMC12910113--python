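"""RepeatMasker-style hit parsing, filtering, defragmentation and copy classification.

A genomic TE copy is often reported as several fragments (hits) split by
nested insertions or deletions.  This module chains fragments of the same
family/contig/strand whose genomic gap and consensus-coordinate
progression are mutually consistent into single copies, then classifies
each copy's length class against the family consensus (full-length iff
>=90% of the canonical length, intact families only) and assesses ORF
integrity (complete iff an ATG-initiated, stop-free, in-frame stretch
covers >=90% of the canonical ORF with the domain structure preserved).

Coordinates are 0-based half-open internally; the RepeatMasker ``.out``
dialect (1-based inclusive, 'C' for minus strand, parenthesized
"remaining" fields) is converted on IO.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .landscape import SaturationError, kimura_distance

__all__ = [
    "ORFModel",
    "TEConsensus",
    "TEHit",
    "TECopy",
    "ORFAssessment",
    "parse_rm_out",
    "write_rm_out",
    "low_complexity_intervals",
    "filter_hits",
    "defragment",
    "classify_copy_length",
    "assess_orf_integrity",
    "annotate_kimura",
    "copies_to_frame",
]

STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ORFModel:
    """Canonical ORF on a consensus: [start, end) including the stop codon."""

    start: int
    end: int
    domain_intervals: tuple[tuple[int, int], ...] = ()

    @property
    def n_codons(self) -> int:
        # coding codons, terminal stop excluded
        return (self.end - self.start) // 3 - 1


@dataclass
class TEConsensus:
    """A curated family's canonical sequence."""

    family: str
    sequence: str
    subclass: str = "LTR"            # one of DNA, RC, LINE, LTR, PLE
    superfamily: str = "unknown"
    status: str = "intact"           # intact | partial | remnant
    orfs: tuple[ORFModel, ...] = ()

    @property
    def canonical_length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        for orf in self.orfs:
            if not (0 <= orf.start < orf.end <= len(self.sequence)):
                raise ValueError(f"ORF {orf} outside consensus {self.family}")


@dataclass(frozen=True)
class TEHit:
    contig: str
    genome_start: int   # 0-based half-open
    genome_end: int
    strand: str         # '+' or '-'
    family: str
    consensus_start: int
    consensus_end: int
    percent_divergence: float
    score: float = 0.0
    hit_id: int = 0

    def __post_init__(self) -> None:
        if self.genome_start >= self.genome_end:
            raise ValueError("hit with empty genomic span")
        if not 0.0 <= self.percent_divergence <= 100.0:
            raise ValueError("percent divergence outside [0, 100]")

    @property
    def length(self) -> int:
        return self.genome_end - self.genome_start


@dataclass
class TECopy:
    copy_id: str
    family: str
    contig: str
    start: int
    end: int
    strand: str
    hit_ids: tuple[int, ...]
    copy_length: int                 # sum of member hit lengths, bp
    consensus_start: int
    consensus_end: int
    length_fraction: float | None = None
    length_class: str | None = None  # full_length | truncated
    K: float | None = None           # Kimura distance, percent scale
    wave_cluster: int | None = None


@dataclass(frozen=True)
class ORFAssessment:
    copy_id: str
    orf_index: int
    fraction_of_canonical_orf: float
    domains_intact: bool
    status: str                      # complete | disrupted | not_assessed
    truncated_overlap: bool = False


# ---------------------------------------------------------------------------
# .out IO

def parse_rm_out(path) -> list[TEHit]:
    """Parse a RepeatMasker ``.out`` table into hits.

    Tolerates the two header lines and blank lines.  Malformed data lines
    raise with their line number.  1-based inclusive file coordinates are
    converted to 0-based half-open; 'C' lines yield strand '-' with
    consensus coordinates normalized to ascending order.
    """
    hits: list[TEHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if fields[0] in {"SW", "score"}:  # header lines
                continue
            try:
                score = float(fields[0])
                div = float(fields[1])
                contig = fields[4]
                qbeg, qend = int(fields[5]), int(fields[6])
                orient = fields[8]
                family = fields[9]
                if orient == "C":
                    # (left) end begin
                    cend = int(fields[12])
                    cbeg = int(fields[13])
                    strand = "-"
                else:
                    cbeg = int(fields[11])
                    cend = int(fields[12])
                    strand = "+"
                hits.append(
                    TEHit(
                        contig=contig,
                        genome_start=qbeg - 1,
                        genome_end=qend,
                        strand=strand,
                        family=family,
                        consensus_start=cbeg - 1,
                        consensus_end=cend,
                        percent_divergence=div,
                        score=score,
                        hit_id=len(hits),
                    )
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"malformed .out line {lineno}: {line.rstrip()!r}") from exc
    return hits


def write_rm_out(hits: list[TEHit], path, consensus_lengths: dict[str, int] | None = None) -> None:
    """Write hits in the RepeatMasker ``.out`` dialect."""
    consensus_lengths = consensus_lengths or {}
    with open(path, "w") as fh:
        fh.write(
            "   SW  perc perc perc  query     position in query    matching"
            "  repeat            position in repeat\n"
            "score  div. del. ins.  sequence  begin end    (left)  repeat"
            "  class/family      begin end   (left)  ID\n\n"
        )
        for h in hits:
            left_q = 0
            clen = consensus_lengths.get(h.family, h.consensus_end)
            left_c = clen - h.consensus_end
            if h.strand == "+":
                cons = f"{h.consensus_start + 1} {h.consensus_end} ({left_c})"
                orient = "+"
            else:
                cons = f"({left_c}) {h.consensus_end} {h.consensus_start + 1}"
                orient = "C"
            fh.write(
                f"{h.score:.0f} {h.percent_divergence:.1f} 0.0 0.0 {h.contig} "
                f"{h.genome_start + 1} {h.genome_end} ({left_q}) {orient} {h.family} "
                f"Unspecified {cons} {h.hit_id}\n"
            )


# ---------------------------------------------------------------------------
# filtering

def low_complexity_intervals(seq: str, window: int = 64, threshold: float = 1.2) -> list[tuple[int, int]]:
    """Windowed dinucleotide-entropy screen for low-complexity stretches.

    Windows whose dinucleotide Shannon entropy (nats) falls below
    ``threshold`` are flagged; adjacent flagged windows are merged.
    Random sequence has entropy ~ln(16) ~ 2.77, mono/dinucleotide repeats
    fall well below 1.2.
    """
    n = len(seq)
    flagged: list[tuple[int, int]] = []
    for start in range(0, max(n - window + 1, 1), window // 2):
        sub = seq[start : start + window]
        if len(sub) < 8:
            break
        counts: dict[str, int] = {}
        for i in range(len(sub) - 1):
            d = sub[i : i + 2]
            counts[d] = counts.get(d, 0) + 1
        tot = sum(counts.values())
        ent = -sum((c / tot) * math.log(c / tot) for c in counts.values())
        if ent < threshold:
            flagged.append((start, min(start + window, n)))
    merged: list[tuple[int, int]] = []
    for s, e in flagged:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _overlap_bp(start: int, end: int, intervals) -> int:
    tot = 0
    for s, e in intervals:
        tot += max(0, min(end, e) - max(start, s))
    return tot


def filter_hits(
    hits: list[TEHit],
    low_complexity: dict[str, list[tuple[int, int]]] | None = None,
    min_identity: float = 90.0,
    min_len: int = 50,
    max_low_complexity_overlap: float = 0.5,
) -> list[TEHit]:
    """Retain hits with identity strictly >``min_identity``%, length strictly
    >``min_len`` bp and low-complexity overlap strictly <50% of hit length."""
    low_complexity = low_complexity or {}
    kept = []
    for h in hits:
        if 100.0 - h.percent_divergence <= min_identity:
            continue
        if h.length <= min_len:
            continue
        lc = _overlap_bp(h.genome_start, h.genome_end, low_complexity.get(h.contig, ()))
        if lc / h.length >= max_low_complexity_overlap:
            continue
        kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# defragmentation

def _chainable(prev: TEHit, nxt: TEHit, insert_tolerance: int, cap: int) -> bool:
    gap = nxt.genome_start - prev.genome_end
    if gap < 0:
        return False
    if prev.strand == "+":
        cons_gap = nxt.consensus_start - prev.consensus_end
    else:
        cons_gap = prev.consensus_start - nxt.consensus_end
    if cons_gap < 0:  # consensus intervals must be ordered, non-overlapping
        return False
    return gap <= min(insert_tolerance * max(cons_gap, 1), cap)


def defragment(hits: list[TEHit], insert_tolerance: int = 11, cap: int = 5000) -> list[TECopy]:
    """Chain same-family/contig/strand fragments into copies.

    Fragments merge when the genomic gap is consistent with the missing
    consensus span (gap <= insert_tolerance * consensus gap, capped) and
    consensus intervals progress without overlap along the strand.
    Every hit ends up in exactly one copy.
    """
    groups: dict[tuple[str, str, str], list[TEHit]] = {}
    for h in hits:
        groups.setdefault((h.contig, h.family, h.strand), []).append(h)
    copies: list[TECopy] = []
    for (contig, family, strand), members in sorted(groups.items()):
        members.sort(key=lambda h: h.genome_start)
        chain: list[TEHit] = []
        def flush():
            if not chain:
                return
            copies.append(
                TECopy(
                    copy_id=f"{family}:{contig}:{chain[0].genome_start}",
                    family=family,
                    contig=contig,
                    start=chain[0].genome_start,
                    end=chain[-1].genome_end,
                    strand=strand,
                    hit_ids=tuple(h.hit_id for h in chain),
                    copy_length=sum(h.length for h in chain),
                    consensus_start=min(h.consensus_start for h in chain),
                    consensus_end=max(h.consensus_end for h in chain),
                )
            )
        for h in members:
            if chain and _chainable(chain[-1], h, insert_tolerance, cap):
                chain.append(h)
            else:
                flush()
                chain = [h]
        flush()
    copies.sort(key=lambda c: (c.contig, c.start))
    return copies


# ---------------------------------------------------------------------------
# classification

def classify_copy_length(copy: TECopy, consensus: TEConsensus) -> str:
    """'full_length' iff length fraction >= 0.9 and the family is intact.

    Partial and remnant families are by definition considered truncated,
    whatever the fraction.
    """
    if copy.family != consensus.family:
        raise ValueError(f"copy family {copy.family} does not match consensus {consensus.family}")
    frac = copy.copy_length / consensus.canonical_length
    copy.length_fraction = frac
    cls = "full_length" if (frac >= 0.9 and consensus.status == "intact") else "truncated"
    copy.length_class = cls
    return cls


def _scan_orf(copy_seq: str, cons_offset: int, orf: ORFModel) -> tuple[float, bool, bool]:
    """Longest ATG-initiated in-frame stop-free stretch within the copy's
    overlap with a canonical ORF.

    ``cons_offset`` is the consensus coordinate of ``copy_seq[0]``.
    Returns (fraction of canonical coding length, domains_intact,
    truncated_overlap).
    """
    cs, ce = cons_offset, cons_offset + len(copy_seq)
    lo = max(orf.start, cs)
    hi = min(orf.end, ce)
    truncated = lo > orf.start or hi < orf.end
    if hi - lo < 3:
        return 0.0, False, True
    # align to the canonical reading frame
    lo += (orf.start - lo) % 3
    codon_starts = range(lo, hi - 2, 3)
    codons = [copy_seq[s - cs : s - cs + 3] for s in codon_starts]
    is_stop = [c in STOPS for c in codons]
    is_atg = [c == "ATG" for c in codons]
    # stop positions in consensus coords (codon start), within the overlap
    stop_cons = {s for s, st in zip(codon_starts, is_stop) if st}

    best = 0
    run_start = 0
    n = len(codons)
    i = 0
    while i <= n:
        if i == n or is_stop[i]:
            # run of stop-free codons [run_start, i)
            first_atg = next((j for j in range(run_start, i) if is_atg[j]), None)
            if first_atg is not None:
                best = max(best, i - first_atg)
            run_start = i + 1
        i += 1
    canonical = orf.n_codons
    fraction = best / canonical if canonical > 0 else 0.0

    domains_ok = True
    for ds, de in orf.domain_intervals:
        if ds < cs or de > ce:
            domains_ok = False
            break
        if any(ds <= s < de for s in stop_cons):
            domains_ok = False
            break
    return fraction, domains_ok, truncated


def assess_orf_integrity(
    copy_seq: str,
    consensus: TEConsensus,
    cons_offset: int,
    copy_id: str = "",
) -> list[ORFAssessment]:
    """Assess each canonical ORF against the positioned copy sequence.

    The copy is assumed positionally aligned to the consensus
    (substitutions only), with ``cons_offset`` the consensus coordinate
    of its first base.  Remnant families are not assessed.
    """
    out: list[ORFAssessment] = []
    for i, orf in enumerate(consensus.orfs):
        if consensus.status == "remnant":
            out.append(ORFAssessment(copy_id, i, 0.0, False, "not_assessed"))
            continue
        frac, dom_ok, trunc = _scan_orf(copy_seq, cons_offset, orf)
        status = "complete" if (frac >= 0.9 and dom_ok) else "disrupted"
        out.append(ORFAssessment(copy_id, i, frac, dom_ok, status, truncated_overlap=trunc))
    return out


def annotate_kimura(copy_seq: str, consensus_segment: str) -> float | None:
    """Kimura distance (percent) of a copy against its consensus segment.

    Returns None on saturation (excluded from landscapes, counted apart).
    """
    try:
        return 100.0 * kimura_distance(copy_seq, consensus_segment).K
    except SaturationError:
        return None


def copies_to_frame(copies: list[TECopy]) -> pd.DataFrame:
    rows = [
        {
            "copy_id": c.copy_id,
            "family": c.family,
            "contig": c.contig,
            "start": c.start,
            "end": c.end,
            "strand": c.strand,
            "copy_length": c.copy_length,
            "consensus_start": c.consensus_start,
            "consensus_end": c.consensus_end,
            "length_fraction": c.length_fraction,
            "length_class": c.length_class,
            "K": c.K,
            "wave_cluster": c.wave_cluster,
        }
        for c in copies
    ]
    return pd.DataFrame(rows)
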