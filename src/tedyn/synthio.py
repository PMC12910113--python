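"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the data underlying a multi-strain TE-dynamics
study: a curated consensus library, a genome carrying TE copies planted
in temporal waves of Kimura divergence, RepeatMasker-style hit tables,
ovarian small-RNA reads with a 1U bias and 10-nt ping-pong overlaps,
per-strain ChIP/input signal tracks with distance-decaying enrichment
around a subset of insertions, per-strain insertion-call tables with
shared/unique loci and TE allele frequencies, RNA-seq-like count tables,
and a multi-species sequence panel with controlled synonymous divergence
for horizontal-transfer screening.

Every generator is fully deterministic under its seed.  The mutation
model is substitution-only (two-parameter model with transition bias);
alignments therefore stay positional and divergence oracles are exact.
All wave parameters are on the percent Kimura scale; the low-level
sampler ``mutate_k2p`` takes substitutions/site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import decode_seq, encode_seq, revcomp, rng_for
from .repeatio import ORFModel, STOPS, TEConsensus, TEHit, assess_orf_integrity
from .epigenome import SignalTrack

__all__ = [
    "SimParams",
    "SpeciesPanel",
    "gen_library",
    "mutate_k2p",
    "build_genome",
    "sim_small_rnas",
    "sim_tracks",
    "sim_strain_calls",
    "sim_expression",
    "sim_species_panel",
    "write_fasta",
]

_SUBCLASS_P = {"DNA": 0.14, "RC": 0.05, "LINE": 0.30, "LTR": 0.50, "PLE": 0.01}
_SUPERFAMILIES = {
    "DNA": ["Tc1-Mariner"],
    "RC": ["Helitron"],
    "LINE": ["Jockey", "R1", "CR1", "I"],
    "LTR": ["Gypsy", "Bel-Pao", "Copia"],
    "PLE": ["Penelope"],
}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS
]


@dataclass
class SimParams:
    """Study conditions for the synthetic data.

    Wave means/sds are percent Kimura distance; the defaults place a
    recent wave (K <= 1), a speciation-associated wave near K = 11 and an
    ancient wave near K = 25, mirroring the three mobilization epochs the
    pipeline is meant to resolve.
    """

    seed: int = 0
    n_families: int = 30
    genome_length: int = 2_000_000
    waves: tuple[tuple[float, float, float], ...] = (
        (0.5, 0.3, 1 / 3),
        (11.0, 2.0, 1 / 3),
        (25.0, 3.0, 1 / 3),
    )
    kappa: float = 2.0
    truncation_prob_by_wave: tuple[float, ...] = (0.5, 0.7, 0.9)
    orf_disruption_prob: float = 0.5
    pingpong_fraction: float = 0.5
    bias_1U: float = 0.8
    spread_amplitude: float = 5.0
    spread_decay: float = 1500.0
    shared_insertion_fraction: float = 0.3
    n_strains: int = 5
    ht_identity: float = 0.999
    gene_dS_mean: float = 0.15
    copies_per_family: int = 10
    status_weights: tuple[float, float, float] = (0.44, 0.26, 0.30)
    spread_prob_full_length: float = 0.5

    def __post_init__(self) -> None:
        probs = {
            "orf_disruption_prob": self.orf_disruption_prob,
            "pingpong_fraction": self.pingpong_fraction,
            "bias_1U": self.bias_1U,
            "shared_insertion_fraction": self.shared_insertion_fraction,
            "spread_prob_full_length": self.spread_prob_full_length,
            "ht_identity": self.ht_identity,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for p in self.truncation_prob_by_wave:
            if not 0.0 <= p <= 1.0:
                raise ValueError("truncation probabilities must be in [0, 1]")
        if len(self.truncation_prob_by_wave) != len(self.waves):
            raise ValueError("need one truncation probability per wave")
        w = sum(w for _, _, w in self.waves)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"wave weights must sum to 1, got {w}")
        if any(m < 0 for m, _, _ in self.waves):
            raise ValueError("wave K means must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.spread_decay <= 0:
            raise ValueError("spread_decay must be > 0")

    @property
    def strains(self) -> list[str]:
        return [f"strain_{i + 1}" for i in range(self.n_strains)]


# ---------------------------------------------------------------------------
# library

def _random_orf_sequence(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def gen_library(params: SimParams, names: list[str] | None = None) -> dict[str, TEConsensus]:
    """Generate a consensus library keyed by family name.

    Each intact/partial family carries one ORF starting with ATG and
    ending at an in-frame stop, with two annotated domain intervals.
    """
    if params.n_families < 1:
        raise ValueError("n_families must be >= 1")
    if names is None:
        names = [f"FAM{i + 1:03d}" for i in range(params.n_families)]
    if len(names) != params.n_families:
        raise ValueError("names length must equal n_families")
    if len(set(names)) != len(names):
        raise ValueError("duplicate family names")
    rng = rng_for(params.seed, 1)
    subclasses = list(_SUBCLASS_P)
    sub_p = np.array([_SUBCLASS_P[s] for s in subclasses])
    statuses = ["intact", "partial", "remnant"]
    library: dict[str, TEConsensus] = {}
    for name in names:
        sub = subclasses[rng.choice(len(subclasses), p=sub_p)]
        sup = _SUPERFAMILIES[sub][rng.integers(len(_SUPERFAMILIES[sub]))]
        status = statuses[rng.choice(3, p=np.asarray(params.status_weights))]
        length = int(rng.integers(2400, 5200))
        seq = decode_seq(rng.integers(0, 4, size=length).astype(np.uint8))
        orfs: tuple[ORFModel, ...] = ()
        if status != "remnant":
            orf_start = int(rng.integers(length // 10, length // 5))
            n_codons = int((length - orf_start - length // 10) * 0.9) // 3 - 2
            body = _random_orf_sequence(rng, n_codons - 1)
            stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
            orf_seq = "ATG" + body + stop
            orf_end = orf_start + len(orf_seq)
            seq = seq[:orf_start] + orf_seq + seq[orf_end:]
            third = (orf_end - orf_start) // 9 * 3
            domains = (
                (orf_start + third, orf_start + 2 * third),
                (orf_start + 2 * third + 3, min(orf_start + 3 * third, orf_end - 3)),
            )
            orfs = (ORFModel(orf_start, orf_end, domains),)
        library[name] = TEConsensus(
            family=name, sequence=seq, subclass=sub, superfamily=sup, status=status, orfs=orfs
        )
    return library


# ---------------------------------------------------------------------------
# K2P mutation sampler

def k2p_site_probs(K: float, kappa: float) -> tuple[float, float]:
    """Per-site transition and total transversion probabilities of the
    two-parameter model at divergence K (substitutions/site) with
    transition/transversion rate ratio kappa."""
    if K < 0:
        raise ValueError("K must be >= 0")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    bt = K / (kappa + 2.0)      # beta * t
    at = kappa * bt             # alpha * t
    p_ts = 0.25 + 0.25 * np.exp(-4.0 * bt) - 0.5 * np.exp(-2.0 * (at + bt))
    p_tv = 0.5 - 0.5 * np.exp(-4.0 * bt)
    return float(p_ts), float(p_tv)


# transition partner and the two transversion partners per base code
_TS = np.array([2, 3, 0, 1], dtype=np.uint8)        # A<->G, C<->T
_TV1 = np.array([1, 0, 1, 0], dtype=np.uint8)        # A->C, C->A, G->C, T->A
_TV2 = np.array([3, 2, 3, 2], dtype=np.uint8)        # A->T, C->G, G->T, T->G


def mutate_k2p(seq: str, K: float, kappa: float = 2.0, seed: int | np.random.Generator = 0) -> str:
    """Mutate a sequence to expected divergence K (substitutions/site)
    under the two-parameter model.  Substitutions only; output length
    equals input length."""
    enc = encode_seq(seq)
    p_ts, p_tv = k2p_site_probs(K, kappa)
    rng = seed if isinstance(seed, np.random.Generator) else rng_for(seed, 2)
    u = rng.random(enc.size)
    out = enc.copy()
    m_ts = u < p_ts
    m_tv1 = (u >= p_ts) & (u < p_ts + p_tv / 2)
    m_tv2 = (u >= p_ts + p_tv / 2) & (u < p_ts + p_tv)
    out[m_ts] = _TS[enc[m_ts]]
    out[m_tv1] = _TV1[enc[m_tv1]]
    out[m_tv2] = _TV2[enc[m_tv2]]
    return decode_seq(out)


# ---------------------------------------------------------------------------
# genome

def _allocate_waves(n_families: int, waves, rng: np.random.Generator) -> np.ndarray:
    weights = np.array([w for _, _, w in waves])
    counts = np.floor(weights * n_families).astype(int)
    while counts.sum() < n_families:
        counts[np.argmax(weights * n_families - counts)] += 1
    assign = np.repeat(np.arange(len(waves)), counts)
    rng.shuffle(assign)
    return assign


def _realized_orf_status(copy_seq: str, consensus: TEConsensus, cons_start: int) -> str:
    if consensus.status == "remnant" or not consensus.orfs:
        return "not_assessed"
    assessments = assess_orf_integrity(copy_seq, consensus, cons_start)
    return "complete" if all(a.status == "complete" for a in assessments) else "disrupted"


def build_genome(
    params: SimParams, library: dict[str, TEConsensus]
) -> tuple[dict[str, str], pd.DataFrame, list[TEHit]]:
    """Plant wave-structured TE copies in a random background genome.

    Returns (genome by contig, truth table, RepeatMasker-style hits).
    Truncated copies are cut from a uniformly chosen end; the truth table
    records the realized length fraction and realized ORF status of every
    planted copy.
    """
    if not library:
        raise ValueError("library is empty")
    rng = rng_for(params.seed, 3)
    families = list(library.values())
    wave_of_family = _allocate_waves(len(families), params.waves, rng)

    segments: list[tuple[str, dict]] = []  # (sequence, truth-row stub)
    for fam, wave in zip(families, wave_of_family):
        mean_k, sd_k, _ = params.waves[wave]
        for _ in range(params.copies_per_family):
            target_k = max(float(rng.normal(mean_k, sd_k)), 0.0)
            mutated = mutate_k2p(fam.sequence, target_k / 100.0, params.kappa, rng)
            if rng.random() < params.orf_disruption_prob and fam.orfs:
                orf = fam.orfs[0]
                codon = orf.start + 3 * int(0.4 * orf.n_codons)
                mutated = mutated[:codon] + "TAA" + mutated[codon + 3 :]
            L = len(mutated)
            if rng.random() < params.truncation_prob_by_wave[wave]:
                frac = float(rng.uniform(0.2, 0.85))
                keep = max(int(round(frac * L)), 50)
                if rng.random() < 0.5:
                    cs, ce = 0, keep
                else:
                    cs, ce = L - keep, L
            else:
                cs, ce = 0, L
            copy_seq = mutated[cs:ce]
            strand = "+" if rng.random() < 0.5 else "-"
            mism = sum(a != b for a, b in zip(copy_seq, fam.sequence[cs:ce]))
            segments.append(
                (
                    copy_seq if strand == "+" else revcomp(copy_seq),
                    {
                        "family": fam.family,
                        "wave": int(wave) + 1,
                        "target_K": target_k,
                        "strand": strand,
                        "consensus_start": cs,
                        "consensus_end": ce,
                        "length_fraction": (ce - cs) / L,
                        "orf_status": _realized_orf_status(copy_seq, fam, cs),
                        "raw_divergence": 100.0 * mism / (ce - cs),
                    },
                )
            )
    rng.shuffle(segments)

    total_te = sum(len(s) for s, _ in segments)
    background = params.genome_length - total_te
    n_gaps = len(segments) + 1
    if background < n_gaps:
        raise ValueError(
            f"insufficient genome space: need > {total_te + n_gaps} bp, "
            f"genome_length is {params.genome_length} (short by {total_te + n_gaps - params.genome_length} bp)"
        )
    gaps = rng.multinomial(background - n_gaps, np.full(n_gaps, 1.0 / n_gaps)) + 1
    bg = decode_seq(rng.integers(0, 4, size=background).astype(np.uint8))

    contig = "contig_1"
    parts: list[str] = []
    pos = 0
    bg_used = 0
    rows = []
    hits: list[TEHit] = []
    for i, (seg, stub) in enumerate(segments):
        parts.append(bg[bg_used : bg_used + gaps[i]])
        bg_used += gaps[i]
        pos += gaps[i]
        start, end = pos, pos + len(seg)
        fam = library[stub["family"]]
        is_fl = stub["length_fraction"] >= 0.9 and fam.status == "intact"
        rows.append(
            {
                "copy_id": f"planted_{i:05d}",
                "contig": contig,
                "start": start,
                "end": end,
                **stub,
                "full_length": is_fl,
                "spread_planted": bool(is_fl and rng.random() < params.spread_prob_full_length),
                "strains": "",
            }
        )
        hits.append(
            TEHit(
                contig=contig,
                genome_start=start,
                genome_end=end,
                strand=stub["strand"],
                family=stub["family"],
                consensus_start=stub["consensus_start"],
                consensus_end=stub["consensus_end"],
                percent_divergence=round(stub["raw_divergence"], 2),
                score=float(end - start),
                hit_id=i,
            )
        )
        parts.append(seg)
        pos = end
    parts.append(bg[bg_used : bg_used + gaps[-1]])
    genome = {contig: "".join(parts)}
    truth = pd.DataFrame(rows)
    assert int((truth["end"] - truth["start"]).sum()) == total_te
    return genome, truth, hits


# ---------------------------------------------------------------------------
# small RNAs

def sim_small_rnas(
    family: TEConsensus | str,
    n: int,
    pingpong_fraction: float,
    bias_1U: float,
    seed: int = 0,
    contaminant_fraction: float = 0.0,
    length_range: tuple[int, int] = (23, 29),
) -> pd.DataFrame:
    """Simulate a small-RNA read table for one family.

    Half the piRNA-sized reads are sense, half antisense.  A
    ``pingpong_fraction`` of antisense reads is placed so its 5' end
    overlaps a sense read's 5' end by exactly 10 nt.  The 5' base is U
    (T in DNA space) with probability ``bias_1U``; reads are exact
    substrings of the consensus (sense) or its reverse complement
    (antisense), so downstream 0-mismatch mapping recovers them.
    """
    if not 0.0 <= pingpong_fraction <= 1.0:
        raise ValueError("pingpong_fraction must be in [0, 1]")
    if not 0.0 <= bias_1U <= 1.0:
        raise ValueError("bias_1U must be in [0, 1]")
    if n < 0:
        raise ValueError("n must be >= 0")
    cons = family.sequence if isinstance(family, TEConsensus) else family
    fam_name = family.family if isinstance(family, TEConsensus) else "FAM"
    cols = ["sequence", "count", "family", "strand", "pos5", "length", "contaminant"]
    if n == 0:
        return pd.DataFrame(columns=cols)
    rng = rng_for(seed, 4)
    lmin, lmax = length_range
    L = len(cons)
    if L < lmax + 20:
        raise ValueError("consensus too short for read simulation")
    arr = np.frombuffer(cons.encode(), dtype=np.uint8)
    max_start = L - lmax - 1
    is_t = arr[: max_start + 1] == ord("T")
    t_starts = np.flatnonzero(is_t)
    nt_starts = np.flatnonzero(~is_t)
    p5_lo = lmax  # antisense 5' ends leave room for the longest read
    anti_ok = np.arange(p5_lo, L)
    is_a = arr[anti_ok] == ord("A")
    a_p5 = anti_ok[is_a]
    na_p5 = anti_ok[~is_a]

    n_cont = int(round(n * contaminant_fraction))
    n_pi = n - n_cont
    n_sense = n_pi // 2
    n_anti = n_pi - n_sense
    n_pp = int(round(pingpong_fraction * n_anti))

    rows: list[tuple] = []
    sense_pos: list[int] = []
    for _ in range(n_sense):
        length = int(rng.integers(lmin, lmax + 1))
        pool = t_starts if (rng.random() < bias_1U and t_starts.size) else nt_starts
        s = int(pool[rng.integers(pool.size)])
        rows.append((cons[s : s + length], 1, fam_name, "sense", s, length, False))
        sense_pos.append(s)
    sense_pos_arr = np.array(sense_pos, dtype=int)

    # ping-pong partners: antisense 5' at sense 5' + 9 (10-nt 5'-5' overlap);
    # the partner's 1U corresponds to an A on the consensus at that position,
    # which simultaneously plants the sense-side 10A signal.
    for _ in range(n_pp):
        want_a = rng.random() < bias_1U
        s = None
        for _try in range(100):
            cand = int(sense_pos_arr[rng.integers(sense_pos_arr.size)])
            if cand + 9 < lmin - 1:
                continue
            if (arr[cand + 9] == ord("A")) == want_a:
                s = cand
                break
        if s is None:
            s = int(sense_pos_arr[rng.integers(sense_pos_arr.size)])
        p5 = s + 9
        length = int(rng.integers(lmin, min(lmax, p5 + 1) + 1))
        lo = p5 - length + 1
        rows.append((revcomp(cons[lo : p5 + 1]), 1, fam_name, "antisense", p5, length, False))

    for _ in range(n_anti - n_pp):
        length = int(rng.integers(lmin, lmax + 1))
        pool = a_p5 if (rng.random() < bias_1U and a_p5.size) else na_p5
        p5 = int(pool[rng.integers(pool.size)])
        lo = p5 - length + 1
        rows.append((revcomp(cons[lo : p5 + 1]), 1, fam_name, "antisense", p5, length, False))

    for _ in range(n_cont):
        length = int(rng.choice([18, 19, 20, 21, 22, 30, 31, 32]))
        s = int(rng.integers(0, L - length))
        if rng.random() < 0.5:
            rows.append((cons[s : s + length], 1, fam_name, "sense", s, length, True))
        else:
            rows.append((revcomp(cons[s : s + length]), 1, fam_name, "antisense", s + length - 1, length, True))
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# ChIP-style tracks

def sim_tracks(
    insertions: pd.DataFrame,
    strains: list[str],
    contig_lengths: dict[str, int],
    spread_amplitude: float = 5.0,
    spread_decay: float = 1500.0,
    seed: int = 0,
    bin_size: int = 10,
    pad: int = 6000,
    baseline: float = 1.0,
    noise_sd: float = 0.2,
) -> dict[str, tuple[SignalTrack, SignalTrack]]:
    """Per-strain (ChIP, input) bedGraph-semantics track pairs.

    Tracks cover ``pad`` bp around every insertion.  Around each
    ``spread_planted`` insertion, enrichment decaying as
    exp(-d / spread_decay) with distance d from the insertion edge is
    added -- only in strains listed as carrying the insertion.
    """
    if spread_decay <= 0:
        raise ValueError("spread_decay must be > 0")
    for _, ins in insertions.iterrows():
        clen = contig_lengths[ins["contig"]]
        if ins["start"] < 0 or ins["end"] > clen:
            raise ValueError(f"insertion {ins.get('copy_id', '?')} outside contig bounds")
    # merged bin-aligned regions per contig
    regions: dict[str, list[tuple[int, int]]] = {}
    for contig, grp in insertions.groupby("contig"):
        clen = contig_lengths[contig]
        ivs = sorted(
            (max(int(s) - pad, 0) // bin_size * bin_size, min(-(-min(int(e) + pad, clen) // bin_size) * bin_size, clen // bin_size * bin_size))
            for s, e in zip(grp["start"], grp["end"])
        )
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        regions[contig] = merged

    out: dict[str, tuple[SignalTrack, SignalTrack]] = {}
    for si, strain in enumerate(strains):
        rng = rng_for(seed, 5, si)
        chip_data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        inp_data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for contig, merged in regions.items():
            st = np.concatenate([np.arange(s, e, bin_size) for s, e in merged])
            centers = st + bin_size / 2.0
            chip = np.clip(baseline + rng.normal(0.0, noise_sd, st.size), 0, None)
            inp = np.clip(baseline + rng.normal(0.0, noise_sd, st.size), 0, None)
            sel = insertions[(insertions["contig"] == contig) & insertions["spread_planted"]]
            for ins in sel.itertuples():
                if strain not in str(ins.strains).split(","):
                    continue
                lo = np.searchsorted(centers, ins.start - pad)
                hi = np.searchsorted(centers, ins.end + pad)
                c = centers[lo:hi]
                d = np.maximum(np.maximum(ins.start - c, c - ins.end), 0.0)
                chip[lo:hi] += spread_amplitude * np.exp(-d / spread_decay)
            chip_data[contig] = (st, st + bin_size, chip)
            inp_data[contig] = (st, st + bin_size, inp)
        out[strain] = (SignalTrack(chip_data), SignalTrack(inp_data))
    return out


# ---------------------------------------------------------------------------
# strain insertion calls

def sim_strain_calls(
    truth: pd.DataFrame,
    shared_insertion_fraction: float,
    seed: int = 0,
    strains: list[str] | None = None,
    n_strains: int = 5,
    jitter: int = 20,
    het_prob: float = 0.15,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Assign strain membership to planted copies and emit per-strain calls.

    Shared calls appear at (jittered) identical loci in every strain;
    unique calls in exactly one strain.  TAF is drawn from a mixture
    concentrated near 1 with a heterozygous component below 0.7.
    """
    if strains is None:
        strains = [f"strain_{i + 1}" for i in range(n_strains)]
    if len(strains) < 2:
        raise ValueError("need >= 2 strains")
    if jitter >= 5000:
        raise ValueError("jitter >= 5 kb would alias the sharing window")
    if not 0.0 <= shared_insertion_fraction <= 1.0:
        raise ValueError("shared_insertion_fraction must be in [0, 1]")
    rng = rng_for(seed, 6)
    truth = truth.copy()
    membership: list[list[str]] = []
    for _ in range(len(truth)):
        if rng.random() < shared_insertion_fraction:
            membership.append(list(strains))
        else:
            membership.append([strains[rng.integers(len(strains))]])
    truth["strains"] = [",".join(m) for m in membership]
    truth["unique"] = [len(m) == 1 for m in membership]

    calls: dict[str, list[dict]] = {s: [] for s in strains}
    for row, members in zip(truth.itertuples(), membership):
        for strain in members:
            if rng.random() < het_prob:
                taf = float(rng.uniform(0.25, 0.65))
            else:
                taf = float(np.clip(1.0 - abs(rng.normal(0.0, 0.02)), 0.0, 1.0))
            pos = int(row.start + rng.integers(-jitter, jitter + 1)) if jitter else int(row.start)
            calls[strain].append(
                {
                    "strain": strain,
                    "contig": row.contig,
                    "position": max(pos, 0),
                    "family": row.family,
                    "insertion_length": int(row.end - row.start),
                    "length_fraction": float(row.length_fraction),
                    "taf": taf,
                    "copy_id": row.copy_id,
                }
            )
    tables = {s: pd.DataFrame(rows) for s, rows in calls.items()}
    return truth, tables


# ---------------------------------------------------------------------------
# expression counts

def sim_expression(
    truth: pd.DataFrame,
    effect_model: dict[int, float],
    seed: int = 0,
    strains: list[str] | None = None,
    n_genes: int = 150,
    reps: int = 2,
    dispersion: float = 0.1,
    per_copy_rate: float = 20.0,
    attach_fraction: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial gene and TE-family count tables.

    ``effect_model`` maps distance bin (kb, int) to the log2 fold-change
    planted on genes in that bin -- applied only in the strain carrying
    the nearby unique insertion.  TE-family means are proportional to the
    per-strain copy number.  Requires a truth table with strain
    membership (see :func:`sim_strain_calls`).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if "unique" not in truth.columns:
        raise ValueError("truth table lacks strain membership; run sim_strain_calls first")
    rng = rng_for(seed, 7)
    if strains is None:
        strains = sorted({s for m in truth["strains"] for s in str(m).split(",") if s})
    uniq = truth[truth["unique"]].reset_index(drop=True)
    gene_rows = []
    for g in range(n_genes):
        if len(uniq) and rng.random() < attach_fraction:
            ins = uniq.iloc[int(rng.integers(len(uniq)))]
            dist = float(rng.uniform(0, 5000))
            gene_rows.append(
                {
                    "gene_id": f"gene_{g:04d}",
                    "insertion_id": ins["copy_id"],
                    "carrier": ins["strains"],
                    "distance": dist,
                    "distance_bin": int(dist // 1000),
                }
            )
        else:
            gene_rows.append(
                {"gene_id": f"gene_{g:04d}", "insertion_id": None, "carrier": None,
                 "distance": np.nan, "distance_bin": -1}
            )
    gene_meta = pd.DataFrame(gene_rows)

    base = rng.lognormal(np.log(200.0), 0.8, size=n_genes)

    def nb(mean: np.ndarray) -> np.ndarray:
        if dispersion == 0:
            return rng.poisson(mean)
        lam = rng.gamma(1.0 / dispersion, mean * dispersion)
        return rng.poisson(lam)

    gene_counts = {}
    for strain in strains:
        mult = np.ones(n_genes)
        hit = (gene_meta["carrier"] == strain) & gene_meta["distance_bin"].isin(effect_model)
        if hit.any():
            fc = gene_meta.loc[hit, "distance_bin"].map(effect_model).to_numpy(float)
            mult[hit.to_numpy()] = 2.0 ** fc
        for r in range(reps):
            gene_counts[(strain, f"rep{r + 1}")] = nb(base * mult)
    gene_counts = pd.DataFrame(gene_counts, index=gene_meta["gene_id"])
    gene_counts.columns = pd.MultiIndex.from_tuples(gene_counts.columns, names=["strain", "rep"])

    families = sorted(truth["family"].unique())
    mem = truth["strains"].apply(lambda s: set(str(s).split(",")))
    te_counts = {}
    for strain in strains:
        has = mem.apply(lambda m: strain in m)
        mean = per_copy_rate * (
            truth.loc[has, "family"].value_counts().reindex(families).fillna(0).to_numpy(float)
        )
        for r in range(reps):
            te_counts[(strain, f"rep{r + 1}")] = nb(mean)
    te_counts = pd.DataFrame(te_counts, index=pd.Index(families, name="family"))
    te_counts.columns = pd.MultiIndex.from_tuples(te_counts.columns, names=["strain", "rep"])
    return gene_counts, te_counts, gene_meta


# ---------------------------------------------------------------------------
# species panel for horizontal-transfer screening

@dataclass
class SpeciesPanel:
    focal: str
    species: list[str]
    genomes: dict[str, str]
    te_coords: pd.DataFrame                      # species, family, start, end
    gene_alignments: dict[str, dict[str, str]]   # gene -> species (incl focal) -> sequence
    te_orf_alignments: dict[tuple[str, str], tuple[str, str]]  # (family, species) -> (focal ORF, species ORF)
    ht_families: set[str]


def _fix_stops(mutated: str, reference: str) -> str:
    """Revert any codon that mutated into a stop (keeps coding frames clean)."""
    out = list(mutated)
    for i in range(0, len(mutated) - 2, 3):
        if mutated[i : i + 3] in STOPS and reference[i : i + 3] not in STOPS:
            out[i : i + 3] = reference[i : i + 3]
    return "".join(out)


def sim_species_panel(
    library: dict[str, TEConsensus],
    ht_families: set[str] | list[str],
    gene_dS_mean: float = 0.15,
    seed: int = 0,
    species: list[str] | None = None,
    n_genes: int = 50,
    gene_codons: int = 300,
    kappa: float = 2.0,
    ht_identity: float = 0.999,
) -> SpeciesPanel:
    """Multi-species panel: orthologous genes diverged to a target dS,
    horizontally transferred families nearly unchanged (identity >=
    ``ht_identity``), vertical families diverged like genes."""
    if species is None:
        species = ["species_A", "species_B", "species_C", "species_D"]
    if not species:
        raise ValueError("empty species panel")
    ht_families = set(ht_families)
    unknown = ht_families - set(library)
    if unknown:
        raise ValueError(f"ht_families not in library: {sorted(unknown)}")
    rng = rng_for(seed, 8)
    focal = "focal"

    genes = {f"gene_{i:03d}": _random_orf_sequence(rng, gene_codons) for i in range(n_genes)}
    gene_alignments: dict[str, dict[str, str]] = {g: {focal: s} for g, s in genes.items()}
    for sp in species:
        for g, s in genes.items():
            mut = mutate_k2p(s, gene_dS_mean, kappa, rng)
            gene_alignments[g][sp] = _fix_stops(mut, s)

    genomes: dict[str, str] = {}
    coords = []
    te_orf_alignments: dict[tuple[str, str], tuple[str, str]] = {}
    ht_k = max(1.0 - ht_identity, 0.0)
    for sp in species:
        parts = [decode_seq(rng.integers(0, 4, size=8000).astype(np.uint8))]
        pos = 8000
        for fam in library.values():
            k = ht_k if fam.family in ht_families else gene_dS_mean
            copy = mutate_k2p(fam.sequence, k, kappa, rng)
            spacer = decode_seq(rng.integers(0, 4, size=500).astype(np.uint8))
            parts.extend([copy, spacer])
            coords.append({"species": sp, "family": fam.family, "start": pos, "end": pos + len(copy)})
            if fam.orfs:
                orf = max(fam.orfs, key=lambda o: o.end - o.start)
                a = fam.sequence[orf.start : orf.end - 3]  # drop terminal stop
                b = copy[orf.start : orf.end - 3]
                te_orf_alignments[(fam.family, sp)] = (a, _fix_stops(b, a))
            pos += len(copy) + 500
        genomes[sp] = "".join(parts)
    return SpeciesPanel(
        focal=focal,
        species=list(species),
        genomes=genomes,
        te_coords=pd.DataFrame(coords),
        gene_alignments=gene_alignments,
        te_orf_alignments=te_orf_alignments,
        ht_families=ht_families,
    )


# ---------------------------------------------------------------------------
# writers

def write_fasta(seqs: dict[str, str] | dict[str, TEConsensus], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            if isinstance(seq, TEConsensus):
                seq = seq.sequence
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
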