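"""Reproducible study protocols over synthetic data.

Each function runs one self-contained experiment: generate inputs with
the synthetic module at the study conditions, execute the corresponding
pipeline stage, and measure recovery against the generator's ground
truth or an independent oracle.  The analysis drivers, the acceptance
script and the test suite all call these, so the numbers they report are
produced by one code path.

Oracle helpers (brute-force counting, quadratic neighbour scans, full
dynamic programming) are deliberately simple, direct implementations
kept independent of the optimized code paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import epigenome, horizontal, insertions, landscape, repeatio, smallrna, synthio
from ._util import revcomp, rng_for

__all__ = [
    "kimura_brute_force",
    "kimura_oracle_study",
    "k2p_roundtrip_study",
    "wave_recovery_study",
    "classification_agreement_study",
    "pingpong_study",
    "spreading_study",
    "spreading_null_study",
    "unique_insertion_study",
    "ht_study",
    "worked_examples",
    "normalization_checks",
]


# ---------------------------------------------------------------------------
# oracles

def kimura_brute_force(a: str, b: str) -> float:
    """Independent K2P distance: per-column base classification in a plain
    loop, then the closed form."""
    purines = {"A", "G"}
    ts = tv = n = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if (x in purines) == (y in purines):
            ts += 1
        else:
            tv += 1
    p, q = ts / n, tv / n
    return -0.5 * math.log((1 - 2 * p - q) * math.sqrt(1 - 2 * q))


def unique_brute_force(calls: pd.DataFrame, window: int = 5000) -> np.ndarray:
    """Quadratic pairwise scan: a call is unique iff no other strain has a
    call within +/- window (inclusive) on the same contig."""
    n = len(calls)
    contig = calls["contig"].to_numpy()
    pos = calls["position"].to_numpy()
    strain = calls["strain"].to_numpy()
    uniq = np.ones(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j or strain[i] == strain[j] or contig[i] != contig[j]:
                continue
            if abs(int(pos[i]) - int(pos[j])) <= window:
                uniq[i] = False
                break
    return uniq


# ---------------------------------------------------------------------------
# divergence studies

def kimura_oracle_study(seed: int, n_pairs: int = 200, length: int = 1000) -> dict:
    """Implementation-vs-oracle agreement on random simulated alignments."""
    rng = rng_for(seed, 10)
    worst = 0.0
    for _ in range(n_pairs):
        a = synthio.gen_library(synthio.SimParams(seed=int(rng.integers(2**31)), n_families=1))
        seq = next(iter(a.values())).sequence[:length]
        k = float(rng.uniform(0.0, 0.4))
        b = synthio.mutate_k2p(seq, k, 2.0, int(rng.integers(2**31)))
        got = landscape.kimura_distance(seq, b).K
        worst = max(worst, abs(got - kimura_brute_force(seq, b)))
        worst = max(worst, abs(landscape.kimura_distance(seq, seq).K))
    return {"max_abs_error": worst, "n": n_pairs}


def k2p_roundtrip_study(
    seed: int,
    targets_percent: tuple[float, ...] = (0.5, 2.0, 5.0, 11.0, 25.0),
    n_copies: int = 100,
    length: int = 5000,
    kappa: float = 2.0,
) -> pd.DataFrame:
    """Mutate a 5-kb consensus to each target K and re-estimate; reports
    the median recovered K and its relative error per target."""
    rng = rng_for(seed, 11)
    cons = synthio.gen_library(synthio.SimParams(seed=seed, n_families=1))
    seq = next(iter(cons.values())).sequence
    seq = (seq * (length // len(seq) + 1))[:length]
    rows = []
    for target in targets_percent:
        ks = []
        for _ in range(n_copies):
            mut = synthio.mutate_k2p(seq, target / 100.0, kappa, int(rng.integers(2**31)))
            ks.append(100.0 * landscape.kimura_distance(seq, mut).K)
        med = float(np.median(ks))
        rows.append({"target_K": target, "median_K": med, "rel_error": abs(med - target) / target})
    return pd.DataFrame(rows)


def _copy_table_from_truth(genome: dict, truth: pd.DataFrame, hits, library) -> pd.DataFrame:
    """Defragment hits and annotate copies with Kimura distance and class."""
    contig_seq = genome
    copies = repeatio.defragment(hits)
    for c in copies:
        cons = library[c.family]
        repeatio.classify_copy_length(c, cons)
        seq = contig_seq[c.contig][c.start : c.end]
        if c.strand == "-":
            seq = revcomp(seq)
        c.K = repeatio.annotate_kimura(seq, cons.sequence[c.consensus_start : c.consensus_end])
    return repeatio.copies_to_frame(copies)


def wave_recovery_study(seed: int, params: synthio.SimParams | None = None) -> dict:
    """Simulate three mobilization waves across 30 families, rebuild the
    landscape from hits, cluster, and score recovery of the true waves."""
    params = params or synthio.SimParams(seed=seed)
    library = synthio.gen_library(params)
    genome, truth, hits = synthio.build_genome(params, library)
    df = _copy_table_from_truth(genome, truth, hits, library)
    ls = landscape.build_landscape(df, {f: c.subclass for f, c in library.items()})
    ls = landscape.cluster_waves(ls, seed=seed)
    true_wave = truth.groupby("family")["wave"].first()
    tab = pd.crosstab(true_wave, ls.cluster_of_family.reindex(true_wave.index))
    accuracy = float(tab.max(axis=1).sum() / tab.to_numpy().sum())
    modes = truth.groupby("wave")["target_K"].mean()
    return {
        "k_selected": int(ls.k_selected),
        "accuracy": accuracy,
        "n_families": int(len(true_wave)),
        "silhouette_by_k": ls.silhouette_by_k,
        "wave_mean_K": modes.to_dict(),
    }


def classification_agreement_study(seed: int) -> dict:
    """Pipeline-vs-truth agreement of length-class and ORF-completeness
    labels with no planted ORF disruption."""
    params = synthio.SimParams(seed=seed, orf_disruption_prob=0.0)
    library = synthio.gen_library(params)
    genome, truth, hits = synthio.build_genome(params, library)
    copies = repeatio.defragment(hits)
    copies.sort(key=lambda c: c.start)
    t = truth.sort_values("start").reset_index(drop=True)
    n = len_ok = orf_n = orf_ok = 0
    for c, row in zip(copies, t.itertuples()):
        cons = library[c.family]
        cls = repeatio.classify_copy_length(c, cons)
        n += 1
        len_ok += cls == ("full_length" if row.full_length else "truncated")
        if cons.status != "remnant" and cons.orfs:
            seq = genome[c.contig][c.start : c.end]
            if c.strand == "-":
                seq = revcomp(seq)
            got = (
                "complete"
                if all(a.status == "complete"
                       for a in repeatio.assess_orf_integrity(seq, cons, c.consensus_start))
                else "disrupted"
            )
            orf_n += 1
            orf_ok += got == row.orf_status
    return {
        "n_copies": n,
        "length_class_agreement": len_ok / n,
        "n_orf_assessed": orf_n,
        "orf_agreement": orf_ok / orf_n,
    }


# ---------------------------------------------------------------------------
# piRNA studies

def pingpong_study(
    seed: int,
    n_reads: int = 10_000,
    pingpong_fraction: float = 0.5,
    bias_1u: float = 0.8,
    n_null_seeds: int = 100,
) -> dict:
    """Planted ping-pong recovery plus a null calibration.

    The planted arm maps reads back to the consensus with the 0-mismatch
    mapper; the null arm (pingpong_fraction = 0) recomputes Z10 across
    ``n_null_seeds`` independent simulations.
    """
    library = synthio.gen_library(synthio.SimParams(seed=seed, n_families=1))
    cons = next(iter(library.values()))
    reads = synthio.sim_small_rnas(cons, n_reads, pingpong_fraction, bias_1u, seed=seed)
    mapped = smallrna.filter_and_map(reads, {cons.family: cons.sequence})
    res = smallrna.ping_pong_signature(mapped, total_mapped_reads=float(mapped["count"].sum()))
    bias_err = max(
        abs(res.frac_1U_sense - bias_1u), abs(res.frac_1U_antisense - bias_1u)
    )
    null_z = []
    for i in range(n_null_seeds):
        r = synthio.sim_small_rnas(cons, n_reads, 0.0, bias_1u, seed=seed * 1009 + i)
        null_z.append(smallrna.ping_pong_signature(r).z10)
    null_z = np.asarray(null_z, dtype=float)
    return {
        "z10_planted": float(res.z10),
        "bias_1U_error": float(bias_err),
        "null_frac_abs_z_lt2": float((np.abs(null_z) < 2).mean()),
        "n_reads": n_reads,
        "n_null_seeds": n_null_seeds,
    }


# ---------------------------------------------------------------------------
# spreading studies

def _spread_layout(seed: int, **overrides) -> synthio.SimParams:
    # sparse layout: isolated insertions so windows do not overlap neighbours
    defaults = dict(
        seed=seed,
        n_families=16,
        copies_per_family=12,
        genome_length=24_000_000,
        status_weights=(1.0, 0.0, 0.0),
        spread_prob_full_length=0.5,
        shared_insertion_fraction=0.0,
    )
    defaults.update(overrides)
    return synthio.SimParams(**defaults)


def spreading_study(seed: int) -> dict:
    """Sensitivity and extent of spreading detection with signal planted
    only at full-length insertions (decay 1500 bp, amplitude >> noise)."""
    params = _spread_layout(seed)
    library = synthio.gen_library(params)
    genome, truth, _ = synthio.build_genome(params, library)
    truth, _calls = synthio.sim_strain_calls(truth, params.shared_insertion_fraction, seed=seed,
                                             strains=params.strains)
    ins = truth[truth["unique"]].copy()
    clen = {c: len(s) for c, s in genome.items()}
    tracks = synthio.sim_tracks(ins, params.strains, clen,
                                params.spread_amplitude, params.spread_decay, seed=seed)
    # full-length and truncated insertions are analysed separately (their
    # multiple-testing families do not mix)
    res_fl = epigenome.spreading_analysis(tracks, ins[ins["full_length"]], contig_lengths=clen)
    res_tr = epigenome.spreading_analysis(tracks, ins[~ins["full_length"]], contig_lengths=clen)
    flags_fl = pd.Series({r.insertion_id: r.spreading for r in res_fl})
    extent = pd.Series({r.insertion_id: r.max_distance_kb for r in res_fl})
    flags_tr = pd.Series({r.insertion_id: r.spreading for r in res_tr})
    planted = ins.set_index("copy_id")["spread_planted"]
    pl = planted[planted].index.intersection(flags_fl.index)
    return {
        "sensitivity": float(flags_fl.loc[pl].mean()),
        "max_extent_windows": int(extent.loc[pl].max()),
        "n_planted": int(len(pl)),
        "truncated_flag_rate": float(flags_tr.mean()) if len(flags_tr) else 0.0,
        "n_truncated": int(len(flags_tr)),
    }


def spreading_null_study(seed: int, n_seeds: int = 100) -> dict:
    """False-positive rate of the spreading call with zero amplitude,
    pooled across independent simulations (BH FDR 0.05 within each)."""
    flagged = total = 0
    for i in range(n_seeds):
        s = seed * 997 + i
        params = _spread_layout(s, n_families=4, copies_per_family=5, genome_length=900_000)
        library = synthio.gen_library(params)
        genome, truth, _ = synthio.build_genome(params, library)
        truth, _calls = synthio.sim_strain_calls(truth, 0.0, seed=s, strains=params.strains)
        ins = truth[truth["unique"]].copy()
        clen = {c: len(x) for c, x in genome.items()}
        tracks = synthio.sim_tracks(ins, params.strains, clen, 0.0, params.spread_decay, seed=s)
        results = epigenome.spreading_analysis(tracks, ins, contig_lengths=clen)
        flagged += sum(r.spreading for r in results)
        total += len(results)
    return {"null_flag_rate": flagged / total, "n_insertions": total, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# insertion studies

def unique_insertion_study(
    seed: int, n_calls: int = 1000, n_strains: int = 5, shared_fraction: float = 0.3
) -> dict:
    """Oracle equality on random calls plus expected unique counts on
    generator output with known sharing fraction."""
    rng = rng_for(seed, 12)
    random_calls = pd.DataFrame(
        {
            "strain": rng.choice([f"strain_{i + 1}" for i in range(n_strains)], size=n_calls),
            "contig": rng.choice(["contig_1", "contig_2"], size=n_calls),
            "position": rng.integers(0, 2_000_000, size=n_calls),
        }
    )
    fast = insertions.unique_insertions(random_calls)["unique"].to_numpy()
    slow = unique_brute_force(random_calls)
    agreement = float((fast == slow).mean())

    params = synthio.SimParams(seed=seed, n_families=10, copies_per_family=10,
                               genome_length=1_200_000)
    library = synthio.gen_library(params)
    _genome, truth, _hits = synthio.build_genome(params, library)
    truth, calls = synthio.sim_strain_calls(truth, shared_fraction, seed=seed,
                                            n_strains=n_strains)
    all_calls = pd.concat(calls.values(), ignore_index=True)
    flagged = insertions.unique_insertions(all_calls)
    observed_unique = int(flagged["unique"].sum())
    n_planted = len(truth)
    expected = (1 - shared_fraction) * n_planted
    sd = math.sqrt(n_planted * shared_fraction * (1 - shared_fraction))
    return {
        "oracle_agreement": agreement,
        "n_random_calls": n_calls,
        "observed_unique": observed_unique,
        "expected_unique": expected,
        "binomial_z": (observed_unique - expected) / sd,
    }


# ---------------------------------------------------------------------------
# horizontal-transfer study

def ht_study(
    seed: int,
    n_ht: int = 3,
    n_vertical: int = 10,
    gene_ds_mean: float = 0.15,
    ht_identity: float = 0.999,
) -> dict:
    """End-to-end HT screen on a four-species panel: seed-and-extend
    search, threshold screen, and the dS contrast."""
    params = synthio.SimParams(seed=seed, n_families=n_ht + n_vertical,
                               status_weights=(1.0, 0.0, 0.0),
                               gene_dS_mean=gene_ds_mean, ht_identity=ht_identity)
    library = synthio.gen_library(params)
    ht_families = set(list(library)[:n_ht])
    panel = synthio.sim_species_panel(
        library, ht_families, gene_dS_mean=gene_ds_mean, seed=seed, ht_identity=ht_identity
    )
    hits = []
    for fam, cons in library.items():
        for sp in panel.species:
            h = horizontal.search_te_in_genome(
                cons.sequence, panel.genomes[sp], family=fam, species=sp
            )
            if h is not None:
                hits.append(h)
    screened = horizontal.screen_ht(hits)
    called = set(screened.loc[screened["is_candidate"], "family"])
    recall = len(called & ht_families) / len(ht_families)
    precision = len(called & ht_families) / len(called) if called else 0.0

    gene_ds = [
        horizontal.ds_ng86(aln["focal"], aln[sp]).dS
        for aln in panel.gene_alignments.values()
        for sp in panel.species
    ]
    te_ds_by_family = {
        fam: [
            horizontal.ds_ng86(*panel.te_orf_alignments[(fam, sp)]).dS
            for sp in panel.species
            if (fam, sp) in panel.te_orf_alignments
        ]
        for fam in sorted(ht_families)
    }
    contrast = horizontal.compare_ds_table(te_ds_by_family, gene_ds)
    return {
        "recall": recall,
        "precision": precision,
        "n_candidates": len(called),
        "gene_ds_median": float(np.median(gene_ds)),
        "max_contrast_q": float(contrast["q"].max()),
        "contrast": contrast,
    }


# ---------------------------------------------------------------------------
# closed-form checks

def worked_examples() -> dict:
    """The hand-checkable worked examples of the core statistics."""
    ds = horizontal.ds_ng86("GGG" * 10, "GGG" * 9 + "GGA")
    from ._util import mann_whitney

    _, p55 = mann_whitney([5, 5, 5, 5, 5], [1, 1, 1, 1, 1])
    assoc = epigenome.associate_spreading_downregulation(
        [True] * 40 + [False] * 60,
        [True] * 30 + [False] * 10 + [True] * 15 + [False] * 45,
    )
    k = landscape.kimura_distance("A" * 85 + "G" * 10 + "C" * 5, "A" * 100)
    return {
        "ng86_pS": ds.pS,
        "ng86_dS": ds.dS,
        "mwu_5v5_p": p55,
        "chi2_30_10_15_45": assoc.chi2,
        "kimura_10ts_5tv": k.K,
    }


def normalization_checks() -> dict:
    """RPKM/RPM closed forms and the four-group boundary grid."""
    from . import expression as expr

    counts = pd.DataFrame({"s": [100]}, index=["te"])
    rpkm = expr.rpkm_table(counts, pd.Series({"te": 2000}), pd.Series({"s": 10_000_000}))
    rpm = smallrna.rpm_normalize(50, 1_000_000)
    grid = {
        (2.0, 150.0): 1,
        (1.0, 150.0): 2,   # RPKM exactly 1: not expressed (strict >)
        (2.0, 99.0): 3,
        (1.0, 99.0): 4,
        (2.0, 100.0): 1,   # RPM exactly 100: piRNA-high (inclusive >=)
    }
    grid_ok = all(
        expr.classify_te_group(r, m).group == g for (r, m), g in grid.items()
    )
    return {
        "rpkm_100_2kb_10M": float(rpkm.iloc[0, 0]),
        "rpm_50_per_1M": rpm,
        "group_boundary_grid_ok": bool(grid_ok),
    }
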