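"""H3K9me2/3 enrichment around TE insertions, spreading calls and gene effects.

Silenced TE insertions can nucleate repressive H3K9 methylation that
spreads into flanking sequence and represses nearby genes.  Spreading is
called by comparing, window by window, the input-subtracted ChIP signal
of the one strain carrying an insertion against the per-bin mean signal
of the strains lacking it (Mann-Whitney per 1-kb flanking window,
Benjamini-Hochberg across all windows and insertions).  Gene effects are
quantified as log2 fold-changes of normalized expression, present vs
absent strains, stratified by distance bin and genomic feature context,
and the spreading/downregulation association is tested with a Pearson
chi-squared on the 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import bh_fdr, mann_whitney

__all__ = [
    "SignalTrack",
    "SpreadResult",
    "AssociationResult",
    "enrichment_matrix",
    "test_spreading",
    "spreading_analysis",
    "annotate_feature",
    "gene_effects_by_distance",
    "associate_spreading_downregulation",
]


@dataclass
class SignalTrack:
    """Piecewise-constant coverage with bedGraph semantics.

    ``data`` maps contig -> (starts, ends, values); intervals sorted and
    non-overlapping, 0-based half-open.  Uncovered positions read as 0.
    """

    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        clean = {}
        for contig, (s, e, v) in self.data.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=float)
            order = np.argsort(s)
            s, e, v = s[order], e[order], v[order]
            if (e[:-1] > s[1:]).any():
                raise ValueError(f"overlapping intervals on {contig}")
            if not np.isfinite(v).all():
                raise ValueError(f"non-finite values on {contig}")
            clean[contig] = (s, e, v)
        self.data = clean

    @classmethod
    def from_bedgraph(cls, path) -> "SignalTrack":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["contig", "start", "end", "value"], comment="#")
        data = {
            str(c): (g["start"].to_numpy(), g["end"].to_numpy(), g["value"].to_numpy())
            for c, g in df.groupby("contig")
        }
        return cls(data)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for contig in sorted(self.data):
                s, e, v = self.data[contig]
                for a, b, val in zip(s, e, v):
                    fh.write(f"{contig}\t{a}\t{b}\t{val:.6g}\n")

    def _integral(self, contig: str) -> tuple[np.ndarray, np.ndarray]:
        """Cached cumulative integral of the step function at breakpoints."""
        cache = getattr(self, "_integral_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_integral_cache", cache)
        if contig not in cache:
            s, e, v = self.data[contig]
            xp = np.empty(2 * s.size + 1)
            fp = np.empty_like(xp)
            xp[0], fp[0] = s[0] - 1.0, 0.0
            xp[1::2], xp[2::2] = s, e
            cum = np.concatenate([[0.0], np.cumsum(v * (e - s))])
            fp[1::2] = cum[:-1]
            fp[2::2] = cum[1:]
            cache[contig] = (xp, fp)
        return cache[contig]

    def bin_means(self, contig: str, start: int, end: int, bin_size: int) -> np.ndarray:
        """Coverage-weighted mean value per ``bin_size`` bin over [start, end)."""
        if contig not in self.data or self.data[contig][0].size == 0:
            return np.zeros(max((end - start) // bin_size, 0))
        xp, fp = self._integral(contig)
        edges = np.arange(start, end + 1, bin_size, dtype=float)
        integ = np.interp(edges, xp, fp, left=0.0, right=fp[-1])
        return np.diff(integ) / bin_size


def _window_bounds(start: int, end: int, flank: int, window: int) -> dict[int, tuple[int, int]]:
    """Flanking windows tiled outward from the insertion's outer edges.

    Labels are signed kb: -1 is the first upstream window next to the
    insertion, +1 the first downstream one.  TE body excluded.
    """
    n = flank // window
    out: dict[int, tuple[int, int]] = {}
    for k in range(1, n + 1):
        out[-k] = (start - k * window, start - (k - 1) * window)
        out[k] = (end + (k - 1) * window, end + k * window)
    return out


def enrichment_matrix(
    chip: SignalTrack,
    input_track: SignalTrack,
    insertions: pd.DataFrame,
    flank: int = 4000,
    window: int = 1000,
    bin_size: int = 10,
    contig_lengths: dict[str, int] | None = None,
) -> dict[str, dict[int, dict]]:
    """Per-insertion, per-window vectors of per-bin enrichment (chip - input).

    Negative enrichment is retained.  Windows extending past contig ends
    are truncated and flagged.  Returns
    ``{insertion_id: {window_label: {"values": array, "truncated": bool}}}``.
    """
    n = flank // window
    bins_per_window = window // bin_size
    out: dict[str, dict[int, dict]] = {}
    for row in insertions.itertuples():
        contig = row.contig
        clen = (contig_lengths or {}).get(contig)
        start, end = int(row.start), int(row.end)
        # one enrichment vector per flank, then sliced into windows
        up_lo = start - flank
        dn_hi = end + flank
        up = chip.bin_means(contig, up_lo, start, bin_size) - input_track.bin_means(
            contig, up_lo, start, bin_size
        )
        dn = chip.bin_means(contig, end, dn_hi, bin_size) - input_track.bin_means(
            contig, end, dn_hi, bin_size
        )
        windows = {}
        for k in range(1, n + 1):
            ws = start - k * window
            vals = up[(n - k) * bins_per_window : (n - k + 1) * bins_per_window]
            trunc = ws < 0
            if trunc and ws + window > 0:
                vals = vals[-(ws + window) // bin_size :] if ws + window >= bin_size else np.array([])
            elif trunc:
                vals = np.array([])
            windows[-k] = {"values": vals, "truncated": bool(trunc)}
            we = end + k * window
            vals = dn[(k - 1) * bins_per_window : k * bins_per_window]
            trunc = clen is not None and we > clen
            if trunc:
                keep = max(clen - (end + (k - 1) * window), 0) // bin_size
                vals = vals[:keep]
            windows[k] = {"values": vals, "truncated": bool(trunc)}
        out[getattr(row, "copy_id", None) or str(row.Index)] = windows
    return out


@dataclass
class SpreadResult:
    insertion_id: str
    p_by_window: dict[int, float]
    q_by_window: dict[int, float] = field(default_factory=dict)
    enrichment_present: dict[int, float] = field(default_factory=dict)
    enrichment_absent: dict[int, float] = field(default_factory=dict)
    spreading: bool = False
    max_distance_kb: int = 0
    direction_bias: str = "none"     # downstream | upstream | none


def test_spreading(
    present_windows: dict[int, np.ndarray],
    absent_windows_per_strain: list[dict[int, np.ndarray]],
    insertion_id: str = "",
    alpha: float = 0.05,
) -> SpreadResult:
    """Two-sided Mann-Whitney per flanking window, present strain vs the
    per-bin mean of the absent strains.

    q-values are not filled here; compute them jointly across insertions
    with :func:`spreading_analysis` (or call ``finalize_spread``).
    """
    if not absent_windows_per_strain:
        raise ValueError("need at least one absent strain as control")
    res = SpreadResult(insertion_id=insertion_id, p_by_window={})
    for label, pres in present_windows.items():
        controls = [a[label] for a in absent_windows_per_strain if label in a and len(a[label])]
        if len(pres) == 0 or not controls:
            continue
        m = min(len(pres), *(len(c) for c in controls))
        control = np.mean([c[:m] for c in controls], axis=0)
        _, p = mann_whitney(pres[:m], control)
        res.p_by_window[label] = p
        res.enrichment_present[label] = float(np.mean(pres[:m]))
        res.enrichment_absent[label] = float(np.mean(control))
    return res


def finalize_spread(results: list[SpreadResult], alpha: float = 0.05) -> list[SpreadResult]:
    """BH across all windows x insertions, then per-insertion spreading call.

    A window is significant when q < alpha and present > absent mean.
    Spreading extent is the farthest significant window contiguous from
    the insertion edge; direction bias compares the two flanks' numbers
    of significant windows.
    """
    keys = [(r, label) for r in results for label in sorted(r.p_by_window)]
    if not keys:
        return results
    q = bh_fdr([r.p_by_window[label] for r, label in keys])
    for (r, label), qv in zip(keys, q):
        r.q_by_window[label] = float(qv)
    for r in results:
        sig = {
            label
            for label in r.q_by_window
            if r.q_by_window[label] < alpha
            and r.enrichment_present[label] > r.enrichment_absent[label]
        }
        r.spreading = bool(sig)
        down = 0
        while (down + 1) in sig:
            down += 1
        up = 0
        while -(up + 1) in sig:
            up += 1
        r.max_distance_kb = max(down, up)
        n_down = sum(1 for s in sig if s > 0)
        n_up = sum(1 for s in sig if s < 0)
        if n_down > n_up:
            r.direction_bias = "downstream"
        elif n_up > n_down:
            r.direction_bias = "upstream"
        else:
            r.direction_bias = "none"
    return results


def spreading_analysis(
    tracks: dict[str, tuple[SignalTrack, SignalTrack]],
    insertions: pd.DataFrame,
    flank: int = 4000,
    window: int = 1000,
    bin_size: int = 10,
    alpha: float = 0.05,
    contig_lengths: dict[str, int] | None = None,
) -> list[SpreadResult]:
    """End-to-end spreading call for unique insertions.

    ``insertions`` needs columns contig, start, end, copy_id and
    ``strains`` (comma-joined carrier strains); strains absent from that
    list serve as the control group.
    """
    strains = list(tracks)
    mats = {
        strain: enrichment_matrix(chip, inp, insertions, flank, window, bin_size, contig_lengths)
        for strain, (chip, inp) in tracks.items()
    }
    results = []
    for row in insertions.itertuples():
        iid = row.copy_id
        carriers = [s for s in str(row.strains).split(",") if s]
        absents = [s for s in strains if s not in carriers]
        if not carriers or not absents:
            continue
        present = {l: w["values"] for l, w in mats[carriers[0]][iid].items() if not w["truncated"]}
        controls = [
            {l: w["values"] for l, w in mats[s][iid].items() if not w["truncated"]}
            for s in absents
        ]
        results.append(test_spreading(present, controls, insertion_id=iid, alpha=alpha))
    return finalize_spread(results, alpha=alpha)


# ---------------------------------------------------------------------------
# feature annotation

def annotate_feature(
    position: int,
    contig: str,
    genes: pd.DataFrame,
    exons: pd.DataFrame,
    promoter_len: int = 1000,
    intron_near: int = 1000,
) -> str:
    """Genomic feature context of an insertion point.

    ``genes``: gene_id, contig, strand, start, end (transcript span).
    ``exons``: gene_id, start, end, kind in {5UTR, CDS, 3UTR}.
    Precedence: exon (typed) > promoter (<= 1 kb upstream of TSS,
    strand-aware) > intron (near = within 1 kb of an exon of the same
    gene, else distal) > intergenic.  Overlapping genes resolve to the
    nearest TSS.
    """
    g = genes[genes["contig"] == contig]
    if g.empty:
        return "intergenic"
    tss = np.where(g["strand"] == "+", g["start"], g["end"] - 1)
    order = np.argsort(np.abs(tss - position), kind="stable")
    for gi in order:
        row = g.iloc[gi]
        ex = exons[exons["gene_id"] == row["gene_id"]]
        inside = (row["start"] <= position < row["end"])
        in_exon = ex[(ex["start"] <= position) & (position < ex["end"])]
        if len(in_exon):
            return f"exon_{in_exon.iloc[0]['kind']}"
        if row["strand"] == "+":
            if row["start"] - promoter_len <= position < row["start"]:
                return "promoter"
        else:
            if row["end"] <= position < row["end"] + promoter_len:
                return "promoter"
        if inside:
            dmin = int(np.min(np.minimum(np.abs(ex["start"] - position), np.abs(ex["end"] - 1 - position)))) if len(ex) else np.inf
            return "intron_near" if dmin <= intron_near else "intron_distal"
    return "intergenic"


# ---------------------------------------------------------------------------
# gene effects

def gene_effects_by_distance(
    gene_counts: pd.DataFrame,
    gene_meta: pd.DataFrame,
    pseudocount: float = 0.5,
    max_bin_kb: int = 5,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Present-vs-absent expression contrast per distance bin and per gene.

    ``gene_counts``: genes x (strain, rep) MultiIndex columns of raw
    counts; columns are CPM-normalized internally.  ``gene_meta`` needs
    gene_id, carrier (strain or None) and distance_bin (kb; -1 = no
    nearby insertion; a gene overlapping its insertion is bin 0).

    Returns (per-bin table with pooled Mann-Whitney p and BH q, per-gene
    table with log2FC, p, q and the downregulated flag).
    """
    # median-of-ratios size factors: robust to the minority of genes with
    # genuine expression differences, unlike total-count scaling
    vals = gene_counts.to_numpy(float)
    with np.errstate(divide="ignore"):
        log_geo = np.log(vals).mean(axis=1)
    finite = np.isfinite(log_geo)
    if finite.sum() >= 10:
        ratios = np.log(vals[finite]) - log_geo[finite, None]
        size = np.exp(np.median(ratios, axis=0))
    else:
        size = vals.sum(axis=0) / 1e6
    cpm = gene_counts / size
    strains = cpm.columns.get_level_values("strain").unique()
    gene_rows = []
    for row in gene_meta.itertuples():
        if row.carrier is None or pd.isna(row.carrier) or row.distance_bin < 0:
            continue
        absent_strains = [s for s in strains if s != row.carrier]
        pres = cpm.loc[row.gene_id, row.carrier].to_numpy(float)
        absent = cpm.loc[row.gene_id, absent_strains].to_numpy(float)
        if pres.sum() == 0 and absent.sum() == 0:
            continue  # gene expressed nowhere
        log2fc = float(np.log2((pres.mean() + pseudocount) / (absent.mean() + pseudocount)))
        # per-gene contrast: Welch's t on log2 scale.  A rank test with two
        # replicates has an exact-p floor (2/45) that FDR correction can
        # never clear, so it cannot call genes at q < 0.05 in principle.
        t_res = stats.ttest_ind(np.log2(pres + pseudocount), np.log2(absent + pseudocount),
                                equal_var=False)
        p = float(t_res.pvalue) if np.isfinite(t_res.pvalue) else 1.0
        # per-strain means scaled by the gene's grand mean: exchangeable
        # across strains under the null, hence poolable across genes
        strain_means = cpm.loc[row.gene_id].groupby(level="strain").mean()
        grand = float(strain_means.mean()) + pseudocount
        scaled = (strain_means + pseudocount) / grand
        gene_rows.append(
            {
                "gene_id": row.gene_id,
                "distance_bin": int(row.distance_bin),
                "log2FC": log2fc,
                "mean_present": pres.mean(),
                "mean_absent": absent.mean(),
                "rel_present": float(scaled[row.carrier]),
                "rel_absent": scaled[absent_strains].to_numpy(float),
                "p": p,
            }
        )
    gene_table = pd.DataFrame(gene_rows)
    if len(gene_table):
        gene_table["q"] = bh_fdr(gene_table["p"])
        gene_table["downregulated"] = (gene_table["log2FC"] < 0) & (gene_table["q"] < alpha)
    bin_rows = []
    for b in range(max_bin_kb):
        sub = gene_table[gene_table["distance_bin"] == b] if len(gene_table) else gene_table
        if len(sub) < 2:
            bin_rows.append({"distance_bin": b, "n_genes": len(sub), "p": np.nan})
            continue
        _, p = mann_whitney(sub["rel_present"].to_numpy(float),
                            np.concatenate(sub["rel_absent"].to_list()))
        bin_rows.append({"distance_bin": b, "n_genes": len(sub), "p": p,
                         "median_log2FC": float(sub["log2FC"].median())})
    bin_table = pd.DataFrame(bin_rows)
    ok = bin_table["p"].notna()
    bin_table.loc[ok, "q"] = bh_fdr(bin_table.loc[ok, "p"])
    bin_table["significant"] = bin_table.get("q", pd.Series(dtype=float)) < alpha
    return bin_table, gene_table


# ---------------------------------------------------------------------------
# association

@dataclass(frozen=True)
class AssociationResult:
    table: np.ndarray
    chi2: float
    df: int
    p: float
    reliable: bool = True


def associate_spreading_downregulation(spread_flags, downregulated_flags) -> AssociationResult:
    """Pearson chi-squared (no continuity correction) on the 2x2
    spreading-by-downregulation table."""
    s = np.asarray(spread_flags, dtype=bool)
    d = np.asarray(downregulated_flags, dtype=bool)
    if s.shape != d.shape:
        raise ValueError("flag vectors must align")
    table = np.array(
        [
            [int((s & d).sum()), int((s & ~d).sum())],
            [int((~s & d).sum()), int((~s & ~d).sum())],
        ]
    )
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return AssociationResult(table, 0.0, 1, 1.0, reliable=False)
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    return AssociationResult(table, float(chi2), int(dof), float(p), reliable=bool((expected >= 1).all()))
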