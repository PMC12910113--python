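"""Strain-unique nonreference TE insertions and their summary statistics.

An insertion call (TELR-style breakpoint: contig, point coordinate,
family, length, TE allele frequency) is *unique* to a strain when no
call from any other strain lies within +/- 5 kb (inclusive) on the same
contig.  Matching is coordinate-only by default; ``match_family=True``
additionally requires the family to agree before two calls are
considered shared.  TAF < 0.7 flags a heterozygous insertion; a length
fraction >= 0.9 of the canonical element flags a full-length one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["unique_insertions", "summarize_insertions", "read_calls_bed", "write_calls_bed"]


def unique_insertions(
    calls: pd.DataFrame,
    window: int = 5000,
    match_family: bool = False,
) -> pd.DataFrame:
    """Flag strain-unique calls.

    ``calls`` needs columns strain, contig, position (and family when
    ``match_family``).  Returns a copy with a boolean ``unique`` column;
    a call at exactly ``window`` bp from another strain's call is shared
    (inclusive window).
    """
    if calls["strain"].nunique() < 2:
        raise ValueError("need calls from >= 2 strains")
    out = calls.copy()
    out["unique"] = True
    group_cols = ["contig", "family"] if match_family else ["contig"]
    for _, grp in out.groupby(group_cols):
        pos = grp["position"].to_numpy(np.int64)
        strain = grp["strain"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos_s, strain_s, idx_s = pos[order], strain[order], grp.index.to_numpy()[order]
        uniq = np.ones(len(pos_s), dtype=bool)
        for i in range(len(pos_s)):
            lo = np.searchsorted(pos_s, pos_s[i] - window, side="left")
            hi = np.searchsorted(pos_s, pos_s[i] + window, side="right")
            if (strain_s[lo:hi] != strain_s[i]).any():
                uniq[i] = False
        out.loc[idx_s, "unique"] = uniq
    return out


def summarize_insertions(
    calls: pd.DataFrame,
    consensus_lengths: dict[str, int] | None = None,
    taf_het_threshold: float = 0.7,
    full_length_threshold: float = 0.9,
    taf_bins: int = 10,
) -> dict:
    """TAF histogram, full-length fraction, per-family unique counts and
    heterozygosity flags.

    ``length_fraction`` is taken from the table when present, else
    computed from ``insertion_length`` and ``consensus_lengths``
    (unknown families fall under 'unclassified').
    """
    df = calls.copy()
    if "length_fraction" not in df.columns:
        def frac(row):
            L = (consensus_lengths or {}).get(row["family"])
            return row["insertion_length"] / L if L else np.nan
        df["length_fraction"] = df.apply(frac, axis=1)
    df["heterozygous"] = df["taf"] < taf_het_threshold
    df["full_length"] = df["length_fraction"] >= full_length_threshold
    df["family_label"] = df["family"].where(
        df["family"].isin(consensus_lengths) if consensus_lengths else df["family"].notna(),
        other="unclassified",
    )
    edges = np.linspace(0.0, 1.0, taf_bins + 1)
    taf_hist, _ = np.histogram(df["taf"].clip(0, 1), bins=edges)
    uniq = df[df["unique"]] if "unique" in df.columns else df
    per_family = (
        uniq.pivot_table(index="family_label", columns="strain", values="position",
                         aggfunc="count", fill_value=0)
        if len(uniq)
        else pd.DataFrame()
    )
    known = df[df["length_fraction"].notna()]
    return {
        "calls": df,
        "taf_bin_edges": edges,
        "taf_histogram": taf_hist,
        "full_length_fraction": float(known["full_length"].mean()) if len(known) else np.nan,
        "heterozygous_fraction": float(df["heterozygous"].mean()) if len(df) else np.nan,
        "unique_counts_by_family": per_family,
        "unique_counts_by_strain": uniq.groupby("strain").size() if len(uniq) else pd.Series(dtype=int),
    }


def read_calls_bed(path, strain: str) -> pd.DataFrame:
    """Read a BED-like per-strain call table: contig, pos, pos+1, family,
    taf, insertion length."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["contig", "position", "position_end", "family", "taf", "insertion_length"])
    df["strain"] = strain
    return df.drop(columns=["position_end"])


def write_calls_bed(calls: pd.DataFrame, path) -> None:
    out = calls.copy()
    out["position_end"] = out["position"] + 1
    out[["contig", "position", "position_end", "family", "taf", "insertion_length"]].to_csv(
        path, sep="\t", header=False, index=False
    )
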