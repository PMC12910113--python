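"""TE-family expression: RPKM, four-group expression/piRNA classification,
and copy-number/expression/piRNA correlation.

Families are classified per strain into four groups by two thresholds:
expressed iff log2 mean RPKM > 0 (RPKM > 1), piRNA-high iff log10
antisense RPM >= 2 (RPM >= 100).  Group 1 = expressed & targeted,
2 = silent & targeted, 3 = expressed & untargeted, 4 = neither.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TEGroupAssignment",
    "rpkm_table",
    "classify_te_group",
    "correlation_matrix",
]


@dataclass(frozen=True)
class TEGroupAssignment:
    family: str
    strain: str
    expressed: bool
    pirna_high: bool
    group: int


def rpkm_table(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """RPKM = count / (length_kb * library_size_millions), per column.

    ``counts``: features x samples; ``lengths`` in bp indexed like rows.
    ``library_sizes`` defaults to the column sums.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every feature needs a positive length")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    if (np.asarray(library_sizes) <= 0).any():
        raise ValueError("library sizes must be > 0")
    kb = lengths.to_numpy(float)[:, None] / 1e3
    millions = np.asarray(library_sizes, dtype=float)[None, :] / 1e6
    return pd.DataFrame(counts.to_numpy(float) / kb / millions, index=counts.index, columns=counts.columns)


def classify_te_group(
    mean_rpkm: float | None, antisense_rpm: float | None, family: str = "", strain: str = ""
) -> TEGroupAssignment | None:
    """Four-group classification; None when either statistic is missing.

    Thresholds exactly as defined: expressed iff RPKM strictly > 1
    (log2 > 0); piRNA-high iff RPM >= 100 (log10 >= 2, boundary in).
    """
    if mean_rpkm is None or antisense_rpm is None or np.isnan(mean_rpkm) or np.isnan(antisense_rpm):
        return None
    expressed = mean_rpkm > 1.0
    pirna_high = antisense_rpm >= 100.0
    group = {(True, True): 1, (False, True): 2, (True, False): 3, (False, False): 4}[
        (expressed, pirna_high)
    ]
    return TEGroupAssignment(family, strain, expressed, pirna_high, group)


def correlation_matrix(
    per_strain: dict[str, pd.DataFrame],
    pseudocount: float = 0.5,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], pd.DataFrame]:
    """Pairwise Pearson correlations between copy number, full-length copy
    number, expression and piRNA abundance, per strain, on
    log2(x + pseudocount) scales; plus the cross-strain mean matrix.

    Each per-strain frame is families x {copies_all, copies_full,
    expression, pirna}.  Returns (R by strain, p by strain, mean R).
    Constant columns give missing (NaN) entries.
    """
    r_by, p_by = {}, {}
    cols = None
    for strain, df in per_strain.items():
        if len(df) < 3:
            raise ValueError(f"strain {strain}: need >= 3 families for correlation")
        logged = np.log2(df.astype(float) + pseudocount)
        cols = list(df.columns)
        k = len(cols)
        r = np.full((k, k), np.nan)
        p = np.full((k, k), np.nan)
        for i in range(k):
            for j in range(k):
                x, y = logged.iloc[:, i], logged.iloc[:, j]
                if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
                    continue  # undefined for constant vectors
                res = stats.pearsonr(x, y)
                r[i, j], p[i, j] = res.statistic, res.pvalue
        r_by[strain] = pd.DataFrame(r, index=cols, columns=cols)
        p_by[strain] = pd.DataFrame(p, index=cols, columns=cols)
    mean_r = sum(r_by.values()) / len(r_by)
    return r_by, p_by, mean_r
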