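"""Kimura two-parameter divergence and TE divergence landscapes.

The age of a transposable-element copy is proxied by its substitution-
corrected distance K to the family consensus, distinguishing transitions
(p) from transversions (q):

    K = -1/2 * ln((1 - 2p - q) * sqrt(1 - 2q))

Copies binned by K form the divergence landscape; modes in the landscape
mark historical waves of mobilization.  Families are clustered into waves
by k-means on their row-standardized per-bin genome occupancy profiles,
with the cluster count selected by mean silhouette width.

Unit conventions: ``kimura_distance`` returns substitutions/site; copy
tables, landscapes and wave parameters use the percent scale familiar
from RepeatMasker landscapes (K = 25 means 0.25 substitutions/site).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "KimuraStats",
    "DivergenceLandscape",
    "SaturationError",
    "kimura_distance",
    "build_landscape",
    "cluster_waves",
]

# A=0,C=1,G=2,T=3; transitions are A<->G and C<->T (purine/pyrimidine preserving)
_PURINE = np.array([True, False, True, False])


class SaturationError(ValueError):
    """Raised when p, q put the K2P correction outside its log domain."""


@dataclass(frozen=True)
class KimuraStats:
    """Transition/transversion summary of one aligned pair."""

    sites: int
    p: float  # transition proportion
    q: float  # transversion proportion
    K: float  # substitutions/site


def _k2p_from_pq(p: float, q: float) -> float:
    a = 1.0 - 2.0 * p - q
    b = 1.0 - 2.0 * q
    if a <= 0.0 or b <= 0.0:
        raise SaturationError(f"K2P correction undefined for p={p:.4g}, q={q:.4g} (saturated)")
    return -0.5 * math.log(a * math.sqrt(b))


def kimura_distance(a: str, b: str) -> KimuraStats:
    """Kimura two-parameter distance between two equal-length aligned sequences.

    Columns containing gaps ('-', '.') or ambiguous bases are excluded
    from the site count.  Raises :class:`SaturationError` when the
    correction is undefined.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    ra = np.frombuffer(a.upper().encode("ascii"), dtype=np.uint8)
    rb = np.frombuffer(b.upper().encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for i, base in enumerate(b"ACGT"):
        lut[base] = i
    ea, eb = lut[ra], lut[rb]
    keep = (ea != 255) & (eb != 255)
    sites = int(keep.sum())
    if sites == 0:
        raise ValueError("no gap-free unambiguous columns in alignment")
    ea, eb = ea[keep], eb[keep]
    diff = ea != eb
    ts = diff & (_PURINE[ea] == _PURINE[eb])
    p = float(ts.sum()) / sites
    q = float((diff & ~ts).sum()) / sites
    return KimuraStats(sites=sites, p=p, q=q, K=_k2p_from_pq(p, q))


@dataclass
class DivergenceLandscape:
    """Family-by-K-bin occupancy with clustering state."""

    bin_width: float
    occupancy: pd.DataFrame          # families x bins, bp covered
    histogram: pd.DataFrame          # bins x subclasses, bp covered
    n_saturated: int = 0
    z_matrix: pd.DataFrame | None = None
    k_selected: int | None = None
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    cluster_of_family: pd.Series | None = None

    def family_mean_k(self) -> pd.Series:
        """Occupancy-weighted mean K (percent) per family."""
        centers = self.occupancy.columns.to_numpy(dtype=float) + self.bin_width / 2.0
        tot = self.occupancy.sum(axis=1)
        mean = (self.occupancy * centers).sum(axis=1) / tot.where(tot > 0, np.nan)
        return mean.fillna(0.0)


def _zscore_rows(occ: pd.DataFrame) -> pd.DataFrame:
    vals = occ.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (vals - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    return pd.DataFrame(z, index=occ.index, columns=occ.columns)


def build_landscape(
    copies: pd.DataFrame,
    subclass_of_family: dict[str, str] | pd.Series | None = None,
    bin_width: float = 1.0,
    k_max: float = 50.0,
) -> DivergenceLandscape:
    """Build the divergence landscape from a copy table.

    ``copies`` needs columns ``family``, ``K`` (percent; NaN = saturated)
    and ``copy_length`` (bp).  Saturated copies are excluded and counted.
    """
    required = {"family", "K", "copy_length"}
    missing = required - set(copies.columns)
    if missing:
        raise ValueError(f"copy table lacks columns: {sorted(missing)}")
    bins = np.arange(0.0, k_max, bin_width)
    sat = copies["K"].isna()
    ok = copies.loc[~sat].copy()
    n_saturated = int(sat.sum())
    families = sorted(copies["family"].unique())
    occ = pd.DataFrame(0.0, index=pd.Index(families, name="family"), columns=bins)
    if len(ok):
        idx = np.clip(np.floor(ok["K"].to_numpy(float) / bin_width), 0, len(bins) - 1).astype(int)
        for fam, bi, bp in zip(ok["family"], idx, ok["copy_length"]):
            occ.iat[occ.index.get_loc(fam), bi] += bp
    if subclass_of_family is None:
        sub = pd.Series("TE", index=occ.index)
    else:
        sub = pd.Series(subclass_of_family).reindex(occ.index).fillna("unknown")
    hist = occ.groupby(sub).sum().T
    hist.index.name = "K_bin"
    return DivergenceLandscape(
        bin_width=bin_width,
        occupancy=occ,
        histogram=hist,
        n_saturated=n_saturated,
        z_matrix=_zscore_rows(occ),
    )


def cluster_waves(
    landscape: DivergenceLandscape,
    k_range: range = range(2, 11),
    seed: int = 0,
    n_restarts: int = 10,
) -> DivergenceLandscape:
    """K-means wave clustering of family occupancy profiles.

    Selects the cluster count maximizing mean silhouette width and
    relabels clusters so that index increases with cluster-mean K
    (cluster 1 = youngest wave).  Mutates and returns ``landscape``.
    """
    z = landscape.z_matrix
    if z is None:
        raise ValueError("landscape has no z-matrix")
    x = z.to_numpy(dtype=float)
    if len(np.unique(x, axis=0)) < 2:
        raise ValueError(
            "all families have constant/identical occupancy profiles; clustering is undefined"
        )
    n = x.shape[0]
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        if n <= k:
            continue  # fewer families than clusters
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        lab = km.fit_predict(x)
        if len(np.unique(lab)) < 2:
            continue
        sil[k] = float(silhouette_score(x, lab))
        labels_by_k[k] = lab
    if not sil:
        raise ValueError("no feasible cluster count in k_range")
    k_sel = max(sil, key=sil.get)
    lab = labels_by_k[k_sel]
    mean_k = landscape.family_mean_k().to_numpy()
    order = np.argsort([mean_k[lab == c].mean() for c in range(k_sel)])
    relabel = np.empty(k_sel, dtype=int)
    relabel[order] = np.arange(1, k_sel + 1)
    landscape.k_selected = k_sel
    landscape.silhouette_by_k = sil
    landscape.cluster_of_family = pd.Series(relabel[lab], index=z.index, name="cluster")
    return landscape
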