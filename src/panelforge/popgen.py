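"""Population-genetic statistics.

Allele frequencies and expected heterozygosity, per-sample inbreeding
F = (O - E)/(N - E), Weir–Cockerham (1984) F_ST variance components,
individual p-distance matrices, the Mantel permutation test for isolation
by distance, great-circle (Haversine) distances, and window-based
heterozygosity per sample.

Expected heterozygosity is Nei gene diversity 2pq without sample-size
correction, so a balanced biallelic locus attains exactly 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    AlleleFreqTable,
    GenotypeMatrix,
    PanelforgeError,
    group_allele_table,
)

__all__ = [
    "allele_stats",
    "inbreeding_coefficient",
    "sample_inbreeding",
    "PairwiseFstTable",
    "weir_cockerham_fst",
    "p_distance_matrix",
    "mantel_test",
    "haversine_km",
    "windowed_heterozygosity",
]

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


def allele_stats(
    gm: GenotypeMatrix, labels=None
) -> tuple[AlleleFreqTable, pd.DataFrame]:
    """Per-group allele table plus per-locus overall MAF and He.

    He is Nei gene diversity 2p(1-p) from the pooled frequency; MAF is
    min(p, 1-p).  Loci fully missing in a group carry NaN frequency.
    """
    table = group_allele_table(gm, labels)
    p = gm.alt_freq()
    per_locus = pd.DataFrame(
        {
            "p_alt": p,
            "maf": np.minimum(p, 1.0 - p),
            "he": 2.0 * p * (1.0 - p),
        }
    )
    return table, per_locus


def inbreeding_coefficient(observed_hom: float, expected_hom: float, n_loci: float) -> float:
    """F = (O - E)/(N - E): excess homozygosity relative to HWE expectation."""
    if n_loci == expected_hom:
        raise PanelforgeError("F undefined when N == E")
    return (observed_hom - expected_hom) / (n_loci - expected_hom)


def sample_inbreeding(gm: GenotypeMatrix, labels=None) -> pd.DataFrame:
    """Per-sample F from observed vs HWE-expected homozygote counts.

    Expected homozygosity per locus uses the allele frequency of the
    sample's own group (pooled if ``labels`` is None), summed over the
    sample's typed loci.
    """
    table = group_allele_table(gm, labels)
    if labels is None:
        labels = ["all"] * gm.n_samples
    rows = []
    for i, (sid, lab) in enumerate(zip(gm.samples, labels)):
        gi = table.group_index(lab)
        p = table.freq[gi]
        typed = gm.dosage[i] != MISSING
        typed &= ~np.isnan(p)
        n = int(typed.sum())
        obs = int(((gm.dosage[i] == 0) | (gm.dosage[i] == 2))[typed].sum())
        exp = float((1.0 - 2.0 * p[typed] * (1.0 - p[typed])).sum())
        f = inbreeding_coefficient(obs, exp, n) if n > exp else np.nan
        rows.append({"sample": sid, "observed_hom": obs, "expected_hom": exp,
                     "n_loci": n, "F": f})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir–Cockerham F_ST
# ---------------------------------------------------------------------------

@dataclass
class PairwiseFstTable:
    """Per-locus variance components and theta for each group pair.

    ``components[pair]`` is an ``(n_loci, 3)`` array of the Weir–Cockerham
    a (among populations), b (among individuals within populations) and
    c (within individuals) components; skipped loci are NaN.
    """

    pairs: list[tuple[str, str]]
    components: dict[tuple[str, str], np.ndarray]
    loci: pd.DataFrame = field(default_factory=pd.DataFrame)

    def per_site_theta(self, pair) -> np.ndarray:
        comp = self.components[tuple(pair)]
        denom = comp.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(denom != 0, comp[:, 0] / denom, np.nan)

    def weighted_theta(self, pair) -> float:
        comp = self.components[tuple(pair)]
        ok = ~np.isnan(comp[:, 0])
        denom = comp[ok].sum()
        return float(comp[ok, 0].sum() / denom) if denom != 0 else float("nan")

    def mean_theta(self, pair) -> float:
        theta = self.per_site_theta(pair)
        return float(np.nanmean(theta))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group1": a,
                    "group2": b,
                    "weighted_theta": self.weighted_theta((a, b)),
                    "mean_theta": self.mean_theta((a, b)),
                }
                for a, b in self.pairs
            ]
        )


def _wc_components(
    counts1: np.ndarray, counts2: np.ndarray
) -> np.ndarray:
    """Weir–Cockerham (1984) a, b, c for two populations at many loci.

    ``counts*`` are ``(n_loci, 3)`` genotype-count arrays.  Loci where
    either population has fewer than 2 typed diploids are NaN.
    """
    r = 2
    n1 = counts1.sum(axis=1).astype(float)
    n2 = counts2.sum(axis=1).astype(float)
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = (counts1[:, 1] + 2 * counts1[:, 2]) / (2 * n1)
        p2 = (counts2[:, 1] + 2 * counts2[:, 2]) / (2 * n2)
        h1 = counts1[:, 1] / n1
        h2 = counts2[:, 1] / n2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
    comp = np.stack([a, b, c], axis=1)
    comp[~valid] = np.nan
    # monomorphic across both pops: components all zero -> theta undefined
    return comp


def weir_cockerham_fst(gm: GenotypeMatrix, labels) -> PairwiseFstTable:
    """Pairwise Weir–Cockerham theta between every pair of groups."""
    table = group_allele_table(gm, labels)
    if len(table.groups) < 2:
        raise PanelforgeError("need at least two groups for F_ST")
    pairs = list(combinations(table.groups, 2))
    components = {}
    for a, b in pairs:
        ia, ib = table.group_index(a), table.group_index(b)
        components[(a, b)] = _wc_components(
            table.geno_counts[ia], table.geno_counts[ib]
        )
    return PairwiseFstTable(pairs=pairs, components=components, loci=gm.loci.copy())


# ---------------------------------------------------------------------------
# Distance matrices and the Mantel test
# ---------------------------------------------------------------------------

def p_distance_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Mean per-locus allele-sharing distance |d_i - d_j| / 2 over co-typed
    loci; NaN where a pair shares no typed locus."""
    if gm.n_samples < 2:
        raise PanelforgeError("need at least two samples")
    d = gm.dosage_float()
    n = gm.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(d[i] - d[i + 1 :]) / 2.0
        counts = (~np.isnan(diff)).sum(axis=1)
        with np.errstate(invalid="ignore"):
            vals = np.where(counts > 0, np.nansum(diff, axis=1) / counts, np.nan)
        out[i, i + 1 :] = vals
        out[i + 1 :, i] = vals
    return out


def mantel_test(
    mat_a: np.ndarray,
    mat_b: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the strict upper triangles; the
    one-sided p-value is (1 + #{permuted r >= observed r}) / (n_perm + 1),
    permuting the rows and columns of the second matrix jointly.
    """
    a = np.asarray(mat_a, dtype=float)
    b = np.asarray(mat_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise PanelforgeError("matrices must be square and of equal shape")
    n = a.shape[0]
    if n < 4:
        raise PanelforgeError("need at least 4 samples for a Mantel test")
    iu = np.triu_indices(n, k=1)
    va = a[iu]
    if np.ptp(va) == 0 or np.ptp(b[iu]) == 0:
        raise PanelforgeError("constant distance matrix")
    r_obs = float(np.corrcoef(va, b[iu])[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = np.corrcoef(va, b[np.ix_(perm, perm)][iu])[0, 1]
        if r_perm >= r_obs:
            count += 1
    return r_obs, (1.0 + count) / (n_perm + 1.0)


def haversine_km(lon1, lat1, lon2, lat2) -> float | np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371.0088 km."""
    lat1a, lat2a = np.asarray(lat1, float), np.asarray(lat2, float)
    if (np.abs(lat1a) > 90).any() or (np.abs(lat2a) > 90).any():
        raise PanelforgeError("latitude must be within [-90, 90]")
    lat1r = np.radians(lat1a)
    lat2r = np.radians(lat2a)
    dlon = np.radians(np.asarray(lon2, float) - np.asarray(lon1, float))
    dlat = lat2r - lat1r
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1r) * np.cos(lat2r) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


def windowed_heterozygosity(
    gm: GenotypeMatrix, window_bp: int = 200_000
) -> tuple[pd.DataFrame, pd.Series]:
    """Heterozygous calls per bp in non-overlapping windows.

    Returns a long-form table (sample, chrom, window_start, het_per_bp)
    and a per-sample genome mean (total het calls / total covered length,
    counting each started window at full length).
    """
    if window_bp <= 0:
        raise PanelforgeError("window_bp must be positive")
    rows = []
    chroms = gm.loci["chrom"].astype(str).to_numpy()
    pos = gm.loci["pos"].to_numpy()
    win = (pos - 1) // window_bp
    het = gm.dosage == 1
    total_het = np.zeros(gm.n_samples)
    n_windows = 0
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        for w in np.unique(win[sel]):
            cols = np.where(sel & (win == w))[0]
            h = het[:, cols].sum(axis=1)
            total_het += h
            n_windows += 1
            for i, sid in enumerate(gm.samples):
                rows.append(
                    {
                        "sample": sid,
                        "chrom": chrom,
                        "window_start": int(w * window_bp),
                        "het_per_bp": h[i] / window_bp,
                    }
                )
    per_window = pd.DataFrame(rows)
    genome_mean = pd.Series(
        total_het / (n_windows * window_bp), index=gm.samples, name="het_per_bp"
    )
    return per_window, genome_mean
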