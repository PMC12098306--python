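"""Informative-SNP panel selection.

Three selection routes:

* :func:`select_top_fst_panel` — rank loci by per-site Weir–Cockerham
  theta within each pairwise group comparison, keep the top N per pair and
  deduplicate the union, recording provenance (which pair, rank, theta)
  for every membership;
* :func:`search_reduced_subset` — random search for a smaller subset with
  comparable resolving power, scored by mean silhouette of the true group
  labels on the first two principal components;
* :func:`select_sex_linked` — X-linked sex-diagnostic loci where every
  typed female is homozygous for one shared allele and every typed male
  carries at least one copy of the other allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PanelforgeError
from .popgen import PairwiseFstTable

__all__ = [
    "Panel",
    "select_top_fst_panel",
    "search_reduced_subset",
    "select_sex_linked",
]


@dataclass
class Panel:
    """An ordered set of selected loci with selection provenance.

    ``loci`` has columns ``chrom, pos, ref, alt`` plus ``locus_index``
    (position in the source genotype matrix).  ``provenance`` has one row
    per (locus, comparison) membership: ``locus_index, group1, group2,
    rank, theta``.
    """

    name: str
    loci: pd.DataFrame
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def locus_indices(self) -> np.ndarray:
        return self.loci["locus_index"].to_numpy(dtype=int)

    def to_tsv(self, path) -> None:
        merged = self.loci.merge(
            self.provenance.groupby("locus_index")
            .apply(
                lambda g: ";".join(
                    f"{r.group1}~{r.group2}:rank{int(r.rank)}:theta={r.theta:.4g}"
                    for r in g.itertuples()
                ),
                include_groups=False,
            )
            .rename("provenance"),
            left_on="locus_index",
            right_index=True,
            how="left",
        )
        merged.to_csv(path, sep="\t", index=False)


def select_top_fst_panel(fst: PairwiseFstTable, top_n: int = 50) -> Panel:
    """Top-N loci per pairwise comparison, deduplicated union.

    Within each group pair, loci are ranked by per-site theta descending
    with ties broken by genomic order (chrom, then position).  A locus
    picked by several comparisons appears once, with one provenance row
    per comparison.
    """
    loci = fst.loci.reset_index(drop=True)
    chrom = loci["chrom"].astype(str)
    pos = loci["pos"].to_numpy()
    prov_rows = []
    selected: list[int] = []
    seen: set[int] = set()
    for pair in fst.pairs:
        theta = fst.per_site_theta(pair)
        ok = np.where(~np.isnan(theta))[0]
        if ok.size < top_n:
            raise PanelforgeError(
                f"pair {pair} has only {ok.size} ranked loci (< top_n={top_n})"
            )
        order = sorted(ok, key=lambda j: (-theta[j], chrom.iloc[j], pos[j]))
        for rank, j in enumerate(order[:top_n], start=1):
            prov_rows.append(
                {
                    "locus_index": j,
                    "group1": pair[0],
                    "group2": pair[1],
                    "rank": rank,
                    "theta": theta[j],
                }
            )
            if j not in seen:
                seen.add(j)
                selected.append(j)
    selected.sort(key=lambda j: (chrom.iloc[j], pos[j]))
    panel_loci = loci.iloc[selected][["chrom", "pos", "ref", "alt"]].copy()
    panel_loci["locus_index"] = selected
    return Panel(
        name=f"top{top_n}_fst",
        loci=panel_loci.reset_index(drop=True),
        provenance=pd.DataFrame(prov_rows),
    )


def _pca_scores_2d(dosage: np.ndarray) -> np.ndarray:
    from sklearn.decomposition import PCA

    d = dosage.astype(float)
    d[dosage == MISSING] = np.nan
    mu = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(mu, inds[1])
    sd = d.std(axis=0)
    keep = sd > 0
    d = (d[:, keep] - mu[keep]) / sd[keep]
    if d.shape[1] < 2:
        raise PanelforgeError("need at least two variable loci for PCA scoring")
    return PCA(n_components=2, random_state=0).fit_transform(d)


def subset_separation_score(gm: GenotypeMatrix, labels, idx) -> float:
    """Mean silhouette of the true labels on the first two PCs of a locus
    subset — the label-aware measure of group separation used to rank
    candidate subsets."""
    from sklearn.metrics import silhouette_score

    scores = _pca_scores_2d(gm.dosage[:, np.asarray(idx, dtype=int)])
    return float(silhouette_score(scores, np.asarray(labels)))


def search_reduced_subset(
    panel: Panel,
    gm: GenotypeMatrix,
    labels,
    size: int = 84,
    n_trials: int = 200,
    seed: int = 0,
) -> tuple[Panel, float]:
    """Random subset search maximizing PCA-separation score.

    Draws ``n_trials`` uniform subsets of ``size`` panel loci, scores each
    with :func:`subset_separation_score`, and returns the best (first
    found on ties).  ``size`` equal to the panel size evaluates the full
    panel once (bypass mode).
    """
    pool = panel.locus_indices
    if size > len(pool):
        raise PanelforgeError("subset size exceeds panel size")
    if n_trials < 1:
        raise PanelforgeError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    if size == len(pool):
        best_idx = pool
        best_score = subset_separation_score(gm, labels, pool)
    else:
        best_idx, best_score = None, -np.inf
        for _ in range(n_trials):
            idx = rng.choice(pool, size=size, replace=False)
            score = subset_separation_score(gm, labels, idx)
            if score > best_score:
                best_idx, best_score = idx, score
    chosen = set(int(i) for i in best_idx)
    mask = panel.loci["locus_index"].isin(chosen)
    sub = Panel(
        name=f"{panel.name}_subset{size}",
        loci=panel.loci[mask].reset_index(drop=True),
        provenance=panel.provenance[
            panel.provenance["locus_index"].isin(chosen)
        ].reset_index(drop=True),
    )
    return sub, float(best_score)


def select_sex_linked(gm: GenotypeMatrix, sexes) -> np.ndarray:
    """Indices of sex-diagnostic loci.

    A locus qualifies when every typed female is homozygous for one shared
    allele and every typed male carries at least one copy of the other
    allele.  Missing calls are ignored; any violating call disqualifies
    the locus.  Loci with no typed female or no typed male are excluded.
    """
    sexes = np.asarray(list(sexes))
    is_f = sexes == "F"
    is_m = sexes == "M"
    if not is_f.any() or not is_m.any():
        raise PanelforgeError("both sexes must be present")
    out = []
    for j in range(gm.n_loci):
        col = gm.dosage[:, j]
        fem = col[is_f & (col != MISSING)]
        mal = col[is_m & (col != MISSING)]
        if fem.size == 0 or mal.size == 0:
            continue
        # females homozygous for one shared allele
        if (fem == 1).any() or np.unique(fem).size != 1:
            continue
        female_dose = int(fem[0])  # 0 (hom ref) or 2 (hom alt)
        # every male carries >= 1 copy of the other allele
        if female_dose == 0:
            if (mal == 0).any():
                continue
        else:
            if (mal == 2).any():
                continue
        out.append(j)
    return np.asarray(out, dtype=int)
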