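"""Post-calling site and sample filter cascade.

Mirrors the standard VCFtools/PLINK quality cascade used when distilling a
whole-genome SNP call set into a high-confidence marker pool: numeric INFO
hard filters, biallelic restriction, per-call and per-site depth bounds,
minor-allele-frequency floor, site and sample missingness ceilings,
sliding-window LD pruning, repeat-interval exclusion, and an exact
Hardy–Weinberg test.  Steps run in that fixed order and every step is
logged in a :class:`FilterReport` (site counts removed/remaining, removed
sample ids), mirroring the usual "SNPs retained after each step" table.

Coordinate conventions: VCF positions are 1-based; BED intervals are
half-open 0-based ``[start, end)``.  A variant at VCF position ``pos``
falls in a BED interval when ``start < pos <= end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma
from pathlib import Path

import numpy as np

from .core import MISSING, GenotypeMatrix, PanelforgeError

__all__ = [
    "FilterConfig",
    "FilterReport",
    "hwe_exact_test",
    "ld_r2",
    "ld_prune",
    "read_bed_intervals",
    "apply_filter_cascade",
]


@dataclass
class FilterConfig:
    """Thresholds of the filter cascade (defaults follow common practice
    for panel design: MAF >= 0.05, per-site missingness < 5%, per-sample
    < 20%, depth in [5, 100], LD prune 50/10/0.1, exact HWE p < 0.001)."""

    min_qual: float | None = 30.0
    maf_min: float = 0.05
    min_dp: float = 5.0
    min_mean_dp: float = 5.0
    max_dp: float = 100.0
    max_mean_dp: float = 100.0
    site_missing_max: float = 0.05
    sample_missing_max: float = 0.20
    hwe_alpha: float = 0.001
    ld_window: int = 50
    ld_step: int = 10
    ld_r2_max: float = 0.1
    repeat_bed: str | None = None
    info_hard_filters: dict[str, tuple[str, float]] = field(default_factory=dict)
    """Map INFO key -> (op, threshold); op in {"<", ">", "<=", ">="} states the
    REMOVAL condition, e.g. {"QD": ("<", 2.0), "FS": (">", 60.0)}."""

    def __post_init__(self) -> None:
        for name in ("maf_min", "site_missing_max", "sample_missing_max", "hwe_alpha"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise PanelforgeError(f"{name} must be in [0, 1]")
        if not (self.ld_window >= self.ld_step >= 1):
            raise PanelforgeError("require ld_window >= ld_step >= 1")


@dataclass
class FilterReport:
    """Ordered per-step site accounting plus removed sample ids."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)
    removed_samples: list[str] = field(default_factory=list)

    def add(self, name: str, n_removed: int, n_remaining: int) -> None:
        self.steps.append((name, int(n_removed), int(n_remaining)))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.steps, columns=["step", "filtered_snps", "remaining_snps"]
        )


# ---------------------------------------------------------------------------
# Exact Hardy–Weinberg test
# ---------------------------------------------------------------------------

def _hwe_het_probabilities(n_a: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional probabilities of each feasible heterozygote count given
    ``n`` diploids and ``n_a`` copies of the minor allele."""
    het_min = n_a % 2
    hets = np.arange(het_min, min(n_a, 2 * n - n_a) + 1, 2)
    n_b = 2 * n - n_a
    logp = np.empty(hets.size)
    for i, h in enumerate(hets):
        n_aa = (n_a - h) // 2
        n_bb = (n_b - h) // 2
        logp[i] = (
            lgamma(n + 1)
            - lgamma(n_aa + 1)
            - lgamma(h + 1)
            - lgamma(n_bb + 1)
            + h * np.log(2.0)
            + lgamma(n_a + 1)
            + lgamma(n_b + 1)
            - lgamma(2 * n + 1)
        )
    p = np.exp(logp - logp.max())
    return hets, p / p.sum()


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy–Weinberg test.

    Enumerates all heterozygote counts compatible with the observed allele
    totals and returns the summed probability of configurations whose point
    probability does not exceed the observed one (two-sided, no mid-p).
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise PanelforgeError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise PanelforgeError("need at least one genotype")
    n_a = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    hets, probs = _hwe_het_probabilities(n_a, n)
    p_obs = probs[hets == n_ab][0]
    # 1e-12 relative slack guards against float noise in the comparison
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over pairwise-
    complete entries; NaN flags an undefined (constant-vector) result."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = (a != MISSING) & (b != MISSING) & ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if a.size < 2:
        return float("nan")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _pairwise_r2(d: np.ndarray) -> np.ndarray:
    """Pairwise r^2 matrix over columns of a dosage matrix (NaN missing),
    pairwise-complete; undefined pairs -> 0 (no pruning pressure)."""
    m = d.shape[1]
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            r2 = ld_r2(d[:, i], d[:, j])
            out[i, j] = out[j, i] = 0.0 if np.isnan(r2) else r2
    return out


def ld_prune(
    gm: GenotypeMatrix, window: int = 50, step: int = 10, r2_max: float = 0.1
) -> np.ndarray:
    """Sliding-window LD pruning; returns indices of kept loci.

    Within each window of ``window`` loci (advanced by ``step``), while any
    surviving pair has r^2 > ``r2_max``, the member of the currently worst
    pair with the lower MAF is removed (tie -> later genomic position).
    Removal is global and final.
    """
    loci = gm.loci
    order_key = list(zip(loci["chrom"].astype(str), loci["pos"].astype(int)))
    if order_key != sorted(order_key):
        raise PanelforgeError("loci must be sorted by (chrom, pos) for LD pruning")
    m = gm.n_loci
    d = gm.dosage_float()
    maf = gm.maf()
    removed = np.zeros(m, dtype=bool)
    starts = range(0, max(m - 1, 1), step)
    for s in starts:
        idx = np.arange(s, min(s + window, m))
        idx = idx[~removed[idx]]
        if idx.size < 2:
            continue
        r2 = _pairwise_r2(d[:, idx])
        alive = np.ones(idx.size, dtype=bool)
        while True:
            sub = np.where(alive)[0]
            if sub.size < 2:
                break
            block = r2[np.ix_(sub, sub)]
            worst = np.unravel_index(np.argmax(block), block.shape)
            if block[worst] <= r2_max:
                break
            li, lj = idx[sub[worst[0]]], idx[sub[worst[1]]]
            # victim: lower MAF; tie -> later position
            if maf[li] < maf[lj] or (maf[li] == maf[lj] and li > lj):
                victim = li
            else:
                victim = lj
            alive[np.where(idx == victim)[0][0]] = False
            removed[victim] = True
        if s + window >= m:
            break
    return np.where(~removed)[0]


# ---------------------------------------------------------------------------
# BED intervals and the cascade
# ---------------------------------------------------------------------------

def read_bed_intervals(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Parse a BED3 file into chrom -> list of half-open [start, end)."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise PanelforgeError(f"malformed BED line {ln}: {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise PanelforgeError(f"malformed BED line {ln}: {line!r}") from exc
            if end < start:
                raise PanelforgeError(f"malformed BED line {ln}: end < start")
            intervals.setdefault(parts[0], []).append((start, end))
    return intervals


def _in_intervals(
    loci, intervals: dict[str, list[tuple[int, int]]]
) -> np.ndarray:
    hit = np.zeros(len(loci), dtype=bool)
    for j, (chrom, pos) in enumerate(zip(loci["chrom"].astype(str), loci["pos"])):
        for start, end in intervals.get(chrom, ()):  # BED 0-based, VCF 1-based
            if start < pos <= end:
                hit[j] = True
                break
    return hit


def apply_filter_cascade(
    gm: GenotypeMatrix,
    config: FilterConfig,
    intervals: dict[str, list[tuple[int, int]]] | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the full site/sample filter cascade and log each step.

    Step order: INFO hard filters -> biallelic -> QUAL -> depth -> MAF ->
    site missingness -> sample missingness -> LD prune -> repeat intervals
    -> exact HWE.
    """
    report = FilterReport()
    if intervals is None and config.repeat_bed:
        intervals = read_bed_intervals(config.repeat_bed)

    def drop(name: str, keep: np.ndarray) -> None:
        nonlocal gm
        n_before = gm.n_loci
        gm = gm.take_loci(np.where(keep)[0])
        report.add(name, n_before - gm.n_loci, gm.n_loci)

    # 1. numeric INFO hard filters
    keep = np.ones(gm.n_loci, dtype=bool)
    for key, (op, thr) in config.info_hard_filters.items():
        col = f"info_{key}"
        if col not in gm.loci.columns:
            continue
        vals = gm.loci[col].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if op == "<":
                bad = vals < thr
            elif op == ">":
                bad = vals > thr
            elif op == "<=":
                bad = vals <= thr
            elif op == ">=":
                bad = vals >= thr
            else:
                raise PanelforgeError(f"unknown hard-filter op {op!r}")
        keep &= ~np.nan_to_num(bad, nan=False).astype(bool)
    drop("hard_filters", keep)

    # 2. biallelic SNPs only
    ref = gm.loci["ref"].astype(str)
    alt = gm.loci["alt"].astype(str)
    bial = (ref.str.len() == 1) & (alt.str.len() == 1) & ~alt.isin([".", "*"])
    drop("biallelic", bial.to_numpy())

    # 3. site quality
    if config.min_qual is not None and "qual" in gm.loci.columns:
        q = gm.loci["qual"].to_numpy(dtype=float)
        keep = np.isnan(q) | (q > config.min_qual)
    else:
        keep = np.ones(gm.n_loci, dtype=bool)
    drop("min_qual", keep)

    # 4. depth: per-call bounds mask calls; site mean-depth bounds drop sites
    if gm.depth is not None:
        dp = gm.depth.astype(float)
        typed = gm.dosage != MISSING
        bad_call = typed & ((dp < config.min_dp) | (dp > config.max_dp))
        if bad_call.any():
            dosage = gm.dosage.copy()
            dosage[bad_call] = MISSING
            gm = GenotypeMatrix(dosage, gm.samples, gm.loci, gm.depth)
        typed2 = gm.dosage != MISSING
        n_typed = typed2.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean_dp = np.where(
                n_typed > 0, (dp * typed2).sum(axis=0) / n_typed, np.nan
            )
            keep = (mean_dp >= config.min_mean_dp) & (mean_dp <= config.max_mean_dp)
        keep = np.where(np.isnan(mean_dp), False, keep)
    else:
        keep = np.ones(gm.n_loci, dtype=bool)
    drop("depth", keep)

    # 5. MAF floor
    maf = gm.maf()
    drop("maf", np.nan_to_num(maf, nan=-1.0) >= config.maf_min)

    # 6. site missingness (remove when fraction >= threshold)
    miss = gm.missing_mask().mean(axis=0)
    drop("site_missing", miss < config.site_missing_max)

    # 7. sample missingness (after site filters)
    s_miss = gm.missing_mask().mean(axis=1)
    bad_samples = s_miss >= config.sample_missing_max
    if bad_samples.any():
        report.removed_samples = [
            s for s, b in zip(gm.samples, bad_samples) if b
        ]
        gm = gm.take_samples(np.where(~bad_samples)[0])
    report.add("sample_missing", 0, gm.n_loci)

    # 8. LD prune
    kept = ld_prune(gm, config.ld_window, config.ld_step, config.ld_r2_max)
    keep = np.zeros(gm.n_loci, dtype=bool)
    keep[kept] = True
    drop("ld_prune", keep)

    # 9. repeat-interval exclusion
    if intervals:
        drop("repeat_regions", ~_in_intervals(gm.loci, intervals))
    else:
        report.add("repeat_regions", 0, gm.n_loci)

    # 10. exact HWE
    keep = np.ones(gm.n_loci, dtype=bool)
    for j in range(gm.n_loci):
        col = gm.dosage[:, j]
        n0 = int((col == 0).sum())
        n1 = int((col == 1).sum())
        n2 = int((col == 2).sum())
        if n0 + n1 + n2 == 0:
            keep[j] = False
            continue
        keep[j] = hwe_exact_test(n0, n1, n2) >= config.hwe_alpha
    drop("hwe", keep)

    return gm, report
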