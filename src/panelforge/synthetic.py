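"""Synthetic genotype data with known truth.

Generates the study conditions every downstream stage is tested against:

* structured populations under the Balding–Nichols model, in which each
  population's allele frequency is a Beta draw around an ancestral
  frequency ``p`` with shape ``p(1-F)/F, (1-p)(1-F)/F`` so that the
  expected fixation index among populations equals ``F``;
* optional spatial clines: a fraction of loci get frequencies that vary
  monotonically with position along the west–east axis instead of
  independent population draws, emulating isolation by distance;
* Mendelian pedigrees with a per-allele genotyping-error channel, for
  parentage and sibship validation;
* X-linked loci with planted sex-diagnostic sites (all females homozygous
  reference, every male carrying at least one alternative allele).

All randomness flows from a single integer seed through
:func:`numpy.random.default_rng`.  Males at X loci are emitted as ordinary
diploid calls; hemizygosity is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    AlleleFreqTable,
    GenotypeMatrix,
    PanelforgeError,
    write_fixture,  # re-exported: fixture IO lives with the generator surface
)

__all__ = [
    "PopulationModel",
    "PedigreeSpec",
    "generate_structured_populations",
    "generate_pedigree_genotypes",
    "generate_xlinked_loci",
    "write_fixture",
]


@dataclass
class PopulationModel:
    """Parameters of a Balding–Nichols structured-population simulation.

    ``fst_target`` is the differentiation parameter F of the Beta draw,
    strictly inside (0, 1).  ``pop_coords`` holds one (lon, lat) per
    population; ``cline_fraction`` of loci follow a longitudinal
    frequency gradient instead of independent Beta draws.
    """

    n_pops: int
    fst_target: float
    n_loci: int
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    pop_coords: list[tuple[float, float]] = field(default_factory=list)
    cline_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fst_target < 1.0):
            raise PanelforgeError("fst_target must lie strictly in (0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise PanelforgeError("ancestral_maf_range must be within (0, 0.5]")
        if self.n_pops < 1 or self.n_loci < 1:
            raise PanelforgeError("n_pops and n_loci must be positive")
        if not self.pop_coords:
            # default: populations spread on a west->east line
            self.pop_coords = [(-70.0 + 10.0 * k, -10.0) for k in range(self.n_pops)]
        if len(self.pop_coords) != self.n_pops:
            raise PanelforgeError("pop_coords length must equal n_pops")
        if not (0.0 <= self.cline_fraction <= 1.0):
            raise PanelforgeError("cline_fraction must be in [0, 1]")


@dataclass
class PedigreeSpec:
    """A founder set plus matings, with genotyping error and missingness.

    ``matings`` is a list of ``(dam_id, sire_id, n_offspring)``; ids refer to
    founders ``"F0".."F{n-1}"`` or previously produced offspring, so
    multi-generation pedigrees are expressed by chaining matings.
    """

    founders: int
    matings: list[tuple[str, str, int]] = field(default_factory=list)
    genotyping_error: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.founders < 2:
            raise PanelforgeError("need at least 2 founders")
        for p in (self.genotyping_error, self.missing_rate):
            if not (0.0 <= p <= 1.0):
                raise PanelforgeError("probabilities must be in [0, 1]")


def _locus_table(n_loci: int, chrom: str = "1", spacing: int = 1000) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, n_loci + 1) * spacing,
            "ref": "A",
            "alt": "G",
        }
    )


def generate_structured_populations(
    model: PopulationModel, n_per_pop: int
) -> tuple[GenotypeMatrix, pd.DataFrame, AlleleFreqTable]:
    """Simulate K structured populations; returns genotypes, metadata, truth.

    Per-population frequencies are Balding–Nichols Beta draws around a
    Uniform(ancestral_maf_range) ancestral frequency; genotypes are
    Hardy–Weinberg binomial draws within each population.  Cline loci get
    frequencies increasing linearly with normalised longitude.  The third
    return value is the true per-population frequency table.
    """
    if n_per_pop < 2:
        raise PanelforgeError("n_per_pop must be >= 2")
    rng = np.random.default_rng(model.seed)
    F = model.fst_target
    lo, hi = model.ancestral_maf_range
    anc = rng.uniform(lo, hi, size=model.n_loci)

    shape_a = anc * (1.0 - F) / F
    shape_b = (1.0 - anc) * (1.0 - F) / F
    pop_freq = rng.beta(
        shape_a[None, :], shape_b[None, :], size=(model.n_pops, model.n_loci)
    )

    n_cline = int(round(model.cline_fraction * model.n_loci))
    if n_cline > 0 and model.n_pops > 1:
        cline_idx = rng.choice(model.n_loci, size=n_cline, replace=False)
        lons = np.asarray([c[0] for c in model.pop_coords])
        span = lons.max() - lons.min()
        t = (lons - lons.min()) / (span if span > 0 else 1.0)  # 0..1 west->east
        # monotone gradient from a low to a high frequency per cline locus
        f_lo = rng.uniform(0.05, 0.35, size=n_cline)
        f_hi = rng.uniform(0.65, 0.95, size=n_cline)
        pop_freq[:, cline_idx] = f_lo[None, :] + t[:, None] * (f_hi - f_lo)[None, :]

    doses, labels = [], []
    for k in range(model.n_pops):
        doses.append(
            rng.binomial(2, pop_freq[k], size=(n_per_pop, model.n_loci)).astype(np.int8)
        )
        labels.extend([f"pop{k}"] * n_per_pop)
    dosage = np.vstack(doses)
    samples = [f"S{i:04d}" for i in range(dosage.shape[0])]

    coords = np.repeat(np.asarray(model.pop_coords, dtype=float), n_per_pop, axis=0)
    # jitter individual locations around the population centroid
    coords = coords + rng.normal(0.0, 0.5, size=coords.shape)
    meta = pd.DataFrame(
        {
            "sample": samples,
            "pop": labels,
            "lon": coords[:, 0],
            "lat": coords[:, 1],
            "sex": rng.choice(["F", "M"], size=len(samples)),
        }
    )

    loci = _locus_table(model.n_loci)
    gm = GenotypeMatrix(dosage=dosage, samples=samples, loci=loci)
    groups = [f"pop{k}" for k in range(model.n_pops)]
    n_typed = np.full((model.n_pops, model.n_loci), n_per_pop, dtype=np.int64)
    # truth table stores the generating frequencies, not sample estimates
    truth = AlleleFreqTable(
        groups=groups,
        freq=pop_freq,
        n_typed=n_typed,
        geno_counts=np.zeros((model.n_pops, model.n_loci, 3), dtype=np.int64),
        loci=loci.copy(),
    )
    return gm, meta, truth


def _apply_error_channel(
    dosage: np.ndarray, freqs: np.ndarray, error: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-allele error: each of the two stored alleles is independently
    replaced, with probability ``error``, by a random population allele."""
    if error <= 0:
        return dosage
    n, m = dosage.shape
    out = dosage.copy()
    for allele_slot in range(2):
        hit = rng.random((n, m)) < error
        if not hit.any():
            continue
        rand_allele = (rng.random((n, m)) < freqs[None, :]).astype(np.int8)
        # decompose dosage into two slots: slot0 = first allele, slot1 = second
        slot = np.where(
            allele_slot == 0, np.minimum(out, 1), np.maximum(out - 1, 0)
        ).astype(np.int8)
        new_slot = np.where(hit, rand_allele, slot)
        other = out - slot
        out = (other + new_slot).astype(np.int8)
    return out


def generate_pedigree_genotypes(
    spec: PedigreeSpec, freqs: AlleleFreqTable, group: str | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate founders under HWE and offspring by Mendelian transmission.

    Returns genotypes plus a metadata table with truth columns ``dam`` and
    ``sire`` (empty string for founders).  Genotyping error is applied
    per allele at ``spec.genotyping_error``; calls are masked missing at
    ``spec.missing_rate``.
    """
    gi = 0 if group is None else freqs.group_index(group)
    p = freqs.freq[gi]
    if np.isnan(p).any():
        raise PanelforgeError("frequency table contains undefined loci")
    n_loci = p.size
    rng = np.random.default_rng(spec.seed)

    genos: dict[str, np.ndarray] = {}
    parents: dict[str, tuple[str, str]] = {}
    for i in range(spec.founders):
        genos[f"F{i}"] = rng.binomial(2, p, size=n_loci).astype(np.int8)
        parents[f"F{i}"] = ("", "")

    def _gamete(g: np.ndarray) -> np.ndarray:
        # one allele per locus, uniform among the parent's two
        pick = rng.random(n_loci)
        out = np.where(g == 1, (pick < 0.5).astype(np.int8), (g // 2).astype(np.int8))
        return out

    child_n = 0
    for dam, sire, n_off in spec.matings:
        for pid in (dam, sire):
            if pid not in genos:
                raise PanelforgeError(f"mating references unknown individual {pid!r}")
        for _ in range(n_off):
            cid = f"O{child_n}"
            child_n += 1
            genos[cid] = (_gamete(genos[dam]) + _gamete(genos[sire])).astype(np.int8)
            parents[cid] = (dam, sire)

    ids = list(genos)
    dosage = np.vstack([genos[i] for i in ids])
    dosage = _apply_error_channel(dosage, p, spec.genotyping_error, rng)
    if spec.missing_rate > 0:
        dosage[rng.random(dosage.shape) < spec.missing_rate] = MISSING

    meta = pd.DataFrame(
        {
            "sample": ids,
            "pop": "pedigree",
            "lon": 0.0,
            "lat": 0.0,
            "sex": rng.choice(["F", "M"], size=len(ids)),
            "dam": [parents[i][0] for i in ids],
            "sire": [parents[i][1] for i in ids],
        }
    )
    gm = GenotypeMatrix(dosage=dosage, samples=ids, loci=_locus_table(n_loci))
    return gm, meta


def generate_xlinked_loci(
    n_loci: int,
    n_diagnostic: int,
    sexes: Sequence[str],
    seed: int = 0,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Simulate X-chromosome loci with planted sex-diagnostic sites.

    At diagnostic loci every female is homozygous reference (dosage 0) and
    every male carries at least one alternative allele (dosage 1 or 2).
    Non-diagnostic loci are drawn sex-independently under HWE.  Returns
    the genotype matrix and the sorted planted locus indices.
    """
    sexes = list(sexes)
    if n_diagnostic > n_loci:
        raise PanelforgeError("n_diagnostic cannot exceed n_loci")
    uniq = set(sexes)
    if not {"F", "M"} <= uniq:
        raise PanelforgeError("both sexes must be present")
    rng = np.random.default_rng(seed)
    n = len(sexes)
    is_male = np.asarray([s == "M" for s in sexes])

    p = rng.uniform(0.05, 0.5, size=n_loci)
    dosage = rng.binomial(2, p, size=(n, n_loci)).astype(np.int8)
    diag = np.sort(rng.choice(n_loci, size=n_diagnostic, replace=False)) if n_diagnostic else np.array([], dtype=int)
    for j in diag:
        dosage[~is_male, j] = 0
        dosage[is_male, j] = rng.integers(1, 3, size=is_male.sum()).astype(np.int8)

    loci = _locus_table(n_loci, chrom="X")
    samples = [f"X{i:04d}" for i in range(n)]
    return GenotypeMatrix(dosage=dosage, samples=samples, loci=loci), diag
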