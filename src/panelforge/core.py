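"""Core data containers and file IO.

The universal substrate is a samples x loci allele-dosage matrix
(:class:`GenotypeMatrix`): each entry counts copies of the alternative
allele (0, 1, 2) with ``-1`` marking a missing call.  Per-sample metadata
(population / biome label, longitude, latitude, sex, optional pedigree
links) travels in a plain :class:`pandas.DataFrame` with a fixed column
contract (:data:`META_COLUMNS`).

VCF is the exchange format for genotypes (VCFv4.2, ``GT:DP``), read back
through :mod:`cyvcf2`; metadata is a TSV.  Round-tripping through
:func:`write_vcf` / :func:`read_vcf` preserves dosages, sample ids and
locus coordinates exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: required metadata columns, in canonical order
META_COLUMNS = ("sample", "pop", "lon", "lat", "sex")

LOCUS_COLUMNS = ("chrom", "pos", "ref", "alt")


class PanelforgeError(ValueError):
    """Base class for user-facing parameter / input errors."""


@dataclass
class GenotypeMatrix:
    """Samples x loci alt-allele dosage matrix with per-locus metadata.

    Parameters
    ----------
    dosage
        ``int8`` array of shape ``(n_samples, n_loci)`` with values in
        ``{0, 1, 2, -1}`` (-1 = missing call).
    samples
        Sample identifiers, one per row.
    loci
        Per-locus table with at least the columns ``chrom, pos, ref, alt``;
        optional columns (``qual``, ``info_*``) are carried along untouched.
    depth
        Optional per-call read depth, same shape as ``dosage``.
    """

    dosage: np.ndarray
    samples: list[str]
    loci: pd.DataFrame
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise PanelforgeError("dosage must be 2-D (samples x loci)")
        if len(self.samples) != self.dosage.shape[0]:
            raise PanelforgeError(
                f"{len(self.samples)} sample ids for {self.dosage.shape[0]} rows"
            )
        if len(self.loci) != self.dosage.shape[1]:
            raise PanelforgeError(
                f"{len(self.loci)} locus records for {self.dosage.shape[1]} columns"
            )
        missing_cols = [c for c in LOCUS_COLUMNS if c not in self.loci.columns]
        if missing_cols:
            raise PanelforgeError(f"loci table lacks columns {missing_cols}")
        if self.depth is not None and self.depth.shape != self.dosage.shape:
            raise PanelforgeError("depth shape does not match dosage")
        bad = (self.dosage > 2) | (self.dosage < MISSING)
        if bad.any():
            raise PanelforgeError("dosage values must be in {0,1,2,-1}")
        self.loci = self.loci.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    def dosage_float(self) -> np.ndarray:
        """Dosages as float with NaN for missing calls."""
        d = self.dosage.astype(float)
        d[self.dosage == MISSING] = np.nan
        return d

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def take_loci(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            dosage=self.dosage[:, idx],
            samples=list(self.samples),
            loci=self.loci.iloc[idx].reset_index(drop=True),
            depth=None if self.depth is None else self.depth[:, idx],
        )

    def take_samples(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            dosage=self.dosage[idx, :],
            samples=[self.samples[i] for i in idx],
            loci=self.loci.copy(),
            depth=None if self.depth is None else self.depth[idx, :],
        )

    def alt_freq(self) -> np.ndarray:
        """Per-locus alt-allele frequency over non-missing calls (NaN if none)."""
        d = self.dosage_float()
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)


@dataclass
class AlleleFreqTable:
    """Per-locus, per-group alt-allele frequencies with genotype counts.

    ``freq`` and ``n_typed`` have shape ``(n_groups, n_loci)``;
    ``geno_counts[g, l]`` holds counts of dosage 0/1/2.  A locus fully
    missing in a group carries ``freq = NaN`` and ``n_typed = 0``.
    """

    groups: list[str]
    freq: np.ndarray
    n_typed: np.ndarray
    geno_counts: np.ndarray
    loci: pd.DataFrame = field(default_factory=pd.DataFrame)

    def group_index(self, group: str) -> int:
        return self.groups.index(group)

    @property
    def n_loci(self) -> int:
        return self.freq.shape[1]


def group_allele_table(
    gm: GenotypeMatrix, labels: Sequence[str] | None = None
) -> AlleleFreqTable:
    """Tabulate genotype counts and alt frequencies, overall or by group."""
    if labels is None:
        labels = ["all"] * gm.n_samples
    labels = np.asarray(labels)
    groups = sorted(pd.unique(labels))
    n_g, n_l = len(groups), gm.n_loci
    counts = np.zeros((n_g, n_l, 3), dtype=np.int64)
    for gi, g in enumerate(groups):
        sub = gm.dosage[labels == g]
        for dose in (0, 1, 2):
            counts[gi, :, dose] = (sub == dose).sum(axis=0)
    n_typed = counts.sum(axis=2)
    alt = counts[:, :, 1] + 2 * counts[:, :, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(n_typed > 0, alt / (2.0 * n_typed), np.nan)
    return AlleleFreqTable(
        groups=list(groups), freq=freq, n_typed=n_typed, geno_counts=counts,
        loci=gm.loci.copy(),
    )


# ---------------------------------------------------------------------------
# VCF / TSV round-trip
# ---------------------------------------------------------------------------

_GT_BY_DOSE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCFv4.2 with GT:DP sample fields."""
    path = Path(path)
    contigs = list(pd.unique(gm.loci["chrom"].astype(str)))
    qual = gm.loci["qual"] if "qual" in gm.loci.columns else None
    info_cols = [c for c in gm.loci.columns if c.startswith("info_")]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=panelforge\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        for c in info_cols:
            fh.write(
                f'##INFO=<ID={c[5:]},Number=1,Type=Float,Description="{c[5:]}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j in range(gm.n_loci):
            row = gm.loci.iloc[j]
            q = "." if qual is None or pd.isna(qual.iloc[j]) else f"{qual.iloc[j]:g}"
            if info_cols:
                info = ";".join(
                    f"{c[5:]}={row[c]:g}" for c in info_cols if pd.notna(row[c])
                ) or "."
            else:
                info = "."
            cells = []
            for i in range(gm.n_samples):
                gt = _GT_BY_DOSE[int(gm.dosage[i, j])]
                dp = "." if gm.depth is None else str(int(gm.depth[i, j]))
                cells.append(f"{gt}:{dp}")
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}"
                f"\t{q}\tPASS\t{info}\tGT:DP\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load biallelic diploid genotypes from a VCF into a dosage matrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    doses, depths, records = [], [], []
    has_depth = True
    for var in vcf:
        gt = np.asarray(var.gt_types, dtype=np.int8)  # 0/1/2, 3 = missing
        gt[gt == 3] = MISSING
        doses.append(gt)
        try:
            dp = var.format("DP")
            depths.append(
                np.full(len(samples), 0, dtype=np.int32)
                if dp is None
                else np.where(dp[:, 0] < 0, 0, dp[:, 0]).astype(np.int32)
            )
            if dp is None:
                has_depth = False
        except Exception:
            has_depth = False
        rec = {
            "chrom": var.CHROM,
            "pos": var.POS,
            "ref": var.REF,
            "alt": var.ALT[0] if var.ALT else ".",
        }
        if var.QUAL is not None:
            rec["qual"] = var.QUAL
        for key, val in dict(var.INFO).items():
            try:
                rec[f"info_{key}"] = float(val)
            except (TypeError, ValueError):
                pass
        records.append(rec)
    vcf.close()
    loci = pd.DataFrame(records)
    dosage = np.column_stack(doses) if doses else np.zeros((len(samples), 0), np.int8)
    depth = np.column_stack(depths) if (has_depth and depths) else None
    return GenotypeMatrix(dosage=dosage, samples=samples, loci=loci, depth=depth)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise PanelforgeError(f"metadata lacks columns {missing}")
    meta.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample": str, "pop": str, "sex": str})
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise PanelforgeError(f"metadata file {path} lacks columns {missing}")
    return meta


def write_fixture(
    gm: GenotypeMatrix, meta: pd.DataFrame, prefix: str | Path
) -> tuple[Path, Path]:
    """Write a genotype VCF + metadata TSV pair sharing a path prefix."""
    if len(meta) != gm.n_samples:
        raise PanelforgeError(
            f"metadata rows ({len(meta)}) != samples ({gm.n_samples})"
        )
    if list(meta["sample"]) != list(gm.samples):
        raise PanelforgeError("metadata sample ids do not match genotype matrix")
    prefix = Path(prefix)
    vcf_path = prefix.with_suffix(".vcf")
    meta_path = prefix.with_suffix(".meta.tsv")
    write_vcf(gm, vcf_path)
    write_metadata(meta, meta_path)
    return vcf_path, meta_path


def read_fixture(prefix: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    prefix = Path(prefix)
    return read_vcf(prefix.with_suffix(".vcf")), read_metadata(
        prefix.with_suffix(".meta.tsv")
    )


def dataclass_replace(obj, **kw):
    return dataclasses.replace(obj, **kw)
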