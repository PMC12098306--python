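"""Forensic power statistics for a marker panel.

Per-locus kernels operating on an allele-frequency vector:

* PIC — Botstein polymorphic information content,
  ``1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2``;
* PID — probability that two unrelated individuals share a genotype,
  ``sum p_i^4 + sum_{i<j} (2 p_i p_j)^2``;
* PIDsibs — the full-sib analogue,
  ``0.25 + 0.5 a2 + 0.5 a2^2 - 0.25 a4`` with ``a_k = sum p_i^k``;
* the five non-exclusion probabilities (NE-1P, NE-2P, NE-PP, NE-I, NE-SI),
  computed by exact enumeration of Mendelian-compatible genotype
  configurations under Hardy–Weinberg proportions (NE-I and NE-SI reduce
  to PID and PIDsibs).

Multi-locus power multiplies per-locus values across independent loci;
:func:`cumulative_min_loci` finds the smallest panel whose cumulative
probability of identity crosses a cutoff (0.0001 by convention).

No small-sample bias corrections are applied anywhere: all quantities are
plug-in functions of the supplied allele frequencies.
"""

from __future__ import annotations

from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from .core import AlleleFreqTable, GenotypeMatrix, PanelforgeError, group_allele_table

__all__ = [
    "pic",
    "pid_locus",
    "pid_sibs_locus",
    "cumulative_min_loci",
    "non_exclusion",
    "locus_power_table",
    "panel_power_summary",
    "NE_CATEGORIES",
]

NE_CATEGORIES = ("NE-1P", "NE-2P", "NE-PP", "NE-I", "NE-SI")


def _check_freqs(freqs) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if (p < 0).any():
        raise PanelforgeError("allele frequencies must be non-negative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise PanelforgeError("allele frequencies must sum to 1")
    return p


def _pairs(n: int):
    from itertools import combinations as _c

    return _c(range(n), 2)


def pic(freqs) -> float:
    """Botstein polymorphic information content of one locus."""
    p = _check_freqs(freqs)
    sum_sq = float((p**2).sum())
    cross = sum(2.0 * p[i] ** 2 * p[j] ** 2 for i, j in _pairs(p.size))
    return 1.0 - sum_sq - cross


def pid_locus(freqs) -> float:
    """Probability that two unrelated individuals match at this locus."""
    p = _check_freqs(freqs)
    hom = float((p**4).sum())
    het = sum((2.0 * p[i] * p[j]) ** 2 for i, j in _pairs(p.size))
    return hom + het


def pid_sibs_locus(freqs) -> float:
    """Probability that two full siblings match at this locus."""
    p = _check_freqs(freqs)
    a2 = float((p**2).sum())
    a4 = float((p**4).sum())
    return 0.25 + 0.5 * a2 + 0.5 * a2**2 - 0.25 * a4


def cumulative_min_loci(
    per_locus_values, cutoff: float = 1e-4, order: str = "ascending"
) -> int | None:
    """Smallest k such that the product of the k most informative per-locus
    probabilities falls strictly below ``cutoff``.

    ``order='ascending'`` sorts values ascending (most informative first);
    ``order='given'`` keeps the input order.  Returns None when the full
    product never crosses the cutoff.
    """
    vals = np.asarray(per_locus_values, dtype=float)
    if vals.size == 0:
        raise PanelforgeError("need at least one locus")
    if (vals <= 0).any() or (vals > 1).any():
        raise PanelforgeError("per-locus probabilities must be in (0, 1]")
    if not (0.0 < cutoff < 1.0):
        raise PanelforgeError("cutoff must be in (0, 1)")
    if order == "ascending":
        vals = np.sort(vals)
    elif order != "given":
        raise PanelforgeError("order must be 'ascending' or 'given'")
    log_cum = np.cumsum(np.log(vals))
    below = np.where(log_cum < np.log(cutoff))[0]
    return int(below[0]) + 1 if below.size else None


# ---------------------------------------------------------------------------
# Non-exclusion probabilities by exact enumeration
# ---------------------------------------------------------------------------

def _genotypes(k: int):
    """Unordered genotypes (i <= j) over k alleles."""
    return list(combinations_with_replacement(range(k), 2))


def _hwe_prob(g, p) -> float:
    i, j = g
    return p[i] ** 2 if i == j else 2.0 * p[i] * p[j]


def _transition(child, mother, father) -> float:
    """P(child unordered genotype | parent genotypes), Mendelian."""
    prob = 0.0
    for ma in mother:
        for fa in father:
            if tuple(sorted((ma, fa))) == child:
                prob += 0.25
    return prob


def _share_allele(g1, g2) -> bool:
    return bool(set(g1) & set(g2))


def _second_parent_compatible(child, mother, candidate) -> bool:
    """Candidate can be the second parent given the first (mother)."""
    a, b = child
    for m_allele, p_allele in ((a, b), (b, a)):
        if m_allele in mother and p_allele in candidate:
            return True
    return False


def non_exclusion(freqs, category: str) -> float:
    """Per-locus non-exclusion probability for one of the five categories.

    NE-1P: a random unrelated candidate is not excluded as a sole parent of
    a random offspring.  NE-2P: not excluded as the second parent when the
    true first parent is known.  NE-PP: a random unrelated pair is not
    excluded as the parent pair.  NE-I and NE-SI are the identity
    probabilities PID and PIDsibs.
    """
    p = _check_freqs(freqs)
    if category == "NE-I":
        return pid_locus(p)
    if category == "NE-SI":
        return pid_sibs_locus(p)
    if category not in NE_CATEGORIES:
        raise PanelforgeError(f"unknown category {category!r}")
    genos = _genotypes(p.size)
    probs = {g: _hwe_prob(g, p) for g in genos}
    total = 0.0
    if category == "NE-1P":
        for off, po in probs.items():
            for cand, pc in probs.items():
                if _share_allele(off, cand):
                    total += po * pc
        return total
    if category == "NE-PP":
        for off, po in probs.items():
            for c1, p1 in probs.items():
                for c2, p2 in probs.items():
                    if _transition(off, c1, c2) > 0:
                        total += po * p1 * p2
        return total
    # NE-2P: true mother known, candidate second parent unrelated
    for mom, pm in probs.items():
        for dad, pf in probs.items():
            for off in genos:
                t = _transition(off, mom, dad)
                if t == 0:
                    continue
                for cand, pc in probs.items():
                    if _second_parent_compatible(off, mom, cand):
                        total += pm * pf * t * pc
    return total


# ---------------------------------------------------------------------------
# Panel-level tables
# ---------------------------------------------------------------------------

def locus_power_table(freq_alt: np.ndarray) -> pd.DataFrame:
    """Per-locus power statistics for biallelic loci given alt frequencies."""
    rows = []
    for j, q in enumerate(np.asarray(freq_alt, dtype=float)):
        if np.isnan(q):
            raise PanelforgeError(f"undefined frequency at locus {j}")
        p = np.array([1.0 - q, q])
        rows.append(
            {
                "locus_index": j,
                "p_alt": q,
                "maf": min(q, 1 - q),
                "he": 2 * q * (1 - q),
                "pic": pic(p),
                "pid": pid_locus(p),
                "pid_sibs": pid_sibs_locus(p),
                "ne_1p": non_exclusion(p, "NE-1P"),
                "ne_2p": non_exclusion(p, "NE-2P"),
                "ne_pp": non_exclusion(p, "NE-PP"),
                "ne_i": non_exclusion(p, "NE-I"),
                "ne_si": non_exclusion(p, "NE-SI"),
            }
        )
    return pd.DataFrame(rows)


def panel_power_summary(
    gm: GenotypeMatrix, pid_cutoff: float = 1e-4
) -> tuple[pd.DataFrame, dict]:
    """Per-locus power table plus a panel summary.

    The summary reports panel size, mean typed proportion, mean He / MAF /
    PIC, combined non-exclusion probabilities (products across loci), and
    the minimum locus counts crossing the probability-of-identity cutoff.
    """
    table_src = group_allele_table(gm)
    q = table_src.freq[0]
    table = locus_power_table(q)
    typed = 1.0 - gm.missing_mask().mean()
    combined = {
        c: float(np.exp(np.log(table[k]).sum()))
        for c, k in zip(NE_CATEGORIES, ("ne_1p", "ne_2p", "ne_pp", "ne_i", "ne_si"))
    }
    summary = {
        "n_loci": gm.n_loci,
        "mean_alleles_per_locus": 2.0,
        "mean_prop_typed": float(typed),
        "mean_he": float(table["he"].mean()),
        "mean_maf": float(table["maf"].mean()),
        "mean_pic": float(table["pic"].mean()),
        "combined_non_exclusion": combined,
        "min_loci_pid": cumulative_min_loci(table["pid"], pid_cutoff),
        "min_loci_pid_sibs": cumulative_min_loci(table["pid_sibs"], pid_cutoff),
    }
    return table, summary
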