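"""Identity matching, parentage LOD scores, and pairwise relationship
classification.

* :func:`identity_match` — two profiles are called the same individual
  when they share at least ``min_typed`` of their loci and disagree at no
  more than ``max_mismatch`` of the co-typed loci.
* :func:`parentage_lod` — per-candidate log likelihood ratio of
  "candidate is a parent" vs "candidate is unrelated", with an error
  model that, at rate e, replaces the Mendelian transmission probability
  by the Hardy–Weinberg genotype probability (the class-II simplification
  of the CERVUS/Marshall error model: a genotype is a random population
  draw with probability e).
* :func:`critical_delta` — Monte-Carlo critical values for the Δ
  statistic (LOD gap between the two most likely candidates), chosen so
  that accepted assignments reach a stated confidence (default strict
  0.95, relaxed 0.80).
* :func:`ml_relationship` — maximum-likelihood classification of a pair
  into Unrelated / Half-sib / Full-sib / Parent–Offspring via the
  k-coefficients (probability of sharing 0/1/2 alleles identical by
  descent), with simulation-based consistency testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PanelforgeError

__all__ = [
    "RELATIONSHIP_MODELS",
    "ParentageConfig",
    "identity_match",
    "parentage_lod",
    "critical_delta",
    "ml_relationship",
    "pair_loglik",
]

#: k-coefficients (k0, k1, k2) of the four classified relationships
RELATIONSHIP_MODELS: dict[str, tuple[float, float, float]] = {
    "U": (1.0, 0.0, 0.0),
    "HS": (0.5, 0.5, 0.0),
    "FS": (0.25, 0.5, 0.25),
    "PO": (0.0, 1.0, 0.0),
}


@dataclass
class ParentageConfig:
    """Simulation settings for parentage critical values (field-standard
    defaults: 1% genotyping error, half the loci required typed, 20% of
    parents sampled, 95% strict / 80% relaxed confidence)."""

    n_sim_offspring: int = 10_000
    genotyping_error: float = 0.01
    min_typed_fraction: float = 0.5
    prop_parents_sampled: float = 0.2
    confidence: float = 0.95
    relaxed_confidence: float = 0.80
    n_candidates: int = 5

    def __post_init__(self) -> None:
        for name in (
            "genotyping_error",
            "min_typed_fraction",
            "prop_parents_sampled",
            "confidence",
            "relaxed_confidence",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise PanelforgeError(f"{name} must be in [0, 1]")
        if self.n_sim_offspring < 1 or self.n_candidates < 1:
            raise PanelforgeError("simulation sizes must be positive")


# ---------------------------------------------------------------------------
# Identity matching
# ---------------------------------------------------------------------------

def identity_match(
    query: np.ndarray,
    database: GenotypeMatrix,
    min_typed: float = 0.9,
    max_mismatch: float = 0.05,
) -> pd.DataFrame:
    """Match one dosage profile against a database of profiles.

    A database entry matches when the co-typed fraction of loci is at
    least ``min_typed`` and the fraction of co-typed loci with differing
    dosages is at most ``max_mismatch``.
    """
    query = np.asarray(query)
    if query.size != database.n_loci:
        raise PanelforgeError("query length does not match database loci")
    rows = []
    q_typed = query != MISSING
    for i, sid in enumerate(database.samples):
        d = database.dosage[i]
        co = q_typed & (d != MISSING)
        n_co = int(co.sum())
        frac_typed = n_co / database.n_loci
        mism = int((query[co] != d[co]).sum()) if n_co else 0
        frac_mism = mism / n_co if n_co else 1.0
        rows.append(
            {
                "sample": sid,
                "co_typed": n_co,
                "frac_typed": frac_typed,
                "mismatches": mism,
                "frac_mismatch": frac_mism,
                "match": frac_typed >= min_typed and frac_mism <= max_mismatch,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Parentage LOD
# ---------------------------------------------------------------------------

def _hwe_probs(q: float) -> np.ndarray:
    """HWE genotype probabilities (dose 0,1,2) for alt frequency q."""
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])


def parentage_lod(
    offspring: np.ndarray,
    candidate: np.ndarray,
    freqs: np.ndarray,
    known_parent: np.ndarray | None = None,
    error_rate: float = 0.0,
    base: str = "e",
) -> float:
    """LOD score of the candidate being a parent of the offspring.

    Per typed locus, the likelihood under H1 uses the Mendelian
    transmission probability given the candidate (and known parent when
    provided), error-mixed as (1 - e) * T + e * P_HWE(offspring); the H0
    likelihood is the offspring probability with the candidate unrelated
    (the known parent, if any, is still a parent under H0).  The LOD is
    the summed log ratio (natural log by default, ``base='10'`` for
    log10).  Opposing homozygotes at error 0 give -inf (exclusion).
    """
    if not (0.0 <= error_rate < 1.0):
        raise PanelforgeError("error_rate must be in [0, 1)")
    offspring = np.asarray(offspring)
    candidate = np.asarray(candidate)
    q = np.asarray(freqs, dtype=float)
    if q.size != offspring.size or candidate.size != offspring.size:
        raise PanelforgeError("freqs and genotypes must have equal length")
    typed = (offspring != MISSING) & (candidate != MISSING)
    if known_parent is not None:
        known_parent = np.asarray(known_parent)
        typed &= known_parent != MISSING
    if not typed.any():
        raise PanelforgeError("no co-typed loci")
    go = offspring[typed].astype(float)
    gc = candidate[typed].astype(float)
    qt = q[typed]
    hwe_o = np.choose(
        go.astype(int),
        [(1 - qt) ** 2, 2 * qt * (1 - qt), qt**2],
    )

    def _one_parent(par_dose: np.ndarray, mate_q: np.ndarray) -> np.ndarray:
        pa = par_dose / 2.0
        return np.choose(
            go.astype(int),
            [
                (1 - pa) * (1 - mate_q),
                pa * (1 - mate_q) + (1 - pa) * mate_q,
                pa * mate_q,
            ],
        )

    if known_parent is None:
        t1 = _one_parent(gc, qt)
        l0 = hwe_o
    else:
        gk = known_parent[typed].astype(float)
        pm, pf_ = gk / 2.0, gc / 2.0
        t1 = np.choose(
            go.astype(int),
            [
                (1 - pm) * (1 - pf_),
                pm * (1 - pf_) + (1 - pm) * pf_,
                pm * pf_,
            ],
        )
        l0 = _one_parent(gk, qt)
    l1 = (1 - error_rate) * t1 + error_rate * hwe_o
    with np.errstate(divide="ignore"):
        total = float((np.log(l1) - np.log(l0)).sum())
    if base == "10":
        total /= np.log(10.0)
    elif base != "e":
        raise PanelforgeError("base must be 'e' or '10'")
    return float(total)


# ---------------------------------------------------------------------------
# Critical Δ by simulation
# ---------------------------------------------------------------------------

def critical_delta(
    freqs: np.ndarray,
    config: ParentageConfig,
    seed: int = 0,
    return_details: bool = False,
):
    """Simulate offspring/candidate pools and derive Δ critical values.

    Each replicate draws a true parent pair from HWE, produces an
    offspring, applies the genotyping-error channel, and builds a
    candidate pool of ``n_candidates`` profiles in which the true parent
    is present with probability ``prop_parents_sampled``.  Δ is the LOD
    gap between the two most likely candidates (or the top LOD when only
    one is positive).  The strict (relaxed) threshold is the smallest Δ
    at which the fraction of accepted assignments that name the true
    parent reaches ``confidence`` (``relaxed_confidence``); returns
    (delta_strict, delta_relaxed).
    """
    q = np.asarray(freqs, dtype=float)
    if q.size == 0:
        raise PanelforgeError("need at least one locus")
    rng = np.random.default_rng(seed)
    e = config.genotyping_error
    n_loci = q.size

    def observe(g: np.ndarray) -> np.ndarray:
        if e <= 0:
            return g
        out = g.copy()
        hit = rng.random(n_loci) < e
        if hit.any():
            rand = rng.binomial(2, q[hit])
            out[hit] = rand
        return out

    deltas = np.empty(config.n_sim_offspring)
    correct = np.zeros(config.n_sim_offspring, dtype=bool)
    for s in range(config.n_sim_offspring):
        mother = rng.binomial(2, q)
        father = rng.binomial(2, q)
        offspring = observe(_transmission_two_parents_vec(mother, father, rng))
        true_sampled = rng.random() < config.prop_parents_sampled
        pool = []
        if true_sampled:
            pool.append(("true", observe(father)))
        n_unrel = config.n_candidates - len(pool)
        for u in range(n_unrel):
            pool.append((f"u{u}", observe(rng.binomial(2, q))))
        lods = np.array(
            [
                parentage_lod(offspring, cand, q, known_parent=None, error_rate=max(e, 1e-4))
                for _, cand in pool
            ]
        )
        order = np.argsort(lods)[::-1]
        top = lods[order[0]]
        second = lods[order[1]] if len(pool) > 1 else 0.0
        deltas[s] = top - second if len(pool) > 1 else top
        correct[s] = pool[order[0]][0] == "true" and top > 0
    strict = _delta_threshold(deltas, correct, config.confidence)
    relaxed = _delta_threshold(deltas, correct, config.relaxed_confidence)
    if return_details:
        details = pd.DataFrame({"delta": deltas, "correct": correct})
        return strict, relaxed, details
    return strict, relaxed


def _transmission_two_parents_vec(
    mother: np.ndarray, father: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    m_all = np.where(
        mother == 1, (rng.random(mother.size) < 0.5).astype(np.int8), mother // 2
    )
    f_all = np.where(
        father == 1, (rng.random(father.size) < 0.5).astype(np.int8), father // 2
    )
    return (m_all + f_all).astype(np.int8)


def _delta_threshold(deltas: np.ndarray, correct: np.ndarray, conf: float) -> float:
    """Smallest Δ at which precision of accepted assignments >= conf."""
    order = np.argsort(deltas)[::-1]
    d_sorted = deltas[order]
    c_sorted = correct[order].astype(float)
    cum_correct = np.cumsum(c_sorted)
    n_accept = np.arange(1, deltas.size + 1)
    precision = cum_correct / n_accept
    ok = precision >= conf
    if not ok.any():
        return float(d_sorted[0])
    last = np.where(ok)[0].max()
    return float(max(d_sorted[last], 0.0))


# ---------------------------------------------------------------------------
# ML relationship classification
# ---------------------------------------------------------------------------

def _pair_locus_lik(g1: int, g2: int, q: float, k: tuple[float, float, float]) -> float:
    """P(unordered genotype pair | k-coefficients) at one biallelic locus."""
    p = np.array([1.0 - q, q])
    p1 = _hwe_probs(q)[g1]
    # S0: independent; S2: identical genotypes; S1: one shared IBD allele
    s0 = p1 * _hwe_probs(q)[g2]
    s2 = p1 if g1 == g2 else 0.0
    # S1 per standard unordered-pair tables
    if g1 == g2 == 1:  # (ij, ij)
        s1 = p[0] * p[1] * (p[0] + p[1])
    elif g1 == 1 or g2 == 1:  # one het, one hom: shared allele is the hom's
        hom = g1 if g1 != 1 else g2
        i = 0 if hom == 0 else 1
        s1 = p[i] ** 2 * p[1 - i]
    elif g1 == g2:  # (ii, ii)
        i = 0 if g1 == 0 else 1
        s1 = p[i] ** 3
    else:  # opposing homozygotes
        s1 = 0.0
    k0, k1, k2 = k
    return k0 * s0 + k1 * s1 + k2 * s2


def pair_loglik(
    g1: np.ndarray,
    g2: np.ndarray,
    freqs: np.ndarray,
    category: str,
    error_rate: float = 0.0,
) -> float:
    """Log-likelihood of a genotype pair under one relationship category.

    With error rate e, each observed genotype is an independent random
    HWE draw with probability e, mixing the pair likelihood with the
    product of marginals.
    """
    if category not in RELATIONSHIP_MODELS:
        raise PanelforgeError(f"unknown category {category!r}")
    k = RELATIONSHIP_MODELS[category]
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    q = np.asarray(freqs, dtype=float)
    typed = (g1 != MISSING) & (g2 != MISSING)
    if not typed.any():
        raise PanelforgeError("no co-typed loci")
    keep = (1 - error_rate) ** 2
    total = 0.0
    for j in np.where(typed)[0]:
        lik = _pair_locus_lik(int(g1[j]), int(g2[j]), float(q[j]), k)
        marg = _hwe_probs(float(q[j]))[int(g1[j])] * _hwe_probs(float(q[j]))[int(g2[j])]
        mixed = keep * lik + (1 - keep) * marg
        with np.errstate(divide="ignore"):
            total += np.log(mixed)
    return float(total)


def ml_relationship(
    g1: np.ndarray,
    g2: np.ndarray,
    freqs: np.ndarray,
    error_rate: float = 0.0,
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[str, dict[str, float], list[str]]:
    """Classify a pair into U / HS / FS / PO by maximum likelihood.

    Returns (best category, per-category log-likelihoods, consistent
    categories).  A non-best category R is retained as consistent when
    the observed log-likelihood ratio best-vs-R is not extreme relative
    to ``n_sim`` pairs simulated under R (one-sided, level ``alpha``).
    """
    q = np.asarray(freqs, dtype=float)
    logls = {
        cat: pair_loglik(g1, g2, q, cat, error_rate) for cat in RELATIONSHIP_MODELS
    }
    best = max(logls, key=lambda c: logls[c])
    rng = np.random.default_rng(seed)
    consistent = [best]
    obs_gap = {c: logls[best] - logls[c] for c in logls}
    for cat in RELATIONSHIP_MODELS:
        if cat == best or not np.isfinite(logls[cat]):
            continue
        null_gaps = np.empty(n_sim)
        for s in range(n_sim):
            s1, s2 = _simulate_pair(q, cat, rng, error_rate)
            null_gaps[s] = pair_loglik(s1, s2, q, best, error_rate) - pair_loglik(
                s1, s2, q, cat, error_rate
            )
        p_val = (1.0 + (null_gaps >= obs_gap[cat]).sum()) / (n_sim + 1.0)
        if p_val > alpha:
            consistent.append(cat)
    return best, logls, consistent


def _simulate_pair(
    q: np.ndarray, category: str, rng: np.random.Generator, error_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a genotype pair under a relationship's k-coefficients."""
    k0, k1, k2 = RELATIONSHIP_MODELS[category]
    n = q.size
    mode = rng.choice(3, size=n, p=[k0, k1, k2])
    a1 = (rng.random(n) < q).astype(np.int8)
    a2 = (rng.random(n) < q).astype(np.int8)
    b1 = (rng.random(n) < q).astype(np.int8)
    b2 = (rng.random(n) < q).astype(np.int8)
    # share 1 allele: copy a1 into b1; share 2: copy both
    b1 = np.where(mode >= 1, a1, b1)
    b2 = np.where(mode == 2, a2, b2)
    g1 = (a1 + a2).astype(np.int8)
    g2 = (b1 + b2).astype(np.int8)
    if error_rate > 0:
        for g in (g1, g2):
            hit = rng.random(n) < error_rate
            g[hit] = rng.binomial(2, q[hit]).astype(np.int8)
    return g1, g2
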