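"""Synthetic-data generator: structure recovery, pedigrees, X-linked loci,
fixture round-trips."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from panelforge import (
    AlleleFreqTable,
    PanelforgeError,
    PedigreeSpec,
    PopulationModel,
    generate_pedigree_genotypes,
    generate_structured_populations,
    generate_xlinked_loci,
    read_fixture,
    select_sex_linked,
    weir_cockerham_fst,
    write_fixture,
)


def make_freq_table(freqs):
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    n_g, n_l = freqs.shape
    return AlleleFreqTable(
        groups=[f"g{i}" for i in range(n_g)],
        freq=freqs,
        n_typed=np.full((n_g, n_l), 50),
        geno_counts=np.zeros((n_g, n_l, 3), dtype=np.int64),
        loci=pd.DataFrame(
            {"chrom": "1", "pos": np.arange(1, n_l + 1), "ref": "A", "alt": "G"}
        ),
    )


# ---------------------------------------------------------------------------
# Structured populations
# ---------------------------------------------------------------------------

def test_model_validation():
    with pytest.raises(PanelforgeError):
        PopulationModel(n_pops=2, fst_target=0.0, n_loci=10)
    with pytest.raises(PanelforgeError):
        PopulationModel(n_pops=2, fst_target=0.1, n_loci=10,
                        ancestral_maf_range=(0.0, 0.6))
    with pytest.raises(PanelforgeError):
        PopulationModel(n_pops=3, fst_target=0.1, n_loci=10,
                        pop_coords=[(0, 0)])


def test_same_seed_is_bit_identical():
    model = PopulationModel(n_pops=2, fst_target=0.1, n_loci=200, seed=5)
    gm1, meta1, _ = generate_structured_populations(model, 5)
    gm2, meta2, _ = generate_structured_populations(model, 5)
    assert (gm1.dosage == gm2.dosage).all()
    assert meta1.equals(meta2)


def test_dosages_and_truth_frequencies_in_range():
    model = PopulationModel(n_pops=3, fst_target=0.1, n_loci=300, seed=6,
                            cline_fraction=0.3)
    gm, meta, truth = generate_structured_populations(model, 8)
    assert set(np.unique(gm.dosage)) <= {0, 1, 2}
    assert ((truth.freq >= 0) & (truth.freq <= 1)).all()
    assert len(meta) == gm.n_samples


def test_near_zero_differentiation_gives_near_zero_theta():
    model = PopulationModel(n_pops=2, fst_target=1e-4, n_loci=5000, seed=8)
    gm, meta, _ = generate_structured_populations(model, 50)
    fst = weir_cockerham_fst(gm, meta["pop"])
    assert abs(fst.weighted_theta(fst.pairs[0])) < 0.01


@pytest.mark.parametrize("target", [0.02, 0.05, 0.2])
def test_fst_recovery_across_targets(target):
    """Multi-locus Weir-Cockerham theta recovers the generating F within
    20% relative error (mean over replicates, 5000 loci, 50 per pop)."""
    thetas = []
    for rep in range(3):
        model = PopulationModel(
            n_pops=2, fst_target=target, n_loci=5000, seed=100 + rep
        )
        gm, meta, _ = generate_structured_populations(model, 50)
        fst = weir_cockerham_fst(gm, meta["pop"])
        thetas.append(fst.weighted_theta(fst.pairs[0]))
    assert 0.8 * target <= np.mean(thetas) <= 1.2 * target


def test_cline_loci_are_monotone_in_longitude():
    model = PopulationModel(n_pops=4, fst_target=0.05, n_loci=100, seed=9,
                            cline_fraction=1.0)
    _, _, truth = generate_structured_populations(model, 4)
    diffs = np.diff(truth.freq, axis=0)  # pops ordered west -> east
    assert (diffs >= -1e-12).all()


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------

def test_mendelian_consistency_without_error():
    freqs = make_freq_table(np.random.default_rng(1).uniform(0.2, 0.8, 200))
    spec = PedigreeSpec(
        founders=4,
        matings=[("F0", "F1", 3), ("F2", "F3", 2), ("O0", "F2", 1)],
        seed=2,
    )
    gm, meta = generate_pedigree_genotypes(spec, freqs)
    geno = {s: gm.dosage[i] for i, s in enumerate(gm.samples)}
    rel = meta.set_index("sample")
    for child in rel.index[rel["dam"] != ""]:
        for parent in (rel.loc[child, "dam"], rel.loc[child, "sire"]):
            opposing = (
                ((geno[child] == 0) & (geno[parent] == 2))
                | ((geno[child] == 2) & (geno[parent] == 0))
            )
            assert not opposing.any()


def test_pedigree_truth_is_acyclic_and_complete():
    freqs = make_freq_table(np.full(50, 0.5))
    spec = PedigreeSpec(
        founders=2, matings=[("F0", "F1", 2), ("O0", "F1", 1)], seed=3
    )
    _, meta = generate_pedigree_genotypes(spec, freqs)
    rel = meta.set_index("sample")

    def ancestors(i, seen=()):
        assert i not in seen, "pedigree cycle"
        out = set()
        for p in (rel.loc[i, "dam"], rel.loc[i, "sire"]):
            if p:
                out |= {p} | ancestors(p, seen + (i,))
        return out

    for ind in rel.index:
        anc = ancestors(ind)
        assert ind not in anc
        assert anc <= set(rel.index)


def test_unknown_mating_reference_errors():
    freqs = make_freq_table(np.full(10, 0.5))
    with pytest.raises(PanelforgeError, match="unknown"):
        generate_pedigree_genotypes(
            PedigreeSpec(founders=2, matings=[("F0", "F9", 1)]), freqs
        )


def _opposing_hom_rate_oracle(p, e):
    """Enumerate the joint distribution of one parent's and one offspring's
    observed genotypes under the per-allele error channel and return the
    probability of opposing homozygotes."""
    pr = lambda a: p if a == 1 else 1 - p

    def observed(dose_alleles, errs, reps):
        out = []
        for a, hit, rep in zip(dose_alleles, errs, reps):
            out.append(rep if hit else a)
        return sum(out)

    total = 0.0
    for m1, m2 in product((0, 1), repeat=2):
        for f1, f2 in product((0, 1), repeat=2):
            for tm, tf in product((0, 1), repeat=2):
                child = ((m1, m2)[tm], (f1, f2)[tf])
                base = pr(m1) * pr(m2) * pr(f1) * pr(f2) * 0.25
                for em1, em2, ec1, ec2 in product((0, 1), repeat=4):
                    pe = (e if em1 else 1 - e) * (e if em2 else 1 - e)
                    pe *= (e if ec1 else 1 - e) * (e if ec2 else 1 - e)
                    for r1, r2, r3, r4 in product((0, 1), repeat=4):
                        # replacement alleles are drawn regardless; unused
                        # ones integrate out under their own distribution
                        prep = pr(r1) * pr(r2) * pr(r3) * pr(r4)
                        mo = observed((m1, m2), (em1, em2), (r1, r2))
                        co = observed(child, (ec1, ec2), (r3, r4))
                        if {mo, co} == {0, 2}:
                            total += base * pe * prep
    return total


def test_parent_offspring_opposing_homozygote_rate_matches_oracle():
    """With 1% per-allele error the observed dam-offspring opposing-
    homozygote rate matches the closed-form enumeration within binomial
    noise (+-50% relative)."""
    p, e = 0.3, 0.01
    expected = _opposing_hom_rate_oracle(p, e)
    freqs = make_freq_table(np.full(459, p))
    rate_num, rate_den = 0, 0
    for s in range(25):
        spec = PedigreeSpec(
            founders=2, matings=[("F0", "F1", 4)], genotyping_error=e, seed=s
        )
        gm, meta = generate_pedigree_genotypes(spec, freqs)
        geno = {sid: gm.dosage[i] for i, sid in enumerate(gm.samples)}
        for child in [s for s in gm.samples if s.startswith("O")]:
            opp = ((geno[child] == 0) & (geno["F0"] == 2)) | (
                (geno[child] == 2) & (geno["F0"] == 0)
            )
            rate_num += opp.sum()
            rate_den += len(opp)
    observed = rate_num / rate_den
    assert 0.5 * expected <= observed <= 1.5 * expected


def test_founder_heterozygosity_matches_hwe_expectation():
    rng = np.random.default_rng(4)
    p = rng.uniform(0.1, 0.9, 300)
    freqs = make_freq_table(p)
    spec = PedigreeSpec(founders=1000, seed=5)
    gm, _ = generate_pedigree_genotypes(spec, freqs)
    obs_het = (gm.dosage == 1).mean()
    assert obs_het == pytest.approx((2 * p * (1 - p)).mean(), abs=0.02)


def test_missing_rate_applied():
    freqs = make_freq_table(np.full(500, 0.5))
    spec = PedigreeSpec(founders=20, missing_rate=0.1, seed=6)
    gm, _ = generate_pedigree_genotypes(spec, freqs)
    assert gm.missing_mask().mean() == pytest.approx(0.1, abs=0.02)


# ---------------------------------------------------------------------------
# X-linked loci
# ---------------------------------------------------------------------------

def test_planted_diagnostic_loci_recovered_exactly():
    sexes = ["F"] * 50 + ["M"] * 50
    gm, truth = generate_xlinked_loci(1000, 10, sexes, seed=7)
    found = select_sex_linked(gm, sexes)
    assert sorted(found) == sorted(truth)


def test_no_diagnostic_loci_returns_empty():
    sexes = ["F"] * 20 + ["M"] * 20
    gm, truth = generate_xlinked_loci(200, 0, sexes, seed=8)
    assert truth.size == 0
    assert select_sex_linked(gm, sexes).size == 0


def test_females_have_zero_heterozygosity_at_diagnostic_loci():
    sexes = ["F"] * 30 + ["M"] * 30
    gm, truth = generate_xlinked_loci(100, 5, sexes, seed=9)
    females = np.array([s == "F" for s in sexes])
    assert (gm.dosage[np.ix_(females, truth)] == 0).all()


def test_single_sex_input_errors():
    with pytest.raises(PanelforgeError):
        generate_xlinked_loci(10, 2, ["F"] * 5)


# ---------------------------------------------------------------------------
# Fixture round-trip
# ---------------------------------------------------------------------------

def test_fixture_round_trip(tmp_path):
    model = PopulationModel(n_pops=2, fst_target=0.1, n_loci=100, seed=10)
    gm, meta, _ = generate_structured_populations(model, 5)
    gm.dosage[0, 3] = -1  # plant a missing call
    prefix = tmp_path / "fx"
    write_fixture(gm, meta, prefix)
    gm2, meta2 = read_fixture(prefix)
    assert (gm2.dosage == gm.dosage).all()
    assert gm2.samples == gm.samples
    assert gm2.dosage[0, 3] == -1
    pd.testing.assert_series_equal(
        meta2["lon"], meta["lon"], check_exact=False, rtol=1e-12
    )
    assert list(meta2.columns[:5]) == ["sample", "pop", "lon", "lat", "sex"]


def test_fixture_dimension_mismatch_errors(tmp_path):
    model = PopulationModel(n_pops=2, fst_target=0.1, n_loci=10, seed=11)
    gm, meta, _ = generate_structured_populations(model, 3)
    with pytest.raises(PanelforgeError):
        write_fixture(gm, meta.iloc[:-1], tmp_path / "bad")
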