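"""Gene-drop Monte Carlo against the exact enumeration oracle."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from founderseq.genedrop import (
    FounderAssignment,
    GeneDropError,
    drop_alleles,
    enumerate_exact,
    expected_frequency_sweep,
)
from founderseq.pedigree import Pedigree

from conftest import ind


@pytest.fixture
def twelve_member_pedigree():
    """Three generations, 6 founders, 6 non-founders (12 meioses)."""
    return Pedigree(
        [
            ind("f1", sex="male"), ind("m1", sex="female"),
            ind("f2", sex="male"), ind("m2", sex="female"),
            ind("a", "f1", "m1", sex="male"),
            ind("b", "f2", "m2", sex="female"),
            ind("spouse_a", sex="female"), ind("spouse_b", sex="male"),
            ind("c", "a", "spouse_a", sex="male"),
            ind("d", "spouse_b", "b", sex="female"),
            ind("e", "c", "d"),
            ind("g", "c", "d"),
        ]
    )


def chisq_gof_pvalue(freqs: np.ndarray, pmf: dict[Fraction, float]) -> float:
    """Goodness of fit of Monte-Carlo frequencies to an exact pmf."""
    values = sorted(pmf)
    observed = np.array([(freqs == float(v)).sum() for v in values], dtype=float)
    expected = np.array([pmf[v] for v in values]) * len(freqs)
    # merge bins with tiny expectation into their neighbor
    keep_obs, keep_exp = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= 5:
            keep_obs.append(acc_o)
            keep_exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        keep_obs[-1] += acc_o
        keep_exp[-1] += acc_e
    return stats.chisquare(keep_obs, keep_exp).pvalue


class TestDropAlleles:
    @pytest.mark.parametrize("q,expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_boundary_frequencies(self, trio, q, expected):
        res = drop_alleles(
            trio, FounderAssignment(mode="random_frequency", founder_freq=q),
            ["kid"], n_replicates=500, seed=0,
        )
        assert np.all(res.freqs == expected)

    def test_het_founder_mendelian_transmission(self, trio):
        res = drop_alleles(
            trio, FounderAssignment(mode="fixed_carriers", carrier_ids=frozenset({"dad"})),
            ["kid"], n_replicates=100_000, seed=1,
        )
        se = 0.5 / np.sqrt(res.n_replicates)  # carrier indicator SE
        carrier_prob = (res.freqs > 0).mean()
        assert abs(carrier_prob - 0.5) < 3 * se
        assert abs(res.mean - 0.25) < 3 * res.sd / np.sqrt(res.n_replicates) + 3 * se / 2

    def test_determinism(self, nuclear_family):
        kwargs = dict(
            assignment=FounderAssignment(mode="random_frequency", founder_freq=0.3),
            target_ids=["c1", "c2", "c3"], n_replicates=2000, seed=99,
        )
        r1 = drop_alleles(nuclear_family, **kwargs)
        r2 = drop_alleles(nuclear_family, **kwargs)
        assert np.array_equal(r1.freqs, r2.freqs)

    def test_nonfounder_carrier_rejected(self, trio):
        with pytest.raises(GeneDropError, match="not founders"):
            drop_alleles(
                trio,
                FounderAssignment(mode="fixed_carriers", carrier_ids=frozenset({"kid"})),
                ["kid"], n_replicates=10,
            )

    def test_default_targets_are_leaves(self, nuclear_family):
        res = drop_alleles(
            nuclear_family,
            FounderAssignment(mode="fixed_carriers", carrier_ids=frozenset({"dad"})),
            n_replicates=10, seed=0,
        )
        assert res.target_ids == ["c1", "c2", "c3"]

    def test_summary_consistent_with_freqs(self, nuclear_family):
        res = drop_alleles(
            nuclear_family,
            FounderAssignment(mode="random_frequency", founder_freq=0.4),
            n_replicates=5000, seed=3,
        )
        assert res.mean == pytest.approx(res.freqs.mean())
        assert res.q2_5 <= res.mean <= res.q97_5
        assert np.all((res.freqs >= 0) & (res.freqs <= 1))


class TestEnumerationOracle:
    def test_trio_single_het_founder(self, trio):
        pmf = enumerate_exact(
            trio, FounderAssignment(mode="fixed_carriers", carrier_ids=frozenset({"dad"})),
            ["kid"],
        )
        assert pmf == {Fraction(0): 0.5, Fraction(1, 2): 0.5}

    def test_nuclear_family_punnett(self):
        ped = Pedigree(
            [ind("f", sex="male"), ind("m", sex="female"), ind("c", "f", "m")]
        )
        pmf = enumerate_exact(
            ped,
            FounderAssignment(mode="fixed_carriers", carrier_ids=frozenset({"f", "m"})),
            ["c"],
        )
        assert pmf[Fraction(0)] == pytest.approx(0.25)
        assert pmf[Fraction(1, 2)] == pytest.approx(0.5)
        assert pmf[Fraction(1)] == pytest.approx(0.25)

    def test_pmf_sums_to_one(self, twelve_member_pedigree):
        pmf = enumerate_exact(
            twelve_member_pedigree,
            FounderAssignment(mode="random_frequency", founder_freq=0.2),
            ["e", "g"],
        )
        assert sum(pmf.values()) == pytest.approx(1.0, abs=1e-12)

    def test_too_many_meioses_rejected(self):
        inds = [ind("f", sex="male"), ind("m", sex="female")]
        inds += [ind(f"c{k}", "f", "m") for k in range(9)]
        with pytest.raises(GeneDropError, match="meioses"):
            enumerate_exact(
                Pedigree(inds),
                FounderAssignment(mode="fixed_carriers", carrier_ids=frozenset({"f"})),
            )

    def test_monte_carlo_matches_enumeration(self, twelve_member_pedigree):
        assignment = FounderAssignment(
            mode="fixed_carriers", carrier_ids=frozenset({"f1", "f2"})
        )
        pmf = enumerate_exact(twelve_member_pedigree, assignment, ["e", "g"])
        res = drop_alleles(
            twelve_member_pedigree, assignment, ["e", "g"],
            n_replicates=100_000, seed=7,
        )
        assert chisq_gof_pvalue(res.freqs, pmf) > 0.001


class TestFrequencySweep:
    def test_unconditional_mean_equals_founder_frequency(self, twelve_member_pedigree):
        """Mendelian transmission preserves the expected allele frequency."""
        rows = expected_frequency_sweep(
            twelve_member_pedigree, [0.05, 0.2, 0.5],
            target_ids=["e", "g"], n_replicates=40_000, seed=11,
        )
        for row in rows:
            se = row["sd"] / np.sqrt(row["n_kept"])
            assert abs(row["mean"] - row["q"]) < 3 * se

    def test_conditioning_on_carrier_founders_raises_mean(self, twelve_member_pedigree):
        q = 0.05
        cond = expected_frequency_sweep(
            twelve_member_pedigree, [q], target_ids=["e", "g"],
            n_replicates=60_000, seed=13, condition_het_ids=["f1", "f2"],
        )[0]
        assert cond["mean"] > q
        # agrees with the exact conditional distribution
        pmf = enumerate_exact(
            twelve_member_pedigree,
            FounderAssignment(mode="random_frequency", founder_freq=q),
            ["e", "g"], condition_het_ids=["f1", "f2"],
        )
        exact_mean = float(sum(float(v) * p for v, p in pmf.items()))
        se = cond["sd"] / np.sqrt(cond["n_kept"])
        assert abs(cond["mean"] - exact_mean) < 3 * se

    def test_sweep_emits_one_row_per_q(self, twelve_member_pedigree):
        qs = [0.03, 0.05, 0.07, 0.09]
        rows = expected_frequency_sweep(
            twelve_member_pedigree, qs, n_replicates=2000, seed=0
        )
        assert [r["q"] for r in rows] == qs
        assert all({"mean", "sd", "q2.5", "q97.5"} <= set(r) for r in rows)

    def test_founder_exchangeability(self, twelve_member_pedigree):
        """Relabelling founders in random mode leaves the distribution unchanged."""
        ped = twelve_member_pedigree
        a = drop_alleles(
            ped, FounderAssignment(mode="random_frequency", founder_freq=0.3),
            ["e", "g"], n_replicates=30_000, seed=21,
        )
        # swap founder couple order in the pedigree definition
        swapped = Pedigree(
            [ped["f2"], ped["m2"], ped["f1"], ped["m1"]]
            + [i for i in ped.individuals if i.id not in {"f1", "m1", "f2", "m2"}]
        )
        b = drop_alleles(
            swapped, FounderAssignment(mode="random_frequency", founder_freq=0.3),
            ["e", "g"], n_replicates=30_000, seed=22,
        )
        assert stats.ks_2samp(a.freqs, b.freqs).pvalue > 0.001
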