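"""Allele dropping through a pedigree.

Gene dropping assigns alleles to pedigree founders — either designated
heterozygous carriers or random draws at a founder allele frequency — and
transmits them by Mendelian segregation (each child receives one uniformly
chosen allele from each parent) down to the present generation.  Repeating
the drop predicts the present-day frequency distribution of a founder allele,
which is how a founder effect is quantified when the modern frequency is
observed but the founding genotypes are not.

An exact enumeration oracle is provided for small pedigrees: it sums over
every transmission pattern (and founder genotype configuration in random
mode), so Monte-Carlo results can be checked against the true distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product
from typing import Mapping, Sequence

import numpy as np

from .pedigree import Pedigree


class GeneDropError(ValueError):
    """Raised for invalid founder assignments or oversized enumeration requests."""


@dataclass(frozen=True)
class FounderAssignment:
    """How founder genotypes are assigned before a drop.

    ``fixed_carriers`` sets the named founders heterozygous and every other
    founder homozygous reference; ``random_frequency`` draws each founder
    allele independently as the variant with probability ``founder_freq``
    (Hardy-Weinberg in the founder pool).
    """

    mode: str
    carrier_ids: frozenset[str] = frozenset()
    founder_freq: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_carriers", "random_frequency"):
            raise GeneDropError(f"unknown assignment mode {self.mode!r}")
        if self.mode == "fixed_carriers" and not self.carrier_ids:
            raise GeneDropError("fixed_carriers mode requires at least one carrier id")
        if self.mode == "random_frequency" and not 0.0 <= self.founder_freq <= 1.0:
            raise GeneDropError("founder_freq must lie in [0, 1]")


@dataclass
class GeneDropResult:
    """Monte-Carlo distribution of the variant frequency in the target set."""

    target_ids: list[str]
    n_replicates: int
    freqs: np.ndarray
    seed: int | None
    mean: float = field(init=False)
    sd: float = field(init=False)
    q2_5: float = field(init=False)
    q97_5: float = field(init=False)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.mean = float(self.freqs.mean())
        self.sd = float(self.freqs.std(ddof=1)) if self.freqs.size > 1 else 0.0
        self.q2_5 = float(np.quantile(self.freqs, 0.025))
        self.q97_5 = float(np.quantile(self.freqs, 0.975))


def _check_targets(pedigree: Pedigree, target_ids: Sequence[str] | None) -> list[str]:
    if target_ids is None:
        return pedigree.leaves()
    targets = list(target_ids)
    missing = [t for t in targets if t not in pedigree]
    if missing:
        raise GeneDropError(f"target ids not in pedigree: {missing}")
    if not targets:
        raise GeneDropError("empty target set")
    return targets


def _founder_alleles(
    pedigree: Pedigree,
    assignment: FounderAssignment,
    rng: np.random.Generator,
    n_replicates: int,
) -> dict[str, np.ndarray]:
    founder_ids = {f.id for f in pedigree.founders}
    alleles: dict[str, np.ndarray] = {}
    if assignment.mode == "fixed_carriers":
        bad = set(assignment.carrier_ids) - founder_ids
        if bad:
            raise GeneDropError(f"carrier ids are not founders: {sorted(bad)}")
        for fid in founder_ids:
            a = np.zeros((n_replicates, 2), dtype=np.int8)
            if fid in assignment.carrier_ids:
                a[:, 0] = 1  # heterozygous carrier
            alleles[fid] = a
    else:
        for fid in founder_ids:
            alleles[fid] = (
                rng.random((n_replicates, 2)) < assignment.founder_freq
            ).astype(np.int8)
    return alleles


def _transmit(
    pedigree: Pedigree,
    founder_alleles: Mapping[str, np.ndarray],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Mendelian transmission of per-replicate founder allele arrays.

    Arrays have shape (n_replicates, 2); entries may be 0/1 variant
    indicators or arbitrary integer labels (used for identity-by-descent
    estimation).
    """
    alleles: dict[str, np.ndarray] = dict(founder_alleles)
    n_reps = next(iter(alleles.values())).shape[0] if alleles else 0
    for iid in pedigree.topological_order():
        ind = pedigree[iid]
        if ind.is_founder:
            continue
        out = np.empty((n_reps, 2), dtype=alleles[ind.father_id].dtype)
        for col, parent in enumerate((ind.father_id, ind.mother_id)):
            pa = alleles[parent]
            pick = rng.integers(0, 2, size=n_reps)
            out[:, col] = pa[np.arange(n_reps), pick]
        alleles[iid] = out
    return alleles


def drop_labeled_alleles(
    pedigree: Pedigree, n_replicates: int, seed: int | None = None
) -> dict[str, np.ndarray]:
    """Drop uniquely labelled founder alleles; basis of the IBD kinship oracle.

    Each of the 2F founder alleles gets a distinct integer label; the
    returned per-individual (n_replicates, 2) arrays allow empirical kinship
    estimation as the probability that random alleles from two individuals
    share a label.
    """
    rng = np.random.default_rng(seed)
    alleles: dict[str, np.ndarray] = {}
    for k, founder in enumerate(pedigree.founders):
        a = np.empty((n_replicates, 2), dtype=np.int32)
        a[:, 0] = 2 * k
        a[:, 1] = 2 * k + 1
        alleles[founder.id] = a
    return _transmit(pedigree, alleles, rng)


def estimate_kinship_ibd(
    pedigree: Pedigree, n_replicates: int = 200_000, seed: int | None = None
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Monte-Carlo kinship estimates with per-entry standard errors.

    For each pair (i, j) the kinship coefficient is estimated as the mean
    over replicates of the fraction of the four allele pairings that are
    identical by descent.  Returns (ids, phi_hat, se).
    """
    alleles = drop_labeled_alleles(pedigree, n_replicates, seed)
    ids = pedigree.ids
    n = len(ids)
    phi_hat = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        ai = alleles[ids[i]]
        for j in range(i, n):
            aj = alleles[ids[j]]
            if i == j:
                match = (ai[:, 0] == ai[:, 1]).astype(float)
                v = 0.5 * (1.0 + match)
            else:
                v = 0.25 * (
                    (ai[:, 0] == aj[:, 0]).astype(float)
                    + (ai[:, 0] == aj[:, 1])
                    + (ai[:, 1] == aj[:, 0])
                    + (ai[:, 1] == aj[:, 1])
                )
            phi_hat[i, j] = phi_hat[j, i] = v.mean()
            se[i, j] = se[j, i] = v.std(ddof=1) / np.sqrt(n_replicates)
    return ids, phi_hat, se


def drop_genotypes(
    pedigree: Pedigree,
    assignment: FounderAssignment,
    n_replicates: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Per-individual variant allele counts (n_replicates,) for every member."""
    if rng is None:
        rng = np.random.default_rng(seed)
    founder = _founder_alleles(pedigree, assignment, rng, n_replicates)
    alleles = _transmit(pedigree, founder, rng)
    return {iid: a.sum(axis=1) for iid, a in alleles.items()}


def drop_alleles(
    pedigree: Pedigree,
    assignment: FounderAssignment,
    target_ids: Sequence[str] | None = None,
    n_replicates: int = 100_000,
    seed: int | None = None,
) -> GeneDropResult:
    """Monte-Carlo distribution of the variant allele frequency in the targets.

    The default target set is the pedigree's latest generation (individuals
    with no recorded children).  Reproducible for a fixed seed.
    """
    if n_replicates < 1:
        raise GeneDropError("n_replicates must be at least 1")
    targets = _check_targets(pedigree, target_ids)
    counts = drop_genotypes(pedigree, assignment, n_replicates, seed=seed)
    total = np.zeros(n_replicates, dtype=np.int64)
    for t in targets:
        total += counts[t]
    freqs = total / (2.0 * len(targets))
    return GeneDropResult(
        target_ids=targets, n_replicates=n_replicates, freqs=freqs, seed=seed
    )


def expected_frequency_sweep(
    pedigree: Pedigree,
    q_values: Sequence[float],
    target_ids: Sequence[str] | None = None,
    n_replicates: int = 100_000,
    seed: int | None = None,
    condition_het_ids: Sequence[str] | None = None,
) -> list[dict]:
    """Predicted present-day frequency per founder allele frequency q.

    One random-frequency drop per q.  When ``condition_het_ids`` is given,
    only replicates in which every named founder is heterozygous are kept —
    the scenario of a variant known to be carried (one copy each) by
    designated founders.  Returns one summary row per q with the mean, sd
    and central 95% interval of the target-set frequency.
    """
    if not q_values:
        raise GeneDropError("q_values must be non-empty")
    targets = _check_targets(pedigree, target_ids)
    founder_ids = {f.id for f in pedigree.founders}
    cond = list(condition_het_ids or [])
    bad = [c for c in cond if c not in founder_ids]
    if bad:
        raise GeneDropError(f"conditioning ids are not founders: {bad}")
    rows: list[dict] = []
    seed_seq = np.random.SeedSequence(seed)
    for q, child_seq in zip(q_values, seed_seq.spawn(len(q_values))):
        rng = np.random.default_rng(child_seq)
        counts = drop_genotypes(
            pedigree,
            FounderAssignment(mode="random_frequency", founder_freq=q),
            n_replicates,
            rng=rng,
        )
        keep = np.ones(n_replicates, dtype=bool)
        for cid in cond:
            keep &= counts[cid] == 1
        total = np.zeros(n_replicates, dtype=np.int64)
        for t in targets:
            total += counts[t]
        freqs = (total / (2.0 * len(targets)))[keep]
        if freqs.size == 0:
            rows.append(
                {"q": q, "n_kept": 0, "mean": np.nan, "sd": np.nan,
                 "q2.5": np.nan, "q97.5": np.nan}
            )
            continue
        rows.append(
            {
                "q": q,
                "n_kept": int(freqs.size),
                "mean": float(freqs.mean()),
                "sd": float(freqs.std(ddof=1)) if freqs.size > 1 else 0.0,
                "q2.5": float(np.quantile(freqs, 0.025)),
                "q97.5": float(np.quantile(freqs, 0.975)),
            }
        )
    return rows


# ---------------------------------------------------------------------------
# Exact enumeration oracle
# ---------------------------------------------------------------------------

_GENOTYPE_TO_ALLELES = {0: (0, 0), 1: (1, 0), 2: (1, 1)}


def enumerate_exact(
    pedigree: Pedigree,
    assignment: FounderAssignment,
    target_ids: Sequence[str] | None = None,
    condition_het_ids: Sequence[str] | None = None,
    max_meioses: int = 16,
    max_founder_configs: int = 60_000,
) -> dict[Fraction, float]:
    """Exact distribution of the target-set allele frequency.

    Enumerates all ``2^(2 * non-founders)`` transmission patterns, and in
    random mode every founder genotype configuration weighted by
    Hardy-Weinberg probabilities.  Only feasible for small pedigrees; the
    probability mass function sums to 1 (up to float round-off).
    """
    targets = _check_targets(pedigree, target_ids)
    nonfounders = [i.id for i in pedigree.nonfounders]
    founders = [f.id for f in pedigree.founders]
    n_meioses = 2 * len(nonfounders)
    if n_meioses > max_meioses:
        raise GeneDropError(
            f"pedigree has {n_meioses} meioses; exact enumeration is limited "
            f"to {max_meioses}"
        )
    cond = set(condition_het_ids or [])
    if cond - set(founders):
        raise GeneDropError("conditioning ids must be founders")

    # every transmission pattern as a (2^m, m) bit matrix, m = 2 * non-founders
    n_patterns = 1 << n_meioses
    if n_meioses:
        bits = (
            (np.arange(n_patterns)[:, None] >> np.arange(n_meioses)[None, :]) & 1
        ).astype(np.int8)
    else:
        bits = np.zeros((1, 0), dtype=np.int8)

    topo_nonfounders = [i for i in pedigree.topological_order() if not pedigree[i].is_founder]
    meiosis_index = {
        (iid, col): 2 * k + col for k, iid in enumerate(topo_nonfounders) for col in (0, 1)
    }

    def propagate(founder_pair: dict[str, tuple[int, int]]) -> np.ndarray:
        """Target allele count per transmission pattern."""
        alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for fid, (a0, a1) in founder_pair.items():
            alleles[fid] = (
                np.full(n_patterns, a0, dtype=np.int8),
                np.full(n_patterns, a1, dtype=np.int8),
            )
        for iid in topo_nonfounders:
            ind = pedigree[iid]
            pair = []
            for col, parent in enumerate((ind.father_id, ind.mother_id)):
                b = bits[:, meiosis_index[(iid, col)]]
                pa0, pa1 = alleles[parent]
                pair.append(np.where(b == 0, pa0, pa1))
            alleles[iid] = (pair[0], pair[1])
        total = np.zeros(n_patterns, dtype=np.int32)
        for t in targets:
            a0, a1 = alleles[t]
            total += a0.astype(np.int32) + a1
        return total

    denom = 2 * len(targets)
    pmf_counts: dict[int, float] = {}
    pattern_p = 1.0 / n_patterns

    if assignment.mode == "fixed_carriers":
        bad = assignment.carrier_ids - set(founders)
        if bad:
            raise GeneDropError(f"carrier ids are not founders: {sorted(bad)}")
        founder_pair = {
            fid: ((1, 0) if fid in assignment.carrier_ids else (0, 0))
            for fid in founders
        }
        counts = propagate(founder_pair)
        for c, n in zip(*np.unique(counts, return_counts=True)):
            pmf_counts[int(c)] = pmf_counts.get(int(c), 0.0) + n * pattern_p
    else:
        q = assignment.founder_freq
        gt_probs = {0: (1 - q) ** 2, 1: 2 * q * (1 - q), 2: q * q}
        n_configs = 3 ** len(founders)
        if n_configs > max_founder_configs:
            raise GeneDropError(
                f"{n_configs} founder genotype configurations exceed the "
                f"enumeration limit {max_founder_configs}"
            )
        total_weight = 0.0
        for config in product((0, 1, 2), repeat=len(founders)):
            genotypes = dict(zip(founders, config))
            if any(genotypes[c] != 1 for c in cond):
                continue
            weight = 1.0
            for g in config:
                weight *= gt_probs[g]
            if weight == 0.0:
                continue
            total_weight += weight
            founder_pair = {fid: _GENOTYPE_TO_ALLELES[g] for fid, g in genotypes.items()}
            counts = propagate(founder_pair)
            for c, n in zip(*np.unique(counts, return_counts=True)):
                pmf_counts[int(c)] = pmf_counts.get(int(c), 0.0) + weight * n * pattern_p
        if cond:
            if total_weight == 0.0:
                raise GeneDropError("conditioning event has probability zero")
            pmf_counts = {c: p / total_weight for c, p in pmf_counts.items()}

    return {Fraction(c, denom): p for c, p in sorted(pmf_counts.items())}
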