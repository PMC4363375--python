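"""Synthetic cohorts and exome fixtures with the structure the pipeline assumes.

Three generators:

* a multi-generation founder pedigree (founding couples, Poisson offspring,
  a configurable fraction of within-pedigree unions, married-in spouses
  entering as new founders);
* phenotypes under a two-penetrance Bernoulli model — carriers of the risk
  variant are affected with the carrier penetrance, non-carriers with a
  sex-specific baseline risk calibrated so the overall prevalence matches
  the configured values;
* per-sample exome variant tables in which a known number of novel,
  potentially deleterious, well-supported variants are planted into at
  least a minimum number of samples, against a background of variants each
  guaranteed to fail at least one cascade stage, so the filter cascade has
  an exact truth set.

Everything is deterministic under a seed, and a full file bundle
(PED, per-sample VCF, known-catalogue VCF, BED regions, panel counts,
truth labels, manifest) can be written for end-to-end tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import defaults, io
from .filtering import (
    CONSEQUENCES,
    DELETERIOUS_CONSEQUENCES,
    ReadEvidence,
    RegionSet,
    VariantKey,
    VariantRecord,
)
from .genedrop import FounderAssignment, drop_genotypes
from .pedigree import IndividualRecord, Pedigree, write_ped


class SimulationError(RuntimeError):
    """Raised when a simulation cannot satisfy its configuration."""


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimConfig:
    """Demography, risk-variant and phenotype model for a synthetic cohort."""

    n_founding_couples: int = defaults.N_FOUNDING_COUPLES
    generations: int = defaults.GENERATIONS
    offspring_mean: float = defaults.OFFSPRING_MEAN
    consanguinity_prob: float = defaults.CONSANGUINITY_PROB
    carrier_founders: int | tuple[str, ...] = defaults.CARRIER_FOUNDERS
    penetrance_carrier: float = defaults.PENETRANCE_CARRIER
    baseline_risk_male: float = defaults.baseline_risk(defaults.PREVALENCE_MALE)
    baseline_risk_female: float = defaults.baseline_risk(defaults.PREVALENCE_FEMALE)
    missing_phenotype_prob: float = 0.0
    missing_genotype_prob: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.generations < 2:
            raise SimulationError("generations must be at least 2")
        for name in (
            "consanguinity_prob",
            "penetrance_carrier",
            "baseline_risk_male",
            "baseline_risk_female",
            "missing_phenotype_prob",
            "missing_genotype_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must lie in [0, 1], got {v}")


_DEFAULT_CONSEQUENCE_MIX = {
    "missense": 0.22,
    "nonsense": 0.02,
    "frameshift": 0.02,
    "canonical_splice": 0.02,
    "synonymous": 0.22,
    "intronic": 0.25,
    "nongenic": 0.15,
    "utr": 0.08,
    "other": 0.02,
}


@dataclass(frozen=True)
class ExomeSimConfig:
    """Scale and composition of a synthetic per-sample exome fixture."""

    n_samples: int = defaults.N_EXOME_SAMPLES
    n_background_variants: int = 2000
    n_planted_shared: int = 9
    min_shared_planted: int = defaults.MIN_SHARED
    consequence_mix: tuple[tuple[str, float], ...] = tuple(
        _DEFAULT_CONSEQUENCE_MIX.items()
    )
    known_fraction: float = 0.5
    depth_mean: float = defaults.MEAN_DEPTH
    depth_shape: float = defaults.DEPTH_SHAPE
    seed: int | None = None

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.consequence_mix)
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"consequence_mix proportions sum to {total}, not 1")
        unknown = {c for c, _ in self.consequence_mix} - set(CONSEQUENCES)
        if unknown:
            raise SimulationError(f"unknown consequence classes: {sorted(unknown)}")
        if not 0 <= self.min_shared_planted <= self.n_samples:
            raise SimulationError("min_shared_planted must lie in [0, n_samples]")


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

def simulate_pedigree(
    cfg: CohortSimConfig,
    rng: np.random.Generator | None = None,
    max_retries: int = 20,
) -> Pedigree:
    """Build a multi-generation founder pedigree.

    Founding couples occupy generation 0.  Every member of an intermediate
    generation forms a union: with probability ``consanguinity_prob`` with
    an available non-sibling of the opposite sex from the same generation,
    otherwise with a new married-in founder.  Couples have Poisson
    offspring.  Retries with a fresh random substream when a generation
    goes extinct.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    for _ in range(max_retries):
        ped = _try_simulate_pedigree(cfg, rng)
        if ped is not None:
            return ped
    raise SimulationError(
        f"pedigree went extinct in {max_retries} consecutive attempts"
    )


def _try_simulate_pedigree(
    cfg: CohortSimConfig, rng: np.random.Generator
) -> Pedigree | None:
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:04d}"

    individuals: list[IndividualRecord] = []

    def add(sex: str, father: str | None = None, mother: str | None = None) -> str:
        iid = new_id()
        individuals.append(
            IndividualRecord(id=iid, father_id=father, mother_id=mother, sex=sex)
        )
        return iid

    # generation 0: founding couples
    couples: list[tuple[str, str]] = []
    for _ in range(cfg.n_founding_couples):
        couples.append((add("male"), add("female")))

    sibs: dict[str, frozenset[str]] = {}
    for gen in range(1, cfg.generations):
        children: list[tuple[str, str]] = []  # (id, sex)
        for father, mother in couples:
            n_kids = rng.poisson(cfg.offspring_mean)
            kid_ids = []
            for _ in range(n_kids):
                sex = "male" if rng.random() < 0.5 else "female"
                kid_ids.append((add(sex, father, mother), sex))
            fam = frozenset(k for k, _ in kid_ids)
            for k, _ in kid_ids:
                sibs[k] = fam
            children.extend(kid_ids)
        if not children:
            return None
        if gen == cfg.generations - 1:
            break
        # form unions for the new generation
        couples = []
        unpartnered = list(children)
        order = rng.permutation(len(unpartnered))
        partnered: set[str] = set()
        for idx in order:
            iid, sex = unpartnered[idx]
            if iid in partnered:
                continue
            partner: str | None = None
            if rng.random() < cfg.consanguinity_prob:
                candidates = [
                    (j, s)
                    for j, s in unpartnered
                    if j not in partnered
                    and j != iid
                    and s != sex
                    and j not in sibs.get(iid, frozenset())
                ]
                if candidates:
                    partner, _ = candidates[rng.integers(0, len(candidates))]
            if partner is None:
                partner = add("female" if sex == "male" else "male")
            partnered.update((iid, partner))
            couple = (iid, partner) if sex == "male" else (partner, iid)
            couples.append(couple)
    return Pedigree(individuals=individuals, family_id="SIM")


def designate_carrier_founders(
    pedigree: Pedigree, carrier_founders: int | Sequence[str]
) -> frozenset[str]:
    """Resolve the carrier specification to founder ids.

    An integer picks that many of the original (generation-0) founders in
    input order, males first — emulating variant-introducing founder
    brothers; an explicit id list is validated against the founder set.
    """
    founder_ids = [f.id for f in pedigree.founders]
    if isinstance(carrier_founders, int):
        ranked = sorted(
            founder_ids,
            key=lambda i: (pedigree[i].sex != "male", founder_ids.index(i)),
        )
        if carrier_founders > len(ranked):
            raise SimulationError("more carrier founders requested than founders exist")
        return frozenset(ranked[:carrier_founders])
    bad = set(carrier_founders) - set(founder_ids)
    if bad:
        raise SimulationError(f"designated carriers are not founders: {sorted(bad)}")
    return frozenset(carrier_founders)


# ---------------------------------------------------------------------------
# Phenotype simulation
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    pedigree: Pedigree,
    genotype_counts: Mapping[str, int],
    cfg: CohortSimConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Affection statuses under the two-penetrance Bernoulli model.

    Carriers (at least one variant allele) are affected with
    ``penetrance_carrier``; non-carriers with the sex-specific baseline
    risk (mean of the two for unknown sex).  Statuses are then masked to
    ``unknown`` with ``missing_phenotype_prob``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    baseline_unknown = 0.5 * (cfg.baseline_risk_male + cfg.baseline_risk_female)
    statuses: dict[str, str] = {}
    for ind in pedigree.individuals:
        if genotype_counts.get(ind.id, 0) >= 1:
            risk = cfg.penetrance_carrier
        elif ind.sex == "male":
            risk = cfg.baseline_risk_male
        elif ind.sex == "female":
            risk = cfg.baseline_risk_female
        else:
            risk = baseline_unknown
        status = "affected" if rng.random() < risk else "unaffected"
        if rng.random() < cfg.missing_phenotype_prob:
            status = "unknown"
        statuses[ind.id] = status
    return statuses


@dataclass
class SimulatedCohort:
    """One synthetic cohort: pedigree, risk-variant genotypes, phenotypes."""

    pedigree: Pedigree
    carrier_founders: frozenset[str]
    genotype_counts: dict[str, int]
    affection: dict[str, str]
    genotyped_ids: list[str]
    config: CohortSimConfig


def simulate_cohort(cfg: CohortSimConfig) -> SimulatedCohort:
    """Pedigree + one gene-drop of the founder variant + phenotypes.

    The risk variant enters through the designated carrier founders
    (heterozygous) and segregates by Mendelian transmission; genotypes are
    then masked missing with ``missing_genotype_prob``.  The pedigree's
    individuals get their simulated affection statuses attached.
    """
    seq = np.random.SeedSequence(cfg.seed)
    rng_ped, rng_drop, rng_phen, rng_miss = (
        np.random.default_rng(s) for s in seq.spawn(4)
    )
    pedigree = simulate_pedigree(cfg, rng=rng_ped)
    carriers = designate_carrier_founders(pedigree, cfg.carrier_founders)
    counts_arr = drop_genotypes(
        pedigree,
        FounderAssignment(mode="fixed_carriers", carrier_ids=carriers),
        n_replicates=1,
        rng=rng_drop,
    )
    genotype_counts = {iid: int(a[0]) for iid, a in counts_arr.items()}
    affection = simulate_phenotypes(pedigree, genotype_counts, cfg, rng=rng_phen)
    genotyped = [
        iid
        for iid in pedigree.ids
        if rng_miss.random() >= cfg.missing_genotype_prob
    ]
    individuals = [
        dataclasses.replace(
            ind, affection=affection[ind.id], genotyped=ind.id in set(genotyped)
        )
        for ind in pedigree.individuals
    ]
    pedigree = Pedigree(individuals=individuals, family_id=pedigree.family_id)
    return SimulatedCohort(
        pedigree=pedigree,
        carrier_founders=carriers,
        genotype_counts=genotype_counts,
        affection=affection,
        genotyped_ids=genotyped,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Exome fixture simulation
# ---------------------------------------------------------------------------

_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
_BASES = ("A", "C", "G", "T")


def _draw_depth(rng: np.random.Generator, cfg: ExomeSimConfig) -> int:
    shape = cfg.depth_shape
    p = shape / (shape + cfg.depth_mean)
    return int(rng.negative_binomial(shape, p))


def _passing_evidence(rng: np.random.Generator, cfg: ExomeSimConfig) -> ReadEvidence:
    depth = max(_draw_depth(rng, cfg), 10)
    floor = max(4, int(np.ceil(0.15 * depth)))
    variant_reads = max(int(rng.binomial(depth, 0.5)), floor)
    variant_reads = min(variant_reads, depth)
    uss = 4 + int(rng.binomial(max(variant_reads - 4, 0), 0.7))
    return ReadEvidence(depth=depth, variant_reads=variant_reads, unique_start_sites=uss)


def _failing_evidence(rng: np.random.Generator, cfg: ExomeSimConfig) -> ReadEvidence:
    mode = rng.choice(["uss", "vaf", "nocov"], p=[0.6, 0.35, 0.05])
    if mode == "nocov":
        return ReadEvidence(0, 0, 0)
    depth = max(_draw_depth(rng, cfg), 10)
    if mode == "uss":
        uss = int(rng.integers(0, 4))
        variant_reads = max(int(rng.binomial(depth, 0.5)), uss)
        variant_reads = min(variant_reads, depth)
        return ReadEvidence(depth, variant_reads, uss)
    # vaf mode: below the 15% threshold
    variant_reads = min(max(int(np.ceil(0.15 * depth)) - 1, 0), depth)
    uss = min(variant_reads, 4 + int(rng.binomial(max(variant_reads - 4, 0), 0.7)))
    return ReadEvidence(depth, variant_reads, uss)


def _normal_evidence(rng: np.random.Generator, cfg: ExomeSimConfig) -> ReadEvidence:
    depth = _draw_depth(rng, cfg)
    variant_reads = int(rng.binomial(depth, 0.5)) if depth else 0
    if variant_reads == 0:
        uss = 0
    else:
        uss = 1 + int(rng.binomial(variant_reads - 1, 0.7))
    return ReadEvidence(depth, variant_reads, uss)


@dataclass
class ExomeCohort:
    """Per-sample variant records with truth labels for the filter cascade."""

    records_by_sample: dict[str, list[VariantRecord]]
    truth_keys: list[VariantKey]
    known_keys: set[VariantKey]
    config: ExomeSimConfig


def simulate_exome_cohort(cfg: ExomeSimConfig) -> ExomeCohort:
    """Generate the exome fixture.

    Planted variants are novel, potentially deleterious, carried with
    cascade-passing read evidence by at least ``min_shared_planted``
    samples: exactly these should survive the cascade.  Background variants
    draw their consequence, known status, carrier sets and read evidence
    from the configured distributions; any background variant that would
    survive by chance is thinned to fewer than the sharing threshold, so the
    truth labels are exact by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = [f"S{i + 1}" for i in range(cfg.n_samples)]
    csq_names = [c for c, _ in cfg.consequence_mix]
    csq_probs = np.array([p for _, p in cfg.consequence_mix])

    used_positions: set[tuple[str, int]] = set()

    def new_site() -> tuple[str, int, str, str]:
        while True:
            chrom = _AUTOSOMES[int(rng.integers(0, len(_AUTOSOMES)))]
            pos = int(rng.integers(1, 50_000_000))
            if (chrom, pos) not in used_positions:
                used_positions.add((chrom, pos))
                ref, alt = rng.choice(4, size=2, replace=False)
                return chrom, pos, _BASES[ref], _BASES[alt]

    records: dict[str, list[VariantRecord]] = {s: [] for s in samples}
    known_keys: set[VariantKey] = set()
    truth_keys: list[VariantKey] = []
    gene_counter = 0

    def next_gene() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"GENE{gene_counter:05d}"

    # planted shared variants
    for _ in range(cfg.n_planted_shared):
        chrom, pos, ref, alt = new_site()
        key: VariantKey = (chrom, pos, ref, alt)
        truth_keys.append(key)
        n_carriers = int(rng.integers(cfg.min_shared_planted, cfg.n_samples + 1))
        carrier_samples = rng.choice(samples, size=n_carriers, replace=False)
        csq = str(rng.choice(sorted(DELETERIOUS_CONSEQUENCES)))
        gene = next_gene()
        for s in carrier_samples:
            records[str(s)].append(
                VariantRecord(
                    sample_id=str(s),
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=gene,
                    consequence=csq,
                    evidence=_passing_evidence(rng, cfg),
                )
            )

    # background variants, each guaranteed to fail at least one stage
    for _ in range(cfg.n_background_variants):
        chrom, pos, ref, alt = new_site()
        key = (chrom, pos, ref, alt)
        known = rng.random() < cfg.known_fraction
        csq = str(rng.choice(csq_names, p=csq_probs))
        gene = None if csq == "nongenic" else next_gene()
        n_carriers = int(rng.integers(1, cfg.n_samples + 1))
        carrier_samples = [str(s) for s in rng.choice(samples, size=n_carriers, replace=False)]
        evidence = [_normal_evidence(rng, cfg) for _ in carrier_samples]

        if not known and csq in DELETERIOUS_CONSEQUENCES:
            n_passing = sum(
                1
                for ev in evidence
                if ev.depth > 0 and ev.unique_start_sites >= 4 and ev.vaf >= 0.15
            )
            if n_passing >= cfg.min_shared_planted:
                # would survive the cascade: thin below the sharing threshold
                keep = max(cfg.min_shared_planted - 1, 0)
                if keep == 0:
                    known = True
                else:
                    passing_idx = [
                        i
                        for i, ev in enumerate(evidence)
                        if ev.depth > 0 and ev.unique_start_sites >= 4 and ev.vaf >= 0.15
                    ]
                    drop = set(passing_idx[keep:])
                    carrier_samples = [
                        s for i, s in enumerate(carrier_samples) if i not in drop
                    ]
                    evidence = [e for i, e in enumerate(evidence) if i not in drop]
        if known:
            known_keys.add(key)
        for s, ev in zip(carrier_samples, evidence):
            records[s].append(
                VariantRecord(
                    sample_id=s,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=gene,
                    consequence=csq,
                    known=known,
                    evidence=ev,
                )
            )

    for s in samples:
        records[s].sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    return ExomeCohort(
        records_by_sample=records,
        truth_keys=sorted(truth_keys),
        known_keys=known_keys,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

_LINKAGE_CHROMS = ("chr2", "chr6", "chr7", "chr8", "chr9", "chr12", "chr13", "chr17")


def default_linkage_regions(rng: np.random.Generator) -> RegionSet:
    """A linkage-region set on the chromosomes a prior genome scan flagged."""
    intervals = []
    for chrom in _LINKAGE_CHROMS:
        start = int(rng.integers(1_000_000, 40_000_000))
        intervals.append((chrom, start, start + int(rng.integers(2_000_000, 10_000_000))))
    return RegionSet(intervals=intervals, label="suggestive_linkage")


@dataclass
class FixtureBundle:
    cohort: SimulatedCohort
    exome: ExomeCohort
    regions: RegionSet
    panel_counts: list[dict]
    seed: int


def make_fixture_bundle(
    cohort_cfg: CohortSimConfig | None = None,
    exome_cfg: ExomeSimConfig | None = None,
    seed: int = 0,
) -> FixtureBundle:
    """Simulate every input the pipeline consumes, under one master seed."""
    seq = np.random.SeedSequence(seed)
    s_cohort, s_exome, s_regions, s_panel = seq.spawn(4)
    cohort_cfg = cohort_cfg or CohortSimConfig(seed=int(s_cohort.generate_state(1)[0] % 2**31))
    exome_cfg = exome_cfg or ExomeSimConfig(seed=int(s_exome.generate_state(1)[0] % 2**31))
    cohort = simulate_cohort(cohort_cfg)
    exome = simulate_exome_cohort(exome_cfg)
    rng_regions = np.random.default_rng(s_regions)
    regions = default_linkage_regions(rng_regions)
    rng_panel = np.random.default_rng(s_panel)
    panel_counts = []
    for key in exome.truth_keys:
        chrom, pos, ref, alt = key
        panel_counts.append(
            {
                "panel": "SYNTH_EUR",
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "alt_count": int(rng_panel.integers(0, 3)),
                "total_chromosomes": 9358,
            }
        )
    return FixtureBundle(
        cohort=cohort, exome=exome, regions=regions, panel_counts=panel_counts, seed=seed
    )


def write_fixture_bundle(bundle: FixtureBundle, directory: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text files with a self-describing manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["pedigree"] = directory / "cohort.ped"
    write_ped(bundle.cohort.pedigree, paths["pedigree"])

    for sample, recs in sorted(bundle.exome.records_by_sample.items()):
        p = directory / f"exome_{sample}.vcf"
        io.write_sample_vcf(recs, p)
        paths[f"vcf_{sample}"] = p

    paths["known"] = directory / "known_sites.vcf"
    io.write_known_catalogue_vcf(bundle.exome.known_keys, paths["known"])

    paths["regions"] = directory / "linkage_regions.bed"
    io.write_bed(bundle.regions, paths["regions"])

    paths["panels"] = directory / "panel_counts.tsv"
    with paths["panels"].open("w") as fh:
        fh.write("panel\tchrom\tpos\tref\talt\talt_count\ttotal_chromosomes\n")
        for row in bundle.panel_counts:
            fh.write(
                f"{row['panel']}\t{row['chrom']}\t{row['pos']}\t{row['ref']}\t"
                f"{row['alt']}\t{row['alt_count']}\t{row['total_chromosomes']}\n"
            )

    paths["truth"] = directory / "truth_labels.json"
    truth = {
        "surviving_variants": [list(k) for k in bundle.exome.truth_keys],
        "carrier_founders": sorted(bundle.cohort.carrier_founders),
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")

    paths["manifest"] = directory / "manifest.json"
    manifest = {
        "seed": bundle.seed,
        "cohort_config": dataclasses.asdict(bundle.cohort.config),
        "exome_config": {
            **dataclasses.asdict(bundle.exome.config),
            "consequence_mix": dict(bundle.exome.config.consequence_mix),
        },
        "files": {k: p.name for k, p in sorted(paths.items()) if k != "manifest"},
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
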