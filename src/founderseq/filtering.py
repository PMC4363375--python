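"""Exome variant filter cascade for shared-variant discovery in affected relatives.

The cascade mirrors the discovery strategy used in founder-population exome
studies of a handful of affected relatives: per-record read-evidence quality
control, restriction to potentially deleterious consequences, exclusion of
known (catalogued) sites, and finally selection of variants shared by a
minimum number of the sequenced individuals.  Survivors can be annotated
against regions of prior linkage evidence.

Read-evidence quality rests on a binomial model of heterozygote detection:
with per-read probability ``p`` of sequencing the variant allele at a
heterozygous site, the chance that at least ``k`` of ``n`` reads carry the
variant is an exact binomial tail, which fixes the minimum depth needed for
a target detection probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy import stats

CONSEQUENCES = (
    "missense",
    "nonsense",
    "frameshift",
    "canonical_splice",
    "synonymous",
    "intronic",
    "nongenic",
    "utr",
    "other",
)

#: consequence classes retained as potentially deleterious
DELETERIOUS_CONSEQUENCES = frozenset(
    {"missense", "nonsense", "frameshift", "canonical_splice"}
)

#: amino-acid-changing or splice-disrupting classes (used for verification rules)
NONSYNONYMOUS_CONSEQUENCES = DELETERIOUS_CONSEQUENCES

VariantKey = tuple[str, int, str, str]


class FilterError(ValueError):
    """Raised for malformed records or inconsistent filter parameters."""


@dataclass
class ReadEvidence:
    """Read support for one variant call in one sample."""

    depth: int
    variant_reads: int
    unique_start_sites: int

    def __post_init__(self) -> None:
        if self.depth < 0 or self.variant_reads < 0 or self.unique_start_sites < 0:
            raise FilterError("read counts must be non-negative")
        if self.variant_reads > self.depth:
            raise FilterError("variant_reads cannot exceed depth")
        if self.unique_start_sites > self.variant_reads:
            raise FilterError("unique_start_sites cannot exceed variant_reads")

    @property
    def vaf(self) -> float:
        """Variant allele fraction; 0.0 at zero depth (handled as a failure upstream)."""
        return self.variant_reads / self.depth if self.depth > 0 else 0.0


@dataclass
class VariantRecord:
    """One called variant in one sample, with read evidence and annotation."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    consequence: str | None = None
    known: bool = False
    evidence: ReadEvidence | None = None
    in_linkage_region: bool = False
    validated: bool | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FilterError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise FilterError(f"ref and alt alleles are identical at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or any(b not in "ACGT" for b in allele):
                raise FilterError(f"invalid allele {allele!r} at {self.chrom}:{self.pos}")

    @property
    def key(self) -> VariantKey:
        """Allele-aware variant identity."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class RegionSet:
    """Genomic intervals in 1-based inclusive coordinates."""

    intervals: list[tuple[str, int, int]]
    label: str = ""

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start > end:
                raise FilterError(f"region {chrom}:{start}-{end} has start > end")

    def contains(self, chrom: str, pos: int) -> bool:
        return any(
            c == chrom and start <= pos <= end for c, start, end in self.intervals
        )


@dataclass
class SharedVariant:
    """A variant surviving the cascade, with the samples that carry it."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None
    consequence: str | None
    carriers: list[str]
    in_linkage_region: bool = False
    validated: bool | None = None

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class FilterStage:
    name: str
    n_input: int
    n_kept: int
    n_removed: int


@dataclass
class FilterReport:
    """Per-stage record counts through the cascade (kept + removed = input)."""

    stages: list[FilterStage] = field(default_factory=list)
    surviving_keys: list[VariantKey] = field(default_factory=list)

    def add_stage(self, name: str, n_input: int, n_kept: int) -> None:
        self.stages.append(FilterStage(name, n_input, n_kept, n_input - n_kept))

    def to_dict(self) -> dict:
        return {
            "stages": [vars(s) for s in self.stages],
            "surviving_keys": [list(k) for k in self.surviving_keys],
        }

    def to_tsv(self) -> str:
        lines = ["stage\tinput\tkept\tremoved"]
        for s in self.stages:
            lines.append(f"{s.name}\t{s.n_input}\t{s.n_kept}\t{s.n_removed}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Binomial read-depth model
# ---------------------------------------------------------------------------

def het_detection_probability(
    depth: int, min_variant_reads: int, per_read_prob: float = 0.5
) -> float:
    """P(at least ``min_variant_reads`` variant reads) at a heterozygous site.

    Exact binomial upper tail with ``depth`` trials and per-read success
    probability ``per_read_prob``.  Returns 0 when more variant reads are
    required than the depth can supply, and 1 when none are required.
    """
    if depth < 0:
        raise FilterError("depth must be non-negative")
    if not 0.0 < per_read_prob < 1.0:
        raise FilterError("per_read_prob must lie strictly between 0 and 1")
    if min_variant_reads <= 0:
        return 1.0
    if min_variant_reads > depth:
        return 0.0
    return float(stats.binom.sf(min_variant_reads - 1, depth, per_read_prob))


def min_depth_for_confidence(
    min_variant_reads: int,
    confidence: float,
    per_read_prob: float = 0.5,
    max_depth: int = 100_000,
) -> int:
    """Smallest depth at which the detection probability reaches ``confidence``."""
    if not 0.0 < confidence < 1.0:
        raise FilterError("confidence must lie strictly between 0 and 1")
    depth = max(min_variant_reads, 0)
    while depth <= max_depth:
        if het_detection_probability(depth, min_variant_reads, per_read_prob) >= confidence:
            return depth
        depth += 1
    raise FilterError(f"no depth up to {max_depth} reaches confidence {confidence}")


# ---------------------------------------------------------------------------
# Filter stages
# ---------------------------------------------------------------------------

def apply_quality_filter(
    records: Iterable[VariantRecord],
    min_unique_starts: int = 4,
    min_vaf: float = 0.15,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Keep records with enough independent variant reads and allele fraction.

    Both thresholds are inclusive: at least ``min_unique_starts`` distinct
    alignment start sites among variant reads, and a variant allele fraction
    of at least ``min_vaf``.  Zero-depth records are removed with reason
    ``"no coverage"``.
    """
    kept: list[VariantRecord] = []
    removed: list[tuple[VariantRecord, str]] = []
    for rec in records:
        if rec.evidence is None:
            raise FilterError(f"record {rec.key} lacks read evidence")
        ev = rec.evidence
        if ev.depth == 0:
            removed.append((rec, "no coverage"))
        elif ev.unique_start_sites < min_unique_starts:
            removed.append((rec, f"unique start sites < {min_unique_starts}"))
        elif ev.vaf < min_vaf:
            removed.append((rec, f"VAF < {min_vaf}"))
        else:
            kept.append(rec)
    return kept, removed


def apply_consequence_filter(
    records: Iterable[VariantRecord],
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Keep potentially deleterious consequences (missense, nonsense,
    frameshift, canonical splice); exclude synonymous, intronic, nongenic,
    UTR and other classes."""
    kept: list[VariantRecord] = []
    removed: list[tuple[VariantRecord, str]] = []
    for rec in records:
        if rec.consequence is None:
            raise FilterError(f"record {rec.key} in sample {rec.sample_id} has no consequence annotation")
        if rec.consequence not in CONSEQUENCES:
            raise FilterError(f"record {rec.key}: unknown consequence {rec.consequence!r}")
        if rec.consequence in DELETERIOUS_CONSEQUENCES:
            kept.append(rec)
        else:
            removed.append((rec, f"consequence {rec.consequence}"))
    return kept, removed


def apply_novelty_filter(
    records: Iterable[VariantRecord],
    known_catalogues: set[VariantKey] | Sequence[set[VariantKey]],
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Exclude records whose allele-aware key appears in any known catalogue.

    A catalogued site with a *different* alternate allele still counts as
    novel.  Each record's ``known`` flag is set to reflect the lookup.
    """
    if isinstance(known_catalogues, set):
        union = known_catalogues
    else:
        union = set().union(*known_catalogues) if known_catalogues else set()
    kept: list[VariantRecord] = []
    removed: list[tuple[VariantRecord, str]] = []
    for rec in records:
        rec.known = rec.key in union
        if rec.known:
            removed.append((rec, "known site"))
        else:
            kept.append(rec)
    return kept, removed


def apply_sharing_filter(
    records: Iterable[VariantRecord],
    min_shared: int = 3,
    n_samples: int | None = None,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]], list[SharedVariant]]:
    """Keep variants present in at least ``min_shared`` distinct samples.

    Returns the kept and removed records plus one :class:`SharedVariant` per
    surviving variant with its carrier sample list.
    """
    records = list(records)
    if n_samples is None:
        n_samples = len({r.sample_id for r in records})
    if min_shared > n_samples:
        raise FilterError(
            f"min_shared ({min_shared}) exceeds the number of samples ({n_samples})"
        )
    carriers: dict[VariantKey, list[str]] = {}
    exemplar: dict[VariantKey, VariantRecord] = {}
    for rec in records:
        lst = carriers.setdefault(rec.key, [])
        if rec.sample_id not in lst:
            lst.append(rec.sample_id)
        exemplar.setdefault(rec.key, rec)
    shared_keys = {k for k, c in carriers.items() if len(c) >= min_shared}
    kept = [r for r in records if r.key in shared_keys]
    removed = [
        (r, f"shared by {len(carriers[r.key])} < {min_shared} samples")
        for r in records
        if r.key not in shared_keys
    ]
    shared = [
        SharedVariant(
            chrom=k[0],
            pos=k[1],
            ref=k[2],
            alt=k[3],
            gene=exemplar[k].gene,
            consequence=exemplar[k].consequence,
            carriers=sorted(carriers[k]),
        )
        for k in sorted(shared_keys)
    ]
    return kept, removed, shared


def annotate_linkage_regions(
    variants: Iterable[VariantRecord | SharedVariant], regions: RegionSet
) -> None:
    """Flag each variant whose position falls inside a region (1-based inclusive)."""
    for var in variants:
        var.in_linkage_region = regions.contains(var.chrom, var.pos)


def run_filter_cascade(
    records_by_sample: Mapping[str, Sequence[VariantRecord]],
    known_catalogues: set[VariantKey] | Sequence[set[VariantKey]] = frozenset(),
    regions: RegionSet | None = None,
    min_unique_starts: int = 4,
    min_vaf: float = 0.15,
    min_shared: int = 3,
) -> tuple[list[SharedVariant], FilterReport]:
    """Quality -> consequence -> novelty -> sharing, with per-stage accounting.

    Counts are in per-sample records at every stage so that kept + removed =
    input holds throughout; the sharing stage keeps a record iff its variant
    is carried by at least ``min_shared`` samples.  Survivors are returned
    collapsed to distinct variants with carrier lists and, when ``regions``
    is given, a linkage-region overlap flag.
    """
    records = [r for sample in records_by_sample.values() for r in sample]
    report = FilterReport()

    kept, _ = apply_quality_filter(records, min_unique_starts, min_vaf)
    report.add_stage("quality", len(records), len(kept))

    n_in = len(kept)
    kept, _ = apply_consequence_filter(kept)
    report.add_stage("consequence", n_in, len(kept))

    n_in = len(kept)
    kept, _ = apply_novelty_filter(kept, known_catalogues)
    report.add_stage("novelty", n_in, len(kept))

    n_in = len(kept)
    kept, _, shared = apply_sharing_filter(
        kept, min_shared=min_shared, n_samples=len(records_by_sample)
    )
    report.add_stage("sharing", n_in, len(kept))

    if regions is not None:
        annotate_linkage_regions(shared, regions)
    report.surviving_keys = [sv.key for sv in shared]
    return shared, report
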