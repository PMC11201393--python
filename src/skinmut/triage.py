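"""Somatic-variant triage downstream of paired tumor/blood variant calling.

The triage logic answers one question per variant call: is it a credible
somatic event inside the sequenced target region?  A call survives when it

* is present in the tissue sample but absent from the paired blood sample
  (blood serves as the germline proxy),
* passes the low-frequency detection thresholds (coverage, supporting read
  count, variant-allele frequency, and a phred-scaled variant quality),
* falls inside the targeted panel, and
* is not a known common germline variant (local blacklist).

Surviving calls are then classified cohort-wide into three categories of
unique loci: tumor-only (``NMSC_ONLY``), seen in tumor and healthy skin
(``SHARED``), and healthy-skin-only (``HEALTHY_ONLY``).  Healthy skin is
sun-exposed and carries its own somatic burden, so the tumor-only stratum,
not the raw somatic list, is the cancer-associated candidate set.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)

NMSC_ONLY = "NMSC_ONLY"
SHARED = "SHARED"
HEALTHY_ONLY = "HEALTHY_ONLY"
CATEGORIES = (NMSC_ONLY, SHARED, HEALTHY_ONLY)

#: the 12 uncollapsed single-nucleotide substitution classes; C>T and G>A are
#: deliberately kept separate because the UVR signature is reported per strand.
SUBSTITUTION_CLASSES = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)

Locus = tuple[str, int, str, str]


def infer_vtype(ref: str, alt: str) -> str:
    """Classify a ref/alt pair as SNV, INS, or DEL from allele lengths."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "INS"
    return "DEL"


@dataclass
class VariantCall:
    """One called variant in one sample.

    ``frequency`` is the variant-allele frequency in percent (0, 100];
    ``q_score`` is the phred-scaled variant-allele quality used for the Q60
    cut-off; ``qual`` is the phred-scaled call quality from the VCF QUAL
    column.  A stop-gain (``*`` in the amino-acid change) is always
    non-synonymous.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    coverage: int | None
    count: int | None
    frequency: float | None
    q_score: float | None
    qual: float | None = None
    vtype: str = ""
    gene: str = ""
    coding_change: str = ""
    aa_change: str = ""
    nonsynonymous: bool = False

    def __post_init__(self) -> None:
        if not self.vtype:
            self.vtype = infer_vtype(self.ref, self.alt)
        if "*" in self.aa_change:
            self.nonsynonymous = True
        if self.coverage is not None and self.count is not None:
            if self.count > self.coverage:
                raise ValueError(
                    f"{self.sample_id} {self.chrom}:{self.pos} "
                    f"count {self.count} exceeds coverage {self.coverage}"
                )
            if self.coverage > 0:
                recomputed = 100.0 * self.count / self.coverage
                if (
                    self.frequency is not None
                    and abs(self.frequency - recomputed) > 0.5
                ):
                    warnings.warn(
                        f"{self.sample_id} {self.chrom}:{self.pos} stated "
                        f"frequency {self.frequency:.2f}% disagrees with "
                        f"count/coverage ({recomputed:.2f}%); recomputing",
                        stacklevel=2,
                    )
                self.frequency = recomputed

    @property
    def locus(self) -> Locus:
        """Allele-aware locus identity (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterParams:
    """Low-frequency variant detection thresholds (all inclusive minima)."""

    min_coverage: int = 10
    min_count: int = 2
    min_frequency_pct: float = 2.0
    min_q: float = 60.0

    def __post_init__(self) -> None:
        for name in ("min_coverage", "min_count", "min_frequency_pct", "min_q"):
            if getattr(self, name) < 0:
                raise ValueError(f"FilterParams.{name} must be >= 0")


@dataclass
class TriageConfig:
    """Panel geometry and germline blacklist for triage."""

    panel_size_mb: float = 1.7
    target_regions: Sequence[tuple[str, int, int]] = ()
    germline_blacklist: frozenset[Locus] = frozenset()

    def __post_init__(self) -> None:
        if self.panel_size_mb <= 0:
            raise ValueError("panel_size_mb must be > 0")
        for chrom, start, end in self.target_regions:
            if start < 0 or start >= end:
                raise ValueError(f"bad interval {chrom}:{start}-{end}")


def subtract_paired(
    tissue_calls: Sequence[VariantCall],
    blood_calls: Sequence[VariantCall],
    *,
    tissue_id: str | None = None,
    blood_id: str | None = None,
) -> list[VariantCall]:
    """Remove tissue calls whose locus is also seen in the paired blood.

    Both lists must each come from a single sample; pass ``tissue_id`` /
    ``blood_id`` to assert the pairing against the sample sheet.
    """
    for calls, expected, label in (
        (tissue_calls, tissue_id, "tissue"),
        (blood_calls, blood_id, "blood"),
    ):
        ids = {c.sample_id for c in calls}
        if len(ids) > 1:
            raise ValueError(f"{label} calls mix samples: {sorted(ids)}")
        if expected is not None and ids and ids != {expected}:
            raise ValueError(
                f"{label} calls are from {sorted(ids)}, expected {expected}"
            )
    blood_loci = {c.locus for c in blood_calls}
    return [c for c in tissue_calls if c.locus not in blood_loci]


def apply_quality_filters(
    calls: Iterable[VariantCall], params: FilterParams = FilterParams()
) -> list[VariantCall]:
    """Keep calls meeting every detection threshold (inclusive minima)."""
    kept = []
    for c in calls:
        for name in ("coverage", "count", "frequency", "q_score"):
            if getattr(c, name) is None:
                raise ValueError(
                    f"missing {name} on {c.sample_id} {c.chrom}:{c.pos}"
                )
        if (
            c.coverage >= params.min_coverage
            and c.count >= params.min_count
            and c.frequency >= params.min_frequency_pct
            and c.q_score >= params.min_q
        ):
            kept.append(c)
    return kept


def build_target_index(
    target_regions: Sequence[tuple[str, int, int]],
) -> dict[str, IntervalTree]:
    """Build per-chromosome interval trees from 0-based half-open regions."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for chrom, start, end in target_regions:
        trees[chrom].addi(start, end)
    return dict(trees)


def restrict_to_target(
    calls: Iterable[VariantCall],
    target_regions: Sequence[tuple[str, int, int]] | Mapping[str, IntervalTree],
) -> list[VariantCall]:
    """Keep calls whose 1-based position falls in a 0-based half-open region."""
    if isinstance(target_regions, Mapping):
        trees = target_regions
    else:
        trees = build_target_index(target_regions)
    kept = []
    warned: set[str] = set()
    for c in calls:
        tree = trees.get(c.chrom)
        if tree is None:
            if c.chrom not in warned:
                logger.warning(
                    "chromosome %s absent from target BED; dropping calls",
                    c.chrom,
                )
                warned.add(c.chrom)
            continue
        if tree.overlaps_point(c.pos - 1):
            kept.append(c)
    return kept


def remove_germline_blacklist(
    calls: Iterable[VariantCall], blacklist: frozenset[Locus] | set[Locus]
) -> list[VariantCall]:
    """Drop calls matching a known common germline variant (allele-aware)."""
    return [c for c in calls if c.locus not in blacklist]


def triage_sample(
    tissue_calls: Sequence[VariantCall],
    blood_calls: Sequence[VariantCall],
    params: FilterParams,
    config: TriageConfig,
    *,
    target_index: Mapping[str, IntervalTree] | None = None,
) -> list[VariantCall]:
    """Full per-sample somatic triage: subtract, filter, restrict, blacklist."""
    calls = subtract_paired(tissue_calls, blood_calls)
    calls = apply_quality_filters(calls, params)
    calls = restrict_to_target(
        calls, target_index if target_index is not None else config.target_regions
    )
    calls = remove_germline_blacklist(calls, config.germline_blacklist)
    return calls


@dataclass
class TriageResult:
    """Cohort-level three-way partition of unique somatic loci."""

    category: dict[Locus, str]
    locus_samples: dict[Locus, frozenset[str]]
    locus_gene: dict[Locus, str]
    tumor_samples: tuple[str, ...]
    healthy_samples: tuple[str, ...]
    calls: dict[str, list[VariantCall]] = field(repr=False, default_factory=dict)

    def loci_in(self, category: str) -> list[Locus]:
        return [l for l, c in self.category.items() if c == category]

    def category_summary(self) -> pd.DataFrame:
        """Unique-locus, gene, and total-call counts per category."""
        call_count = {cat: 0 for cat in CATEGORIES}
        for locus, cat in self.category.items():
            call_count[cat] += sum(
                1
                for sample in self.locus_samples[locus]
                for c in self.calls.get(sample, [])
                if c.locus == locus
            )
        rows = []
        for cat in CATEGORIES:
            loci = self.loci_in(cat)
            genes = {self.locus_gene[l] for l in loci if self.locus_gene[l]}
            rows.append(
                {
                    "category": cat,
                    "unique_loci": len(loci),
                    "genes": len(genes),
                    "total_calls": call_count[cat],
                }
            )
        return pd.DataFrame(rows).set_index("category")


def classify_loci(
    tumor_callsets: Mapping[str, Sequence[VariantCall]],
    healthy_callsets: Mapping[str, Sequence[VariantCall]],
) -> TriageResult:
    """Partition unique somatic loci by tumor/healthy cohort occurrence.

    A locus seen in >=1 tumor sample and no healthy sample is ``NMSC_ONLY``;
    in >=1 of each, ``SHARED``; in no tumor sample, ``HEALTHY_ONLY``.  The
    three categories partition the observed unique loci by construction.
    """
    if not tumor_callsets and not healthy_callsets:
        raise ValueError("empty cohort: no callsets provided")
    locus_samples: dict[Locus, set[str]] = defaultdict(set)
    locus_gene: dict[Locus, str] = {}
    in_tumor: set[Locus] = set()
    in_healthy: set[Locus] = set()
    all_calls: dict[str, list[VariantCall]] = {}
    for callsets, seen in (
        (tumor_callsets, in_tumor),
        (healthy_callsets, in_healthy),
    ):
        for sample, calls in callsets.items():
            all_calls[sample] = list(calls)
            for c in calls:
                locus_samples[c.locus].add(sample)
                seen.add(c.locus)
                if c.gene:
                    locus_gene.setdefault(c.locus, c.gene)
    category = {}
    for locus in locus_samples:
        if locus in in_tumor and locus in in_healthy:
            category[locus] = SHARED
        elif locus in in_tumor:
            category[locus] = NMSC_ONLY
        else:
            category[locus] = HEALTHY_ONLY
    result = TriageResult(
        category=category,
        locus_samples={l: frozenset(s) for l, s in locus_samples.items()},
        locus_gene={l: locus_gene.get(l, "") for l in locus_samples},
        tumor_samples=tuple(tumor_callsets),
        healthy_samples=tuple(healthy_callsets),
        calls=all_calls,
    )
    # partition property asserted on every run
    n = sum(len(result.loci_in(cat)) for cat in CATEGORIES)
    assert n == len(locus_samples), "categories must partition unique loci"
    return result


def mutation_status_matrix(
    triage: TriageResult,
    genes: Sequence[str],
    *,
    annotation_genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Sample x gene 0/1 matrix: harbors >=1 tumor-only non-synonymous SNV.

    A sample is a mutant for a gene only when it carries at least one
    ``NMSC_ONLY`` non-synonymous SNV in that gene; synonymous variants and
    variants shared with healthy skin do not count.  Healthy samples are all
    zero by construction of the tumor-only category.
    """
    if annotation_genes is None:
        annotation_genes = {
            c.gene for calls in triage.calls.values() for c in calls if c.gene
        }
    else:
        annotation_genes = set(annotation_genes)
    missing = [g for g in genes if g not in annotation_genes]
    if missing:
        raise KeyError(f"genes absent from annotation space: {missing}")
    samples = list(triage.tumor_samples) + list(triage.healthy_samples)
    status = pd.DataFrame(0, index=samples, columns=list(genes), dtype=int)
    for sample in triage.tumor_samples:
        for c in triage.calls.get(sample, []):
            if (
                c.vtype == "SNV"
                and c.nonsynonymous
                and c.gene in status.columns
                and triage.category.get(c.locus) == NMSC_ONLY
            ):
                status.loc[sample, c.gene] = 1
    return status


def compute_tmb(n_mutations: float, panel_size_mb: float) -> float:
    """Tumor mutation burden: somatic mutations per megabase of target."""
    if panel_size_mb <= 0:
        raise ValueError("panel_size_mb must be > 0")
    return n_mutations / panel_size_mb


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def tmb_summary(
    mutation_counts: Mapping[str, int],
    groups: Mapping[str, str],
    panel_size_mb: float = 1.7,
) -> pd.DataFrame:
    """Per-group median somatic count and TMB (rounded to nearest integer)."""
    by_group: dict[str, list[int]] = defaultdict(list)
    for sample, n in mutation_counts.items():
        by_group[groups[sample]].append(n)
    rows = []
    for group in sorted(by_group):
        med = float(np.median(by_group[group]))
        rows.append(
            {
                "group": group,
                "n_samples": len(by_group[group]),
                "median_mutations": med,
                "median_tmb": _round_half_away(compute_tmb(med, panel_size_mb)),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def substitution_spectrum(
    callsets: Mapping[str, Sequence[VariantCall]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample substitution-class percentages and a cohort summary.

    Only SNVs are counted; samples without SNVs are excluded.  Returns
    ``(per_sample, summary)`` where ``per_sample`` is samples x 12 classes in
    percent (rows sum to 100) and ``summary`` holds the cohort median and the
    2.5/97.5 percentile band per class.
    """
    rows = {}
    for sample, calls in callsets.items():
        counts = dict.fromkeys(SUBSTITUTION_CLASSES, 0)
        for c in calls:
            if c.vtype != "SNV":
                logger.debug("ignoring non-SNV %s:%s in spectrum", c.chrom, c.pos)
                continue
            counts[f"{c.ref}>{c.alt}"] += 1
        total = sum(counts.values())
        if total == 0:
            continue
        rows[sample] = {k: 100.0 * v / total for k, v in counts.items()}
    per_sample = pd.DataFrame.from_dict(rows, orient="index")
    per_sample = per_sample.reindex(columns=list(SUBSTITUTION_CLASSES))
    if per_sample.empty:
        summary = pd.DataFrame(
            index=list(SUBSTITUTION_CLASSES),
            columns=["median_pct", "pct_2.5", "pct_97.5"],
            dtype=float,
        )
    else:
        summary = pd.DataFrame(
            {
                "median_pct": per_sample.median(),
                "pct_2.5": per_sample.quantile(0.025),
                "pct_97.5": per_sample.quantile(0.975),
            }
        )
    return per_sample, summary


def compare_group_location(
    values_by_group: Mapping[str, Sequence[float]],
) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H test across >=2 groups.

    Returns ``(H, p)``.  When every value is identical across all groups the
    statistic is 0 and p is 1 by convention.
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, g in zip(values_by_group, groups):
        if g.size == 0:
            raise ValueError(f"group {name!r} is empty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def top_mutated_genes(
    triage: TriageResult,
    category: str,
    k: int,
    *,
    sample_subset: Sequence[str] | None = None,
) -> list[tuple[str, float]]:
    """Top genes by percent of samples carrying a category mutation.

    The denominator defaults to the samples relevant to the category (tumor
    samples for ``NMSC_ONLY``, healthy for ``HEALTHY_ONLY``, all for
    ``SHARED``); pass ``sample_subset`` to restrict e.g. to BCC only.  Ties
    break alphabetically by gene symbol.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if sample_subset is None:
        if category == NMSC_ONLY:
            sample_subset = triage.tumor_samples
        elif category == HEALTHY_ONLY:
            sample_subset = triage.healthy_samples
        else:
            sample_subset = tuple(triage.tumor_samples) + tuple(
                triage.healthy_samples
            )
    subset = set(sample_subset)
    gene_samples: dict[str, set[str]] = defaultdict(set)
    for locus, cat in triage.category.items():
        if cat != category or not triage.locus_gene[locus]:
            continue
        for sample in triage.locus_samples[locus]:
            if sample in subset:
                gene_samples[triage.locus_gene[locus]].add(sample)
    if not gene_samples:
        return []
    pct = [
        (gene, 100.0 * len(samples) / len(subset))
        for gene, samples in gene_samples.items()
    ]
    pct.sort(key=lambda t: (-t[1], t[0]))
    return pct[:k]
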