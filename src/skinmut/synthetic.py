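"""Synthetic paired-sample NMSC cohort with known ground truth.

The generator emulates the study design the pipeline targets: tumor samples
(basal and squamous cell carcinoma) and independent healthy-skin samples,
each with a paired blood sample; a targeted cancer-gene panel of ~1.7 Mb;
somatic single-nucleotide variants with a UVR-skewed substitution spectrum
(excess C>T and G>A); driver genes whose non-synonymous mutation status
modulates expression of configured gene sets; and an arsenic-exposure
stratum per tumor sample (baseline urinary arsenic/creatinine ratio).

Everything downstream is recoverable from the emitted files alone, and the
``TruthRecord`` indexes what was planted so tests can demand exact recovery:

* germline variants appear in tissue AND paired blood (removed by paired
  subtraction);
* common germline variants appear in tissue only but sit on the blacklist
  (removed by the blacklist step);
* decoy variants fail exactly one triage criterion (quality below Q60, low
  coverage, sub-2% frequency, or outside the target region);
* true somatic variants pass every threshold, so triage recovers them with
  zero false positives or negatives.

Expression counts are negative-binomial (gamma-Poisson) around
``2**(baseline + subgroup effect)`` scaled by a per-sample library factor;
genes outside every affected set carry exactly zero true effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .triage import SUBSTITUTION_CLASSES, VariantCall, Locus

BASES = "ACGT"
SUBGROUPS = ("mut0_low", "mut0_high", "mut1_low", "mut1_high")

#: default true log2 shifts per mutation x exposure subgroup.  The pattern
#: encodes "driver mutation raises, high arsenic exposure damps" with
#: magnitudes in the fold-change 1.3-7 range typical of pathway-level
#: signals in small bulk cohorts.
DEFAULT_SET_EFFECTS: dict[str, dict[str, float]] = {
    "BASAL_CELL_CARCINOMA": {
        "mut0_low": 2.02,
        "mut1_low": 2.79,
        "mut0_high": 0.41,
        "mut1_high": 1.57,
    },
    "HEDGEHOG_SIGNALING": {
        "mut0_low": 1.55,
        "mut1_low": 2.48,
        "mut0_high": 0.45,
        "mut1_high": 1.59,
    },
    "NULL_PATHWAY": {},
}


def _default_tumor_class() -> tuple[str, ...]:
    return ("BCC",) * 26 + ("SCC",) * 6


def _default_mut_genes() -> tuple[str, ...]:
    return ("PTCH1", "NOTCH1", "SYNE1", "PKHD1", "TP53")


def _default_prevalence() -> dict[str, float]:
    return {"PTCH1": 0.46, "NOTCH1": 0.27, "SYNE1": 0.31, "PKHD1": 0.28, "TP53": 0.5}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort; defaults mirror the study design."""

    n_healthy: int = 16
    n_tumor: int = 32
    tumor_class: tuple[str, ...] = field(default_factory=_default_tumor_class)
    mut_genes: tuple[str, ...] = field(default_factory=_default_mut_genes)
    mut_prevalence: dict[str, float] = field(default_factory=_default_prevalence)
    uacr_split: float = 0.5
    panel_size_mb: float = 1.7
    somatic_rate: float = 148.0
    ct_fraction: float = 0.315
    indel_fraction: float = 0.12
    nonsyn_fraction: float = 0.375
    germline_rate: float = 30.0
    decoy_rate: float = 25.0
    blacklist_size: int = 50
    blacklist_carry_prob: float = 0.4
    n_hotspots: int = 30
    hotspot_prob: float = 0.15
    n_genes: int = 1000
    n_panel_genes: int = 400
    set_size: int = 30
    set_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            name: dict(effects) for name, effects in DEFAULT_SET_EFFECTS.items()
        }
    )
    dispersion: float = 0.1
    baseline_log2_range: tuple[float, float] = (4.0, 10.0)
    libsize_factor_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.tumor_class = tuple(self.tumor_class)
        self.mut_genes = tuple(self.mut_genes)
        self.validate()

    def validate(self) -> None:
        for name in ("n_healthy", "n_tumor", "blacklist_size", "n_hotspots",
                     "n_genes", "n_panel_genes", "set_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("uacr_split", "ct_fraction", "indel_fraction",
                     "nonsyn_fraction", "blacklist_carry_prob", "hotspot_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.panel_size_mb <= 0:
            raise ValueError("panel_size_mb must be > 0")
        for name in ("somatic_rate", "germline_rate", "decoy_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if len(self.tumor_class) != self.n_tumor:
            raise ValueError(
                f"tumor_class has {len(self.tumor_class)} labels for "
                f"n_tumor={self.n_tumor}"
            )
        bad = sorted(set(self.tumor_class) - {"BCC", "SCC"})
        if bad:
            raise ValueError(f"tumor_class labels must be BCC|SCC, got {bad}")
        unknown = sorted(set(self.mut_prevalence) - set(self.mut_genes))
        if unknown:
            raise ValueError(f"mut_prevalence for unknown gene(s): {unknown}")
        for gene in self.mut_genes:
            p = self.mut_prevalence.get(gene, 0.0)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"mut_prevalence[{gene}] must be in [0, 1]")
        for set_name, effects in self.set_effects.items():
            bad = sorted(set(effects) - set(SUBGROUPS))
            if bad:
                raise ValueError(
                    f"set_effects[{set_name}] has unknown subgroup(s): {bad}"
                )
        needed = len(self.mut_genes) + len(self.set_effects) * self.set_size
        if self.n_genes < needed:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {len(self.mut_genes)} "
                f"driver genes plus {len(self.set_effects)} sets of "
                f"{self.set_size}"
            )
        if self.n_panel_genes < len(self.mut_genes):
            raise ValueError("n_panel_genes must cover every driver gene")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["tumor_class"] = list(self.tumor_class)
        data["mut_genes"] = list(self.mut_genes)
        data["baseline_log2_range"] = list(self.baseline_log2_range)
        data["libsize_factor_range"] = list(self.libsize_factor_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class TruthRecord:
    """Ground truth planted by the generator, for recovery tests."""

    mutation_status: pd.DataFrame  # samples x driver genes, 0/1
    exposure: pd.Series  # tumor sample -> low|high
    set_effects: dict[str, dict[str, float]]
    gene_effects: pd.DataFrame  # genes x subgroups, true log2 shifts
    somatic_loci: dict[str, set[Locus]]  # per tissue sample
    germline_loci: dict[str, set[Locus]]

    def expected_partition(
        self, tumor_samples: Sequence[str], healthy_samples: Sequence[str]
    ) -> dict[Locus, str]:
        """Expected three-way locus classification from the planted truth."""
        in_tumor: set[Locus] = set()
        in_healthy: set[Locus] = set()
        for s in tumor_samples:
            in_tumor |= self.somatic_loci.get(s, set())
        for s in healthy_samples:
            in_healthy |= self.somatic_loci.get(s, set())
        out = {}
        for locus in in_tumor | in_healthy:
            if locus in in_tumor and locus in in_healthy:
                out[locus] = "SHARED"
            elif locus in in_tumor:
                out[locus] = "NMSC_ONLY"
            else:
                out[locus] = "HEALTHY_ONLY"
        return out


@dataclass
class SyntheticCohort:
    """Everything the generator emits, plus the truth that indexes it."""

    config: CohortConfig
    sample_sheet: pd.DataFrame
    tissue_calls: dict[str, list[VariantCall]]
    blood_calls: dict[str, list[VariantCall]]
    counts: pd.DataFrame  # genes x samples, raw integers
    gene_sets: dict[str, list[str]]
    panel: pd.DataFrame  # gene, chrom, start, end (0-based half-open)
    target_regions: list[tuple[str, int, int]]
    blacklist: frozenset[Locus]
    truth: TruthRecord


def build_panel(config: CohortConfig) -> pd.DataFrame:
    """Lay panel genes out as fixed-width intervals on synthetic chromosomes.

    Interval width is chosen so the total covered length equals
    ``panel_size_mb``; a 10 kb gap between consecutive intervals leaves room
    for out-of-target decoys.  The layout is deterministic (no RNG).
    """
    genes = list(config.mut_genes) + [
        f"G{i:04d}"
        for i in range(1, config.n_panel_genes - len(config.mut_genes) + 1)
    ]
    width = max(1, int(round(config.panel_size_mb * 1e6 / len(genes))))
    gap = 10_000
    per_chrom = 50
    rows = []
    for i, gene in enumerate(genes):
        chrom = f"chr{i // per_chrom + 1}"
        slot = i % per_chrom
        start = slot * (width + gap) + gap
        rows.append({"gene": gene, "chrom": chrom, "start": start,
                     "end": start + width})
    return pd.DataFrame(rows)


def _gene_universe(config: CohortConfig) -> list[str]:
    return list(config.mut_genes) + [
        f"G{i:04d}" for i in range(1, config.n_genes - len(config.mut_genes) + 1)
    ]


def _draw_snv_class(rng: np.random.Generator, ct_fraction: float) -> tuple[str, str]:
    """Draw (ref, alt) from the 12-class spectrum with C>T/G>A weight."""
    p_uv = ct_fraction / 2.0
    p_other = (1.0 - ct_fraction) / 10.0
    probs = np.array(
        [p_uv if cls in ("C>T", "G>A") else p_other for cls in SUBSTITUTION_CLASSES]
    )
    cls = SUBSTITUTION_CLASSES[rng.choice(len(probs), p=probs / probs.sum())]
    ref, alt = cls.split(">")
    return ref, alt


def _passing_metrics(rng: np.random.Generator) -> dict:
    coverage = int(rng.integers(50, 501))
    freq = float(rng.uniform(0.05, 0.5))
    count = max(2, int(round(coverage * freq)))
    return {
        "coverage": coverage,
        "count": count,
        "frequency": 100.0 * count / coverage,
        "q_score": float(np.round(rng.uniform(60.0, 99.0), 2)),
        "qual": 200.0,
    }


def _decoy_metrics(rng: np.random.Generator, kind: str) -> dict:
    if kind == "lowq":
        m = _passing_metrics(rng)
        m["q_score"] = float(np.round(rng.uniform(10.0, 59.0), 2))
        return m
    if kind == "lowcov":
        coverage = int(rng.integers(3, 10))
        count = min(2, coverage)
        return {
            "coverage": coverage,
            "count": count,
            "frequency": 100.0 * count / coverage,
            "q_score": float(np.round(rng.uniform(60.0, 99.0), 2)),
            "qual": 200.0,
        }
    if kind == "lowfreq":
        coverage = int(rng.integers(300, 801))
        count = max(1, int(coverage * 0.01))
        return {
            "coverage": coverage,
            "count": count,
            "frequency": 100.0 * count / coverage,
            "q_score": float(np.round(rng.uniform(60.0, 99.0), 2)),
            "qual": 200.0,
        }
    # out-of-target decoys pass every numeric threshold
    return _passing_metrics(rng)


class _PanelSampler:
    """Draws variant loci inside (or deliberately outside) panel intervals."""

    def __init__(self, panel: pd.DataFrame, mut_genes: Sequence[str]):
        self.panel = panel.reset_index(drop=True)
        self.mut_genes = set(mut_genes)
        self.gene_row = {row.gene: row for row in panel.itertuples()}

    def in_target(self, rng: np.random.Generator, gene: str | None = None):
        row = (
            self.gene_row[gene]
            if gene is not None
            else self.panel.iloc[int(rng.integers(len(self.panel)))]
        )
        pos = int(rng.integers(row.start + 1, row.end + 1))  # 1-based in target
        return row.gene, row.chrom, pos

    def out_of_target(self, rng: np.random.Generator):
        row = self.panel.iloc[int(rng.integers(len(self.panel)))]
        pos = int(rng.integers(row.end + 2, row.end + 9_000))  # in the gap
        return row.chrom, pos


def _aa_change(rng: np.random.Generator, stop_gain_prob: float = 0.3) -> str:
    aas = ("Ala", "Gly", "Thr", "Ser", "Gln", "Pro", "Glu", "Lys", "Trp", "Cys")
    p = int(rng.integers(20, 1200))
    a = aas[int(rng.integers(len(aas)))]
    if rng.random() < stop_gain_prob:
        return f"p.{a}{p}*"
    b = aas[int(rng.integers(len(aas)))]
    return f"p.{a}{p}{b}"


def _make_variant(
    sample_id: str,
    rng: np.random.Generator,
    sampler: _PanelSampler,
    config: CohortConfig,
    *,
    gene: str | None = None,
    force_nonsyn: bool = False,
    metrics: dict | None = None,
    used: set[Locus] | None = None,
) -> VariantCall:
    """Draw one in-target variant; re-draws on locus collision with ``used``."""
    for _ in range(100):
        g, chrom, pos = sampler.in_target(rng, gene)
        if force_nonsyn or rng.random() >= config.indel_fraction:
            ref, alt = _draw_snv_class(rng, config.ct_fraction)
        else:
            base = BASES[int(rng.integers(4))]
            other = BASES[int(rng.integers(4))]
            if rng.random() < 0.5:
                ref, alt = base, base + other  # insertion
            else:
                ref, alt = base + other, base  # deletion
        locus = (chrom, pos, ref, alt)
        if used is None or locus not in used:
            break
    else:  # pragma: no cover - 100 collisions in a 1.7 Mb panel
        raise RuntimeError("could not draw a fresh locus")
    if used is not None:
        used.add(locus)
    snv = len(ref) == 1 and len(alt) == 1
    if force_nonsyn:
        nonsyn = True
    elif snv and g not in sampler.mut_genes:
        # random hits inside driver genes stay synonymous so that planted
        # driver status is exactly the recoverable mutation-status matrix
        nonsyn = bool(rng.random() < config.nonsyn_fraction)
    else:
        nonsyn = False
    m = metrics if metrics is not None else _passing_metrics(rng)
    return VariantCall(
        sample_id=sample_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=g,
        coding_change=f"c.{pos % 5000 + 1}{ref}>{alt}" if snv else "",
        aa_change=_aa_change(rng) if (snv and nonsyn) else "",
        nonsynonymous=nonsyn,
        **m,
    )


def simulate_variant_calls(
    sample_id: str,
    blood_id: str,
    is_tumor: bool,
    driver_status: Mapping[str, int],
    config: CohortConfig,
    sampler: _PanelSampler,
    blacklist: Sequence[Locus],
    hotspots: Sequence[VariantCall],
    rng: np.random.Generator,
) -> tuple[list[VariantCall], list[VariantCall], set[Locus], set[Locus]]:
    """Tissue and blood variant tables for one participant.

    Returns ``(tissue_calls, blood_calls, somatic_truth, germline_truth)``.
    Driver genes with status 1 receive at least one guaranteed non-synonymous
    SNV; every emitted somatic variant passes the triage thresholds so truth
    is recoverable.
    """
    missing = [g for g in driver_status if g not in sampler.gene_row]
    if missing:
        raise KeyError(f"driver gene(s) absent from panel: {missing}")
    used: set[Locus] = set(blacklist)
    tissue: list[VariantCall] = []
    blood: list[VariantCall] = []
    somatic_truth: set[Locus] = set()
    germline_truth: set[Locus] = set()

    # germline: same locus in tissue and paired blood, metrics drawn per tube
    for _ in range(rng.poisson(config.germline_rate)):
        v = _make_variant(sample_id, rng, sampler, config, used=used)
        germline_truth.add(v.locus)
        tissue.append(v)
        bm = _passing_metrics(rng)
        blood.append(
            VariantCall(
                sample_id=blood_id, chrom=v.chrom, pos=v.pos, ref=v.ref,
                alt=v.alt, gene=v.gene, coding_change=v.coding_change,
                aa_change=v.aa_change, nonsynonymous=v.nonsynonymous, **bm,
            )
        )

    # common germline variants: tissue-only but on the public blacklist
    for locus in blacklist:
        if rng.random() < config.blacklist_carry_prob:
            chrom, pos, ref, alt = locus
            tissue.append(
                VariantCall(
                    sample_id=sample_id, chrom=chrom, pos=pos, ref=ref,
                    alt=alt, gene="", **_passing_metrics(rng),
                )
            )

    # recurrent somatic hotspots, shared across tissue samples
    for hv in hotspots:
        if rng.random() < config.hotspot_prob:
            tissue.append(
                VariantCall(
                    sample_id=sample_id, chrom=hv.chrom, pos=hv.pos,
                    ref=hv.ref, alt=hv.alt, gene=hv.gene,
                    coding_change=hv.coding_change, aa_change=hv.aa_change,
                    nonsynonymous=hv.nonsynonymous, **_passing_metrics(rng),
                )
            )
            somatic_truth.add(hv.locus)

    # private somatic variants
    for _ in range(rng.poisson(config.somatic_rate)):
        v = _make_variant(sample_id, rng, sampler, config, used=used)
        tissue.append(v)
        somatic_truth.add(v.locus)

    # guaranteed driver hits for mutant tumor samples
    if is_tumor:
        for gene, status in driver_status.items():
            if status:
                for _ in range(1 + rng.poisson(0.3)):
                    v = _make_variant(
                        sample_id, rng, sampler, config,
                        gene=gene, force_nonsyn=True, used=used,
                    )
                    tissue.append(v)
                    somatic_truth.add(v.locus)

    # decoys failing exactly one triage criterion
    kinds = ("lowq", "lowcov", "lowfreq", "outtarget")
    for _ in range(rng.poisson(config.decoy_rate)):
        kind = kinds[int(rng.integers(len(kinds)))]
        if kind == "outtarget":
            chrom, pos = sampler.out_of_target(rng)
            ref, alt = _draw_snv_class(rng, config.ct_fraction)
            tissue.append(
                VariantCall(
                    sample_id=sample_id, chrom=chrom, pos=pos, ref=ref,
                    alt=alt, gene="", **_decoy_metrics(rng, kind),
                )
            )
        else:
            v = _make_variant(
                sample_id, rng, sampler, config,
                metrics=_decoy_metrics(rng, kind), used=used,
            )
            tissue.append(v)
    return tissue, blood, somatic_truth, germline_truth


def simulate_expression(
    labels: pd.Series,
    gene_effects: pd.DataFrame,
    dispersion: float,
    rng: np.random.Generator,
    *,
    baseline_log2_range: tuple[float, float] = (4.0, 10.0),
    libsize_factor_range: tuple[float, float] = (0.5, 2.0),
) -> pd.DataFrame:
    """Negative-binomial raw counts (genes x samples) from true log2 shifts.

    ``labels`` maps sample -> subgroup; ``gene_effects`` is genes x subgroups
    of true log2 shifts (missing subgroup columns mean zero effect).  The
    mean is ``2**(baseline + effect)`` times a per-sample library factor, and
    counts are gamma-Poisson with the given dispersion (variance
    ``mu + dispersion * mu**2``); dispersion 0 gives Poisson.
    """
    genes = gene_effects.index
    samples = list(labels.index)
    baseline = rng.uniform(*baseline_log2_range, size=len(genes))
    factors = rng.uniform(*libsize_factor_range, size=len(samples))
    counts = np.empty((len(genes), len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        group = labels[sample]
        eff = (
            gene_effects[group].to_numpy(dtype=float)
            if group in gene_effects.columns
            else np.zeros(len(genes))
        )
        mu = np.exp2(baseline + eff) * factors[j]
        if dispersion > 0:
            lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
        else:
            lam = mu
        counts[:, j] = rng.poisson(lam)
    return pd.DataFrame(counts, index=genes, columns=samples)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full cohort: sheet, paired variants, counts, sets, truth."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    # fixed spawn layout: 0 = cohort-level draws, 1 = expression,
    # 2 + i = sample i; adding samples never perturbs earlier ones.
    cohort_rng = np.random.default_rng(root.spawn(1)[0])
    n_samples = config.n_tumor + config.n_healthy
    children = np.random.SeedSequence(config.seed).spawn(2 + n_samples)
    expr_rng = np.random.default_rng(children[1])

    panel = build_panel(config)
    sampler = _PanelSampler(panel, config.mut_genes)
    target_regions = [
        (r.chrom, int(r.start), int(r.end)) for r in panel.itertuples()
    ]

    # cohort-level: blacklist loci, hotspot variants, sample sheet
    blacklist: set[Locus] = set()
    while len(blacklist) < config.blacklist_size:
        _, chrom, pos = sampler.in_target(cohort_rng)
        ref, alt = _draw_snv_class(cohort_rng, config.ct_fraction)
        blacklist.add((chrom, pos, ref, alt))
    blacklist_frozen = frozenset(blacklist)

    filler_panel = [g for g in panel.gene if g not in set(config.mut_genes)]
    hotspots: list[VariantCall] = []
    used_hotspot: set[Locus] = set(blacklist)
    for _ in range(config.n_hotspots):
        gene = filler_panel[int(cohort_rng.integers(len(filler_panel)))]
        v = _make_variant(
            "hotspot", cohort_rng, sampler, config, gene=gene, used=used_hotspot
        )
        hotspots.append(v)

    tumor_ids = [f"T{i + 1:02d}" for i in range(config.n_tumor)]
    healthy_ids = [f"H{i + 1:02d}" for i in range(config.n_healthy)]

    # per-sample attributes and variants all come from that sample's own
    # rng child, so growing the cohort never perturbs earlier samples
    sample_rngs = {
        sid: np.random.default_rng(children[2 + i])
        for i, sid in enumerate(tumor_ids + healthy_ids)
    }
    rows = []
    status = pd.DataFrame(
        0, index=tumor_ids + healthy_ids, columns=list(config.mut_genes),
        dtype=int,
    )
    for i, sid in enumerate(tumor_ids + healthy_ids):
        rng = sample_rngs[sid]
        is_tumor = i < config.n_tumor
        high = bool(rng.random() < config.uacr_split)
        uacr = (
            float(np.round(rng.uniform(193.0, 800.0), 1))
            if high
            else float(np.round(rng.uniform(20.0, 192.0), 1))
        )
        rows.append(
            {
                "sample_id": sid,
                "tissue": config.tumor_class[i] if is_tumor else "healthy",
                "blood_id": f"B{sid}",
                "sex": "m" if rng.random() < 0.5 else "f",
                "uacr": uacr,
            }
        )
        if is_tumor:
            for gene in config.mut_genes:
                p = config.mut_prevalence.get(gene, 0.0)
                status.loc[sid, gene] = int(rng.random() < p)
    sheet = pd.DataFrame(rows).set_index("sample_id")

    tissue_calls: dict[str, list[VariantCall]] = {}
    blood_calls: dict[str, list[VariantCall]] = {}
    somatic_truth: dict[str, set[Locus]] = {}
    germline_truth: dict[str, set[Locus]] = {}
    ordered_blacklist = sorted(blacklist)
    for i, sid in enumerate(tumor_ids + healthy_ids):
        rng = sample_rngs[sid]
        tis, blo, som, germ = simulate_variant_calls(
            sid,
            sheet.loc[sid, "blood_id"],
            i < config.n_tumor,
            {g: int(status.loc[sid, g]) for g in config.mut_genes},
            config,
            sampler,
            ordered_blacklist,
            hotspots,
            rng,
        )
        tissue_calls[sid] = tis
        blood_calls[sheet.loc[sid, "blood_id"]] = blo
        somatic_truth[sid] = som
        germline_truth[sid] = germ

    # expression: subgroups keyed on the first driver gene x exposure stratum
    primary = config.mut_genes[0]
    exposure = pd.Series(
        {
            sid: ("high" if sheet.loc[sid, "uacr"] > 192.0 else "low")
            for sid in tumor_ids
        }
    )
    labels = pd.Series(
        {
            sid: (
                f"mut{status.loc[sid, primary]}_{exposure[sid]}"
                if sid in exposure.index
                else "healthy"
            )
            for sid in tumor_ids + healthy_ids
        }
    )
    universe = _gene_universe(config)
    filler_expr = [g for g in universe if g not in set(config.mut_genes)]
    gene_sets: dict[str, list[str]] = {}
    cursor = 0
    for set_name in config.set_effects:
        gene_sets[set_name] = filler_expr[cursor : cursor + config.set_size]
        cursor += config.set_size
    # the primary driver participates in the first affected set, mirroring
    # a receptor gene sitting inside its own pathway
    if gene_sets:
        first = next(iter(gene_sets))
        if config.set_effects.get(first):
            gene_sets[first] = [primary] + gene_sets[first][:-1]

    gene_effects = pd.DataFrame(
        0.0, index=universe, columns=list(SUBGROUPS)
    )
    for set_name, effects in config.set_effects.items():
        for subgroup, shift in effects.items():
            gene_effects.loc[gene_sets[set_name], subgroup] = shift

    counts = simulate_expression(
        labels,
        gene_effects,
        config.dispersion,
        expr_rng,
        baseline_log2_range=config.baseline_log2_range,
        libsize_factor_range=config.libsize_factor_range,
    )

    truth = TruthRecord(
        mutation_status=status,
        exposure=exposure,
        set_effects={k: dict(v) for k, v in config.set_effects.items()},
        gene_effects=gene_effects,
        somatic_loci=somatic_truth,
        germline_loci=germline_truth,
    )
    return SyntheticCohort(
        config=config,
        sample_sheet=sheet,
        tissue_calls=tissue_calls,
        blood_calls=blood_calls,
        counts=counts,
        gene_sets=gene_sets,
        panel=panel,
        target_regions=target_regions,
        blacklist=blacklist_frozen,
        truth=truth,
    )


def write_fixtures(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort as on-disk fixtures (VCF, BED, TSV, GMT).

    Returns a mapping of logical names to paths; everything written is
    re-readable by :mod:`skinmut.io` with content equality.
    """
    from . import io as skio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vcf_dir = directory / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    paths: dict[str, Path] = {}
    contigs = sorted(
        {c for c, _, _ in cohort.target_regions},
        key=lambda c: int(c.replace("chr", "")),
    )
    for sid, calls in cohort.tissue_calls.items():
        p = vcf_dir / f"{sid}.vcf"
        skio.write_vcf(p, sid, calls, contigs=contigs)
        paths[f"vcf:{sid}"] = p
    for bid, calls in cohort.blood_calls.items():
        p = vcf_dir / f"{bid}.vcf"
        skio.write_vcf(p, bid, calls, contigs=contigs)
        paths[f"vcf:{bid}"] = p
    paths["bed"] = directory / "target_regions.bed"
    skio.write_bed(paths["bed"], cohort.target_regions)
    paths["blacklist"] = directory / "germline_blacklist.tsv"
    skio.write_blacklist(paths["blacklist"], cohort.blacklist)
    paths["counts"] = directory / "counts.tsv"
    skio.write_counts(paths["counts"], cohort.counts)
    paths["sample_sheet"] = directory / "sample_sheet.tsv"
    skio.write_sample_sheet(paths["sample_sheet"], cohort.sample_sheet)
    paths["gmt"] = directory / "gene_sets.gmt"
    skio.write_gmt(paths["gmt"], cohort.gene_sets)
    return paths
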