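"""Cohort-level QC filters and variant tier assignment.

Variants are placed into three nested analysis tiers:

* ``RIV`` — rare inactivating variants: loss-of-function consequences
  (stop gain/loss, splice site, frameshift indel) with allele frequency
  below ``rare_af_max`` (default 0.01) in both the reference population
  and the control cohort;
* ``RDV`` — rare damaging variants: every RIV, plus rare missense variants
  predicted damaging (M-CAP score strictly above ``mcap_min``, default
  0.025);
* ``NONSYN`` — the non-synonymous tier fed to SKAT: any protein-altering
  consequence with both allele frequencies below ``nonsyn_af_max``
  (default 0.1).

Threshold direction is strict on all three cuts ("less than", "below",
"more than").  QC precedes tiering: variants failing call rate or the
control-cohort Hardy-Weinberg exact test receive no tier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_cohort import (
    LOF_CONSEQUENCES,
    MISSING,
    NONSYN_CONSEQUENCES,
    AnnotationRecord,
    CohortGenotypes,
    VariantKey,
)

logger = logging.getLogger(__name__)

TIERS = ("RIV", "RDV", "NONSYN")


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds for QC and tier assignment.

    The HWE and call-rate cut-offs are QC conventions of this pipeline
    (the source filters are standard but unparameterised in the field's
    reports); both are logged and configurable.
    """

    rare_af_max: float = 0.01
    nonsyn_af_max: float = 0.1
    mcap_min: float = 0.025
    hwe_alpha: float = 1e-6
    min_call_rate: float = 0.9
    min_gene_count: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.rare_af_max < self.nonsyn_af_max <= 1:
            raise ValueError("need 0 < rare_af_max < nonsyn_af_max <= 1")
        if not 0 <= self.mcap_min <= 1:
            raise ValueError("mcap_min must lie in [0,1]")
        if not 0 < self.hwe_alpha < 1:
            raise ValueError("hwe_alpha must lie in (0,1)")
        if not 0 <= self.min_call_rate <= 1:
            raise ValueError("min_call_rate must lie in [0,1]")


@dataclass
class TierAssignment:
    """Tier membership of one (variant, gene) pair after QC."""

    key: VariantKey
    gene: str
    tiers: frozenset[str]
    qc_pass: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.qc_pass and self.tiers:
            raise ValueError("QC-failed variants cannot carry tiers")
        if "RIV" in self.tiers and "RDV" not in self.tiers:
            raise ValueError("every RIV is an RDV")


def cohort_af(
    geno: CohortGenotypes, key: VariantKey, subset: str = "all"
) -> float:
    """Alternate-allele frequency: alt alleles / called alleles.

    Missing genotypes are excluded from the denominator.  ``subset``
    selects ``all``, ``cases`` or ``controls``.  A subset with zero called
    alleles raises (distinct from a true frequency of zero).
    """
    col = geno.column(key)
    if subset == "cases":
        col = col[geno.manifest.case_mask()]
    elif subset == "controls":
        col = col[~geno.manifest.case_mask()]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    called = col != MISSING
    n_alleles = 2 * int(called.sum())
    if n_alleles == 0:
        raise ZeroDivisionError(f"no called alleles for {key} in subset {subset}")
    return float(col[called].sum()) / n_alleles


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact test of Hardy-Weinberg genotype proportions.

    Conditions on the observed allele counts and sums, over heterozygote
    counts of matching parity, the probabilities of all configurations no
    more probable than the observed one (the standard exact HWE
    convention).  Probabilities are built by recurrence with running
    renormalisation, which is stable for the cohort sizes seen here.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotypes")
    n_alt = 2 * n_hom_alt + n_het
    n_rare = min(n_alt, 2 * n - n_alt)
    if n_rare == 0:
        return 1.0

    # P(het = h+2) / P(het = h) with allele counts fixed:
    #   hom_rare(h) = (n_rare - h) / 2, hom_common(h) = n - h - hom_rare(h)
    hets = list(range(n_rare % 2, n_rare + 1, 2))
    probs = np.empty(len(hets))
    probs[0] = 1.0
    for i in range(1, len(hets)):
        h = hets[i - 1]
        hom_r = (n_rare - h) / 2
        hom_c = n - h - hom_r
        probs[i] = probs[i - 1] * (4.0 * hom_r * hom_c) / ((h + 2.0) * (h + 1.0))
        if probs[i] > 1e250:  # renormalise to avoid overflow
            probs /= probs[i]
    probs /= probs.sum()
    p_obs = probs[hets.index(n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-10)].sum()))


def genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    """(hom_ref, het, hom_alt) counts of a dosage column, ignoring missing."""
    return int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())


def qc_filter(
    geno: CohortGenotypes, ann: AnnotationRecord, cfg: ClassificationConfig
) -> tuple[bool, list[str]]:
    """Cohort-level QC for one variant: call rate and control-cohort HWE."""
    col = geno.column(ann.key)
    reasons: list[str] = []
    call_rate = float((col != MISSING).mean())
    if call_rate < cfg.min_call_rate:
        reasons.append("call_rate")
    controls = col[~geno.manifest.case_mask()]
    controls = controls[controls != MISSING]
    if controls.size:
        p_hwe = hwe_exact_test(*genotype_counts(controls))
        if p_hwe < cfg.hwe_alpha:
            reasons.append("hwe")
    return (not reasons, reasons)


def classify_variant(
    ann: AnnotationRecord, cohort_control_af: float, cfg: ClassificationConfig
) -> TierAssignment:
    """Assign analysis tiers to one QC-passed (variant, gene) pair.

    Pure function of the annotation, the control-cohort allele frequency
    and the thresholds.  A missense variant with no M-CAP score is never
    RDV-eligible (logged, not an error).
    """
    tiers: set[str] = set()
    both_rare = ann.ref_pop_af < cfg.rare_af_max and cohort_control_af < cfg.rare_af_max

    if ann.consequence in LOF_CONSEQUENCES and both_rare:
        tiers |= {"RIV", "RDV"}
    if ann.consequence == "missense" and both_rare:
        if ann.mcap is None:
            logger.info("missense %s has no M-CAP score; not RDV-eligible", ann.key)
        elif ann.mcap > cfg.mcap_min:
            tiers.add("RDV")
    if (
        ann.consequence in NONSYN_CONSEQUENCES
        and ann.ref_pop_af < cfg.nonsyn_af_max
        and cohort_control_af < cfg.nonsyn_af_max
    ):
        tiers.add("NONSYN")

    return TierAssignment(ann.key, ann.gene, frozenset(tiers), qc_pass=True)


@dataclass
class GeneVariantSet:
    """Qualifying variants of one gene in one tier, with eligibility."""

    gene: str
    tier: str
    variants: list[VariantKey]
    n_carrier_observations: int | None = None
    eligible: bool = True


def select_variant_set(
    assignments: list[TierAssignment],
    tier: str,
    geno: CohortGenotypes | None = None,
    min_gene_count: int = 5,
) -> dict[str, GeneVariantSet]:
    """Group tier-qualifying variants by gene.

    When genotypes are supplied, each gene is additionally flagged
    eligible/ineligible for the association scan by its total number of
    qualifying carrier-observations (case + control (sample, variant)
    pairs with at least one alternate allele), threshold
    ``min_gene_count``.  Ineligible genes are retained — the filter-based
    ranking uses all of them.
    """
    if tier not in TIERS:
        raise ValueError(f"unknown tier {tier!r}")
    sets: dict[str, GeneVariantSet] = {}
    for a in assignments:
        if tier in a.tiers:
            sets.setdefault(a.gene, GeneVariantSet(a.gene, tier, [])).variants.append(a.key)
    if geno is not None:
        for gs in sets.values():
            carriers = geno.columns(gs.variants) >= 1
            gs.n_carrier_observations = int(carriers.sum())
            gs.eligible = gs.n_carrier_observations >= min_gene_count
    return sets
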