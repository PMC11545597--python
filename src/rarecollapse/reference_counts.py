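"""Published carrier counts from the motivating high-risk colorectal-cancer
case-control exome study (146 cases, 1395 controls).

These tables hold the carrier counts, odds ratios and p-values printed for
the study's rare-inactivating-variant (RIV), rare-damaging-variant (RDV)
and non-synonymous/SKAT gene lists.  Because the association statistics are
deterministic functions of the carrier counts and the cohort margins, the
counts double as a regression fixture for the burden statistics and as
planting targets for the synthetic-cohort generator
(:func:`rarecollapse.synthetic_data.replant_reference_tables`).

``expected_or``/``expected_p`` are the values the pipeline's conventions
produce (Pearson 1-df chi-square without continuity correction;
Haldane-Anscombe 0.5 correction on zero cells).  They match the published
values at printed precision with two curated exceptions:

* the control-only frameshift deletion in *APC* (0 case / 1 control
  carriers) was published once with a garbled sign and once on the
  reciprocal (control-vs-case) scale; identical counts elsewhere in the
  same table were published as OR = 3.2, and that consistently oriented
  value is stored here;
* p-values published as ``0.00 x 10^-0`` are display underflow and are
  stored as ``None`` (the computed value is below 1e-15).
"""

from __future__ import annotations

from dataclasses import dataclass

N_CASE = 146
N_CONTROL = 1395


@dataclass(frozen=True)
class VariantCount:
    """One published per-variant row: locus, consequence and carrier counts."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    n_case_carriers: int
    n_control_carriers: int
    expected_p: float | None
    expected_or: float


@dataclass(frozen=True)
class GeneCount:
    """One published per-gene row: carrier counts and association statistics."""

    gene: str
    n_case_carriers: int
    n_control_carriers: int
    expected_p: float | None
    expected_or: float


# Per-variant RIV list (the published study's drivers of the APC, RIMS1 and
# ST6GALNAC2 signals).  Indels are stored VCF-style with an anchor base; the
# published display notation ("T / -") is display-only.
RIV_VARIANTS: list[VariantCount] = [
    VariantCount("APC", "chr5", 112154963, "C", "T", "stop_gain", 3, 0, 8.36e-8, 68.1),
    VariantCount("APC", "chr5", 112128191, "C", "T", "stop_gain", 1, 0, 0.002, 28.8),
    VariantCount("APC", "chr5", 112155042, "G", "C", "stop_gain", 1, 0, 0.002, 28.8),
    VariantCount("APC", "chr5", 112174112, "G", "T", "stop_gain", 1, 0, 0.002, 28.8),
    VariantCount("APC", "chr5", 112175077, "CT", "C", "frameshift_deletion", 0, 1, 0.746, 3.2),
    VariantCount("RIMS1", "chr6", 72974704, "T", "G", "stop_gain", 4, 0, 6.01e-10, 88.1),
    VariantCount("RIMS1", "chr6", 72975696, "T", "TTC", "frameshift_insertion", 1, 0, 0.002, 28.8),
    VariantCount("RIMS1", "chr6", 72945397, "T", "C", "stop_gain", 0, 1, 0.746, 3.2),
    VariantCount("RIMS1", "chr6", 72984083, "C", "T", "stop_gain", 0, 1, 0.746, 3.2),
    VariantCount("ST6GALNAC2", "chr17", 74566661, "GT", "G", "frameshift_deletion", 2, 1, 0.001, 19.4),
    VariantCount("ST6GALNAC2", "chr17", 74568782, "AG", "A", "frameshift_deletion", 1, 1, 0.050, 9.6),
]

# Top-10 genes by number of RIV case carriers (the filter-based ranking list).
RIV_TOP_GENES: list[GeneCount] = [
    GeneCount("APC", 6, 1, 5.08e-12, 59.7),
    GeneCount("CD36", 6, 25, 0.058, 2.3),
    GeneCount("RIMS1", 5, 2, 2.03e-8, 24.7),
    GeneCount("ACOT4", 3, 4, 0.003, 7.3),
    GeneCount("ST6GALNAC2", 3, 2, 1.12e-4, 14.6),
    GeneCount("FSIP2", 3, 7, 0.026, 4.2),
    GeneCount("PNPLA7", 3, 9, 0.065, 3.2),
    GeneCount("TTN", 2, 32, 0.470, 0.6),
    GeneCount("TTLL10", 2, 5, 0.084, 3.9),
    GeneCount("ITGA10", 2, 52, 0.140, 0.4),
]

# Genes exome-wide significant in the RDV (rare damaging variant) scan.
RDV_GENES: list[GeneCount] = [
    GeneCount("TNXB", 10, 1, None, 102.5),
    GeneCount("GPR112", 7, 0, None, 150.1),
    GeneCount("COL11A2", 5, 0, 4.42e-12, 108.5),
    GeneCount("ANKRD33B", 4, 1, 6.91e-8, 39.3),
    GeneCount("TBKBP1", 5, 2, 2.03e-8, 24.7),
    GeneCount("OR5K4", 5, 2, 2.03e-8, 24.7),
    GeneCount("MTAP", 5, 2, 2.03e-8, 24.7),
    GeneCount("SHANK1", 10, 13, 2.02e-8, 7.8),
    GeneCount("SPRED1", 4, 1, 6.91e-8, 39.3),
    GeneCount("MPP2", 4, 1, 6.91e-8, 39.3),
    GeneCount("KANSL1", 4, 1, 6.91e-8, 39.3),
    GeneCount("PIAS4", 4, 1, 6.91e-8, 39.3),
    GeneCount("TNNI3", 4, 1, 6.91e-8, 39.3),
    GeneCount("BTNL2", 4, 1, 6.91e-8, 39.3),
    GeneCount("CAPZA1", 4, 2, 1.64e-6, 19.6),
    GeneCount("OSTC", 4, 2, 1.64e-6, 19.6),
    GeneCount("SOX4", 4, 2, 1.64e-6, 19.6),
]

# Genes exome-wide significant in the SKAT (non-synonymous tier) scan, with
# their published carrier-collapsing summaries.
SKAT_GENES: list[GeneCount] = [
    GeneCount("TNXB", 16, 1, None, 171.6),
    GeneCount("TAP2", 8, 0, None, 171.3),
    GeneCount("GPSM3", 7, 0, None, 150.1),
    GeneCount("ADGRG4", 7, 0, None, 150.1),
    GeneCount("TMEM229A", 8, 4, 1.11e-11, 20.2),
    GeneCount("ANKRD33B", 6, 1, 5.08e-12, 59.7),
]

# Additional per-variant anchors quoted in the study text: four RDV loci each
# carried by 3 cases and 0 controls (OR 68.1, p 8.36e-8).
RDV_TEXT_VARIANTS: list[VariantCount] = [
    VariantCount("SPRED1", "chr15", 38545392, "C", "A", "missense", 3, 0, 8.36e-8, 68.1),
    VariantCount("SHANK1", "chr19", 51206940, "G", "A", "missense", 3, 0, 8.36e-8, 68.1),
    VariantCount("OR5K4", "chr3", 98073028, "G", "T", "missense", 3, 0, 8.36e-8, 68.1),
    VariantCount("COL11A2", "chr6", 33154366, "G", "T", "missense", 3, 0, 8.36e-8, 68.1),
]

ALL_GENE_COUNTS: dict[str, list[GeneCount]] = {
    "riv": RIV_TOP_GENES,
    "rdv": RDV_GENES,
    "nonsyn": SKAT_GENES,
}
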