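"""Cohort I/O: sample manifests, multi-sample VCFs, variant annotation
tables and association-result tables.

The internal data model is deliberately small:

* :class:`SampleManifest` — who is a case and who is a control;
* :class:`VariantKey` — one alternate allele at a locus (1-based VCF
  coordinates, anchored-base indel representation);
* :class:`AnnotationRecord` — the annotation a variant needs for tiering
  (gene, consequence class, reference-population allele frequency,
  missense pathogenicity score);
* :class:`CohortGenotypes` — a samples x variants dosage matrix.

Multi-allelic VCF sites are decomposed into one :class:`VariantKey` per
alternate allele at read time; everything downstream is bi-allelic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING: int = -1

Status = Literal["case", "control"]

#: Controlled vocabulary for consequence classes.
CONSEQUENCES = {
    "missense",
    "stop_gain",
    "stop_loss",
    "splice_site",
    "frameshift_insertion",
    "frameshift_deletion",
    "nonframeshift_insertion",
    "nonframeshift_deletion",
    "synonymous",
    "other",
}

#: Loss-of-function classes (the inactivating consequence classes).
LOF_CONSEQUENCES = {
    "stop_gain",
    "stop_loss",
    "splice_site",
    "frameshift_insertion",
    "frameshift_deletion",
}

#: Consequence classes eligible for the non-synonymous (SKAT) tier.
NONSYN_CONSEQUENCES = LOF_CONSEQUENCES | {
    "missense",
    "nonframeshift_insertion",
    "nonframeshift_deletion",
}

#: Common annotator spellings mapped onto the controlled vocabulary.
CONSEQUENCE_SPELLINGS = {
    "missense": "missense",
    "missense_variant": "missense",
    "nonsynonymous snv": "missense",
    "nonsynonymous_snv": "missense",
    "stopgain": "stop_gain",
    "stop_gain": "stop_gain",
    "stop_gained": "stop_gain",
    "stoploss": "stop_loss",
    "stop_loss": "stop_loss",
    "stop_lost": "stop_loss",
    "splicing": "splice_site",
    "splice_site": "splice_site",
    "splice_site_variant": "splice_site",
    "frameshift insertion": "frameshift_insertion",
    "frameshift_insertion": "frameshift_insertion",
    "frameshift deletion": "frameshift_deletion",
    "frameshift_deletion": "frameshift_deletion",
    "nonframeshift insertion": "nonframeshift_insertion",
    "nonframeshift_insertion": "nonframeshift_insertion",
    "nonframeshift deletion": "nonframeshift_deletion",
    "nonframeshift_deletion": "nonframeshift_deletion",
    "synonymous": "synonymous",
    "synonymous snv": "synonymous",
    "synonymous_snv": "synonymous",
    "other": "other",
}


class VariantKey(NamedTuple):
    """One alternate allele at a locus, VCF-style (1-based, anchored)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:  # pragma: no cover - display helper
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class AnnotationRecord:
    """Annotation of one alternate allele within one gene.

    ``mcap`` is ``None`` when the missense pathogenicity score is not
    available (typical for non-missense consequences); absence is distinct
    from a score of zero.
    """

    key: VariantKey
    gene: str
    consequence: str
    ref_pop_af: float
    mcap: float | None = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence class: {self.consequence!r}")
        if not 0.0 <= self.ref_pop_af <= 1.0:
            raise ValueError(f"ref_pop_af outside [0,1]: {self.ref_pop_af}")
        if self.mcap is not None and not 0.0 <= self.mcap <= 1.0:
            raise ValueError(f"mcap outside [0,1]: {self.mcap}")


@dataclass(frozen=True)
class SampleManifest:
    """Ordered case/control labels for the cohort."""

    entries: tuple[tuple[str, Status], ...]

    def __post_init__(self) -> None:
        ids = [s for s, _ in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids in manifest: {dupes}")
        for sid, status in self.entries:
            if status not in ("case", "control"):
                raise ValueError(f"invalid status {status!r} for sample {sid}")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("manifest must contain at least one case and one control")

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.entries]

    @property
    def n_case(self) -> int:
        return sum(1 for _, st in self.entries if st == "case")

    @property
    def n_control(self) -> int:
        return sum(1 for _, st in self.entries if st == "control")

    @property
    def n_samples(self) -> int:
        return len(self.entries)

    def case_mask(self) -> np.ndarray:
        """Boolean array, True where the sample is a case."""
        return np.array([st == "case" for _, st in self.entries], dtype=bool)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "SampleManifest":
        return cls(tuple((str(s), str(st)) for s, st in pairs))  # type: ignore[arg-type]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleManifest":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample_id", "status"}
        if not required.issubset(df.columns):
            raise ValueError(f"manifest must have columns {sorted(required)}, got {list(df.columns)}")
        return cls.from_pairs(zip(df["sample_id"], df["status"]))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.entries, columns=["sample_id", "status"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class CohortGenotypes:
    """Samples x variants alternate-allele dosage matrix.

    ``dosage`` entries are 0, 1, 2 or :data:`MISSING` (-1).  Rows follow
    manifest order, columns follow ``variants`` order.
    """

    manifest: SampleManifest
    variants: list[VariantKey]
    dosage: np.ndarray
    _index: dict[VariantKey, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (self.manifest.n_samples, len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{self.manifest.n_samples} samples x {len(self.variants)} variants"
            )
        self._index = {k: j for j, k in enumerate(self.variants)}
        if len(self._index) != len(self.variants):
            raise ValueError("duplicate variant keys in genotype matrix")

    @property
    def n_samples(self) -> int:
        return self.manifest.n_samples

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def column(self, key: VariantKey) -> np.ndarray:
        """Dosage column for one variant (int8, MISSING = -1)."""
        try:
            return self.dosage[:, self._index[key]]
        except KeyError:
            raise KeyError(f"variant {key} not in cohort") from None

    def columns(self, keys: Sequence[VariantKey]) -> np.ndarray:
        idx = [self._index[k] for k in keys]
        return self.dosage[:, idx]

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._index


class VcfReadError(RuntimeError):
    pass


def read_vcf_cohort(vcf_path: str | Path, manifest: SampleManifest) -> CohortGenotypes:
    """Read a multi-sample VCF into a :class:`CohortGenotypes`.

    Multi-allelic sites are decomposed into one column per alternate allele;
    the dosage of allele ``k`` is the number of GT alleles equal to ``k``.
    Genotypes with any missing allele become :data:`MISSING`.  Phased
    separators are accepted and treated as unphased.  Samples present in
    the VCF but absent from the manifest are ignored; manifest samples
    missing from the VCF are a hard error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    header_samples = list(vcf.samples)
    missing = [s for s in manifest.sample_ids if s not in set(header_samples)]
    if missing:
        raise VcfReadError(
            f"manifest sample(s) absent from VCF {vcf_path}: {', '.join(missing)}"
        )
    col_of = {s: i for i, s in enumerate(header_samples)}
    order = np.array([col_of[s] for s in manifest.sample_ids])

    keys: list[VariantKey] = []
    columns: list[np.ndarray] = []
    for rec_no, rec in enumerate(vcf, start=1):
        gts = np.array([g[:-1] for g in rec.genotypes], dtype=np.int16)
        if gts.ndim != 2 or gts.shape[0] != len(header_samples):
            raise VcfReadError(
                f"malformed GT field at record {rec_no} ({rec.CHROM}:{rec.POS})"
            )
        gts = gts[order]
        any_missing = (gts < 0).any(axis=1)
        for k, alt in enumerate(rec.ALT, start=1):
            dos = (gts == k).sum(axis=1).astype(np.int8)
            dos[any_missing] = MISSING
            keys.append(VariantKey(rec.CHROM, rec.POS, rec.REF, alt))
            columns.append(dos)
    vcf.close()

    dosage = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((manifest.n_samples, 0), dtype=np.int8)
    )
    return CohortGenotypes(manifest=manifest, variants=keys, dosage=dosage)


ANNOTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "consequence", "ref_pop_af", "mcap"]


def read_annotations(tsv_path: str | Path) -> list[AnnotationRecord]:
    """Read a tab-separated variant annotation table.

    Unknown consequence spellings fall back to ``other`` with a warning;
    an absent M-CAP score ('.', '', 'NA') is parsed as missing, never as 0.
    Duplicate (variant, gene) rows and unparseable frequencies are hard
    errors.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"annotation table missing column(s): {missing_cols}")

    records: list[AnnotationRecord] = []
    seen: set[tuple[VariantKey, str]] = set()
    for row in df.itertuples(index=False):
        key = VariantKey(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        gene = str(row.gene)
        if (key, gene) in seen:
            raise ValueError(f"duplicate annotation row for {key} in gene {gene}")
        seen.add((key, gene))

        raw = str(row.consequence).strip().lower()
        consequence = CONSEQUENCE_SPELLINGS.get(raw)
        if consequence is None:
            logger.warning("unknown consequence %r at %s; mapped to 'other'", raw, key)
            consequence = "other"

        try:
            ref_pop_af = float(row.ref_pop_af)
        except ValueError as exc:
            raise ValueError(f"unparseable ref_pop_af {row.ref_pop_af!r} at {key}") from exc

        mcap_raw = str(row.mcap).strip()
        mcap = None if mcap_raw in {".", "", "NA", "nan"} else float(mcap_raw)

        records.append(AnnotationRecord(key, gene, consequence, ref_pop_af, mcap))
    return records


def write_annotations(records: Sequence[AnnotationRecord], tsv_path: str | Path) -> None:
    rows = [
        (r.key.chrom, r.key.pos, r.key.ref, r.key.alt, r.gene, r.consequence,
         f"{r.ref_pop_af:.6g}", "." if r.mcap is None else f"{r.mcap:.4g}")
        for r in records
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(tsv_path, sep="\t", index=False)


RESULT_COLUMNS = [
    "gene", "tier", "chrom", "pos", "ref", "alt",
    "n_case_carriers", "pct_case", "n_control_carriers", "pct_control",
    "p_value", "odds_ratio", "significance_tier",
]


def _round_half_even_pct(count: int, total: int) -> str:
    # percent computed from counts at write time; bankers' rounding to 1 dp
    pct = 100.0 * count / total
    q = math.floor(pct * 10)
    rem = pct * 10 - q
    if abs(rem - 0.5) < 1e-9:
        q += q % 2  # round half to even
    else:
        q = round(pct * 10)
    return f"{q / 10:.1f}"


def write_results(results: Sequence[object], out_path: str | Path) -> None:
    """Write gene- or variant-level association results as a TSV.

    Accepts :class:`~rarecollapse.burden.GeneAssociationResult` and
    :class:`~rarecollapse.burden.VariantAssociationResult` objects (mixed
    lists allowed).  Percentages are recomputed from the counts, odds
    ratios are printed to 1 decimal and p-values in scientific notation
    with 3 significant digits.  P-values below 1e-300 are floored to
    ``1.00e-300`` for display (underflow guard).
    """
    rows = []
    for r in results:
        key = getattr(r, "key", None)
        table = r.table
        p = max(r.p_value, 1e-300)
        rows.append({
            "gene": r.gene,
            "tier": getattr(r, "tier", ""),
            "chrom": key.chrom if key else "",
            "pos": key.pos if key else "",
            "ref": key.ref if key else "",
            "alt": key.alt if key else "",
            "n_case_carriers": table.a,
            "pct_case": _round_half_even_pct(table.a, table.n_case),
            "n_control_carriers": table.c,
            "pct_control": _round_half_even_pct(table.c, table.n_control),
            "p_value": f"{p:.2e}",
            # 1 decimal like the field's tables; 2 decimals below 1 so
            # protective ORs keep a significant digit (0.31, not 0.3)
            "odds_ratio": f"{r.odds_ratio:.1f}" if r.odds_ratio >= 1 else f"{r.odds_ratio:.2f}",
            "significance_tier": getattr(r, "significance", ""),
        })
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    try:
        df.to_csv(out_path, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"cannot write results to {out_path}: {exc}") from exc


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results TSV back as a DataFrame (round-trip convenience)."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})


def write_vcf(geno: CohortGenotypes, path: str | Path) -> None:
    """Write the cohort genotype matrix as an uncompressed VCF v4.2 text file.

    Emits one bi-allelic record per variant key (sites are already
    decomposed in the internal model), with GT as the only FORMAT field.
    Output is byte-deterministic for a given genotype matrix.
    """
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    contigs = sorted({k.chrom for k in geno.variants}, key=_chrom_sort_key)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        *(f"##contig=<ID={c}>" for c in contigs),
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(geno.manifest.sample_ids),
    ]
    order = sorted(
        range(geno.n_variants),
        key=lambda j: (_chrom_sort_key(geno.variants[j].chrom), geno.variants[j].pos,
                       geno.variants[j].ref, geno.variants[j].alt),
    )
    for j in order:
        k = geno.variants[j]
        gts = "\t".join(gt_str[int(d)] for d in geno.dosage[:, j])
        lines.append(f"{k.chrom}\t{k.pos}\t.\t{k.ref}\t{k.alt}\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = chrom.removeprefix("chr")
    return (int(c), "") if c.isdigit() else (99, c)
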