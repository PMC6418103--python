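"""Somatic variant data model, table I/O and the pre-TH variant filters.

VAFs are stored as percentages in [0, 100] throughout the package.  Input
files on the fraction scale are converted at read time when
``vaf_scale="fraction"`` is passed; the scale is declared per file, never
guessed from the data.

Coordinates are 1-based inclusive (VCF convention); strand is ignored.
The upstream false-positive filter is represented only by a boolean flag
(``fp_flag``); its algorithm is out of scope here, as are variant calling
and annotation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Columns of the tab-delimited variant dialect, in order.
TSV_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "ref_count",
    "alt_count",
    "vaf",
    "germline_flag",
    "fp_flag",
]

_VAF_TOL = 1e-6


@dataclass(frozen=True)
class VariantRecord:
    """A single somatic variant call with its read support.

    ``vaf`` is a percentage in [0, 100].  ``ref_count``/``alt_count`` may be
    absent (``None``) for tables that only report a VAF; when both are
    present the VAF must equal ``100 * alt / (ref + alt)`` and total depth
    must be at least 1.  ``pop_af`` is an optional population allele
    frequency annotation (fraction) used by the germline filter.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene: str
    ref_count: Optional[int] = None
    alt_count: Optional[int] = None
    vaf: Optional[float] = None
    germline_flag: bool = False
    fp_flag: bool = False
    sample_id: str = ""
    pop_af: Optional[float] = None

    def __post_init__(self) -> None:
        if self.vaf is not None and not 0.0 <= self.vaf <= 100.0:
            raise ValueError(f"VAF {self.vaf} outside [0, 100]")
        if self.ref_count is not None and self.ref_count < 0:
            raise ValueError("negative ref_count")
        if self.alt_count is not None and self.alt_count < 0:
            raise ValueError("negative alt_count")
        if self.ref_count is not None and self.alt_count is not None:
            depth = self.ref_count + self.alt_count
            if self.vaf is not None:
                if depth < 1:
                    raise ValueError("vaf present but total depth is 0")
                expected = 100.0 * self.alt_count / depth
                if not math.isclose(self.vaf, expected, abs_tol=0.5):
                    raise ValueError(
                        f"vaf {self.vaf} inconsistent with counts "
                        f"{self.ref_count}/{self.alt_count} (expect {expected:.3f})"
                    )

    @property
    def depth(self) -> Optional[int]:
        if self.ref_count is None or self.alt_count is None:
            return None
        return self.ref_count + self.alt_count


@dataclass(frozen=True)
class PanelDefinition:
    """A named set of genes targeted by a sequencing panel."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError("panel must contain at least one gene")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class VafProfile:
    """Per-sample VAFs restricted to a gene panel; input to the TH statistic."""

    sample_id: str
    vafs: list[float]
    panel: PanelDefinition
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for v in self.vafs:
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"VAF {v} outside [0, 100]")
        if self.genes and len(self.genes) != len(self.vafs):
            raise ValueError("genes and vafs length mismatch")

    @property
    def n_mutations(self) -> int:
        return len(self.vafs)


def _records_from_frame(df: pd.DataFrame, vaf_scale: str) -> list[VariantRecord]:
    if vaf_scale not in ("percent", "fraction"):
        raise ValueError(f"unknown vaf_scale {vaf_scale!r}")
    records: list[VariantRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        ref_count = None if pd.isna(row.get("ref_count")) else int(row["ref_count"])
        alt_count = None if pd.isna(row.get("alt_count")) else int(row["alt_count"])
        vaf = None if pd.isna(row.get("vaf")) else float(row["vaf"])
        if vaf is not None and vaf_scale == "fraction":
            vaf *= 100.0
        if vaf is None and (ref_count is None or alt_count is None):
            errors.append(f"row {idx}: neither vaf nor read counts present")
            continue
        if vaf is None:
            depth = ref_count + alt_count
            if depth < 1:
                errors.append(f"row {idx}: zero total depth")
                continue
            vaf = 100.0 * alt_count / depth
        pop_af = None
        if "pop_af" in df.columns and not pd.isna(row["pop_af"]):
            pop_af = float(row["pop_af"])
        records.append(
            VariantRecord(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref_allele=str(row["ref"]),
                alt_allele=str(row["alt"]),
                gene=str(row["gene"]),
                ref_count=ref_count,
                alt_count=alt_count,
                vaf=vaf,
                germline_flag=bool(row.get("germline_flag", False)),
                fp_flag=bool(row.get("fp_flag", False)),
                sample_id=str(row.get("sample_id", "")),
                pop_af=pop_af,
            )
        )
    for msg in errors:
        logger.warning("skipped variant row: %s", msg)
    return records


def _records_from_vcf(
    path: Path, sample: Optional[str], gene_info_key: str
) -> list[VariantRecord]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if not vcf.samples:
        raise ValueError(f"{path}: VCF has no samples (per-sample AD required)")
    if sample is None:
        sample_idx, sample_id = 0, vcf.samples[0]
    else:
        if sample not in vcf.samples:
            raise ValueError(f"sample {sample!r} not in VCF ({vcf.samples})")
        sample_idx, sample_id = vcf.samples.index(sample), sample

    records: list[VariantRecord] = []
    for var in vcf:
        ad = var.format("AD")
        if ad is None:
            logger.warning(
                "skipped variant row: %s:%d lacks per-sample AD", var.CHROM, var.POS
            )
            continue
        depths = [int(x) for x in ad[sample_idx]]
        ref_count = max(depths[0], 0)
        gene = var.INFO.get(gene_info_key) or ""
        germline = "GERMLINE" in (var.FILTER or "")
        fp = "FP" in (var.FILTER or "")
        pop_af = var.INFO.get("POP_AF")
        for alt_idx, alt in enumerate(var.ALT, start=1):
            if alt_idx >= len(depths):
                continue
            alt_count = max(depths[alt_idx], 0)
            depth = ref_count + alt_count
            if depth < 1:
                logger.warning(
                    "skipped variant row: %s:%d %s>%s has zero depth",
                    var.CHROM,
                    var.POS,
                    var.REF,
                    alt,
                )
                continue
            records.append(
                VariantRecord(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref_allele=var.REF,
                    alt_allele=alt,
                    gene=str(gene),
                    ref_count=ref_count,
                    alt_count=alt_count,
                    vaf=100.0 * alt_count / depth,
                    germline_flag=germline,
                    fp_flag=fp,
                    sample_id=sample_id,
                    pop_af=None if pop_af is None else float(pop_af),
                )
            )
    return records


def read_variant_table(
    path: str | Path,
    format: str = "tsv",
    vaf_scale: str = "percent",
    sample: Optional[str] = None,
    gene_info_key: str = "GENE",
) -> list[VariantRecord]:
    """Read somatic variants from a TSV table or a VCF.

    Parameters
    ----------
    path:
        Input file.  The TSV dialect has the header columns in
        :data:`TSV_COLUMNS` (``pop_af`` optional).  VCF input must carry a
        per-sample ``AD`` (allelic depth) FORMAT field; multi-allelic rows
        are split into one record per alternative allele.
    format:
        ``"tsv"`` or ``"vcf"``.
    vaf_scale:
        Scale of the ``vaf`` column for TSV input: ``"percent"`` (default)
        or ``"fraction"``.  VCF VAFs are always derived from counts.
    sample:
        Sample name for multi-sample VCFs; defaults to the first sample.
    gene_info_key:
        INFO key holding the gene symbol in VCF input.

    Rows that provide neither a VAF nor read counts (or have zero depth)
    are skipped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
        missing = [c for c in TSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        return _records_from_frame(df, vaf_scale)
    if format == "vcf":
        return _records_from_vcf(path, sample, gene_info_key)
    raise ValueError(f"unknown format {format!r}")


def variants_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Render records as a DataFrame in the TSV dialect's column order."""
    rows = []
    any_pop_af = any(r.pop_af is not None for r in records)
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref_allele,
            "alt": r.alt_allele,
            "gene": r.gene,
            "ref_count": r.ref_count,
            "alt_count": r.alt_count,
            "vaf": r.vaf,
            "germline_flag": r.germline_flag,
            "fp_flag": r.fp_flag,
        }
        if any_pop_af:
            row["pop_af"] = r.pop_af
        rows.append(row)
    cols = TSV_COLUMNS + (["pop_af"] if any_pop_af else [])
    return pd.DataFrame(rows, columns=cols)


def write_variant_table(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write records in the TSV dialect (round-trips with ``read_variant_table``)."""
    df = variants_to_frame(records)
    df.to_csv(path, sep="\t", index=False)


def filter_variants(
    records: Sequence[VariantRecord],
    germline_af_threshold: float = 0.01,
    min_depth: int = 0,
) -> list[VariantRecord]:
    """Apply the variant-level filters used before TH computation.

    Removes records flagged as germline or as upstream false positives,
    records whose population allele frequency exceeds
    ``germline_af_threshold`` (when the annotation is present — a missing
    annotation is a no-op for that criterion), and records with total depth
    below ``min_depth`` (records without counts are kept).  Order is
    preserved and the input is untouched.
    """
    if germline_af_threshold < 0 or min_depth < 0:
        raise ValueError("thresholds must be non-negative")
    kept = []
    for r in records:
        if r.germline_flag or r.fp_flag:
            continue
        if r.pop_af is not None and r.pop_af > germline_af_threshold:
            continue
        if r.depth is not None and r.depth < min_depth:
            continue
        kept.append(r)
    return kept


def extract_vaf_profile(
    records: Sequence[VariantRecord],
    panel: PanelDefinition,
    sample_id: str,
) -> VafProfile:
    """Restrict filtered variants to panel genes and collect their VAFs.

    Returns VAFs in input order.  A profile with zero surviving mutations is
    valid; downstream code decides how to treat it (the TH index is then
    undefined).
    """
    if len(panel) == 0:  # pragma: no cover - PanelDefinition forbids this
        raise ValueError("empty panel")
    vafs: list[float] = []
    genes: list[str] = []
    for r in records:
        if r.gene in panel.genes:
            if r.vaf is None:
                raise ValueError("record without VAF reached extract_vaf_profile")
            vafs.append(r.vaf)
            genes.append(r.gene)
    return VafProfile(sample_id=sample_id, vafs=vafs, panel=panel, genes=genes)
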