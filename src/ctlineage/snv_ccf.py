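"""Somatic variant filtering and cancer-cell-fraction (CCF) computation.

The CCF of a mutation is the fraction of cancer cells in a sample that
carry it, obtained from the variant allele frequency (VAF) by correcting
for tumour purity ``p`` and the local total copy number ``CNt``::

    CCF = VAF * (p * CNt + 2 * (1 - p)) / (p * m)

with ``m`` the number of mutated alleles (multiplicity), fixed at 1 to
avoid overcalling subclonality.  At ``p = 1, CNt = 2, m = 1`` this
reduces to ``CCF = 2 * VAF``.

Two filter stages are implemented:

* :func:`filter_somatic_calls` — call-level reliability: read depth
  strictly greater than 10 in tumour and matched normal, at least three
  variant reads in at least one tumour sample, genotype ``0/0`` in the
  normal but not in every tumour, and the highest tumour VAF at least
  ten times the normal VAF.
* :func:`filter_for_subclonal_analysis` — region-level strictness for
  subclonal reconstruction: clonal diploid copy-number state, mean
  mappability of exactly 1 in the ±25 bp window around the variant, no
  overlap with simple repeats / low-complexity regions, and
  CCF >= 0.2 in two or more samples (mutations subclonal in one sample
  and clonal/subclonal in another are the ones informative about the
  metastatic cascade, as opposed to private subclones).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class AnnotationError(KeyError):
    """A required per-variant annotation is missing."""


@dataclass
class SampleCall:
    """Per-sample evidence for one variant."""

    depth: int
    alt_count: int
    genotype: str = "./."

    def __post_init__(self) -> None:
        if self.alt_count > self.depth:
            raise ValueError("alt count cannot exceed depth")

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth > 0 else 0.0


@dataclass
class VariantRecord:
    """A somatic variant with per-sample calls and region annotations.

    ``mappability`` is the mean uniqueness score over ±25 bp around the
    position; ``in_repeat`` flags overlap with simple repeats or
    low-complexity regions; ``cn_total``/``cn_clonal`` describe the local
    copy-number state.  Caller filter flags are carried as opaque
    strings.
    """

    chromosome: str
    position: int
    ref: str
    alt: str
    samples: dict[str, SampleCall]
    flags: tuple[str, ...] = ("PASS",)
    mappability: float | None = None
    in_repeat: bool | None = None
    cn_total: float | None = None
    cn_clonal: bool | None = None
    info: dict = field(default_factory=dict)

    @property
    def key(self) -> str:
        return f"{self.chromosome}:{self.position}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class SamplePurity:
    """Tumour purity and ploidy of one sample (consumed, not estimated)."""

    sample_id: str
    purity: float
    ploidy: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must be in (0, 1]")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")


# ---------------------------------------------------------------------------
# call-level filtering

def filter_somatic_calls(records: Sequence[VariantRecord], normal_id: str,
                         tumour_ids: Sequence[str] | None = None,
                         min_depth: int = 10, min_alt: int = 3,
                         vaf_ratio: float = 10.0,
                         allowed_flags: Iterable[str] | None = None
                         ) -> tuple[list[VariantRecord], Counter]:
    """Apply call-level reliability filters; returns (kept, drop tally).

    A record survives when all of the following hold (each record is
    tallied under the first rule it fails):

    * every caller flag is in ``allowed_flags`` (when a whitelist is
      given);
    * read depth strictly greater than ``min_depth`` in the normal and in
      at least one tumour sample which also shows >= ``min_alt`` variant
      reads;
    * the normal genotype is ``0/0`` and at least one tumour genotype is
      not;
    * the highest tumour VAF is at least ``vaf_ratio`` times the normal
      VAF.
    """
    if not records:
        return [], Counter()
    if normal_id not in records[0].samples:
        raise ValueError(f"matched normal {normal_id!r} missing from records")
    allowed = set(allowed_flags) if allowed_flags is not None else None
    kept: list[VariantRecord] = []
    dropped: Counter = Counter()
    for rec in records:
        if normal_id not in rec.samples:
            raise ValueError(
                f"matched normal {normal_id!r} missing from {rec.key}")
        t_ids = (list(tumour_ids) if tumour_ids is not None
                 else [s for s in rec.samples if s != normal_id])
        normal = rec.samples[normal_id]
        tumours = [rec.samples[s] for s in t_ids]
        if allowed is not None and any(f not in allowed for f in rec.flags):
            dropped["caller_flag"] += 1
            continue
        if normal.depth <= min_depth or not any(
                t.depth > min_depth and t.alt_count >= min_alt
                for t in tumours):
            dropped["depth_alt"] += 1
            continue
        if normal.genotype != "0/0" or all(
                t.genotype == "0/0" for t in tumours):
            dropped["genotype"] += 1
            continue
        max_vaf = max(t.vaf for t in tumours)
        if max_vaf < vaf_ratio * normal.vaf:
            dropped["vaf_ratio"] += 1
            continue
        kept.append(rec)
    return kept, dropped


# ---------------------------------------------------------------------------
# region-level filtering for subclonal reconstruction

def filter_for_subclonal_analysis(records: Sequence[VariantRecord],
                                  ccf: pd.DataFrame | None = None,
                                  require_clonal_diploid: bool = True,
                                  min_mappability: float = 1.0,
                                  exclude_repeats: bool = True,
                                  min_ccf: float = 0.2,
                                  min_samples_at_ccf: int = 2
                                  ) -> list[VariantRecord]:
    """Region-level strict filters ahead of subclonal reconstruction.

    The four rules (each individually toggleable) are combined as a
    conjunction; their order does not matter.  ``ccf`` is a mutation-key ×
    sample CCF matrix used for the "CCF >= ``min_ccf`` in >=
    ``min_samples_at_ccf`` samples" rule (skipped when None and
    ``min_samples_at_ccf`` is 0).

    Raises :class:`AnnotationError` naming the first missing annotation.
    """
    out = []
    for rec in records:
        if require_clonal_diploid:
            if rec.cn_total is None or rec.cn_clonal is None:
                raise AnnotationError(
                    f"{rec.key}: missing cn_total/cn_clonal annotation")
            if not (rec.cn_clonal and rec.cn_total == 2):
                continue
        if min_mappability is not None:
            if rec.mappability is None:
                raise AnnotationError(
                    f"{rec.key}: missing mappability annotation")
            if rec.mappability < min_mappability:
                continue
        if exclude_repeats:
            if rec.in_repeat is None:
                raise AnnotationError(
                    f"{rec.key}: missing in_repeat annotation")
            if rec.in_repeat:
                continue
        if min_samples_at_ccf > 0:
            if ccf is None:
                raise AnnotationError("CCF matrix required for the "
                                      "min-samples-at-CCF rule")
            if rec.key not in ccf.index:
                raise AnnotationError(f"{rec.key}: missing from CCF matrix")
            n_at = int((ccf.loc[rec.key] >= min_ccf).sum())
            if n_at < min_samples_at_ccf:
                continue
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# CCF

def compute_ccf(vaf, purity, cn_total, multiplicity: int = 1):
    """CCF from VAF, purity and local total copy number.

    ``CCF = VAF * (p * CNt + 2 * (1 - p)) / (p * m)``; values are
    returned uncapped (use :func:`cap_ccf` for the capped-at-1 view).
    Accepts scalars or numpy arrays.
    """
    vaf = np.asarray(vaf, dtype=float)
    p = np.asarray(purity, dtype=float)
    cnt = np.asarray(cn_total, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("purity must be in (0, 1]")
    if np.any(cnt < 0):
        raise ValueError("total copy number must be >= 0")
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    out = vaf * (p * cnt + 2.0 * (1.0 - p)) / (p * multiplicity)
    return float(out) if out.ndim == 0 else out


def cap_ccf(ccf):
    """Capped-at-1 view of a CCF value/array/DataFrame."""
    if isinstance(ccf, pd.DataFrame):
        return ccf.clip(upper=1.0)
    return np.minimum(np.asarray(ccf, dtype=float), 1.0)


def ccf_matrix(records: Sequence[VariantRecord],
               purities: Mapping[str, SamplePurity],
               sample_ids: Sequence[str] | None = None,
               multiplicity: int = 1) -> pd.DataFrame:
    """Mutation-key × sample CCF matrix from per-sample VAFs.

    Per-record local total copy number is taken from ``cn_total``
    (default 2 when unannotated).
    """
    if sample_ids is None:
        sample_ids = list(purities)
    rows = {}
    for rec in records:
        cnt = rec.cn_total if rec.cn_total is not None else 2.0
        rows[rec.key] = {
            s: compute_ccf(rec.samples[s].vaf, purities[s].purity, cnt,
                           multiplicity)
            for s in sample_ids if s in rec.samples}
    return pd.DataFrame.from_dict(rows, orient="index")[list(sample_ids)]


def max_cluster_count(n_tumour_samples: int) -> int:
    """Maximum number of mutation clusters to allow: ``2n - 1``.

    This is the number of non-private edges in a clone tree with twice as
    many clones as tumour samples, i.e. the largest number of shared
    clusters such a tree could expose.
    """
    if n_tumour_samples < 1:
        raise ValueError("need at least one tumour sample")
    return 2 * n_tumour_samples - 1


# ---------------------------------------------------------------------------
# input readers

def read_variants_tsv(path, sample_ids: Sequence[str],
                      normal_id: str | None = None) -> list[VariantRecord]:
    """Flat TSV reader: one row per variant with per-sample
    ``<sample>_depth`` / ``<sample>_alt`` / ``<sample>_gt`` columns and
    optional ``mappability``, ``in_repeat``, ``cn_total``, ``cn_clonal``,
    ``flags`` columns."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    out = []
    for _, row in df.iterrows():
        samples = {}
        for s in sample_ids:
            samples[s] = SampleCall(
                depth=int(row[f"{s}_depth"]),
                alt_count=int(row[f"{s}_alt"]),
                genotype=str(row.get(f"{s}_gt", "./.")))
        rec = VariantRecord(
            chromosome=str(row["chromosome"]), position=int(row["position"]),
            ref=str(row["ref"]), alt=str(row["alt"]), samples=samples,
            flags=tuple(str(row["flags"]).split(";"))
            if "flags" in row and pd.notna(row["flags"]) else ("PASS",),
            mappability=float(row["mappability"])
            if "mappability" in row and pd.notna(row["mappability"]) else None,
            in_repeat=bool(row["in_repeat"])
            if "in_repeat" in row and pd.notna(row["in_repeat"]) else None,
            cn_total=float(row["cn_total"])
            if "cn_total" in row and pd.notna(row["cn_total"]) else None,
            cn_clonal=bool(row["cn_clonal"])
            if "cn_clonal" in row and pd.notna(row["cn_clonal"]) else None)
        out.append(rec)
    return out


def read_variants_vcf(path, normal_id: str | None = None
                      ) -> list[VariantRecord]:
    """Multi-sample VCF reader (cyvcf2); FORMAT must carry per-sample
    depth (DP/AD) and genotypes.  Annotations are taken from INFO keys
    ``MAPPABILITY``, ``REPEAT``, ``CNT``, ``CN_CLONAL`` when present."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    out = []
    for var in vcf:
        depths = var.format("DP")
        ad = var.format("AD")
        gts = var.gt_types  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        samples = {}
        for i, s in enumerate(sample_ids):
            depth = int(depths[i][0]) if depths is not None else 0
            alt = int(ad[i][1]) if ad is not None and ad.shape[1] > 1 else 0
            gt = {0: "0/0", 1: "0/1", 2: "1/1"}.get(int(gts[i]), "./.")
            samples[s] = SampleCall(depth=max(depth, alt), alt_count=alt,
                                    genotype=gt)
        info = dict(var.INFO)
        out.append(VariantRecord(
            chromosome=var.CHROM, position=var.POS, ref=var.REF,
            alt=var.ALT[0] if var.ALT else ".", samples=samples,
            flags=tuple((var.FILTER or "PASS").split(";")),
            mappability=info.get("MAPPABILITY"),
            in_repeat=bool(info["REPEAT"]) if "REPEAT" in info else None,
            cn_total=info.get("CNT"),
            cn_clonal=bool(info["CN_CLONAL"]) if "CN_CLONAL" in info
            else None,
            info=info))
    return out
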