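"""Methylation-clock haplotype extraction and filtering.

A *methylation clock* is a CpG island whose methylation drifts steadily
with cell division, so that the binary methylated/unmethylated pattern
across the CpGs of one sequenced molecule — the methylation *haplotype*,
a "barcode" of zeros and ones — carries lineage information about the
cell the molecule came from.

This module turns per-read CpG calls from targeted bisulfite sequencing
(e.g. Bismark methylation-extractor output) into haplotype count tables
and applies the analysis filter cascade:

1. per-CpG coverage: a site is used only if its total number of calls
   (methylated + unmethylated) is at least ``min_site_calls`` (default
   1000);
2. completeness: reads missing a call at any retained site are removed,
   leaving only complete reads;
3. informativeness: reads must have at least one methylated CpG (removes
   molecules from low-turnover normal cells) and at most 80% methylation
   (removes saturated, uninformative clocks);
4. rarity (for genealogy building only): haplotypes with an overall
   abundance of 1% or less are removed.

Coordinates are 1-based and refer to the forward-strand cytosine of each
CpG; calls from the bottom strand (the reverse-complement cytosine at
position + 1) are collapsed onto the same CpG.
"""

from __future__ import annotations

import gzip
import io
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

#: per-CpG call codes
METHYLATED = 1
UNMETHYLATED = 0
MISSING = -1

_CALL_CODE = {"M": METHYLATED, "U": UNMETHYLATED,
              "Z": METHYLATED, "z": UNMETHYLATED}


class ClockFileError(ValueError):
    """A per-read call file could not be parsed."""


class EmptyTableError(ValueError):
    """An operation required a non-empty haplotype table."""


@dataclass(frozen=True)
class ClockLocus:
    """A clock CpG island: an ordered set of CpG coordinates.

    Parameters
    ----------
    name : str
        Locus identifier, e.g. ``"IRX2"`` (a 201-bp locus with 9 CpGs) or
        ``"ZNF454"`` (16 CpGs).
    chromosome : str
    cpg_positions : tuple of int
        1-based forward-strand coordinates of the CpG cytosines, strictly
        increasing, at least two.
    """

    name: str
    chromosome: str
    cpg_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = tuple(int(p) for p in self.cpg_positions)
        object.__setattr__(self, "cpg_positions", pos)
        if len(pos) < 2:
            raise ValueError("a clock locus needs at least 2 CpGs")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("cpg_positions must be strictly increasing")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)


@dataclass
class ReadCallSet:
    """Per-read ternary CpG calls at one locus.

    ``calls`` holds one slot per CpG of the locus, coded
    ``1`` = methylated, ``0`` = unmethylated, ``-1`` = missing.
    """

    read_id: str
    locus: ClockLocus
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (self.locus.n_cpgs,):
            raise ValueError("one call slot per CpG of the locus required")
        if not np.isin(self.calls, (-1, 0, 1)).all():
            raise ValueError("calls must be in {-1, 0, 1}")
        if (self.calls == MISSING).all():
            raise ValueError("a read needs at least one non-missing call")

    @property
    def n_called(self) -> int:
        return int((self.calls != MISSING).sum())


@dataclass
class HaplotypeTable:
    """Counts of binary methylation haplotypes for one sample × locus.

    ``site_positions`` records the (possibly coverage-reduced) CpG
    coordinates the haplotype strings index — the *effective* locus
    length; all per-haplotype fractions downstream use this length, not
    the locus's nominal CpG count.
    """

    sample_id: str
    locus: ClockLocus
    counts: dict[str, int]
    site_positions: tuple[int, ...]
    filters: tuple[str, ...] = ()
    status: str = "ok"
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        L = len(self.site_positions)
        for bits, n in self.counts.items():
            if len(bits) != L or set(bits) - {"0", "1"}:
                raise ValueError(f"bad haplotype {bits!r} for {L} sites")
            if n < 0:
                raise ValueError("haplotype counts must be non-negative")

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def frequencies(self) -> dict[str, float]:
        return haplotype_frequencies(self)


# ---------------------------------------------------------------------------
# parsing

def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def parse_read_calls(path, locus: ClockLocus, *, fmt: str = "simple",
                     sample_id: str | None = None) -> list[ReadCallSet]:
    """Parse a per-read CpG call file into one :class:`ReadCallSet` per read.

    Two tab-separated formats are supported (gzip transparently handled):

    ``simple``
        columns ``read_id  sample_id  locus  position  call`` with call in
        ``{M, U}``; rows for other loci (or other samples, when
        ``sample_id`` is given) are skipped.
    ``bismark``
        Bismark methylation-extractor CpG output: ``read_id  strand
        chromosome  position  call`` with call ``Z`` (methylated) / ``z``
        (unmethylated); rows on other chromosomes are skipped.

    Positions not matching a CpG of ``locus`` are ignored.  Calls on the
    bottom strand (position = CpG position + 1) are collapsed onto the
    CpG's forward-strand coordinate; a read carrying conflicting duplicate
    calls at one CpG is dropped with a logged warning.

    Raises
    ------
    ClockFileError
        On a malformed line (the message names the line number).
    """
    if fmt not in ("simple", "bismark"):
        raise ValueError(f"unknown format {fmt!r}")
    pos_index: dict[int, int] = {}
    for i, p in enumerate(locus.cpg_positions):
        pos_index[p] = i          # top-strand C
        pos_index[p + 1] = i      # bottom-strand C of the same CpG
    per_read: dict[str, dict[int, int]] = {}
    conflicted: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ClockFileError(
                    f"line {lineno}: expected 5 tab-separated fields, "
                    f"got {len(parts)}")
            if fmt == "simple":
                read_id, rec_sample, rec_locus, pos_s, call_s = parts[:5]
                if rec_locus != locus.name:
                    continue
                if sample_id is not None and rec_sample != sample_id:
                    continue
            else:
                read_id, _strand, chrom, pos_s, call_s = parts[:5]
                if chrom != locus.chromosome:
                    continue
            try:
                pos = int(pos_s)
            except ValueError:
                raise ClockFileError(
                    f"line {lineno}: position {pos_s!r} is not an integer"
                ) from None
            if call_s not in _CALL_CODE:
                raise ClockFileError(
                    f"line {lineno}: call {call_s!r} not one of M/U/Z/z")
            idx = pos_index.get(pos)
            if idx is None:
                continue
            calls = per_read.setdefault(read_id, {})
            code = _CALL_CODE[call_s]
            if idx in calls and calls[idx] != code:
                conflicted.add(read_id)
            else:
                calls[idx] = code
    out: list[ReadCallSet] = []
    for rid in per_read:  # dict preserves first-seen order
        if rid in conflicted:
            logger.warning(
                "read %s dropped: conflicting duplicate call at a CpG", rid)
            continue
        calls = np.full(locus.n_cpgs, MISSING, dtype=np.int8)
        for idx, code in per_read[rid].items():
            calls[idx] = code
        out.append(ReadCallSet(read_id=rid, locus=locus, calls=calls))
    return out


def write_read_calls(reads: Iterable[ReadCallSet], path, *,
                     sample_id: str = "sample") -> None:
    """Write reads in the ``simple`` five-column format (round-trips with
    :func:`parse_read_calls`)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for r in reads:
            for idx, code in enumerate(r.calls):
                if code == MISSING:
                    continue
                call = "M" if code == METHYLATED else "U"
                pos = r.locus.cpg_positions[idx]
                fh.write(f"{r.read_id}\t{sample_id}\t{r.locus.name}"
                         f"\t{pos}\t{call}\n")


# ---------------------------------------------------------------------------
# assembly and filtering

def assemble_haplotypes(reads: Iterable[ReadCallSet], *,
                        min_site_calls: int = 1000,
                        sample_id: str = "sample") -> HaplotypeTable:
    """Assemble complete-read haplotypes over sufficiently covered CpGs.

    A CpG is retained when its total calls (methylated + unmethylated)
    are >= ``min_site_calls``; reads missing a call at any retained site
    are discarded, and the remaining complete reads become haplotypes
    over the retained sites.  When no site passes coverage the returned
    table is empty with ``status == "no_sites_pass_coverage"``.
    """
    reads = list(reads)
    if not reads:
        return HaplotypeTable(sample_id=sample_id,
                              locus=ClockLocus("empty", ".", (1, 3)),
                              counts={}, site_positions=(),
                              status="no_sites_pass_coverage",
                              stats={"n_input": 0, "n_complete": 0,
                                     "n_dropped_missing": 0})
    locus = reads[0].locus
    if any(r.locus is not locus and r.locus != locus for r in reads):
        raise ValueError("all reads must come from one locus")
    calls = np.stack([r.calls for r in reads])            # (n_reads, L)
    site_totals = (calls != MISSING).sum(axis=0)
    keep_sites = np.flatnonzero(site_totals >= min_site_calls)
    stats = {"n_input": len(reads),
             "site_totals": site_totals.tolist()}
    if keep_sites.size == 0:
        stats.update(n_complete=0, n_dropped_missing=len(reads))
        return HaplotypeTable(sample_id=sample_id, locus=locus, counts={},
                              site_positions=(),
                              status="no_sites_pass_coverage", stats=stats)
    sub = calls[:, keep_sites]
    complete = (sub != MISSING).all(axis=1)
    stats.update(n_complete=int(complete.sum()),
                 n_dropped_missing=int((~complete).sum()))
    counts = Counter(
        "".join("1" if c == METHYLATED else "0" for c in row)
        for row in sub[complete])
    positions = tuple(locus.cpg_positions[i] for i in keep_sites)
    return HaplotypeTable(sample_id=sample_id, locus=locus,
                          counts=dict(counts), site_positions=positions,
                          filters=("coverage", "complete"), stats=stats)


def _meth_fraction(bits: str) -> float:
    return bits.count("1") / len(bits)


def filter_haplotypes(table: HaplotypeTable, *, min_methylated: int = 1,
                      max_meth_fraction: float = 0.8,
                      rare_threshold: float = 0.01,
                      apply_rare: bool = False,
                      meth_comparator: str = "le") -> HaplotypeTable:
    """Apply the informativeness (and optionally rarity) filters.

    Haplotypes with fewer than ``min_methylated`` methylated CpGs are
    removed (molecules likely from normal, low-turnover cells), as are
    haplotypes whose methylated fraction exceeds ``max_meth_fraction``
    (saturated clocks).  The boundary is kept: a haplotype at exactly 80%
    methylation survives under the default ``meth_comparator="le"``; pass
    ``"lt"`` for a strict cut.

    With ``apply_rare`` (used for genealogy building), haplotypes whose
    frequency — computed on the post-methylation-filter total — is
    ``<= rare_threshold`` are removed; a haplotype at exactly 1% is
    removed ("1% or less").
    """
    if meth_comparator not in ("le", "lt"):
        raise ValueError("meth_comparator must be 'le' or 'lt'")
    kept = {}
    for bits, n in table.counts.items():
        n_meth = bits.count("1")
        if n_meth < min_methylated:
            continue
        frac = n_meth / len(bits)
        if meth_comparator == "le":
            if frac > max_meth_fraction:
                continue
        else:
            if frac >= max_meth_fraction:
                continue
        kept[bits] = n
    applied = table.filters + ("methylation",)
    if apply_rare:
        total = sum(kept.values())
        if total > 0:
            kept = {b: n for b, n in kept.items()
                    if n / total > rare_threshold}
        applied = applied + ("rarity",)
    return replace(table, counts=kept, filters=applied)


def haplotype_frequencies(table: HaplotypeTable) -> dict[str, float]:
    """Haplotype relative frequencies, keys in lexicographic order.

    Raises :class:`EmptyTableError` when the table holds no reads.
    """
    total = table.total
    if total == 0:
        raise EmptyTableError(
            f"no haplotypes in table for sample {table.sample_id!r}")
    return {bits: table.counts[bits] / total
            for bits in sorted(table.counts)}


def flag_hypermethylation(table: HaplotypeTable, *,
                          frac_threshold: float = 0.5,
                          meth_fraction_cut: float = 0.8
                          ) -> tuple[bool, float]:
    """Flag a clock that has drifted to saturation.

    Returns ``(flagged, fraction)`` where ``fraction`` is the proportion
    of complete reads whose methylated fraction exceeds
    ``meth_fraction_cut``; ``flagged`` is true when that proportion
    exceeds ``frac_threshold``.  A saturated clock is uninformative for
    lineage tracing; the read-fraction criterion here is a documented
    heuristic and the raw fraction is always reported so callers can
    apply their own cut.
    """
    total = table.total
    if total == 0:
        return False, 0.0
    n_hyper = sum(n for bits, n in table.counts.items()
                  if _meth_fraction(bits) > meth_fraction_cut)
    frac = n_hyper / total
    return frac > frac_threshold, frac


# ---------------------------------------------------------------------------
# table I/O

def write_haplotype_tables(tables: Iterable[HaplotypeTable], path) -> None:
    """Write tables as TSV: sample_id, locus, bits, count, frequency."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("sample_id\tlocus\tbits\tcount\tfrequency\n")
        for t in tables:
            total = t.total
            for bits in sorted(t.counts):
                n = t.counts[bits]
                freq = n / total if total else 0.0
                fh.write(f"{t.sample_id}\t{t.locus.name}\t{bits}\t{n}"
                         f"\t{freq:.10g}\n")


def read_haplotype_tables(path, loci: Mapping[str, ClockLocus] | None = None
                          ) -> list[HaplotypeTable]:
    """Read tables written by :func:`write_haplotype_tables`.

    When ``loci`` does not provide the locus, a placeholder locus with
    unit-spaced coordinates is reconstructed (positions are not stored in
    the TSV).
    """
    groups: dict[tuple[str, str], dict[str, int]] = {}
    with _open_text(path) as fh:
        header = fh.readline()
        if not header.startswith("sample_id"):
            raise ClockFileError("line 1: missing header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ClockFileError(f"line {lineno}: expected >= 4 fields")
            sample, locus_name, bits, count = parts[:4]
            groups.setdefault((sample, locus_name), {})[bits] = int(count)
    out = []
    for (sample, locus_name), counts in groups.items():
        L = len(next(iter(counts)))
        locus = (loci or {}).get(locus_name) or ClockLocus(
            locus_name, ".", tuple(2 * i + 1 for i in range(max(L, 2))))
        positions = locus.cpg_positions[:L]
        out.append(HaplotypeTable(sample_id=sample, locus=locus,
                                  counts=counts, site_positions=positions))
    return out
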