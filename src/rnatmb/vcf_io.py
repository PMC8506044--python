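"""Reading, writing, merging and intersecting Mutect2-dialect VCF callsets.

The in-memory model is deliberately small: a :class:`VariantRecord` keeps the
coordinate key, the caller's FILTER labels, a flattened map of numeric caller
fields (TLOD, ECNT, SA_MAP_AF_1/2, ...), the sample AD pair, and the
population-frequency / dbSNP annotations that downstream germline filters
consume.  Multiallelic sites never survive ingestion: records with a comma in
ALT are dropped, and so are groups of biallelic lines that share
(chrom, pos, ref) — both encodings of a tri-allelic site are treated alike.

Coordinates are 1-based (VCF convention) everywhere inside the package; BED
input is converted once at the boundary by :func:`read_regions`.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pysam

logger = logging.getLogger(__name__)

SOURCE_TAGS = ("rnaseq_tumor_only", "wes_matched", "wes_tumor_only")

#: canonical chromosome ordering chr1..chr22, chrX, chrY
CHROMOSOMES = tuple(f"chr{i}" for i in list(range(1, 23)) + ["X", "Y"])
_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}

ANNOT_EXAC_NONTCGA = "ExAC_nontcga_ALL"
ANNOT_EXAC_ALL = "ExAC_ALL"
ANNOT_DBSNP = "dbSNP150_ID"

# INFO fields carried as single numbers
_INFO_SCALARS = ("TLOD", "ECNT", "POPAF", "GERMQ", "MBQ", "MMQ", "MPOS", "NLOD", "SEQQ")
# INFO fields carried as pairs, with the suffixes used in the feature registry
_INFO_PAIRS = {
    "MFRL": ("MFRL_ref", "MFRL_alt"),
    "SA_MAP_AF": ("SA_MAP_AF_1", "SA_MAP_AF_2"),
    "SA_POST_PROB": ("SA_POST_PROB_1", "SA_POST_PROB_2"),
}
_FORMAT_PAIRS = {"F1R2": ("F1R2_ref", "F1R2_alt"), "F2R1": ("F2R1_ref", "F2R1_alt")}


class VcfFormatError(ValueError):
    """Malformed VCF/BED input; the message names the offending file/line."""


class ContractError(ValueError):
    """A precondition of an operation was violated."""


def normalize_chrom(chrom: str) -> str:
    """Unify ``1`` and ``chr1`` style names to the ``chr``-prefixed form."""
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


def _chrom_rank(chrom: str):
    return (_CHROM_RANK.get(chrom, len(_CHROM_RANK)), chrom)


@dataclass
class VariantRecord:
    """One biallelic called variant with caller fields and annotations."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    rsid: str | None = None
    filter_labels: frozenset[str] = frozenset()  # empty set <=> PASS
    caller_info: dict[str, float] = field(default_factory=dict)
    ad_ref: int | None = None
    ad_alt: int | None = None
    annotations: dict[str, object] = field(default_factory=dict)
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ContractError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ContractError("ref and alt must be nonempty")
        if any(b not in "ACGTN" for b in self.ref + self.alt):
            raise ContractError(f"alleles must be A/C/G/T/N: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ContractError("alt must differ from ref")
        for ad in (self.ad_ref, self.ad_alt):
            if ad is not None and ad < 0:
                raise ContractError("AD values must be >= 0")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def coord(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def is_pass(self) -> bool:
        return not self.filter_labels

    @property
    def exac_nontcga_all(self) -> float | None:
        return self.annotations.get(ANNOT_EXAC_NONTCGA)

    @property
    def exac_all(self) -> float | None:
        return self.annotations.get(ANNOT_EXAC_ALL)

    @property
    def in_dbsnp(self) -> bool:
        """dbSNP membership via either the ID column or the annotation field."""
        if self.rsid is not None and self.rsid.startswith("rs"):
            return True
        return self.annotations.get(ANNOT_DBSNP) is not None

    def sort_key(self):
        return (*_chrom_rank(self.chrom), self.pos, self.ref, self.alt, self.sample_id)


@dataclass
class Callset:
    """A sample's (or pooled) ordered variant collection with provenance."""

    sample_id: str
    source: str
    variants: list[VariantRecord] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)
    multiallelic_excluded: int = 0

    def __post_init__(self) -> None:
        if self.source not in SOURCE_TAGS:
            raise ContractError(
                f"unknown source tag {self.source!r}; expected one of {SOURCE_TAGS}"
            )

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.variants)

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {v.key for v in self.variants}

    def coords(self) -> set[tuple[str, int]]:
        return {v.coord for v in self.variants}

    def with_variants(self, variants: Sequence[VariantRecord], step: str) -> "Callset":
        """New callset with ``variants`` and ``step`` appended to provenance."""
        return Callset(
            sample_id=self.sample_id,
            source=self.source,
            variants=list(variants),
            provenance=[*self.provenance, step],
            multiallelic_excluded=self.multiallelic_excluded,
        )


@dataclass
class RegionSet:
    """Non-overlapping genomic intervals, 0-based half-open, defining the
    TMB denominator."""

    intervals: list[tuple[str, int, int]]
    _starts: dict[str, list[int]] = field(init=False, repr=False)
    _ends: dict[str, list[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.intervals = _merge_intervals(self.intervals)
        self._starts, self._ends = {}, {}
        for chrom, start, end in self.intervals:
            self._starts.setdefault(chrom, []).append(start)
            self._ends.setdefault(chrom, []).append(end)

    @property
    def total_bases(self) -> int:
        return sum(end - start for _, start, end in self.intervals)

    @property
    def total_megabases(self) -> float:
        return self.total_bases / 1e6

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect_right(starts, pos - 1) - 1
        return i >= 0 and pos - 1 < self._ends[chrom][i]

    def __len__(self) -> int:
        return len(self.intervals)


def _merge_intervals(
    intervals: Iterable[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    ordered = sorted(intervals, key=lambda iv: (_chrom_rank(iv[0]), iv[1], iv[2]))
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in ordered:
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            merged.append((chrom, start, end))
    return merged


# ---------------------------------------------------------------------------
# VCF ingestion


def _as_float(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        value = value[0] if value else None
    if isinstance(value, bytes):
        value = value.decode()
    if isinstance(value, str):
        if value in (".", ""):
            return None
        try:
            return float(value)
        except ValueError:
            return None
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def _pair(value) -> tuple[float | None, float | None]:
    """Map a 2- or 3-element caller list onto the (artifact, no-artifact) pair.

    Three-element strand-artifact lists are (forward-artifact, reverse-artifact,
    no-artifact); the registry keeps the last two.
    """
    if value is None:
        return (None, None)
    if not isinstance(value, (tuple, list)):
        return (_as_float(value), None)
    vals = list(value)
    if len(vals) >= 3:
        vals = vals[-2:]
    if len(vals) == 1:
        vals = [vals[0], None]
    return (_as_float(vals[0]), _as_float(vals[1]))


def _parse_record(rec, sample_name: str, source: str) -> VariantRecord:
    info = rec.info
    caller_info: dict[str, float] = {}
    for key in _INFO_SCALARS:
        if key in info:
            val = _as_float(info.get(key))
            if val is not None:
                caller_info[key] = val
    for key, (name_a, name_b) in _INFO_PAIRS.items():
        if key in info:
            a, b = _pair(info.get(key))
            if a is not None:
                caller_info[name_a] = a
            if b is not None:
                caller_info[name_b] = b

    ad_ref = ad_alt = None
    sample = rec.samples[sample_name]
    ad = sample.get("AD")
    if ad is not None and ad[0] is not None:
        ad_ref, ad_alt = int(ad[0]), int(ad[1]) if len(ad) > 1 and ad[1] is not None else 0
        caller_info["AD_ref"], caller_info["AD_alt"] = float(ad_ref), float(ad_alt)
    af = _as_float(sample.get("AF"))
    if af is not None:
        caller_info["AF"] = af
    dp = _as_float(sample.get("DP"))
    if dp is not None:
        caller_info["DP"] = dp
    for key, (name_a, name_b) in _FORMAT_PAIRS.items():
        val = sample.get(key)
        if val is not None:
            a, b = _pair(val)
            if a is not None:
                caller_info[name_a] = a
            if b is not None:
                caller_info[name_b] = b

    annotations: dict[str, object] = {}
    for key in (ANNOT_EXAC_NONTCGA, ANNOT_EXAC_ALL):
        if key in info:
            val = _as_float(info.get(key))
            if val is not None:
                annotations[key] = val
    if ANNOT_DBSNP in info:
        raw = info.get(ANNOT_DBSNP)
        if isinstance(raw, (tuple, list)):
            raw = raw[0] if raw else None
        if isinstance(raw, bytes):
            raw = raw.decode()
        if raw not in (None, "", "."):
            annotations[ANNOT_DBSNP] = str(raw)

    filters = frozenset(f for f in rec.filter.keys() if f != "PASS")
    rsid = rec.id if rec.id not in (None, ".") else None
    return VariantRecord(
        chrom=normalize_chrom(rec.chrom),
        pos=rec.pos,
        ref=rec.ref.upper(),
        alt=rec.alts[0].upper(),
        rsid=rsid,
        filter_labels=filters,
        caller_info=caller_info,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
        annotations=annotations,
        sample_id=sample_name,
    )


def read_callset(path: str | Path, source: str, sample_id: str | None = None) -> Callset:
    """Read a single-sample Mutect2-dialect VCF into a :class:`Callset`.

    Multiallelic records (comma in ALT, or several biallelic lines sharing
    chrom/pos/ref) are excluded and counted in ``multiallelic_excluded``.
    Missing INFO/annotation fields are left absent, never coerced to zero.
    """
    if source not in SOURCE_TAGS:
        raise ContractError(f"unknown source tag {source!r}")
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise VcfFormatError(f"{path}: VCF has zero sample columns")
        sample_name = samples[0]
        raw: list = []
        n_multi = 0
        for rec in vcf:
            if rec.alts is None or len(rec.alts) == 0:
                continue
            if len(rec.alts) > 1:
                n_multi += 1
                continue
            raw.append(rec)
        # biallelic lines that share a site are one multiallelic site in disguise
        site_counts: dict[tuple[str, int, str], int] = {}
        for rec in raw:
            site = (normalize_chrom(rec.chrom), rec.pos, rec.ref.upper())
            site_counts[site] = site_counts.get(site, 0) + 1
        variants = []
        for rec in raw:
            site = (normalize_chrom(rec.chrom), rec.pos, rec.ref.upper())
            if site_counts[site] > 1:
                n_multi += 1
                continue
            variants.append(_parse_record(rec, sample_name, source))
    sid = sample_id or sample_name
    for v in variants:
        v.sample_id = sid
    variants.sort(key=VariantRecord.sort_key)
    return Callset(
        sample_id=sid,
        source=source,
        variants=variants,
        provenance=[f"read_callset:{path.name}"],
        multiallelic_excluded=n_multi,
    )


# ---------------------------------------------------------------------------
# VCF output

_FILTER_DEFS = (
    ("germline_risk", "Evidence indicates this site is germline, not somatic"),
    ("panel_of_normals", "Blacklisted site in panel of normals"),
    ("germline", "Evidence indicates this site is germline, not somatic"),
    ("base_qual", "Alt median base quality below threshold"),
    ("weak_evidence", "Mutation does not meet likelihood threshold"),
    ("map_qual", "Alt median mapping quality below threshold"),
)

_HEADER_LINES = (
    '##INFO=<ID=TLOD,Number=1,Type=Float,Description="Log odds that the variant is present in the tumor relative to expected noise">',
    '##INFO=<ID=NLOD,Number=1,Type=Float,Description="Normal log odds of being reference">',
    '##INFO=<ID=ECNT,Number=1,Type=Integer,Description="Number of events in this haplotype">',
    '##INFO=<ID=POPAF,Number=1,Type=Float,Description="Negative log10 population allele frequency">',
    '##INFO=<ID=GERMQ,Number=1,Type=Integer,Description="Phred-scaled quality that alt alleles are not germline">',
    '##INFO=<ID=SEQQ,Number=1,Type=Integer,Description="Phred-scaled quality that alt alleles are not sequencing errors">',
    '##INFO=<ID=MBQ,Number=1,Type=Float,Description="Median base quality of alt reads">',
    '##INFO=<ID=MMQ,Number=1,Type=Float,Description="Median mapping quality of alt reads">',
    '##INFO=<ID=MPOS,Number=1,Type=Float,Description="Median distance of alt from end of read">',
    '##INFO=<ID=MFRL,Number=2,Type=Float,Description="Median fragment length of ref and alt reads">',
    '##INFO=<ID=SA_MAP_AF,Number=2,Type=Float,Description="MAP allele fraction given a reverse-strand artifact and given no artifact">',
    '##INFO=<ID=SA_POST_PROB,Number=2,Type=Float,Description="Posterior probability of a reverse-strand artifact and of no artifact">',
    f'##INFO=<ID={ANNOT_EXAC_NONTCGA},Number=1,Type=Float,Description="Allele frequency in ExAC excluding TCGA participants">',
    f'##INFO=<ID={ANNOT_EXAC_ALL},Number=1,Type=Float,Description="Allele frequency in complete ExAC">',
    f'##INFO=<ID={ANNOT_DBSNP},Number=1,Type=String,Description="dbSNP build 150 identifier">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">',
    '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=F1R2,Number=R,Type=Integer,Description="Count of reads in F1R2 pair orientation">',
    '##FORMAT=<ID=F2R1,Number=R,Type=Integer,Description="Count of reads in F2R1 pair orientation">',
)


def _build_header(sample_id: str, extra_filters: Iterable[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##source=rnatmb")
    for chrom in CHROMOSOMES:
        header.add_line(f"##contig=<ID={chrom},length=250000000>")
    seen = set()
    for name, desc in _FILTER_DEFS:
        header.add_line(f'##FILTER=<ID={name},Description="{desc}">')
        seen.add(name)
    for name in sorted(extra_filters):
        if name not in seen and name != "PASS":
            header.add_line(f'##FILTER=<ID={name},Description="Caller filter">')
    for line in _HEADER_LINES:
        header.add_line(line)
    header.add_sample(sample_id)
    return header


def write_callset(callset: Callset, path: str | Path) -> Path:
    """Write a single-sample callset to a VCF 4.2 text file (round-trips with
    :func:`read_callset` for all fields used downstream)."""
    path = Path(path)
    labels: set[str] = set()
    for v in callset.variants:
        labels.update(v.filter_labels)
    header = _build_header(callset.sample_id, labels)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(callset.variants, key=VariantRecord.sort_key):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            rec.id = v.rsid
            if v.filter_labels:
                for f in sorted(v.filter_labels):
                    rec.filter.add(f)
            else:
                rec.filter.add("PASS")
            ci = v.caller_info
            for key in _INFO_SCALARS:
                if key in ci:
                    val = ci[key]
                    rec.info[key] = int(val) if key in ("ECNT", "GERMQ", "SEQQ") else val
            for key, (name_a, name_b) in _INFO_PAIRS.items():
                if name_a in ci or name_b in ci:
                    rec.info[key] = (ci.get(name_a, 0.0), ci.get(name_b, 0.0))
            for key, val in v.annotations.items():
                rec.info[key] = val
            sample = rec.samples[callset.sample_id]
            sample["GT"] = (0, 1)
            if v.ad_ref is not None:
                sample["AD"] = (v.ad_ref, v.ad_alt)
            if "AF" in ci:
                sample["AF"] = ci["AF"]
            if "DP" in ci:
                sample["DP"] = int(ci["DP"])
            for key, (name_a, name_b) in _FORMAT_PAIRS.items():
                if name_a in ci:
                    sample[key] = (int(ci[name_a]), int(ci.get(name_b, 0)))
            out.write(rec)
    return path


# ---------------------------------------------------------------------------
# Set operations


def merge_callsets(callsets: Sequence[Callset]) -> Callset:
    """Pool callsets of one source tag, retaining per-variant origin sample."""
    if not callsets:
        raise ContractError("merge_callsets requires at least one callset")
    sources = {c.source for c in callsets}
    if len(sources) > 1:
        raise ContractError(f"cannot merge mixed source tags: {sorted(sources)}")
    variants = [replace(v) for c in callsets for v in c.variants]
    variants.sort(key=VariantRecord.sort_key)
    member_ids = ",".join(c.sample_id for c in callsets)
    return Callset(
        sample_id="merged" if len(callsets) > 1 else callsets[0].sample_id,
        source=callsets[0].source,
        variants=variants,
        provenance=[f"merge_callsets:[{member_ids}]"],
        multiallelic_excluded=sum(c.multiallelic_excluded for c in callsets),
    )


MATCH_MODES = ("full_key", "coordinate_only")


def intersect_callsets(a: Callset, b: Callset, match_mode: str = "full_key") -> Callset:
    """Subset of ``a`` matching ``b`` by full key (chrom,pos,ref,alt) or by
    genomic coordinate only."""
    if match_mode not in MATCH_MODES:
        raise ContractError(f"unknown match_mode {match_mode!r}; expected {MATCH_MODES}")
    if match_mode == "full_key":
        ref = b.keys()
        kept = [v for v in a.variants if v.key in ref]
    else:
        ref = b.coords()
        kept = [v for v in a.variants if v.coord in ref]
    return a.with_variants(kept, f"intersect:{match_mode}:{b.sample_id}")


# ---------------------------------------------------------------------------
# BED regions


def read_regions(path: str | Path) -> RegionSet:
    """Read a 3+ column BED (0-based half-open) into a merged RegionSet."""
    path = Path(path)
    intervals: list[tuple[str, int, int]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise VcfFormatError(f"{path}:{lineno}: BED line has <3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise VcfFormatError(
                    f"{path}:{lineno}: non-integer BED coordinates"
                ) from exc
            if start >= end:
                raise VcfFormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            intervals.append((normalize_chrom(fields[0]), start, end))
    return RegionSet(intervals)


def write_regions(regions: RegionSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as handle:
        for chrom, start, end in regions.intervals:
            handle.write(f"{chrom}\t{start}\t{end}\n")
    return path
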