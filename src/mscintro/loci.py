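"""Multilocus dataset extraction from genotype calls.

Turns per-sample genotype calls (VCF), a reference sequence and
annotation intervals into filtered short locus alignments:

* loci are short, well-spaced segments: a coding locus coincides with a
  CDS of length >= 100 bp; a noncoding locus is carved from the
  complement of CDS and annotated repeats with length 100-1000 bp; loci
  are spaced >= 2 kb apart (spacing is relaxed to simple non-overlap in
  designated regions, e.g. an inversion interior);
* genotype calls are kept only with site QUAL >= 20, genotype GQ >= 20
  and depth within max(meanDP/2, d) <= DP <= 2*meanDP (d halved on the
  Z chromosome in females, which are the heterogametic sex);
* sites within 5 bp of an indel are masked;
* heterozygous diploid genotypes become IUPAC ambiguity codes in a
  single unphased sequence per individual.

Two genotyping pipelines are supported: ``per_individual`` (every
column with missing data removed; locus rejected if more than half the
data are missing before removal or if 10 or fewer sites remain) and
``joint`` (constant sites taken from the reference unless masked by low
depth ('-') or non-SNP/low-quality variation ('N'); SNPs kept only with
QD >= 2.0 and MQ >= 40; sequences > 50% missing dropped, all-missing
columns dropped, loci with fewer than two sequences rejected).

Coordinates are 0-based half-open internally (BED native; GFF3 and VCF
positions converted on read).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

from .alignment import IUPAC_PAIR, LocusAlignment, write_fasta

__all__ = [
    "LocusSpec",
    "ExtractConfig",
    "plan_loci",
    "genotype_keep",
    "mask_near_indels",
    "build_locus_alignment",
    "extract_dataset",
    "read_bed",
    "read_gff_cds",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LocusSpec:
    chrom: str
    start: int  # 0-based, half-open
    end: int
    cls: str  # "coding" | "noncoding"
    region: str | None = None
    relaxed: bool = False

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("locus end must exceed start")
        length = self.end - self.start
        if self.cls == "coding" and length < 100:
            raise ValueError("coding locus shorter than 100 bp")
        if self.cls == "noncoding" and not (100 <= length <= 1000):
            raise ValueError("noncoding locus length must be in [100, 1000]")
        if self.cls not in ("coding", "noncoding"):
            raise ValueError(f"unknown locus class {self.cls!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ExtractConfig:
    min_coding_len: int = 100
    min_noncoding_len: int = 100
    max_noncoding_len: int = 1000
    spacing: int = 2000
    relaxed_regions: set = field(default_factory=set)
    d: int = 20  # read-depth floor; the study used 12 or 20 by dataset
    qual_min: float = 20.0
    gq_min: float = 20.0
    indel_window: int = 5
    max_missing: float = 0.5
    min_sites: int = 11  # loci with 10 or fewer sites are discarded
    joint_dp_min: float = 20.0
    qd_min: float = 2.0
    mq_min: float = 40.0


# ---------------------------------------------------------------------------
# locus planning
# ---------------------------------------------------------------------------

def _check_sorted(intervals, chrom: str, chrom_len: int, what: str) -> None:
    prev = -1
    for s, e in intervals:
        if e <= s:
            raise ValueError(f"{what} interval ({s},{e}) on {chrom} is empty")
        if s < prev:
            raise ValueError(f"{what} intervals on {chrom} are not sorted")
        if e > chrom_len:
            raise ValueError(f"{what} interval ({s},{e}) beyond {chrom} length {chrom_len}")
        prev = s


def _merge(intervals):
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _overlaps(s, e, merged) -> bool:
    for ms, me in merged:
        if s < me and ms < e:
            return True
        if ms >= e:
            break
    return False


def plan_loci(
    cds_intervals: dict[str, list[tuple[int, int]]],
    repeat_intervals: dict[str, list[tuple[int, int]]],
    region_intervals: dict[str, tuple[str, int, int]],
    chrom_lengths: dict[str, int],
    cfg: ExtractConfig | None = None,
) -> list[LocusSpec]:
    """Plan coding and noncoding locus coordinates.

    Coding loci are CDS intervals of length >= 100 not overlapping any
    repeat; noncoding loci are carved from the complement of CDS and
    repeats in chunks of at most 1000 bp.  Within each class, loci are
    selected greedily left to right with >= ``cfg.spacing`` bp between
    consecutive loci, except inside regions whose label is in
    ``cfg.relaxed_regions`` where only non-overlap is required.
    """
    cfg = cfg or ExtractConfig()
    out: list[LocusSpec] = []

    def region_of(chrom: str, s: int, e: int):
        for label, (rc, rs, re_) in region_intervals.items():
            if rc == chrom and s < re_ and rs < e:
                return label
        return None

    for chrom, clen in sorted(chrom_lengths.items()):
        cds = list(cds_intervals.get(chrom, []))
        _check_sorted(cds, chrom, clen, "CDS")
        _check_sorted(repeat_intervals.get(chrom, []), chrom, clen, "repeat")
        reps = _merge(repeat_intervals.get(chrom, []))

        # coding: CDS >= min length, repeat-free, greedy spacing
        prev_end = None
        for s, e in cds:
            if e - s < cfg.min_coding_len or _overlaps(s, e, reps):
                continue
            label = region_of(chrom, s, e)
            relaxed = label in cfg.relaxed_regions
            gap = 0 if relaxed else cfg.spacing
            if prev_end is not None and s < prev_end + gap:
                continue
            out.append(LocusSpec(chrom, s, e, "coding", label, relaxed))
            prev_end = e

        # noncoding: complement of CDS+repeats, chunked
        blocked = _merge(list(cds) + list(reps))
        free = []
        pos = 0
        for s, e in blocked:
            if s > pos:
                free.append((pos, s))
            pos = max(pos, e)
        if pos < clen:
            free.append((pos, clen))
        prev_end = None
        for s, e in free:
            pos = s
            while e - pos >= cfg.min_noncoding_len:
                label = region_of(chrom, pos, pos + cfg.min_noncoding_len)
                relaxed = label in cfg.relaxed_regions
                gap = 0 if relaxed else cfg.spacing
                if prev_end is not None and pos < prev_end + gap:
                    pos = prev_end + gap
                    continue
                stop = min(pos + cfg.max_noncoding_len, e)
                if stop - pos < cfg.min_noncoding_len:
                    break
                out.append(LocusSpec(chrom, pos, stop, "noncoding", label, relaxed))
                prev_end = stop
                pos = stop
    return out


# ---------------------------------------------------------------------------
# genotype-level filters
# ---------------------------------------------------------------------------

def genotype_keep(
    call: dict,
    mean_dp: float,
    d: float = 20,
    female_z: bool = False,
    qual_min: float = 20.0,
    gq_min: float = 20.0,
) -> bool:
    """Keep a genotype call iff QUAL >= 20, GQ >= 20 and
    max(meanDP/2, d') <= DP <= 2*meanDP with d' = d/2 on the female Z."""
    if mean_dp <= 0:
        raise ValueError("mean depth must be positive")
    qual = call.get("QUAL")
    gq = call.get("GQ")
    dp = call.get("DP")
    if qual is None or gq is None or dp is None:
        return False
    d_eff = d / 2.0 if female_z else d
    lo = max(mean_dp / 2.0, d_eff)
    return qual >= qual_min and gq >= gq_min and lo <= dp <= 2.0 * mean_dp


def mask_near_indels(site_positions, indel_positions, window: int = 5) -> set[int]:
    """Sites within ``window`` bp of any indel position (0-based)."""
    indels = sorted(indel_positions)
    out = set()
    for s in site_positions:
        for p in indels:
            if abs(s - p) <= window:
                out.add(s)
                break
            if p > s + window:
                break
    return out


# ---------------------------------------------------------------------------
# alignment construction
# ---------------------------------------------------------------------------

class _VcfAccessor:
    """Region queries over a VCF: tabix fetch when indexed, otherwise an
    in-memory scan (adequate for the short plain-text files used here)."""

    def __init__(self, vcf: "pysam.VariantFile | str | Path"):
        if isinstance(vcf, (str, Path)):
            vcf = pysam.VariantFile(str(vcf))
        self.vcf = vcf
        self._records: dict[str, list] | None = None
        self._indexed = vcf.index is not None

    @property
    def header(self):
        return self.vcf.header

    def _load(self) -> None:
        if self._records is None:
            vcf = pysam.VariantFile(self.vcf.filename)
            self._records = {}
            for rec in vcf:
                self._records.setdefault(rec.chrom, []).append(rec)

    def fetch(self, chrom: str, start: int, end: int):
        if self._indexed:
            yield from self.vcf.fetch(chrom, start, end)
            return
        self._load()
        for rec in self._records.get(chrom, []):
            if rec.start < end and rec.start + max(len(rec.ref), 1) > start:
                yield rec


def _genotype_symbol(alleles: tuple) -> str:
    """IUPAC symbol for a (possibly heterozygous) diploid or haploid call."""
    bases = {a.upper() for a in alleles if a is not None}
    if not bases or any(len(b) != 1 or b not in "ACGT" for b in bases):
        return "N"
    if len(bases) == 1:
        return next(iter(bases))
    if len(bases) == 2:
        return IUPAC_PAIR[frozenset(bases)]
    return "N"


def build_locus_alignment(
    vcf,
    reference: dict[str, str],
    spec: LocusSpec,
    mode: str = "per_individual",
    cfg: ExtractConfig | None = None,
    mean_dp: dict[str, float] | None = None,
    female_z_samples: set[str] | None = None,
) -> LocusAlignment | None:
    """Build one locus alignment, or return None if the locus is
    rejected by the filtering rules.

    ``per_individual`` mode expects an all-sites VCF (invariant sites
    included); positions without a record are treated as missing.
    ``joint`` mode expects a jointly-called variants-only VCF; constant
    sites come from the reference.
    """
    cfg = cfg or ExtractConfig()
    if not isinstance(vcf, _VcfAccessor):
        vcf = _VcfAccessor(vcf)
    if spec.chrom not in reference:
        raise ValueError(f"chromosome {spec.chrom!r} not in reference")
    ref_chrom = reference[spec.chrom]
    if spec.end > len(ref_chrom):
        raise ValueError("locus beyond reference bounds")
    ref_seg = ref_chrom[spec.start : spec.end].upper()
    samples = list(vcf.header.samples)
    if not samples:
        return None
    female_z_samples = female_z_samples or set()
    mean_dp = mean_dp or {}
    length = spec.length
    if mode == "per_individual":
        cols = {s: ["N"] * length for s in samples}
        seen = [False] * length
        indel_pos: list[int] = []
        for rec in vcf.fetch(spec.chrom, max(spec.start - cfg.indel_window, 0),
                             spec.end + cfg.indel_window):
            is_indel = any(
                len(a) != len(rec.ref) for a in (rec.alts or ())
            ) or len(rec.ref) != 1
            if is_indel:
                indel_pos.extend(range(rec.start, rec.start + len(rec.ref)))
                continue
            if not (spec.start <= rec.start < spec.end):
                continue
            j = rec.start - spec.start
            seen[j] = True
            qual = rec.qual if rec.qual is not None else 0.0
            for s in samples:
                smp = rec.samples[s]
                call = {
                    "QUAL": qual,
                    "GQ": smp.get("GQ"),
                    "DP": smp.get("DP"),
                }
                mdp = mean_dp.get(s, 0.0)
                if mdp <= 0:
                    raise ValueError(f"missing mean depth for sample {s}")
                if None in (call["GQ"], call["DP"]) or not genotype_keep(
                    call, mdp, cfg.d, s in female_z_samples, cfg.qual_min, cfg.gq_min
                ):
                    continue
                alleles = smp.alleles
                if alleles is None or any(a is None for a in alleles):
                    continue
                cols[s][j] = _genotype_symbol(tuple(alleles))
        masked = mask_near_indels(
            range(spec.start, spec.end), indel_pos, cfg.indel_window
        )
        for pos in masked:
            j = pos - spec.start
            for s in samples:
                cols[s][j] = "N"
        n_cells = length * len(samples)
        n_missing = sum(c == "N" for s in samples for c in cols[s])
        if n_cells == 0 or n_missing / n_cells > cfg.max_missing:
            return None
        drop = {
            j for j in range(length) if any(cols[s][j] == "N" for s in samples)
        }
        kept = [j for j in range(length) if j not in drop]
        if len(kept) < cfg.min_sites:
            return None
        aln = LocusAlignment(
            samples,
            ["".join(cols[s][j] for j in kept) for s in samples],
            {"spec": spec, "n_sites_kept": len(kept)},
        )
        return aln
    if mode == "joint":
        cols = {s: list(ref_seg) for s in samples}
        for rec in vcf.fetch(spec.chrom, spec.start, spec.end):
            if not (spec.start <= rec.start < spec.end):
                continue
            j = rec.start - spec.start
            if rec.alts is None:
                continue  # invariant record: reference base stands
            is_snp = len(rec.ref) == 1 and all(len(a) == 1 for a in rec.alts)
            qd = rec.info.get("QD")
            mq = rec.info.get("MQ")
            good_snp = (
                is_snp
                and qd is not None
                and mq is not None
                and qd >= cfg.qd_min
                and mq >= cfg.mq_min
            )
            if not good_snp:
                # non-SNP variant or low-quality SNP: masked as 'N'
                for s in samples:
                    cols[s][j] = "N"
                continue
            for s in samples:
                smp = rec.samples[s]
                alleles = smp.alleles
                if alleles is None or any(a is None for a in alleles):
                    cols[s][j] = "N"
                else:
                    cols[s][j] = _genotype_symbol(tuple(alleles))
        # low-depth constant-site mask per sample
        for s in samples:
            depth = _sample_depths(vcf, spec, s)
            for j, dp in enumerate(depth):
                if cols[s][j] not in "ACGTRYSWKMBDHV":
                    continue
                if dp is not None and dp < cfg.joint_dp_min:
                    cols[s][j] = "-"
        keep_samples = [
            s
            for s in samples
            if sum(c in "-N" for c in cols[s]) / length <= cfg.max_missing
        ]
        if len(keep_samples) < 2:
            return None
        drop = {
            j
            for j in range(length)
            if all(cols[s][j] in "-N" for s in keep_samples)
        }
        kept = [j for j in range(length) if j not in drop]
        if not kept:
            return None
        return LocusAlignment(
            keep_samples,
            ["".join(cols[s][j] for j in kept) for s in keep_samples],
            {"spec": spec, "n_sites_kept": len(kept)},
        )
    raise ValueError(f"unknown mode {mode!r}")


def _sample_depths(vcf, spec: LocusSpec, sample: str):
    """Per-position DP for one sample across a locus (None if no record).

    Depth masking of constant sites needs positional depths; in an
    all-sites VCF these come from the records, otherwise unknown
    positions are left unmasked.
    """
    depth = [None] * spec.length
    for rec in vcf.fetch(spec.chrom, spec.start, spec.end):
        if spec.start <= rec.start < spec.end:
            dp = rec.samples[sample].get("DP")
            depth[rec.start - spec.start] = dp
    return depth


# ---------------------------------------------------------------------------
# annotation readers and the pipeline driver
# ---------------------------------------------------------------------------

def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    """BED intervals (0-based half-open) grouped by chromosome."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
    )
    out: dict[str, list[tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.chrom), []).append((int(row.start), int(row.end)))
    for v in out.values():
        v.sort()
    return out


def read_gff_cds(path) -> dict[str, list[tuple[int, int]]]:
    """CDS intervals from a GFF3 file, converted to 0-based half-open."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8 or parts[2] != "CDS":
                continue
            out.setdefault(parts[0], []).append((int(parts[3]) - 1, int(parts[4])))
    for v in out.values():
        v.sort()
    return out


def extract_dataset(
    vcf_path,
    reference: dict[str, str],
    loci: list[LocusSpec],
    mode: str = "per_individual",
    cfg: ExtractConfig | None = None,
    mean_dp: dict[str, float] | None = None,
    female_z_samples: set[str] | None = None,
    out_dir=None,
):
    """Run the extraction over a list of planned loci.

    Returns (alignments, index DataFrame, rejection counts); optionally
    writes one FASTA per surviving locus and a loci_index.tsv.
    """
    cfg = cfg or ExtractConfig()
    vcf = _VcfAccessor(vcf_path)
    alignments, rows = [], []
    rejected = {"filtered": 0}
    for k, spec in enumerate(loci):
        aln = build_locus_alignment(
            vcf, reference, spec, mode, cfg, mean_dp, female_z_samples
        )
        if aln is None:
            rejected["filtered"] += 1
            continue
        alignments.append(aln)
        rows.append(
            {
                "chrom": spec.chrom,
                "start": spec.start,
                "end": spec.end,
                "class": spec.cls,
                "region": spec.region or "",
                "n_seqs": aln.n_seqs,
                "n_sites": aln.n_sites,
                "file": f"locus_{k:05d}.fasta",
            }
        )
    index = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "class", "region", "n_seqs", "n_sites", "file"],
    )
    logger.info(
        "extracted %d loci, rejected %d", len(alignments), rejected["filtered"]
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for aln, row in zip(alignments, rows):
            write_fasta(aln, out / row["file"])
        index.to_csv(out / "loci_index.tsv", sep="\t", index=False)
    return alignments, index, rejected
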