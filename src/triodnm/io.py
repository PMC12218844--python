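"""Readers and writers for the pipeline's on-disk formats.

VCF is the minimal multi-sample dialect the simulator emits (GT:AD:DP:GQ,
site INFO statistics QD/FS/MQ/SOR/MQRankSum/ReadPosRankSum); reading goes
through :mod:`pysam` so any spec-conformant VCF works. Tabular side files
(pedigree, truth, read evidence, linkage map) are plain TSV via pandas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import ReadEvidence, SampleCall, SiteRecord, Trio

log = logging.getLogger("triodnm")

INFO_FIELDS = ("QD", "FS", "MQ", "SOR", "MQRankSum", "ReadPosRankSum")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

VCF_HEADER_TEMPLATE = """##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias (phred)">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=SOR,Number=1,Type=Float,Description="Symmetric odds ratio of strand bias">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank-sum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank-sum">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def _format_call(call: SampleCall) -> str:
    gt = "./." if call.gt is None else f"{call.gt[0]}/{call.gt[1]}"
    ad = "." if call.ad is None else f"{call.ad[0]},{call.ad[1]}"
    gq = "." if call.gq is None else str(call.gq)
    return f"{gt}:{ad}:{call.dp}:{gq}"


def write_vcf(
    records: Iterable[SiteRecord],
    samples: Sequence[str],
    path: str | Path,
    contigs: Optional[dict[str, int]] = None,
) -> None:
    """Write site records as an uncompressed multi-sample VCF (deterministic)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(VCF_HEADER_TEMPLATE)
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for rec in records:
            if rec.info:
                info = ";".join(
                    f"{k}={rec.info[k]:.4g}" for k in INFO_FIELDS if k in rec.info
                )
            else:
                info = "."
            alt = rec.alt if rec.alt is not None else "."
            cols = [
                rec.chrom,
                str(rec.pos),
                ".",
                rec.ref,
                alt,
                ".",
                "PASS",
                info or ".",
                "GT:AD:DP:GQ",
            ]
            cols.extend(
                _format_call(rec.calls.get(s, SampleCall(gt=None))) for s in samples
            )
            fh.write("\t".join(cols) + "\n")


class VcfParseError(RuntimeError):
    pass


def read_vcf(
    path: str | Path,
    include_monomorphic: bool = False,
    stats: Optional[dict] = None,
) -> Iterator[SiteRecord]:
    """Stream SiteRecords from a VCF.

    Multi-allelic records are skipped (counted in ``stats['multiallelic']``);
    monomorphic records (ALT '.') are yielded with alt=None only when
    ``include_monomorphic`` is set (used for the depth-survey file). A parse
    failure names the last successfully read site.
    """
    path = Path(path)
    if stats is None:
        stats = {}
    stats.setdefault("multiallelic", 0)
    stats.setdefault("non_snv", 0)
    try:
        vf = pysam.VariantFile(str(path))
    except Exception as exc:  # malformed header
        raise VcfParseError(f"cannot parse VCF header of {path}: {exc}") from exc
    samples = list(vf.header.samples)
    stats["samples"] = samples
    last_good = "start of file"
    try:
        for rec in vf:
            alts = rec.alts
            if alts is not None and len(alts) > 1:
                stats["multiallelic"] += 1
                continue
            alt = alts[0] if alts else None
            if alt is not None and (len(rec.ref) != 1 or len(alt) != 1 or alt == "*"):
                stats["non_snv"] += 1
                continue
            if alt is None and not include_monomorphic:
                continue
            calls = {}
            for s in samples:
                sc = rec.samples[s]
                gt = sc.get("GT")
                if gt is None or any(a is None for a in gt):
                    gt_t = None
                else:
                    gt_t = (gt[0], gt[1])
                ad = sc.get("AD")
                if ad is not None and len(ad) >= 2 and ad[0] is not None:
                    ad_t = (int(ad[0]), int(ad[1]))
                elif ad is not None and len(ad) == 1 and ad[0] is not None:
                    ad_t = (int(ad[0]), 0)
                else:
                    ad_t = None
                dp = sc.get("DP")
                gq = sc.get("GQ")
                calls[s] = SampleCall(
                    gt=gt_t,
                    dp=int(dp) if dp is not None else 0,
                    ad=ad_t,
                    gq=int(gq) if gq is not None else None,
                )
            info = {
                k: float(rec.info[k]) for k in INFO_FIELDS if k in rec.info
            }
            yield SiteRecord(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                info=info, calls=calls,
            )
            last_good = f"{rec.chrom}:{rec.pos}"
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(
            f"VCF parse error in {path} after {last_good}: {exc}"
        ) from exc


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Pedigree / truth / evidence / linkage-map TSVs
# ---------------------------------------------------------------------------

def write_pedigree(trios: Sequence[Trio], path: str | Path) -> None:
    pd.DataFrame(
        [(t.family, t.father, t.mother, t.child) for t in trios],
        columns=["family", "father", "mother", "child"],
    ).to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> list[Trio]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"family", "father", "mother", "child"}
    if not required.issubset(df.columns):
        raise ValueError(f"pedigree file {path} must have columns {sorted(required)}")
    return [
        Trio(family=r.family, father=r.father, mother=r.mother, child=r.child)
        for r in df.itertuples()
    ]


def write_read_evidence(fragments: Sequence[ReadEvidence], path: str | Path) -> None:
    rows = [
        (f.fragment_id, f.sample, chrom, pos, base)
        for f in fragments
        for chrom, pos, base in f.observations
    ]
    pd.DataFrame(
        rows, columns=["fragment_id", "sample", "chrom", "pos", "allele"]
    ).to_csv(path, sep="\t", index=False)


def read_read_evidence(path: str | Path) -> list[ReadEvidence]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "allele": str})
    fragments: list[ReadEvidence] = []
    for (fid, sample), grp in df.groupby(["fragment_id", "sample"], sort=False):
        obs = [(r.chrom, int(r.pos), r.allele) for r in grp.itertuples()]
        obs.sort(key=lambda o: (o[0], o[1]))
        fragments.append(ReadEvidence(fragment_id=str(fid), sample=sample, observations=obs))
    return fragments


def read_linkage_map(path: str | Path) -> pd.DataFrame:
    """Linkage map TSV with columns chrom, physical_pos (bp), genetic_pos (cM)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "physical_pos", "genetic_pos"}
    if not required.issubset(df.columns):
        raise ValueError(f"linkage map {path} must have columns {sorted(required)}")
    df = df.sort_values(["chrom", "physical_pos"]).reset_index(drop=True)
    for chrom, grp in df.groupby("chrom"):
        if (grp["genetic_pos"].diff().dropna() < 0).any():
            raise ValueError(f"genetic positions decrease along {chrom}")
    return df


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """0-based half-open intervals from a 3+ column BED file."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    """Gene model with exon and CDS intervals (0-based half-open)."""

    tid: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int, int]]  # (start, end, phase)

    @property
    def coding(self) -> bool:
        return bool(self.cds)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


def read_gff3(path: str | Path) -> list[Transcript]:
    """Parse mRNA/exon/CDS features from GFF3 into transcript models.

    GFF3 is 1-based inclusive; intervals are converted to 0-based half-open.
    """
    transcripts: dict[str, Transcript] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            chrom, _, ftype, start, end, _, strand, phase, attrs = parts[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            s0, e0 = int(start) - 1, int(end)
            if ftype in ("mRNA", "transcript"):
                tid = attr.get("ID", f"{chrom}:{start}-{end}")
                transcripts[tid] = Transcript(
                    tid=tid, chrom=chrom, start=s0, end=e0, strand=strand,
                    exons=[], cds=[],
                )
            elif ftype == "exon":
                parent = attr.get("Parent")
                if parent in transcripts:
                    transcripts[parent].exons.append((s0, e0))
            elif ftype == "CDS":
                parent = attr.get("Parent")
                if parent in transcripts:
                    ph = int(phase) if phase in ("0", "1", "2") else 0
                    if phase not in ("0", "1", "2", "."):
                        raise ValueError(f"invalid CDS phase {phase!r} for {parent}")
                    transcripts[parent].cds.append((s0, e0, ph))
    for t in transcripts.values():
        t.exons.sort()
        t.cds.sort()
    return list(transcripts.values())


def write_gff3(transcripts: Sequence[Transcript], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            gid = t.tid + ".gene"
            fh.write(
                f"{t.chrom}\ttriodnm\tgene\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{t.chrom}\ttriodnm\tmRNA\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t"
                f"ID={t.tid};Parent={gid}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\ttriodnm\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\tParent={t.tid}\n"
                )
            for s, e, ph in t.cds:
                fh.write(
                    f"{t.chrom}\ttriodnm\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t{ph}\tParent={t.tid}\n"
                )
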