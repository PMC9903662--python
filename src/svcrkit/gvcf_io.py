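"""gVCF record model and file I/O.

A gVCF tiles every targeted base of a sample's genome with two kinds of
records: *reference blocks* (runs of homozygous-reference calls summarized by
a start, an END, a genotype-quality band, and a minimum depth) and *variant
records* (sites where the sample carries at least one alternate allele, with
the symbolic ``<NON_REF>`` placeholder as the final alternate).

Internally all coordinates are 0-based half-open; VCF text is 1-based
inclusive (so the number written for END equals the internal half-open end).
Files are parsed with pysam; emission goes through a small text writer so the
rendered field set is exactly the modeled one (CHROM, POS, REF, ALT, END,
GT, AD, PL, GQ, DP, MIN_DP) and byte-level comparisons are meaningful.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pysam

NON_REF = "<NON_REF>"

#: GQ bands used to compress reference blocks.
GQ_BINS = (0, 10, 20, 30, 40, 50, 60)


def bin_reference_gq(gq: int) -> int:
    """Map a reference-block GQ to the largest band at or below it, capped at 60.

    >>> bin_reference_gq(37)
    30
    """
    if gq < 0:
        raise ValueError(f"GQ must be non-negative, got {gq}")
    return min((gq // 10) * 10, GQ_BINS[-1])


@dataclass(frozen=True)
class GvcfRecord:
    """One gVCF line for one sample (block or variant), 0-based coordinates."""

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]  # () for reference blocks; NON_REF last for variants
    gt: tuple[int, ...]
    gq: int
    dp: int
    end: int | None = None  # reference blocks only, 0-based exclusive
    ad: tuple[int, ...] | None = None
    pl: tuple[int, ...] | None = None

    @property
    def is_block(self) -> bool:
        return self.end is not None

    def __post_init__(self) -> None:
        if self.is_block:
            if self.end <= self.pos:
                raise ValueError(f"block END {self.end} <= start {self.pos}")
            if self.alts:
                raise ValueError("reference blocks carry no concrete alternates")
        else:
            if not self.alts or self.alts[-1] != NON_REF:
                raise ValueError("variant records must list <NON_REF> last")


def bin_and_merge_blocks(records: Sequence[GvcfRecord]) -> list[GvcfRecord]:
    """GQ-bin reference blocks and coalesce adjacent blocks in the same band.

    Variant records pass through untouched. Merged blocks keep the minimum DP
    of their constituents (min-DP semantics). Losslessness of the sparse
    representation is defined from this binned, block-merged form onward.
    """
    out: list[GvcfRecord] = []
    for rec in records:
        if not rec.is_block:
            out.append(rec)
            continue
        rec = replace(rec, gq=bin_reference_gq(rec.gq))
        prev = out[-1] if out else None
        if (
            prev is not None
            and prev.is_block
            and prev.contig == rec.contig
            and prev.end == rec.pos
            and prev.gq == rec.gq
        ):
            out[-1] = replace(prev, end=rec.end, dp=min(prev.dp, rec.dp))
        else:
            out.append(rec)
    return out


def _header_text(sample: str, contigs: Sequence[tuple[str, int]]) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of reference block">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=MIN_DP,Number=1,Type=Integer,Description="Minimum depth in reference block">',
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">',
    ]
    lines += [f"##contig=<ID={name},length={length}>" for name, length in contigs]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    return "\n".join(lines) + "\n"


def _format_record(rec: GvcfRecord) -> str:
    pos1 = rec.pos + 1
    if rec.is_block:
        gt = "/".join(str(a) for a in rec.gt)
        sample = f"{gt}:{rec.dp}:{rec.gq}:{rec.dp}"
        return (
            f"{rec.contig}\t{pos1}\t.\t{rec.ref}\t{NON_REF}\t.\t.\t"
            f"END={rec.end}\tGT:DP:GQ:MIN_DP\t{sample}"
        )
    gt = "/".join(str(a) for a in rec.gt)
    ad = ",".join(str(x) for x in rec.ad)
    pl = ",".join("." if x is None else str(x) for x in rec.pl)
    alt = ",".join(rec.alts)
    sample = f"{gt}:{ad}:{rec.dp}:{rec.gq}:{pl}"
    return (
        f"{rec.contig}\t{pos1}\t.\t{rec.ref}\t{alt}\t.\t.\t.\t"
        f"GT:AD:DP:GQ:PL\t{sample}"
    )


def render_gvcf(
    sample: str,
    records: Iterable[GvcfRecord],
    contigs: Sequence[tuple[str, int]],
) -> str:
    """Render a single-sample gVCF as VCF v4.2 text."""
    buf = io.StringIO()
    buf.write(_header_text(sample, contigs))
    for rec in records:
        buf.write(_format_record(rec) + "\n")
    return buf.getvalue()


def write_gvcf(
    path: str | Path,
    sample: str,
    records: Iterable[GvcfRecord],
    contigs: Sequence[tuple[str, int]],
) -> None:
    Path(path).write_text(render_gvcf(sample, records, contigs))


def read_gvcf(path: str | Path) -> tuple[str, list[GvcfRecord], list[tuple[str, int]]]:
    """Parse a single-sample gVCF with pysam into the internal record model."""
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if len(samples) != 1:
            raise ValueError(f"expected a single-sample gVCF, got {samples}")
        sample = samples[0]
        contigs = [(c.name, c.length) for c in vf.header.contigs.values()]
        records: list[GvcfRecord] = []
        for rec in vf:
            call = rec.samples[sample]
            gt = tuple(a for a in call["GT"] if a is not None)
            alts = tuple(rec.alts or ())
            if alts == (NON_REF,):
                # reference block; pysam folds the END info key into rec.stop
                records.append(
                    GvcfRecord(
                        contig=rec.contig,
                        pos=rec.pos - 1,
                        ref=rec.ref,
                        alts=(),
                        gt=gt,
                        gq=int(call["GQ"]),
                        dp=int(call["MIN_DP"] if call.get("MIN_DP") is not None else call["DP"]),
                        end=int(rec.stop),
                    )
                )
            else:
                pl = tuple(None if x is None else int(x) for x in call["PL"])
                records.append(
                    GvcfRecord(
                        contig=rec.contig,
                        pos=rec.pos - 1,
                        ref=rec.ref,
                        alts=alts,
                        gt=gt,
                        gq=int(call["GQ"]),
                        dp=int(call["DP"]),
                        ad=tuple(int(x) for x in call["AD"]),
                        pl=pl,
                    )
                )
    return sample, records, contigs
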