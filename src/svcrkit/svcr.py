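"""The sparse, local-allele cohort representation and its algebra.

A joint callset is stored as a locus-by-sample matrix that keeps each gVCF
record essentially verbatim: a row exists for every locus where any sample's
gVCF has a record (including monomorphic rows where reference blocks begin),
a row's alleles are the union of alternates discovered in any sample, and an
entry is present only where the sample's own gVCF had a record. Entries do
not store allele strings: they store LA, a list mapping the sample's *local*
allele indices to the row's global allele list, and the genotype fields are
renamed LGT/LAD/LPL to signal that their indices are local. This makes the
stored entry count — and hence storage — exactly linear in the sum of input
record counts, regardless of how many samples are merged, and makes the
transformation from (binned) gVCFs lossless.

Merging datasets is an outer join on loci: the merged alternate list is the
sorted union of inputs (plain lexicographic, symbolic alleles like
``<NON_REF>`` and ``*`` last), and only the LA field of each surviving entry
is rewritten; LGT/LAD/LPL are untouched. The join is associative, so a
hierarchical merge in rounds of ``branch_factor`` inputs produces the same
object as one flat merge.

Densification converts the sparse matrix into a conventional per-sample call
matrix on the fly, carrying forward each sample's most recent reference
block along a contig and using it to fill homozygous-reference calls at loci
it spans; entries beyond a block's END stay missing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pysam

from .gvcf_io import NON_REF, GvcfRecord, bin_and_merge_blocks


# ---------------------------------------------------------------------------
# allele collation and genotype-index arithmetic


def _is_symbolic(allele: str) -> bool:
    return allele.startswith("<") or allele == "*"


def allele_sort_key(allele: str) -> tuple[int, str]:
    """Deterministic collation: concrete alts lexicographic, symbolic last."""
    return (1 if _is_symbolic(allele) else 0, allele)


def genotype_index(alleles: Sequence[int]) -> int:
    """VCF genotype-array index of an unordered genotype (any ploidy)."""
    idx = 0
    for m, a in enumerate(sorted(alleles), start=1):
        num = 1
        for k in range(m):
            num = num * (a + k) // (k + 1)
        idx += num
    return idx


def n_genotypes(n_alleles: int, ploidy: int) -> int:
    """Number of unordered genotypes of given ploidy over n_alleles alleles."""
    num = 1
    for k in range(ploidy):
        num = num * (n_alleles + k) // (k + 1)
    return num


def genotype_tuples(n_alleles: int, ploidy: int) -> list[tuple[int, ...]]:
    """All unordered genotypes in VCF array order."""
    if ploidy == 1:
        return [(a,) for a in range(n_alleles)]
    out = []
    for k in range(n_alleles):
        for j in range(k + 1):
            out.append((j, k))
    return out


# ---------------------------------------------------------------------------
# core types


@dataclass(frozen=True, order=True)
class Locus:
    contig: str
    position: int  # 0-based


@dataclass(frozen=True)
class SvcrEntry:
    """One sample's record at one row: a reference block or a variant call.

    ``la`` maps local allele index -> row (global) allele index; la[0] is
    always 0 (the reference). LGT/LAD/LPL are in local index space.
    """

    kind: str  # "reference_block" | "variant_call"
    la: tuple[int, ...]
    lgt: tuple[int, ...]
    gq: int
    dp: int
    lad: tuple[int, ...] | None = None
    lpl: tuple[int, ...] | None = None
    end: int | None = None  # blocks only, 0-based exclusive

    def __post_init__(self) -> None:
        if self.la[0] != 0:
            raise ValueError("LA[0] must be 0")
        if self.kind == "reference_block" and self.end is None:
            raise ValueError("reference blocks need END")
        if self.lad is not None and len(self.lad) != len(self.la):
            raise ValueError("|LAD| must equal |LA|")
        if self.lpl is not None and len(self.lpl) != n_genotypes(
            len(self.la), len(self.lgt)
        ):
            raise ValueError("|LPL| inconsistent with |LA| and ploidy")
        if any(g >= len(self.la) for g in self.lgt):
            raise ValueError("LGT index outside LA")


@dataclass
class SvcrRow:
    locus: Locus
    ref: str
    alts: tuple[str, ...]
    entries: dict[str, SvcrEntry]  # sample id -> entry; sparse

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts


@dataclass
class SvcrDataset:
    """Locus-sorted sparse cohort matrix."""

    samples: list[str]
    rows: list[SvcrRow]
    contigs: list[tuple[str, int]]

    @property
    def n_entries(self) -> int:
        return sum(len(r.entries) for r in self.rows)

    def contig_order(self) -> dict[str, int]:
        return {name: i for i, (name, _) in enumerate(self.contigs)}

    def validate(self) -> None:
        order = self.contig_order()
        keys = [(order[r.locus.contig], r.locus.position) for r in self.rows]
        if keys != sorted(keys):
            raise ValueError("rows not locus-sorted")
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate loci")
        sset = set(self.samples)
        for r in self.rows:
            if len(set(r.alts)) != len(r.alts):
                raise ValueError(f"duplicate alternates at {r.locus}")
            for s, e in r.entries.items():
                if s not in sset:
                    raise ValueError(f"entry for unknown sample {s}")
                if any(i >= len(r.alleles) for i in e.la):
                    raise ValueError(f"LA outside row alleles at {r.locus}")


@dataclass
class DenseCall:
    """A densified per-sample call in global allele indices."""

    gt: tuple[int, ...]
    gq: int
    dp: int
    ad: tuple[int, ...] | None = None
    pl: tuple[int | None, ...] | None = None
    filled: bool = False  # True if carried from a spanning reference block


@dataclass
class DenseRow:
    locus: Locus
    ref: str
    alts: tuple[str, ...]
    calls: list[DenseCall | None]  # one per dataset sample, None = missing


@dataclass
class DenseMatrix:
    samples: list[str]
    rows: list[DenseRow]
    contigs: list[tuple[str, int]]


# ---------------------------------------------------------------------------
# conversion gVCF -> SVCR


def gvcf_to_svcr(
    sample: str,
    records: Sequence[GvcfRecord],
    contigs: Sequence[tuple[str, int]],
) -> SvcrDataset:
    """Convert one sample's gVCF records to a single-column sparse dataset.

    Reference blocks are GQ-binned and adjacent same-band blocks coalesced
    first; thereafter the conversion is a trivial reorganization: one row per
    record, LA the identity over the record's own alleles. Raises on
    unsorted input or overlapping variant records.
    """
    records = bin_and_merge_blocks(records)
    order = {name: i for i, (name, _) in enumerate(contigs)}
    rows: list[SvcrRow] = []
    prev_key: tuple[int, int] | None = None
    prev_variant_span: tuple[int, int] | None = None  # (contig idx, end of ref span)
    for rec in records:
        key = (order[rec.contig], rec.pos)
        if prev_key is not None and key <= prev_key:
            raise ValueError(f"unsorted gVCF input at {rec.contig}:{rec.pos + 1}")
        if not rec.is_block:
            span = (key[0], rec.pos + len(rec.ref))
            if (
                prev_variant_span is not None
                and prev_variant_span[0] == key[0]
                and rec.pos < prev_variant_span[1]
            ):
                raise ValueError(
                    f"overlapping variant records at {rec.contig}:{rec.pos + 1}"
                )
            prev_variant_span = span
        prev_key = key

        locus = Locus(rec.contig, rec.pos)
        if rec.is_block:
            entry = SvcrEntry(
                kind="reference_block",
                la=(0,),
                lgt=rec.gt,
                gq=rec.gq,
                dp=rec.dp,
                end=rec.end,
            )
            rows.append(SvcrRow(locus, rec.ref, (), {sample: entry}))
        else:
            la = tuple(range(len(rec.alts) + 1))
            entry = SvcrEntry(
                kind="variant_call",
                la=la,
                lgt=rec.gt,
                gq=rec.gq,
                dp=rec.dp,
                lad=rec.ad,
                lpl=rec.pl,
            )
            rows.append(SvcrRow(locus, rec.ref, rec.alts, {sample: entry}))
    return SvcrDataset([sample], rows, list(contigs))


# ---------------------------------------------------------------------------
# merging


def merge_alleles(
    allele_sets: Sequence[tuple[str, tuple[str, ...]]],
) -> tuple[tuple[str, tuple[str, ...]], list[tuple[int, ...]]]:
    """Union the alternate alleles of co-located rows; return index maps.

    Each input is (ref, alts). All refs must agree. The merged alternates are
    the sorted set union (lexicographic, symbolic last). The i-th returned
    map sends input allele index -> merged allele index, with map[0] = 0.
    """
    refs = {ref for ref, _ in allele_sets}
    if len(refs) != 1:
        raise ValueError(f"conflicting reference alleles: {sorted(refs)}")
    ref = refs.pop()
    merged_alts = tuple(
        sorted({a for _, alts in allele_sets for a in alts}, key=allele_sort_key)
    )
    pos = {a: i + 1 for i, a in enumerate(merged_alts)}
    maps = [
        (0,) + tuple(pos[a] for a in alts) for _, alts in allele_sets
    ]
    return (ref, merged_alts), maps


def _remap_entry(entry: SvcrEntry, amap: tuple[int, ...]) -> SvcrEntry:
    """Rewrite an entry's LA through an input->merged allele index map."""
    return replace(entry, la=tuple(amap[i] for i in entry.la))


def merge_svcr(datasets: Sequence[SvcrDataset]) -> SvcrDataset:
    """Outer join on loci over datasets with disjoint sample sets."""
    if not datasets:
        raise ValueError("nothing to merge")
    samples: list[str] = []
    for ds in datasets:
        for s in ds.samples:
            if s in samples:
                raise ValueError(f"duplicate sample id across inputs: {s}")
            samples.append(s)
    contigs = datasets[0].contigs
    order = {name: i for i, (name, _) in enumerate(contigs)}

    by_locus: dict[tuple[int, int], list[SvcrRow]] = {}
    for ds in datasets:
        for row in ds.rows:
            key = (order[row.locus.contig], row.locus.position)
            by_locus.setdefault(key, []).append(row)

    rows: list[SvcrRow] = []
    for key in sorted(by_locus):
        group = by_locus[key]
        if len(group) == 1:
            rows.append(group[0])
            continue
        try:
            (ref, alts), maps = merge_alleles([(r.ref, r.alts) for r in group])
        except ValueError as exc:
            loc = group[0].locus
            raise ValueError(f"{exc} at {loc.contig}:{loc.position + 1}") from None
        entries: dict[str, SvcrEntry] = {}
        for row, amap in zip(group, maps):
            identity = amap == tuple(range(len(amap)))
            for s, e in row.entries.items():
                entries[s] = e if identity else _remap_entry(e, amap)
        rows.append(SvcrRow(group[0].locus, ref, alts, entries))
    return SvcrDataset(samples, rows, contigs)


def merge_rounds(n_inputs: int, branch_factor: int) -> int:
    """Number of merge rounds for S inputs at branch factor N: ceil(log_N S)."""
    if branch_factor < 2:
        raise ValueError("branch factor must be >= 2")
    if n_inputs < 1:
        raise ValueError("need at least one input")
    rounds = 0
    width = 1
    while width < n_inputs:
        width *= branch_factor
        rounds += 1
    return rounds


def hierarchical_merge(
    datasets: Sequence[SvcrDataset], branch_factor: int = 100
) -> tuple[SvcrDataset, int]:
    """Merge in rounds of ``branch_factor`` until one dataset remains.

    Returns (merged dataset, rounds executed). Entry-identical to a single
    flat merge; the default branch factor of 100 reaches a million inputs in
    three rounds.
    """
    if branch_factor < 2:
        raise ValueError("branch factor must be >= 2")
    if not datasets:
        raise ValueError("nothing to merge")
    level = list(datasets)
    rounds = 0
    while len(level) > 1:
        level = [
            merge_svcr(level[i : i + branch_factor])
            for i in range(0, len(level), branch_factor)
        ]
        rounds += 1
    return level[0], rounds


# ---------------------------------------------------------------------------
# densification


def _expand_call(entry: SvcrEntry, n_row_alleles: int) -> DenseCall:
    """Convert a variant entry's local-index fields to global indices."""
    la = entry.la
    gt = tuple(la[g] for g in entry.lgt)
    ad = None
    if entry.lad is not None:
        buf = [0] * n_row_alleles
        for i, d in enumerate(entry.lad):
            buf[la[i]] = d
        ad = tuple(buf)
    pl: tuple[int | None, ...] | None = None
    if entry.lpl is not None:
        ploidy = len(entry.lgt)
        out: list[int | None] = [None] * n_genotypes(n_row_alleles, ploidy)
        for li, gt_local in enumerate(genotype_tuples(len(la), ploidy)):
            out[genotype_index([la[a] for a in gt_local])] = entry.lpl[li]
        pl = tuple(out)
    return DenseCall(gt=gt, gq=entry.gq, dp=entry.dp, ad=ad, pl=pl)


def project_pl_to_local(
    pl_global: Sequence[int | None], la: Sequence[int], ploidy: int
) -> tuple[int, ...]:
    """Project a global PL array back onto local genotype indices."""
    out = []
    for gt_local in genotype_tuples(len(la), ploidy):
        out.append(pl_global[genotype_index([la[a] for a in gt_local])])
    return tuple(out)


def densify(
    ds: SvcrDataset, loci: set[Locus] | None = None
) -> DenseMatrix:
    """Fill sparse entries from each sample's most recent spanning block.

    ``loci`` restricts the output rows; by default all rows carrying at least
    one concrete alternate allele (variant rows) are produced. A sample with
    no record at a row gets a homozygous-reference call if its last reference
    block on the same contig spans the row's position, and a missing call
    otherwise; no block state carries across contigs.
    """
    sample_idx = {s: i for i, s in enumerate(ds.samples)}
    carry: list[SvcrEntry | None] = [None] * len(ds.samples)
    current_contig: str | None = None
    out_rows: list[DenseRow] = []

    for row in ds.rows:
        if row.locus.contig != current_contig:
            carry = [None] * len(ds.samples)
            current_contig = row.locus.contig
        wanted = (
            loci is not None and row.locus in loci
        ) or (loci is None and any(a != NON_REF for a in row.alts))
        calls: list[DenseCall | None] | None = [None] * len(ds.samples) if wanted else None
        for s, entry in row.entries.items():
            i = sample_idx[s]
            if entry.kind == "reference_block":
                carry[i] = entry
                if calls is not None:
                    calls[i] = DenseCall(
                        gt=entry.lgt, gq=entry.gq, dp=entry.dp, filled=False
                    )
            elif calls is not None:
                calls[i] = _expand_call(entry, len(row.alleles))
        if calls is None:
            continue
        for i in range(len(ds.samples)):
            if calls[i] is not None:
                continue
            block = carry[i]
            if block is not None and block.end > row.locus.position:
                ploidy = len(block.lgt)
                calls[i] = DenseCall(
                    gt=(0,) * ploidy, gq=block.gq, dp=block.dp, filled=True
                )
        out_rows.append(DenseRow(row.locus, row.ref, row.alts, calls))
    return DenseMatrix(list(ds.samples), out_rows, list(ds.contigs))


# ---------------------------------------------------------------------------
# export back to gVCF / pVCF


def svcr_to_gvcf(ds: SvcrDataset, sample: str) -> list[GvcfRecord]:
    """Reconstruct one sample's (binned, block-merged) gVCF records.

    Alleles are restored through LA, inverting the conversion and any merges:
    the result is field-for-field identical to the sample's input records
    after GQ binning and block coalescing.
    """
    if sample not in ds.samples:
        raise ValueError(f"unknown sample {sample}")
    records: list[GvcfRecord] = []
    for row in ds.rows:
        entry = row.entries.get(sample)
        if entry is None:
            continue
        alleles = row.alleles
        if any(i >= len(alleles) for i in entry.la):
            raise ValueError(
                f"corrupt entry: LA references allele absent from row at "
                f"{row.locus.contig}:{row.locus.position + 1}"
            )
        if entry.kind == "reference_block":
            records.append(
                GvcfRecord(
                    contig=row.locus.contig,
                    pos=row.locus.position,
                    ref=row.ref,
                    alts=(),
                    gt=entry.lgt,
                    gq=entry.gq,
                    dp=entry.dp,
                    end=entry.end,
                )
            )
        else:
            local_alleles = tuple(alleles[i] for i in entry.la)
            records.append(
                GvcfRecord(
                    contig=row.locus.contig,
                    pos=row.locus.position,
                    ref=local_alleles[0],
                    alts=local_alleles[1:],
                    gt=entry.lgt,
                    gq=entry.gq,
                    dp=entry.dp,
                    ad=entry.lad,
                    pl=entry.lpl,
                )
            )
    return records


def export_pvcf(dm: DenseMatrix) -> str:
    """Render a densified matrix as a conventional multi-sample VCF v4.2.

    Missing calls render as ``./.``; the symbolic <NON_REF> alternate is kept
    so the emitted file parses back to exactly the input matrix.
    """
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
    buf.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
    buf.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
    buf.write(
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">\n'
    )
    for name, length in dm.contigs:
        buf.write(f"##contig=<ID={name},length={length}>\n")
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(dm.samples)
        + "\n"
    )
    for row in dm.rows:
        fields = [
            row.locus.contig,
            str(row.locus.position + 1),
            ".",
            row.ref,
            ",".join(row.alts) if row.alts else ".",
            ".",
            ".",
            ".",
            "GT:AD:DP:GQ:PL",
        ]
        for call in row.calls:
            if call is None:
                fields.append("./.")
                continue
            gt = "/".join(str(a) for a in call.gt)
            ad = "." if call.ad is None else ",".join(str(x) for x in call.ad)
            pl = (
                "."
                if call.pl is None
                else ",".join("." if x is None else str(x) for x in call.pl)
            )
            fields.append(f"{gt}:{ad}:{call.dp}:{call.gq}:{pl}")
        buf.write("\t".join(fields) + "\n")
    return buf.getvalue()


def read_pvcf(path: str | Path) -> DenseMatrix:
    """Parse a multi-sample VCF (as written by export_pvcf) with pysam."""
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        contigs = [(c.name, c.length) for c in vf.header.contigs.values()]
        rows: list[DenseRow] = []
        for rec in vf:
            calls: list[DenseCall | None] = []
            for s in samples:
                call = rec.samples[s]
                gt_raw = call["GT"]
                if gt_raw is None or all(a is None for a in gt_raw):
                    calls.append(None)
                    continue
                gt = tuple(a for a in gt_raw if a is not None)
                ad = call.get("AD")
                pl = call.get("PL")
                calls.append(
                    DenseCall(
                        gt=gt,
                        gq=int(call["GQ"]),
                        dp=int(call["DP"]),
                        ad=None if ad is None or all(x is None for x in ad)
                        else tuple(int(x) for x in ad),
                        pl=None if pl is None or all(x is None for x in pl)
                        else tuple(None if x is None else int(x) for x in pl),
                    )
                )
            rows.append(
                DenseRow(
                    Locus(rec.contig, rec.pos - 1),
                    rec.ref,
                    tuple(rec.alts or ()),
                    calls,
                )
            )
    return DenseMatrix(samples, rows, contigs)
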