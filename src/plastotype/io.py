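"""Readers and writers for every external representation the pipeline touches.

Formats
-------
* aligned multi-FASTA (one plastome per sample, gaps as ``-``)
* sample sheet TSV: sample_id, group, role, mother_id, father_id, fertility
* gene map BED (chrom, start, end, name, category, region), GFF3 import fallback
* minimal VCF 4.2 (haploid GT) with a flat TSV mirror
* KASP marker table TSV in the published VCP dialect

All internal coordinates are 0-based half-open; VCF POS is converted to
1-based only at the boundary.  Sequences are upper-cased on read.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentError,
    CoordinateError,
    EncodingError,
    FormatError,
    MetadataError,
)
from .model import (
    DELETION,
    GROUPS,
    GeneInterval,
    GeneMap,
    MarkerTableRow,
    PlastomeAlignment,
    SampleRecord,
    VariantLocus,
)

PathLike = Union[str, Path]

SHEET_COLUMNS = ["sample_id", "group", "role", "mother_id", "father_id", "fertility"]

MARKER_COLUMNS = [
    "Marker",
    "Variation Loci",
    "AlleleFAM",
    "AlleleHEX",
    "Specific Type",
    "Corresponding Alleles of cpGenome Groups",
    "Primer_AlleleFAM",
    "Primer_AlleleHEX",
    "Primer_Common",
    "Flank1",
    "Flank2",
]

_PRIMER_ALPHABET = frozenset("ACGT")


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path: PathLike) -> list[SampleRecord]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(SHEET_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        records = []
        for row in reader:
            group = row["group"].strip() or None
            if group in ("unknown", "?", "NA"):
                group = None
            if group is not None and group not in GROUPS:
                raise MetadataError(
                    f"sample {row['sample_id']!r}: unknown group {group!r}"
                )
            records.append(
                SampleRecord(
                    sample_id=row["sample_id"].strip(),
                    group=group,
                    role=row["role"].strip() or "cultivar",
                    mother_id=row["mother_id"].strip() or None,
                    father_id=row["father_id"].strip() or None,
                    fertility=row["fertility"].strip() or "unknown",
                )
            )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise MetadataError("duplicate sample ids in sheet")
    return records


def write_sample_sheet(records: Sequence[SampleRecord], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SHEET_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.sample_id,
                    r.group or "",
                    r.role,
                    r.mother_id or "",
                    r.father_id or "",
                    r.fertility,
                ]
            )


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def read_alignment(fasta_path: PathLike, sheet_path: PathLike) -> PlastomeAlignment:
    """Load an aligned multi-FASTA + sample sheet; order follows the sheet."""
    records = read_sample_sheet(sheet_path)
    seqs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    sheet_ids = {r.sample_id for r in records}
    extra = set(seqs) - sheet_ids
    if extra:
        raise MetadataError(f"FASTA ids absent from sample sheet: {sorted(extra)}")
    ordered = []
    for r in records:
        if r.sample_id not in seqs:
            raise MetadataError(f"sheet sample {r.sample_id!r} absent from FASTA")
        ordered.append(seqs[r.sample_id])
    lengths = {len(s) for s in ordered}
    if len(lengths) > 1:
        for r, s in zip(records, ordered):
            if len(s) != len(ordered[0]):
                raise AlignmentError(
                    f"sample {r.sample_id!r} has length {len(s)}, "
                    f"expected {len(ordered[0])}"
                )
    return PlastomeAlignment(samples=records, sequences=ordered)


def write_alignment(
    aln: PlastomeAlignment, fasta_path: PathLike, sheet_path: PathLike
) -> None:
    recs = [
        SeqRecord(Seq(seq), id=s.sample_id, description="")
        for s, seq in zip(aln.samples, aln.sequences)
    ]
    SeqIO.write(recs, str(fasta_path), "fasta")
    write_sample_sheet(aln.samples, sheet_path)


# ---------------------------------------------------------------------------
# gene map
# ---------------------------------------------------------------------------

def read_gene_map(path: PathLike) -> GeneMap:
    """Read a gene map from BED (default) or GFF3 (by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gene_map_gff3(path)
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"gene BED needs >= 5 columns: {line!r}")
            _, start, end, name, category = fields[:5]
            region = fields[5] if len(fields) > 5 and fields[5] else None
            intervals.append(
                GeneInterval(
                    name=name,
                    start=int(start),
                    end=int(end),
                    category=category,
                    region=region,
                )
            )
    return GeneMap(intervals=intervals)


def _read_gene_map_gff3(path: Path) -> GeneMap:
    type_map = {"gene": None, "tRNA": "tRNA", "rRNA": "rRNA", "CDS": "protein_coding"}
    intervals = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(f"malformed GFF3 line: {line!r}")
            ftype = f[2]
            if ftype not in ("gene", "tRNA", "rRNA", "CDS"):
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID") or attrs.get("gene", "?")
            category = type_map[ftype] or attrs.get("gene_biotype", "protein_coding")
            if category not in ("protein_coding", "tRNA", "rRNA"):
                category = "protein_coding"
            intervals.append(
                GeneInterval(
                    name=name,
                    start=int(f[3]) - 1,  # GFF3 is 1-based inclusive
                    end=int(f[4]),
                    category=category,
                )
            )
    return GeneMap(intervals=intervals)


def write_gene_map(gene_map: GeneMap, path: PathLike, chrom: str = "plastome") -> None:
    with open(path, "w") as fh:
        for iv in gene_map.sorted():
            fh.write(
                "\t".join(
                    [chrom, str(iv.start), str(iv.end), iv.name, iv.category,
                     iv.region or ""]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# marker table (published VCP dialect)
# ---------------------------------------------------------------------------

def _parse_allele(value: str) -> str:
    value = value.strip().upper()
    return DELETION if value == "-" else value


def _format_allele(value: str) -> str:
    return "-" if value == DELETION else value


def read_marker_table(path: PathLike) -> list[MarkerTableRow]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        got = reader.fieldnames or []
        missing = [c for c in MARKER_COLUMNS if c not in got]
        if missing:
            raise FormatError(f"marker table missing columns: {missing}")
        rows = []
        for raw in reader:
            rows.append(_parse_marker_row(raw))
    return rows


def _parse_marker_row(raw: dict[str, str]) -> MarkerTableRow:
    marker_id = raw["Marker"].strip()
    spec = raw["Specific Type"].strip()
    corr = raw["Corresponding Alleles of cpGenome Groups"].strip()
    primer_fam = raw["Primer_AlleleFAM"].strip().upper()
    primer_hex = raw["Primer_AlleleHEX"].strip().upper()
    primer_common = raw["Primer_Common"].strip().upper()
    flank1 = (raw.get("Flank1") or "").strip().upper()
    flank2 = (raw.get("Flank2") or "").strip().upper()
    notes: list[str] = []
    for label, primer in (("FAM", primer_fam), ("HEX", primer_hex)):
        if not primer:
            raise FormatError(f"{marker_id}: empty {label} allele primer")
        if set(primer) - _PRIMER_ALPHABET:
            raise FormatError(f"{marker_id}: invalid bases in {label} primer")
    if primer_common:
        if set(primer_common) - _PRIMER_ALPHABET:
            raise FormatError(f"{marker_id}: invalid bases in common primer")
    elif flank1 or flank2:
        # large-InDel two-flank layout: accepted but flagged
        notes.append("missing common primer (two-flank InDel layout)")
    else:
        raise FormatError(f"{marker_id}: empty common primer")
    return MarkerTableRow(
        marker_id=marker_id,
        variation_locus_id=raw["Variation Loci"].strip(),
        allele_fam=_parse_allele(raw["AlleleFAM"]),
        allele_hex=_parse_allele(raw["AlleleHEX"]),
        specific_type=None if spec == "/" else spec,
        corresponding_allele=None if corr == "/" else corr,
        primer_fam=primer_fam,
        primer_hex=primer_hex,
        primer_common=primer_common,
        flank1=flank1,
        flank2=flank2,
        notes=notes,
    )


def write_marker_table(rows: Sequence[MarkerTableRow], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(MARKER_COLUMNS)
        for r in rows:
            w.writerow(
                [
                    r.marker_id,
                    r.variation_locus_id,
                    _format_allele(r.allele_fam),
                    _format_allele(r.allele_hex),
                    r.specific_type if r.specific_type is not None else "/",
                    r.corresponding_allele
                    if r.corresponding_allele is not None
                    else "/",
                    r.primer_fam,
                    r.primer_hex,
                    r.primer_common,
                    r.flank1,
                    r.flank2,
                ]
            )


def packaged_marker_table() -> list[MarkerTableRow]:
    """The VCP marker table shipped with the package (59 validated markers)."""
    from importlib.resources import files

    path = files("plastotype").joinpath("data/vcp_markers.tsv")
    return read_marker_table(str(path))


# ---------------------------------------------------------------------------
# variants: VCF 4.2 + TSV mirror
# ---------------------------------------------------------------------------

def reference_coordinates(ref_sequence: str) -> np.ndarray:
    """Map alignment column -> 0-based ungapped position in the reference.

    For a gap column, the value is the position of the next reference base
    (i.e. the number of reference bases strictly before that column).
    """
    arr = np.frombuffer(ref_sequence.encode("ascii"), dtype="S1")
    is_base = arr != b"-"
    return np.concatenate([[0], np.cumsum(is_base)])[:-1]


def write_variants(
    loci: Sequence[VariantLocus],
    aln: PlastomeAlignment,
    vcf_path: PathLike,
    tsv_path: Optional[PathLike] = None,
    reference_sample: Optional[str] = None,
    chrom: str = "plastome",
) -> None:
    """Emit loci as minimal VCF 4.2 (haploid GT) plus a flat TSV mirror.

    The designated reference sample (default: first in the alignment)
    provides REF alleles and the ungapped coordinate frame.  InDels are
    left-anchored on one reference base, per VCF convention.
    """
    ref_idx = 0 if reference_sample is None else aln.index_of(reference_sample)
    ref_seq = aln.sequences[ref_idx]
    coords = reference_coordinates(ref_seq)
    ref_ungapped = ref_seq.replace("-", "")

    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={len(ref_ungapped)}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(aln.sample_ids),
    ]
    entries = []
    for locus in loci:
        entries.append(_vcf_entry(locus, aln, ref_idx, coords, ref_ungapped, chrom))
    entries.sort(key=lambda e: e[0])
    lines.extend(e[1] for e in entries)
    Path(vcf_path).write_text("\n".join(lines) + "\n")

    if tsv_path is not None:
        _write_variant_tsv(loci, aln, coords, tsv_path)


def _vcf_entry(
    locus: VariantLocus,
    aln: PlastomeAlignment,
    ref_idx: int,
    coords: np.ndarray,
    ref_ungapped: str,
    chrom: str,
) -> tuple[int, str]:
    ref_allele = locus.allele_of(ref_idx)
    if ref_allele is None:
        raise EncodingError(
            f"{locus.locus_id}: reference sample has no resolvable allele"
        )
    start_col = locus.cols[0]
    alts = [a for a in locus.alleles if a != ref_allele]
    needs_anchor = locus.kind == "InDel" or not ref_allele or any(not a for a in alts)
    if needs_anchor:
        anchor_pos = int(coords[start_col]) - 1
        if anchor_pos < 0:
            raise EncodingError(
                f"{locus.locus_id}: no reference base available for left anchor"
            )
        anchor = ref_ungapped[anchor_pos]
        pos = anchor_pos + 1  # 1-based
        ref_field = anchor + ref_allele
        alt_field = [anchor + a for a in alts]
    else:
        pos = int(coords[start_col]) + 1
        ref_field = ref_allele
        alt_field = alts
    allele_order = [ref_allele] + alts
    code = {a: str(i) for i, a in enumerate(allele_order)}
    gts = []
    for i in range(aln.n_samples):
        a = locus.allele_of(i)
        gts.append("." if a is None else code[a])
    line = "\t".join(
        [chrom, str(pos), locus.locus_id, ref_field, ",".join(alt_field) or ".",
         ".", "PASS", ".", "GT"] + gts
    )
    return pos, line


def _write_variant_tsv(
    loci: Sequence[VariantLocus],
    aln: PlastomeAlignment,
    coords: np.ndarray,
    path: PathLike,
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["locus_id", "kind", "aln_start", "aln_end", "ref_pos_1based",
             "alleles", "annotation", "flanks_conserved"]
            + aln.sample_ids
        )
        for locus in loci:
            ann = ""
            if locus.annotation is not None:
                ann = (
                    f"genic:{locus.annotation.gene}"
                    if locus.annotation.genic
                    else "intergenic:%s|%s"
                    % (locus.annotation.between or ("", ""))
                )
            w.writerow(
                [
                    locus.locus_id,
                    locus.kind,
                    locus.cols[0],
                    locus.cols[1],
                    int(coords[locus.cols[0]]) + 1,
                    ",".join(_format_allele(a) for a in locus.alleles),
                    ann,
                    "" if locus.flanks_conserved is None
                    else str(locus.flanks_conserved).lower(),
                ]
                + [
                    "." if locus.allele_of(i) is None
                    else _format_allele(locus.allele_of(i))
                    for i in range(aln.n_samples)
                ]
            )
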