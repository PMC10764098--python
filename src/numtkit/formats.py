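"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open throughout; parsing normalizes
the 1-based inclusive conventions of the tabular alignment dialect, GFF3 and
RepeatMasker ``.out`` files at the boundary.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO

from .core import (
    MINUS,
    PLUS,
    GeneModel,
    GenomeIndex,
    Hsp,
    Numt,
    Phylogeny,
    RepeatInterval,
)

log = logging.getLogger(__name__)

_NONCODING_TYPES = {
    "lncRNA",
    "lnc_RNA",
    "ncRNA",
    "tRNA",
    "rRNA",
    "snRNA",
    "snoRNA",
    "miRNA",
    "pseudogene",
    "misc_RNA",
    "scRNA",
}


class ParseError(ValueError):
    """Raised for malformed records; carries the offending line number."""


def read_hsp_table(path: str | Path) -> list[Hsp]:
    """Parse a 12-column tab-separated alignment table (outfmt-6 dialect).

    Columns: query, subject, %identity, alignment length, mismatches,
    gap opens, qstart, qend, sstart, send, evalue, bitscore (1-based
    inclusive coordinates).  Subject coordinates with sstart > send denote a
    minus-orientation hit and are normalized to an ascending 0-based
    half-open interval with ``orientation == '-'``.
    """
    hsps: list[Hsp] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                identity = float(fields[2])
                aln_length = int(fields[3])
                mismatches = int(fields[4])
                gap_opens = int(fields[5])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if qstart > qend:
                raise ParseError(f"{path}:{lineno}: query coordinates reversed")
            orientation = PLUS if sstart <= send else MINUS
            lo, hi = min(sstart, send), max(sstart, send)
            hsps.append(
                Hsp(
                    mt_start=qstart - 1,
                    mt_end=qend,
                    scaffold=fields[1],
                    n_start=lo - 1,
                    n_end=hi,
                    orientation=orientation,
                    identity=identity,
                    aln_length=aln_length,
                    e_value=evalue,
                    bit_score=bitscore,
                    mismatches=mismatches,
                    gap_opens=gap_opens,
                )
            )
    return hsps


_GFF_ATTR_KEYS = ("gene_name", "gene", "Name", "gene_id", "ID")


def _gff_symbol(attributes: str) -> str | None:
    fields = dict(
        kv.split("=", 1) for kv in attributes.strip().split(";") if "=" in kv
    )
    for key in _GFF_ATTR_KEYS:
        if key in fields and fields[key]:
            return fields[key]
    return None


def read_gene_annotation(path: str | Path) -> list[GeneModel]:
    """Read protein-coding gene models from GFF3 or 6-column BED.

    Noncoding features are dropped; genes lacking a symbol are skipped with
    a warning.  The result is sorted by (scaffold, start).
    """
    path = Path(path)
    genes: list[GeneModel] = []
    if path.suffix.lower() in (".bed", ".bed6"):
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ParseError(f"{path}:{lineno}: BED gene record needs >=4 columns")
                strand = fields[5] if len(fields) >= 6 else PLUS
                if not fields[3]:
                    log.warning("%s:%d: gene without symbol skipped", path, lineno)
                    continue
                genes.append(
                    GeneModel(
                        symbol=fields[3],
                        scaffold=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        strand=strand,
                    )
                )
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
                ftype = fields[2]
                if ftype != "gene":
                    continue
                attrs = fields[8]
                biotype_match = re.search(r"(?:gene_biotype|biotype|gene_type)=([^;]+)", attrs)
                if biotype_match and biotype_match.group(1) != "protein_coding":
                    continue
                if ftype in _NONCODING_TYPES:
                    continue
                symbol = _gff_symbol(attrs)
                if symbol is None:
                    log.warning("%s:%d: gene without symbol skipped", path, lineno)
                    continue
                try:
                    start, end = int(fields[3]), int(fields[4])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from None
                genes.append(
                    GeneModel(
                        symbol=symbol,
                        scaffold=fields[0],
                        start=start - 1,
                        end=end,
                        strand=fields[6] if fields[6] in (PLUS, MINUS) else PLUS,
                    )
                )
    genes.sort(key=lambda g: (g.scaffold, g.start, g.end, g.symbol))
    return genes


def read_repeat_annotation(path: str | Path) -> list[RepeatInterval]:
    """Read TE intervals from a RepeatMasker ``.out`` file or BED.

    RepeatMasker coordinates are 1-based inclusive and follow three header
    lines; BED input is consumed as-is (0-based half-open).  Overlapping
    intervals are retained as given.
    """
    path = Path(path)
    repeats: list[RepeatInterval] = []
    if path.suffix.lower() == ".out":
        with open(path) as fh:
            lines = fh.readlines()
        for lineno, line in enumerate(lines[3:], start=4):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 11:
                raise ParseError(f"{path}:{lineno}: truncated RepeatMasker record")
            try:
                start, end = int(fields[5]), int(fields[6])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from None
            repeats.append(
                RepeatInterval(
                    scaffold=fields[4],
                    start=start - 1,
                    end=end,
                    repeat_class=fields[10],
                )
            )
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ParseError(f"{path}:{lineno}: BED record needs >=3 columns")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from None
                repeats.append(
                    RepeatInterval(
                        scaffold=fields[0],
                        start=start,
                        end=end,
                        repeat_class=fields[3] if len(fields) >= 4 else "Unknown",
                    )
                )
    return repeats


def read_tree(path: str | Path) -> Phylogeny:
    """Read a rooted, ultrametric, strictly bifurcating newick tree (Myr)."""
    with open(path) as fh:
        return read_tree_string(fh.read())


def read_tree_string(newick: str) -> Phylogeny:
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", rooting="force-rooted",
            preserve_underscores=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels in tree: {exc}") from None
    return Phylogeny.from_dendropy(tree)


def read_genome_index(path: str | Path) -> GenomeIndex:
    """Build a scaffold-length table from FASTA or a 2-column TSV."""
    path = Path(path)
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        items = [(rec.id, len(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    else:
        items = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ParseError(f"{path}:{lineno}: scaffold-length TSV needs 2 columns")
                items.append((fields[0], int(fields[1])))
    return GenomeIndex(items)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _format_mt_intervals(intervals: Sequence[tuple[int, int]]) -> str:
    return ",".join(f"{s}-{e}" for s, e in intervals)


def _parse_mt_intervals(text: str) -> tuple[tuple[int, int], ...]:
    out = []
    for part in text.split(","):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


def write_numt_bed(path: str | Path, numts: Sequence[Numt]) -> None:
    """Write NUMTs as BED6 plus mt-interval and species columns."""
    with open(path, "w") as fh:
        for n in numts:
            fh.write(
                "\t".join(
                    [
                        n.scaffold,
                        str(n.n_start),
                        str(n.n_end),
                        n.id or ".",
                        f"{n.identity:.2f}",
                        n.orientation,
                        _format_mt_intervals(n.mt_intervals),
                        n.species or ".",
                    ]
                )
                + "\n"
            )


def read_numt_bed(path: str | Path) -> list[Numt]:
    numts: list[Numt] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ParseError(f"{path}:{lineno}: NUMT BED needs >=7 columns")
            numts.append(
                Numt(
                    id=None if fields[3] == "." else fields[3],
                    scaffold=fields[0],
                    n_start=int(fields[1]),
                    n_end=int(fields[2]),
                    orientation=fields[5],
                    mt_intervals=_parse_mt_intervals(fields[6]),
                    identity=float(fields[4]),
                    species=fields[7] if len(fields) > 7 and fields[7] != "." else None,
                )
            )
    return numts


def write_gene_gff3(path: str | Path, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID=gene:{g.symbol};gene_name={g.symbol};gene_biotype=protein_coding"
            fh.write(
                "\t".join(
                    [
                        g.scaffold,
                        "numtkit",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_repeat_bed(path: str | Path, repeats: Sequence[RepeatInterval]) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(f"{r.scaffold}\t{r.start}\t{r.end}\t{r.repeat_class}\n")


def write_scaffold_lengths(path: str | Path, index: GenomeIndex) -> None:
    with open(path, "w") as fh:
        for name, length in index.items():
            fh.write(f"{name}\t{length}\n")
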