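"""Domain types, strand-aware interval algebra, and file format I/O.

Internal coordinates are 0-based half-open everywhere. Conversion to and
from 1-based inclusive coordinates happens only at the GTF/VCF boundaries.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class AnnotationError(ValueError):
    """Raised for malformed annotation records."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


@dataclass(frozen=True)
class HERVElement:
    """One HERV annotation row: an LTR or internal-region interval."""

    element_id: str
    interval: GenomicInterval
    family: str
    component: str  # "LTR" or "INT"
    provirus_id: str | None = None

    def __post_init__(self) -> None:
        if self.component not in ("LTR", "INT"):
            raise ValueError(f"invalid component {self.component!r}")


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more exon chains (transcripts)."""

    gene_id: str
    interval: GenomicInterval
    strand: str
    biotype: str = "protein_coding"
    transcripts: tuple[tuple[GenomicInterval, ...], ...] = ()

    def __post_init__(self) -> None:
        for chain in self.transcripts:
            prev_end = -1
            for exon in chain:
                if exon.start < prev_end:
                    raise ValueError(f"exons overlap or unsorted in {self.gene_id}")
                prev_end = exon.end


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    individual_id: str
    body_site: str
    sex: str = "unknown"
    ethnicity: str = "unknown"
    age: float = 0.0

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be >= 0")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def overlap_len(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared base pairs between two intervals (0 if different chroms)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def strand_relation(a: GenomicInterval, b: GenomicInterval) -> str:
    """Return 'same', 'opposite', or 'undefined'.

    An unknown strand ('.') never satisfies same or opposite.
    """
    if a.strand == "." or b.strand == ".":
        return "undefined"
    return "same" if a.strand == b.strand else "opposite"


def nearest_tss_distance(pos: int, tss_positions: Sequence[int]) -> int:
    """Minimum absolute distance from ``pos`` to any TSS in a sorted list."""
    if len(tss_positions) == 0:
        raise ValueError("no TSS available")
    i = bisect.bisect_left(tss_positions, pos)
    best = None
    for j in (i - 1, i):
        if 0 <= j < len(tss_positions):
            d = abs(pos - tss_positions[j])
            best = d if best is None else min(best, d)
    return best


class IntervalIndex:
    """Per-chromosome overlap lookup over a static interval set.

    Sorted-by-start lists plus a running max-end prefix; adequate for the
    annotation sizes this toolkit handles.
    """

    def __init__(self, items: Iterable[tuple[GenomicInterval, object]]):
        self._by_chrom: dict[str, list[tuple[int, int, object]]] = {}
        for iv, payload in items:
            self._by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, payload))
        self._maxend: dict[str, list[int]] = {}
        for chrom, rows in self._by_chrom.items():
            rows.sort(key=lambda r: (r[0], r[1]))
            running = []
            m = 0
            for s, e, _ in rows:
                m = max(m, e)
                running.append(m)
            self._maxend[chrom] = running

    def overlapping(self, iv: GenomicInterval) -> list[object]:
        rows = self._by_chrom.get(iv.chrom)
        if not rows:
            return []
        out = []
        # scan left of the insertion point until max-end prefix rules out overlap
        starts = [r[0] for r in rows]
        hi = bisect.bisect_left(starts, iv.end)
        for k in range(hi - 1, -1, -1):
            if self._maxend[iv.chrom][k] <= iv.start:
                break
            s, e, payload = rows[k]
            if e > iv.start:
                out.append(payload)
        out.reverse()
        return out

    def any_overlap(self, iv: GenomicInterval) -> bool:
        return bool(self.overlapping(iv))


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf_genes(path: str | Path) -> list[GeneModel]:
    """Read a Gencode-style GTF into GeneModel records.

    Exon rows are grouped by transcript_id and gene_id; gene spans are taken
    from gene rows when present, otherwise inferred from exons.
    """
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(f"{path}: malformed GTF line {lineno}")
            chrom, _, feature, start_s, end_s, _, strand, _, attr_s = fields[:9]
            try:
                start = int(start_s) - 1  # 1-based inclusive -> 0-based half-open
                end = int(end_s)
            except ValueError as exc:
                raise AnnotationError(f"{path}: bad coordinates at line {lineno}") from exc
            if start >= end:
                raise AnnotationError(f"{path}: start >= end at line {lineno}")
            attrs = _parse_gtf_attributes(attr_s)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise AnnotationError(f"{path}: missing gene_id at line {lineno}")
            rec = genes.setdefault(
                gene_id,
                {"strand": strand, "chrom": chrom, "span": None, "tx": {}, "biotype": attrs.get("gene_type", attrs.get("gene_biotype", "protein_coding")), "attrs": attrs},
            )
            if feature == "gene":
                rec["span"] = (start, end)
                rec["attrs"] = attrs
            elif feature == "exon":
                tx_id = attrs.get("transcript_id", gene_id)
                rec["tx"].setdefault(tx_id, []).append(GenomicInterval(chrom, start, end, strand))
    out = []
    for gene_id, rec in genes.items():
        chains = []
        for tx_id in sorted(rec["tx"]):
            exons = tuple(sorted(rec["tx"][tx_id], key=lambda e: e.start))
            chains.append(exons)
        if rec["span"] is not None:
            span = rec["span"]
        else:
            starts = [e.start for chain in chains for e in chain]
            ends = [e.end for chain in chains for e in chain]
            span = (min(starts), max(ends))
        out.append(
            GeneModel(
                gene_id=gene_id,
                interval=GenomicInterval(rec["chrom"], span[0], span[1], rec["strand"]),
                strand=rec["strand"],
                biotype=rec["biotype"],
                transcripts=tuple(chains),
            )
        )
    out.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    return out


def write_gene_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write GeneModel records as a GTF (gene/transcript/exon rows)."""
    with open(path, "w") as fh:
        fh.write("## hervkit gene annotation\n")
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_type "{g.biotype}";'
            fh.write(
                f"{g.interval.chrom}\thervkit\tgene\t{g.interval.start + 1}\t{g.interval.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for ti, chain in enumerate(g.transcripts, 1):
                tx_id = f"{g.gene_id}.t{ti}"
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{tx_id}"; gene_type "{g.biotype}";'
                fh.write(
                    f"{g.interval.chrom}\thervkit\ttranscript\t{chain[0].start + 1}\t{chain[-1].end}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for exon in chain:
                    fh.write(
                        f"{exon.chrom}\thervkit\texon\t{exon.start + 1}\t{exon.end}\t.\t{g.strand}\t.\t{tattrs}\n"
                    )


# ---------------------------------------------------------------------------
# BED (plain BED6 and the HERV annotation dialect)
# ---------------------------------------------------------------------------


def read_bed6(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise AnnotationError(f"{path}: malformed BED line {lineno}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise AnnotationError(f"{path}: bad coordinates at line {lineno}") from exc
            if start >= end:
                raise AnnotationError(f"{path}: start >= end at line {lineno}")
            strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
            out.append(GenomicInterval(fields[0], start, end, strand))
    return out


def parse_herv_element_name(name: str) -> tuple[str, str, str]:
    """Split a name like ``ERV_645668_LTR12`` into (element_id, family, component).

    Family lists may be comma-joined (concatenated annotation); a ``-int``
    suffix on the first family marks the internal region, anything else is
    treated as an LTR.
    """
    parts = name.split("_", 2)
    if len(parts) < 3 or parts[0] != "ERV":
        raise AnnotationError(f"unparseable HERV element name {name!r}")
    element_id = f"{parts[0]}_{parts[1]}"
    family = parts[2]
    first = family.split(",")[0]
    component = "INT" if first.endswith("-int") else "LTR"
    return element_id, family, component


def read_hervd_bed(path: str | Path) -> list[HERVElement]:
    """Read a HERV annotation BED.

    Column 4 encodes ``ERV_<id>_<family[,family...]>``. Optional column 7
    explicitly overrides the component (LTR/INT); optional column 8 carries a
    provirus grouping key.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise AnnotationError(f"{path}: malformed HERV BED line {lineno}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise AnnotationError(f"{path}: bad coordinates at line {lineno}") from exc
            if start >= end:
                raise AnnotationError(f"{path}: start >= end at line {lineno}")
            element_id, family, component = parse_herv_element_name(fields[3])
            strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
            if len(fields) >= 7 and fields[6] in ("LTR", "INT"):
                component = fields[6]
            provirus_id = fields[7] if len(fields) >= 8 and fields[7] not in ("", ".") else None
            out.append(
                HERVElement(
                    element_id=element_id,
                    interval=GenomicInterval(fields[0], start, end, strand),
                    family=family,
                    component=component,
                    provirus_id=provirus_id,
                )
            )
    return out


def write_hervd_bed(elements: Iterable[HERVElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        for el in elements:
            iv = el.interval
            name = f"{el.element_id}_{el.family}"
            prov = el.provirus_id if el.provirus_id is not None else "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\t{el.component}\t{prov}\n"
            )


def read_annotation(path: str | Path, format: str):
    """Dispatching reader: ``GTF`` -> GeneModel list, ``BED6`` -> intervals,
    ``HERVd-BED`` -> HERVElement list."""
    fmt = format.upper()
    if fmt == "GTF":
        return read_gtf_genes(path)
    if fmt == "BED6":
        return read_bed6(path)
    if fmt in ("HERVD-BED", "HERVD"):
        return read_hervd_bed(path)
    raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# Locus GTF
# ---------------------------------------------------------------------------


def write_locus_gtf(loci, path: str | Path) -> None:
    """Write consensus HERV loci as a GTF (one gene/transcript per locus).

    Labels, when present, are embedded as attributes so the file is
    self-describing; coordinates are 1-based inclusive per GTF convention.
    """
    with open(path, "w") as fh:
        fh.write("## hervkit candidate HERV loci\n")
        for locus in loci:
            attrs = f'gene_id "{locus.locus_id}"; transcript_id "{locus.locus_id}.t1";'
            labels = getattr(locus, "labels", None)
            if labels is not None:
                attrs += f' location "{labels.location}"; origin "{labels.origin}";'
                if labels.fl_subtype is not None:
                    attrs += f' fl_subtype "{labels.fl_subtype}";'
            chrom = locus.exons[0].chrom
            span_start = locus.exons[0].start
            span_end = locus.exons[-1].end
            fh.write(
                f"{chrom}\thervkit\tgene\t{span_start + 1}\t{span_end}\t.\t{locus.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{chrom}\thervkit\ttranscript\t{span_start + 1}\t{span_end}\t.\t{locus.strand}\t.\t{attrs}\n"
            )
            for exon in locus.exons:
                fh.write(
                    f"{chrom}\thervkit\texon\t{exon.start + 1}\t{exon.end}\t.\t{locus.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_genotypes(vcf_path: str | Path):
    """Read biallelic SNVs from a VCF into a GenotypeStudy.

    Multi-allelic records are skipped (count logged); missing GT becomes a
    missing dosage.
    """
    import numpy as np

    from .genetics import GenotypeStudy

    individuals: list[str] = []
    rows = []
    meta = []
    n_skipped = 0
    with open(vcf_path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                individuals = line.rstrip("\n").split("\t")[9:]
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 10:
                continue
            chrom, pos_s, vid, ref, alt = fields[:5]
            if "," in alt or len(ref) != 1 or len(alt) != 1 or alt == ".":
                n_skipped += 1
                continue
            fmt = fields[8].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError:
                n_skipped += 1
                continue
            dos = np.full(len(individuals), np.nan)
            for i, sample_field in enumerate(fields[9:]):
                gt = sample_field.split(":")[gt_idx]
                alleles = gt.replace("|", "/").split("/")
                if "." in alleles or len(alleles) != 2:
                    continue
                dos[i] = sum(int(a) > 0 for a in alleles)
            rows.append(dos)
            meta.append(
                {"variant_id": vid if vid != "." else f"{chrom}:{pos_s}", "chrom": chrom, "pos": int(pos_s), "ref": ref, "alt": alt}
            )
    if n_skipped:
        log.info("read_genotypes: skipped %d non-biallelic/invalid records", n_skipped)
    dosage = np.array(rows, dtype=float) if rows else np.empty((0, len(individuals)))
    variants = pd.DataFrame(meta, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    return GenotypeStudy(dosage=dosage, variants=variants, individuals=list(individuals), n_skipped=n_skipped)


def write_vcf(study, path: str | Path) -> None:
    """Write a GenotypeStudy back to a minimal GT-only VCF."""
    import numpy as np

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(study.individuals) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for vi in range(study.dosage.shape[0]):
            row = study.variants.iloc[vi]
            gts = []
            for d in study.dosage[vi]:
                gts.append("./." if np.isnan(d) else gt_map[int(d)])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# TSV matrices and metadata
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV matrix (first column = feature ids)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", float_format=float_format)


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "individual_id": str})
    return [
        SampleMeta(
            sample_id=str(r.sample_id),
            individual_id=str(r.individual_id),
            body_site=str(r.body_site),
            sex=str(r.sex),
            ethnicity=str(r.ethnicity),
            age=float(r.age),
        )
        for r in df.itertuples()
    ]


def write_sample_meta(meta: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "individual_id": [m.individual_id for m in meta],
            "body_site": [m.body_site for m in meta],
            "sex": [m.sex for m in meta],
            "ethnicity": [m.ethnicity for m in meta],
            "age": [m.age for m in meta],
        }
    ).to_csv(path, sep="\t", index=False)
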