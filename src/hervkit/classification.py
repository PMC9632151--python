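"""Locus taxonomy: location class, origin class, and full-length subtype.

Location is decided against gene bodies (inserted > antisense > intergenic);
origin against overlapped HERV elements grouped by provirus; full-length
loci get one of four mutually exclusive subtypes with a fixed priority
(host-chimeric > upstream-TSS > 3'-readthrough > unit-length).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core_io import GeneModel, GenomicInterval, HERVElement, IntervalIndex, overlap_len
from .detection import HervLocus, LocusLabels, _chain_contains

LOCATIONS = ("antisense", "intergenic", "inserted")
ORIGINS = ("solo-LTR", "truncated", "chimeric", "full-length")
FL_SUBTYPES = ("unit-length", "upstream-TSS", "3p-readthrough", "host-chimeric")


def classify_location(locus: HervLocus, genes: Sequence[GeneModel]) -> str:
    """inserted if any same-strand gene-body overlap; else antisense on any
    opposite-strand overlap; else intergenic."""
    if locus.strand == ".":
        raise ValueError(f"unstranded locus {locus.locus_id}")
    span = locus.span
    same = opposite = False
    for gene in genes:
        if overlap_len(span, gene.interval) <= 0:
            continue
        if gene.strand == locus.strand:
            same = True
        elif gene.strand in ("+", "-"):
            opposite = True
    if same:
        return "inserted"
    if opposite:
        return "antisense"
    return "intergenic"


def _provirus_groups(elements: Sequence[HERVElement]) -> dict[str, list[HERVElement]]:
    """Group elements by provirus id; ungrouped elements are singletons."""
    groups: dict[str, list[HERVElement]] = {}
    for el in elements:
        key = el.provirus_id if el.provirus_id is not None else f"__solo__{el.element_id}"
        groups.setdefault(key, []).append(el)
    return groups


def classify_origin(locus: HervLocus, herv: Sequence[HERVElement]) -> str:
    """Origin from the set of overlapped HERV elements.

    >= 2 distinct provirus groups -> chimeric; a single provirus with its
    5'LTR, internal region, and 3'LTR all overlapped -> full-length; only
    LTR components overlapped with no internal region annotated for that
    provirus -> solo-LTR; anything else -> truncated.
    """
    idx = IntervalIndex((el.interval, el) for el in herv)
    overlapped: list[HERVElement] = []
    seen = set()
    for exon in locus.exons:
        for el in idx.overlapping(exon):
            if el.element_id not in seen:
                seen.add(el.element_id)
                overlapped.append(el)
    if not overlapped:
        raise ValueError(f"locus {locus.locus_id} overlaps no HERV element")

    hit_groups = _provirus_groups(overlapped)
    if len(hit_groups) >= 2:
        return "chimeric"
    (group_key, hit_elements), = hit_groups.items()

    # full annotation of the provirus this group belongs to
    provirus_id = hit_elements[0].provirus_id
    if provirus_id is None:
        annotated = hit_elements
    else:
        annotated = [el for el in herv if el.provirus_id == provirus_id]
    annotated_sorted = sorted(annotated, key=lambda el: el.interval.start)
    has_int = any(el.component == "INT" for el in annotated_sorted)
    hit_ids = {el.element_id for el in hit_elements}

    if has_int:
        ltrs = [el for el in annotated_sorted if el.component == "LTR"]
        ints = [el for el in annotated_sorted if el.component == "INT"]
        five_prime = ltrs[0] if ltrs else None
        three_prime = ltrs[-1] if len(ltrs) >= 2 else None
        full = (
            five_prime is not None
            and three_prime is not None
            and five_prime.element_id in hit_ids
            and three_prime.element_id in hit_ids
            and all(i.element_id in hit_ids for i in ints)
        )
        if full:
            return "full-length"
        return "truncated"
    # no internal region annotated anywhere in the group
    if all(el.component == "LTR" for el in hit_elements):
        return "solo-LTR"
    return "truncated"


def provirus_span(elements: Sequence[HERVElement]) -> GenomicInterval:
    """Genomic span covered by a provirus's annotated elements."""
    start = min(el.interval.start for el in elements)
    end = max(el.interval.end for el in elements)
    return GenomicInterval(elements[0].interval.chrom, start, end, elements[0].interval.strand)


def classify_fl_subtype(
    locus: HervLocus,
    provirus_elements: Sequence[HERVElement],
    genes: Sequence[GeneModel],
) -> str:
    """Subtype of a full-length locus.

    host-chimeric when the locus exon chain is contained in a same-strand
    host transcript's exon chain; else upstream-TSS when the strand-aware 5'
    end lies strictly upstream of the provirus span; else 3'-readthrough when
    the 3' end lies strictly downstream; else unit-length.
    """
    span = provirus_span(provirus_elements)
    for gene in genes:
        if gene.strand != locus.strand:
            continue
        for chain in gene.transcripts:
            if _chain_contains(chain, locus.exons):
                return "host-chimeric"
    if locus.strand == "-":
        five_upstream = locus.exons[-1].end > span.end
        three_downstream = locus.exons[0].start < span.start
    else:
        five_upstream = locus.exons[0].start < span.start
        three_downstream = locus.exons[-1].end > span.end
    if five_upstream:
        return "upstream-TSS"
    if three_downstream:
        return "3p-readthrough"
    return "unit-length"


def classify_all(
    loci: Sequence[HervLocus],
    herv: Sequence[HERVElement],
    genes: Sequence[GeneModel],
) -> list[HervLocus]:
    """Fill LocusLabels for every locus; returns labelled copies."""
    out = []
    idx = IntervalIndex((el.interval, el) for el in herv)
    for locus in loci:
        location = classify_location(locus, genes)
        origin = classify_origin(locus, herv)
        fl_subtype = None
        if origin == "full-length":
            overlapped = []
            seen = set()
            for exon in locus.exons:
                for el in idx.overlapping(exon):
                    if el.element_id not in seen:
                        seen.add(el.element_id)
                        overlapped.append(el)
            provirus_id = overlapped[0].provirus_id
            elements = (
                [el for el in herv if el.provirus_id == provirus_id]
                if provirus_id is not None
                else overlapped
            )
            fl_subtype = classify_fl_subtype(locus, elements, genes)
        out.append(
            HervLocus(
                locus_id=locus.locus_id,
                exons=locus.exons,
                strand=locus.strand,
                supporting_samples=locus.supporting_samples,
                labels=LocusLabels(location=location, origin=origin, fl_subtype=fl_subtype),
            )
        )
    return out


def labels_to_frame(loci: Sequence[HervLocus]) -> pd.DataFrame:
    rows = []
    for locus in loci:
        labels = locus.labels or LocusLabels()
        rows.append(
            {
                "locus_id": locus.locus_id,
                "location": labels.location,
                "origin": labels.origin,
                "fl_subtype": labels.fl_subtype if labels.fl_subtype is not None else "NA",
            }
        )
    return pd.DataFrame(rows, columns=["locus_id", "location", "origin", "fl_subtype"])


def write_labels(loci: Sequence[HervLocus], path: str | Path) -> None:
    labels_to_frame(loci).to_csv(path, sep="\t", index=False)
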