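"""Candidate HERV transcript detection.

Stages: select HERV-informative reads, gate assembled-transcript alignments
on support count and identity, merge per-sample candidates into consensus
loci, require a unique genomic placement overlapping a HERV element, and
call per-body-site expression. Each stage logs every dropped record with a
machine-readable reason so eliminations are attributable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import (
    GeneModel,
    GenomicInterval,
    HERVElement,
    IntervalIndex,
    overlap_len,
)

log = logging.getLogger(__name__)

ExonChain = tuple[GenomicInterval, ...]


@dataclass(frozen=True)
class ReadAlignmentRecord:
    read_id: str
    sample_id: str
    blocks: ExonChain
    is_multimapper: bool = False

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("read must have at least one aligned block")


@dataclass(frozen=True)
class TranscriptHit:
    """One genomic placement of an assembled transcript."""

    exons: ExonChain
    identity: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must be in [0, 1]")


@dataclass(frozen=True)
class TranscriptAlignment:
    transcript_id: str
    sample_id: str
    support_count: int
    hits: tuple[TranscriptHit, ...]

    def __post_init__(self) -> None:
        if self.support_count < 0:
            raise ValueError("support_count must be >= 0")

    @property
    def best_hit(self) -> TranscriptHit:
        return max(self.hits, key=lambda h: (h.score, h.identity))


@dataclass
class LocusLabels:
    location: str | None = None  # antisense | intergenic | inserted
    origin: str | None = None  # solo-LTR | truncated | chimeric | full-length
    fl_subtype: str | None = None  # unit-length | upstream-TSS | 3p-readthrough | host-chimeric


@dataclass
class HervLocus:
    """A merged, strand-assigned consensus transcript locus."""

    locus_id: str
    exons: ExonChain
    strand: str
    supporting_samples: frozenset[str]
    labels: LocusLabels | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("locus must have exons")
        prev = -1
        for e in self.exons:
            if e.start < prev:
                raise ValueError("exons must be disjoint and sorted")
            prev = e.end

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def tss(self) -> int:
        """Strand-aware transcription start: first base on '+', last on '-'."""
        if self.strand == "-":
            return self.exons[-1].end - 1
        return self.exons[0].start


@dataclass
class DropLog:
    """Per-stage accounting of dropped records."""

    records: list[dict] = field(default_factory=list)

    def drop(self, stage: str, item_id: str, reason: str, detail: str = "") -> None:
        self.records.append({"stage": stage, "item_id": item_id, "reason": reason, "detail": detail})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["stage", "item_id", "reason", "detail"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def reason_for(self, item_id: str) -> str | None:
        for rec in self.records:
            if rec["item_id"] == item_id:
                return rec["reason"]
        return None


# ---------------------------------------------------------------------------
# Stage 1: read selection
# ---------------------------------------------------------------------------


def select_herv_reads(
    reads: Iterable[ReadAlignmentRecord],
    herv: Sequence[HERVElement],
    genes: Sequence[GeneModel],
) -> dict[str, set[str]]:
    """Select reads touching a HERV element while avoiding all gene exons.

    A read qualifies iff at least one aligned block overlaps a HERV element
    and no block overlaps any exon of any gene transcript. Strand is ignored
    at this stage.
    """
    herv_idx = IntervalIndex((el.interval, el) for el in herv)
    exon_idx = IntervalIndex(
        (exon, gene)
        for gene in genes
        for chain in gene.transcripts
        for exon in chain
    )
    selected: dict[str, set[str]] = {}
    for read in reads:
        touches_herv = any(herv_idx.any_overlap(b) for b in read.blocks)
        touches_exon = any(exon_idx.any_overlap(b) for b in read.blocks)
        if touches_herv and not touches_exon:
            selected.setdefault(read.sample_id, set()).add(read.read_id)
    return selected


# ---------------------------------------------------------------------------
# Stage 2: alignment filtering
# ---------------------------------------------------------------------------


def alignment_identity(matched: int, mismatched: int, inserted: int = 0, deleted: int = 0) -> float:
    """Fraction of aligned columns that match the reference."""
    for v in (matched, mismatched, inserted, deleted):
        if v < 0:
            raise ValueError("counts must be >= 0")
    denom = matched + mismatched + inserted + deleted
    if matched + mismatched == 0 or denom == 0:
        raise ValueError("no aligned bases")
    return matched / denom


def filter_candidates(
    alignments: Iterable[TranscriptAlignment],
    min_count: int = 5,
    min_identity: float = 0.96,
    drop_log: DropLog | None = None,
) -> list[TranscriptAlignment]:
    """Keep transcripts with support_count > min_count (strict) and best-hit
    identity >= min_identity; retained records carry only the best hit."""
    retained = []
    for aln in alignments:
        if not aln.hits:
            if drop_log:
                drop_log.drop("filter_candidates", aln.transcript_id, "no_hits")
            continue
        best = aln.best_hit
        if aln.support_count <= min_count:
            if drop_log:
                drop_log.drop("filter_candidates", aln.transcript_id, "low_count")
            continue
        if best.identity < min_identity:
            if drop_log:
                drop_log.drop("filter_candidates", aln.transcript_id, "low_identity")
            continue
        retained.append(replace(aln, hits=(best,)))
    return retained


# ---------------------------------------------------------------------------
# Stage 3: consensus merge
# ---------------------------------------------------------------------------


def _chains_overlap(a: ExonChain, b: ExonChain) -> bool:
    if a[0].chrom != b[0].chrom or a[0].strand != b[0].strand:
        return False
    for ea in a:
        for eb in b:
            if overlap_len(ea, eb) > 0:
                return True
    return False


def _union_exons(chains: Sequence[ExonChain]) -> ExonChain:
    """Union of exon intervals, merging overlapping or abutting pieces."""
    ivs = sorted((e for chain in chains for e in chain), key=lambda e: e.start)
    chrom, strand = ivs[0].chrom, ivs[0].strand
    merged: list[list[int]] = []
    for e in ivs:
        if merged and e.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e.end)
        else:
            merged.append([e.start, e.end])
    return tuple(GenomicInterval(chrom, s, t, strand) for s, t in merged)


def merge_candidates(
    per_sample: Mapping[str, Sequence[ExonChain]],
    min_sample_fraction: float = 0.5,
    min_len: int = 200,
    drop_log: DropLog | None = None,
    locus_prefix: str = "CAND",
) -> list[HervLocus]:
    """Single-linkage merge of per-sample exon chains into consensus loci.

    Chains cluster when they share >= 1 bp on the same strand; the consensus
    exon chain is the union of member exons. A cluster is kept iff it is
    supported by >= ceil(min_sample_fraction * n_samples) samples and the
    consensus length is >= min_len.
    """
    n_samples = len(per_sample)
    if n_samples == 0:
        raise ValueError("merge_candidates requires at least one sample")
    items: list[tuple[str, ExonChain]] = []
    for sample_id, chains in per_sample.items():
        for chain in chains:
            items.append((sample_id, chain))
    # union-find over chains, linking same-strand overlaps
    parent = list(range(len(items)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    order = sorted(range(len(items)), key=lambda k: (items[k][1][0].chrom, items[k][1][0].start))
    for ii in range(len(order)):
        i = order[ii]
        span_i = items[i][1]
        for jj in range(ii + 1, len(order)):
            j = order[jj]
            span_j = items[j][1]
            if span_j[0].chrom != span_i[0].chrom or span_j[0].start >= span_i[-1].end:
                break
            if _chains_overlap(span_i, span_j):
                union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(len(items)):
        clusters.setdefault(find(i), []).append(i)

    min_support = math.ceil(min_sample_fraction * n_samples)
    loci: list[HervLocus] = []
    cluster_keys = sorted(
        clusters, key=lambda r: (items[r][1][0].chrom, min(items[m][1][0].start for m in clusters[r]))
    )
    for ci, root in enumerate(cluster_keys, 1):
        members = clusters[root]
        chains = [items[m][1] for m in members]
        samples = frozenset(items[m][0] for m in members)
        exons = _union_exons(chains)
        locus = HervLocus(
            locus_id=f"{locus_prefix}_{ci:06d}",
            exons=exons,
            strand=exons[0].strand,
            supporting_samples=samples,
        )
        span = f"{locus.chrom}:{locus.exons[0].start}-{locus.exons[-1].end}"
        if len(samples) < min_support:
            if drop_log:
                drop_log.drop("merge_candidates", locus.locus_id, "low_recurrence", span)
            continue
        if locus.length < min_len:
            if drop_log:
                drop_log.drop("merge_candidates", locus.locus_id, "short_length", span)
            continue
        loci.append(locus)
    return loci


# ---------------------------------------------------------------------------
# Stage 4: unique placement
# ---------------------------------------------------------------------------


def assign_unique_locus(
    loci: Sequence[HervLocus],
    remap_hits: Mapping[str, Sequence[TranscriptHit]],
    herv: Sequence[HERVElement],
    min_identity: float = 0.96,
    uniqueness_margin: float = 0.01,
    drop_log: DropLog | None = None,
) -> list[HervLocus]:
    """Retain loci with exactly one qualifying genomic placement overlapping
    a HERV element.

    A placement qualifies when its identity passes the gate; a second hit
    within ``uniqueness_margin`` of the best identity also voids uniqueness.
    Retained loci take their final coordinates from the unique hit.
    """
    herv_idx = IntervalIndex((el.interval, el) for el in herv)
    out = []
    for locus in loci:
        span = f"{locus.chrom}:{locus.exons[0].start}-{locus.exons[-1].end}"
        hits = list(remap_hits.get(locus.locus_id, ()))
        if not hits:
            if drop_log:
                drop_log.drop("assign_unique_locus", locus.locus_id, "no_hits", span)
            continue
        # distinct placements: dedupe identical exon chains, keep max identity
        dedup: dict[tuple, TranscriptHit] = {}
        for h in hits:
            key = tuple((e.chrom, e.start, e.end, e.strand) for e in h.exons)
            if key not in dedup or h.identity > dedup[key].identity:
                dedup[key] = h
        placements = sorted(dedup.values(), key=lambda h: -h.identity)
        qualifying = [h for h in placements if h.identity >= min_identity]
        if len(qualifying) != 1:
            if drop_log:
                drop_log.drop("assign_unique_locus", locus.locus_id, "not_unique", span)
            continue
        best = qualifying[0]
        near_ties = [
            h for h in placements if h is not best and h.identity >= best.identity - uniqueness_margin
        ]
        if near_ties:
            if drop_log:
                drop_log.drop("assign_unique_locus", locus.locus_id, "not_unique", span)
            continue
        if not any(herv_idx.any_overlap(e) for e in best.exons):
            if drop_log:
                drop_log.drop("assign_unique_locus", locus.locus_id, "no_herv_overlap", span)
            continue
        out.append(
            HervLocus(
                locus_id=locus.locus_id,
                exons=tuple(best.exons),
                strand=best.exons[0].strand,
                supporting_samples=locus.supporting_samples,
                labels=locus.labels,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Stage 5: expression calling
# ---------------------------------------------------------------------------


def call_expressed(
    counts: pd.DataFrame,
    tpm: pd.DataFrame,
    groups: Mapping[str, str],
    min_count: int = 5,
    min_tpm: float = 0.1,
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-(locus, body_site) expressed flags.

    A locus is expressed in a site iff the fraction of the site's samples
    with raw count > min_count (strict) and TPM >= min_tpm is >= min_fraction.
    """
    if counts.shape != tpm.shape or not counts.index.equals(tpm.index) or not counts.columns.equals(tpm.columns):
        raise ValueError("counts and tpm must share shape and labels")
    sites = sorted(set(groups.values()))
    flags = {}
    for site in sites:
        samples = [s for s in counts.columns if groups.get(s) == site]
        if not samples:
            raise ValueError(f"body site {site!r} has no samples")
        ok = (counts[samples] > min_count) & (tpm[samples] >= min_tpm)
        flags[site] = ok.mean(axis=1) >= min_fraction
    return pd.DataFrame(flags)


# ---------------------------------------------------------------------------
# Stage 6: cross-site de-duplication
# ---------------------------------------------------------------------------


def _chain_contains(outer: ExonChain, inner: ExonChain) -> bool:
    """True when every exon of ``inner`` lies within the exon union of ``outer``."""
    if outer[0].chrom != inner[0].chrom or outer[0].strand != inner[0].strand:
        return False
    for e in inner:
        if not any(oe.start <= e.start and e.end <= oe.end for oe in outer):
            return False
    return True


def deduplicate_loci(
    per_site_loci: Mapping[str, Sequence[HervLocus]],
    id_prefix: str = "HERV",
) -> tuple[list[HervLocus], dict[str, set[str]]]:
    """Merge redundant loci found in several body sites under unified ids.

    Loci cluster when one's exon chain is identical to or contained in the
    other's (same strand); the representative is the longest member. Global
    ids are assigned in deterministic genomic sort order. Returns the
    unified loci and a map global_id -> site memberships.
    """
    items: list[tuple[str, HervLocus]] = []
    for site, loci in per_site_loci.items():
        for locus in loci:
            items.append((site, locus))
    parent = list(range(len(items)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            ci, cj = items[i][1].exons, items[j][1].exons
            if _chain_contains(ci, cj) or _chain_contains(cj, ci):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    clusters: dict[int, list[int]] = {}
    for i in range(len(items)):
        clusters.setdefault(find(i), []).append(i)

    reps = []
    for members in clusters.values():
        rep = max(members, key=lambda m: (items[m][1].length, items[m][1].locus_id))
        sites = {items[m][0] for m in members}
        samples = frozenset().union(*(items[m][1].supporting_samples for m in members))
        reps.append((items[rep][1], sites, samples))
    reps.sort(key=lambda r: (r[0].chrom, r[0].exons[0].start, r[0].exons[-1].end))

    unified = []
    memberships = {}
    for k, (rep, sites, samples) in enumerate(reps, 1):
        gid = f"{id_prefix}_{k:08d}"
        unified.append(
            HervLocus(
                locus_id=gid,
                exons=rep.exons,
                strand=rep.strand,
                supporting_samples=samples,
                labels=rep.labels,
            )
        )
        memberships[gid] = sites
    return unified, memberships


# ---------------------------------------------------------------------------
# Pipeline driver and transcript GTF I/O
# ---------------------------------------------------------------------------


def detect_loci(
    per_sample_alignments: Mapping[str, Sequence[TranscriptAlignment]],
    herv: Sequence[HERVElement],
    min_count: int = 5,
    min_identity: float = 0.96,
    min_sample_fraction: float = 0.5,
    min_len: int = 200,
    uniqueness_margin: float = 0.01,
    drop_log: DropLog | None = None,
) -> list[HervLocus]:
    """Run filter -> merge -> unique placement on per-sample transcript sets.

    The remap hit set for each merged locus is the union of its member
    transcripts' placements (deduplicated); multi-placement members therefore
    void uniqueness exactly as a multi-mapping remap would.
    """
    drop_log = drop_log if drop_log is not None else DropLog()
    filtered: dict[str, list[TranscriptAlignment]] = {}
    all_hits: dict[str, tuple[str, tuple[TranscriptHit, ...]]] = {}
    for sample_id, alns in per_sample_alignments.items():
        kept = filter_candidates(alns, min_count=min_count, min_identity=min_identity, drop_log=drop_log)
        filtered[sample_id] = kept
        for aln in alns:
            all_hits[aln.transcript_id] = (sample_id, aln.hits)
    per_sample_chains = {
        sample_id: [aln.hits[0].exons for aln in alns] for sample_id, alns in filtered.items()
    }
    chain_owner: dict[tuple, list[str]] = {}
    for sample_id, alns in filtered.items():
        for aln in alns:
            key = tuple((e.chrom, e.start, e.end, e.strand) for e in aln.hits[0].exons)
            chain_owner.setdefault(key, []).append(aln.transcript_id)
    loci = merge_candidates(
        per_sample_chains,
        min_sample_fraction=min_sample_fraction,
        min_len=min_len,
        drop_log=drop_log,
    )
    # collect every placement of every member transcript of each locus
    remap_hits: dict[str, list[TranscriptHit]] = {}
    for locus in loci:
        hits: list[TranscriptHit] = []
        for key, tx_ids in chain_owner.items():
            chain = tuple(GenomicInterval(c, s, e, st) for c, s, e, st in key)
            if _chains_overlap(chain, locus.exons):
                for tx_id in tx_ids:
                    hits.extend(all_hits[tx_id][1])
        remap_hits[locus.locus_id] = hits
    return assign_unique_locus(
        loci,
        remap_hits,
        herv,
        min_identity=min_identity,
        uniqueness_margin=uniqueness_margin,
        drop_log=drop_log,
    )


def write_transcript_gtf(alignments: Sequence[TranscriptAlignment], path: str | Path) -> None:
    """Write assembled-transcript alignments with support_count/identity
    attributes; each placement is one transcript entry with a hit_index."""
    with open(path, "w") as fh:
        fh.write("## hervkit assembled transcript alignments\n")
        for aln in alignments:
            for hi, hit in enumerate(aln.hits):
                attrs = (
                    f'gene_id "{aln.transcript_id}"; transcript_id "{aln.transcript_id}";'
                    f' sample_id "{aln.sample_id}"; support_count "{aln.support_count}";'
                    f' identity "{hit.identity:.4f}"; score "{hit.score:.4f}";'
                    f' hit_index "{hi}"; n_hits "{len(aln.hits)}";'
                )
                chrom = hit.exons[0].chrom
                strand = hit.exons[0].strand
                fh.write(
                    f"{chrom}\thervkit\ttranscript\t{hit.exons[0].start + 1}\t{hit.exons[-1].end}\t.\t{strand}\t.\t{attrs}\n"
                )
                for exon in hit.exons:
                    fh.write(
                        f"{chrom}\thervkit\texon\t{exon.start + 1}\t{exon.end}\t.\t{strand}\t.\t{attrs}\n"
                    )


def read_transcript_gtf(path: str | Path) -> list[TranscriptAlignment]:
    from .core_io import _parse_gtf_attributes

    tx: dict[tuple[str, int], dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, _, feature, start_s, end_s, _, strand, _, attr_s = fields[:9]
            if feature != "exon":
                continue
            attrs = _parse_gtf_attributes(attr_s)
            key = (attrs["transcript_id"], int(attrs.get("hit_index", 0)))
            rec = tx.setdefault(
                key,
                {
                    "sample_id": attrs["sample_id"],
                    "support_count": int(attrs["support_count"]),
                    "identity": float(attrs["identity"]),
                    "score": float(attrs.get("score", 0.0)),
                    "exons": [],
                },
            )
            rec["exons"].append(GenomicInterval(chrom, int(start_s) - 1, int(end_s), strand))
    grouped: dict[str, list[tuple[int, dict]]] = {}
    for (tx_id, hit_index), rec in tx.items():
        grouped.setdefault(tx_id, []).append((hit_index, rec))
    out = []
    for tx_id in sorted(grouped):
        hits = []
        sample_id = None
        support = 0
        for _, rec in sorted(grouped[tx_id]):
            sample_id = rec["sample_id"]
            support = rec["support_count"]
            exons = tuple(sorted(rec["exons"], key=lambda e: e.start))
            hits.append(TranscriptHit(exons=exons, identity=rec["identity"], score=rec["score"]))
        hits.sort(key=lambda h: (-h.score, -h.identity))
        out.append(
            TranscriptAlignment(
                transcript_id=tx_id, sample_id=sample_id, support_count=support, hits=tuple(hits)
            )
        )
    return out


def read_locus_gtf(path: str | Path) -> list[HervLocus]:
    """Read a locus GTF written by :func:`hervkit.core_io.write_locus_gtf`."""
    from .core_io import _parse_gtf_attributes

    loci: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, _, feature, start_s, end_s, _, strand, _, attr_s = fields[:9]
            if feature != "exon":
                continue
            attrs = _parse_gtf_attributes(attr_s)
            rec = loci.setdefault(attrs["gene_id"], {"exons": [], "strand": strand, "attrs": attrs})
            rec["exons"].append(GenomicInterval(chrom, int(start_s) - 1, int(end_s), strand))
    out = []
    for locus_id in sorted(loci):
        rec = loci[locus_id]
        attrs = rec["attrs"]
        labels = None
        if "origin" in attrs or "location" in attrs:
            labels = LocusLabels(
                location=attrs.get("location"),
                origin=attrs.get("origin"),
                fl_subtype=attrs.get("fl_subtype"),
            )
        out.append(
            HervLocus(
                locus_id=locus_id,
                exons=tuple(sorted(rec["exons"], key=lambda e: e.start)),
                strand=rec["strand"],
                supporting_samples=frozenset({"NA"}),
                labels=labels,
            )
        )
    out.sort(key=lambda l: (l.chrom, l.exons[0].start))
    return out
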