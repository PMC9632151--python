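"""Seeded generators for every input the pipeline consumes.

The annotation generator plants loci with known origin/location/subtype
geometry plus decoys that each violate exactly one detection gate, so every
stage's behaviour is attributable. Count, genotype, and epigenome
generators plant effects whose recovery the association modules are tested
against. Identical configs (including seed) produce identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    GeneModel,
    GenomicInterval,
    HERVElement,
    SampleMeta,
)
from .detection import HervLocus, TranscriptAlignment, TranscriptHit
from .epigenetics import MethylationTrack, PeakSet
from .genetics import GenotypeStudy

LTR_LEN = 600
INT_LEN = 5000
DECOY_GATES = ("low_identity", "low_count", "short_length", "low_recurrence", "multi_hit")


@dataclass
class SimConfig:
    seed: int = 0
    chrom: str = "chrS"
    slot_spacing: int = 100_000
    n_per_origin: int = 3
    n_decoys_per_gate: int = 2
    n_samples: int = 8  # per body site
    n_sites: int = 2
    base_mean: float = 200.0
    dispersion: float = 0.1
    support_count: int = 20
    identity: float = 0.99
    n_site_specific: int = 2
    n_sex_biased: int = 2
    n_age_assoc: int = 2
    sex_delta: float = 1.0  # log2 units
    age_slope: float = 0.02  # log2 units per year
    qtl_beta: float = 1.0
    maf_low: float = 0.05
    maf_high: float = 0.5
    peak_p_active: float = 0.9
    peak_p_background: float = 0.1
    meth_expressed: float = 0.85
    meth_silent: float = 0.70

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class TruthSet:
    """Machine-readable ground truth for every generated object."""

    loci: list[dict] = field(default_factory=list)
    decoys: list[dict] = field(default_factory=list)
    expression_effects: dict = field(default_factory=dict)
    qtl: list[dict] = field(default_factory=list)
    epigenome: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "loci": self.loci,
                "decoys": self.decoys,
                "expression_effects": self.expression_effects,
                "qtl": self.qtl,
                "epigenome": self.epigenome,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        data = json.loads(Path(path).read_text())
        return cls(
            loci=data["loci"],
            decoys=data["decoys"],
            expression_effects=data.get("expression_effects", {}),
            qtl=data.get("qtl", []),
            epigenome=data.get("epigenome", {}),
        )


# ---------------------------------------------------------------------------
# Annotation geometry
# ---------------------------------------------------------------------------

_ORIGINS = ("solo-LTR", "truncated", "chimeric", "full-length")
_LOCATIONS = ("intergenic", "inserted", "antisense")
_FL_SUBTYPES = ("unit-length", "upstream-TSS", "3p-readthrough")


def simulate_annotation(cfg: SimConfig) -> tuple[list[HERVElement], list[GeneModel], TruthSet]:
    """Plant HERV elements, genes, and locus geometry on a toy chromosome.

    Each planted locus occupies its own slot (``slot_spacing`` apart) so no
    unintended overlaps arise; decoy slots follow the planted ones.
    """
    elements: list[HERVElement] = []
    genes: list[GeneModel] = []
    truth = TruthSet()
    slot = 0

    def slot_base(i: int) -> int:
        return 50_000 + i * cfg.slot_spacing

    eid = 0

    def next_eid() -> str:
        nonlocal eid
        eid += 1
        return f"ERV_{600000 + eid}"

    for origin in _ORIGINS:
        for j in range(cfg.n_per_origin):
            base = slot_base(slot)
            location = _LOCATIONS[j % len(_LOCATIONS)]
            strand = "-" if (origin == "solo-LTR" and location == "antisense") else "+"
            fl_subtype = _FL_SUBTYPES[j % len(_FL_SUBTYPES)] if origin == "full-length" else None
            key = f"L_{origin.replace('-', '')}_{j + 1}"

            if origin == "solo-LTR":
                elements.append(
                    HERVElement(
                        next_eid(),
                        GenomicInterval(cfg.chrom, base, base + LTR_LEN, "+"),
                        "LTR12C",
                        "LTR",
                    )
                )
                locus_iv = (base, base + LTR_LEN)
            elif origin in ("truncated", "full-length"):
                pv = f"PV_{key}"
                elements.append(
                    HERVElement(
                        next_eid(),
                        GenomicInterval(cfg.chrom, base, base + LTR_LEN, "+"),
                        "LTR7",
                        "LTR",
                        pv,
                    )
                )
                elements.append(
                    HERVElement(
                        next_eid(),
                        GenomicInterval(cfg.chrom, base + LTR_LEN, base + LTR_LEN + INT_LEN, "+"),
                        "HERVH-int",
                        "INT",
                        pv,
                    )
                )
                elements.append(
                    HERVElement(
                        next_eid(),
                        GenomicInterval(
                            cfg.chrom,
                            base + LTR_LEN + INT_LEN,
                            base + 2 * LTR_LEN + INT_LEN,
                            "+",
                        ),
                        "LTR7",
                        "LTR",
                        pv,
                    )
                )
                provirus_end = base + 2 * LTR_LEN + INT_LEN  # base + 6200
                if origin == "truncated":
                    locus_iv = (base, base + 3000)  # 5'LTR + part of INT only
                elif fl_subtype == "upstream-TSS":
                    locus_iv = (base - 500, provirus_end)
                elif fl_subtype == "3p-readthrough":
                    locus_iv = (base, provirus_end + 1000)
                else:  # unit-length
                    locus_iv = (base, provirus_end)
            else:  # chimeric: provirus + neighbouring solo LTR
                pv = f"PV_{key}"
                elements.append(
                    HERVElement(
                        next_eid(),
                        GenomicInterval(cfg.chrom, base, base + LTR_LEN, "+"),
                        "LTR7",
                        "LTR",
                        pv,
                    )
                )
                elements.append(
                    HERVElement(
                        next_eid(),
                        GenomicInterval(cfg.chrom, base + LTR_LEN, base + LTR_LEN + INT_LEN, "+"),
                        "HERVH-int",
                        "INT",
                        pv,
                    )
                )
                elements.append(
                    HERVElement(
                        next_eid(),
                        GenomicInterval(
                            cfg.chrom,
                            base + LTR_LEN + INT_LEN,
                            base + 2 * LTR_LEN + INT_LEN,
                            "+",
                        ),
                        "LTR7",
                        "LTR",
                        pv,
                    )
                )
                neighbour_start = base + 2 * LTR_LEN + INT_LEN + 100
                elements.append(
                    HERVElement(
                        next_eid(),
                        GenomicInterval(cfg.chrom, neighbour_start, neighbour_start + LTR_LEN, "+"),
                        "MLT2B4",
                        "LTR",
                    )
                )
                locus_iv = (base + LTR_LEN + INT_LEN, neighbour_start + LTR_LEN)

            if location in ("inserted", "antisense"):
                gene_strand = strand if location == "inserted" else ("-" if strand == "+" else "+")
                gid = f"GENE_{key}"
                g_start, g_end = base - 2000, base + 10_000
                exon1 = GenomicInterval(cfg.chrom, g_start, g_start + 500, gene_strand)
                exon2 = GenomicInterval(cfg.chrom, g_end - 500, g_end, gene_strand)
                genes.append(
                    GeneModel(
                        gene_id=gid,
                        interval=GenomicInterval(cfg.chrom, g_start, g_end, gene_strand),
                        strand=gene_strand,
                        transcripts=((exon1, exon2),),
                    )
                )

            truth.loci.append(
                {
                    "key": key,
                    "chrom": cfg.chrom,
                    "start": locus_iv[0],
                    "end": locus_iv[1],
                    "strand": strand,
                    "origin": origin,
                    "location": location,
                    "fl_subtype": fl_subtype,
                }
            )
            slot += 1

    for gate in DECOY_GATES:
        for j in range(cfg.n_decoys_per_gate):
            base = slot_base(slot)
            key = f"D_{gate}_{j + 1}"
            elements.append(
                HERVElement(
                    next_eid(),
                    GenomicInterval(cfg.chrom, base, base + LTR_LEN, "+"),
                    "LTR12C",
                    "LTR",
                )
            )
            end = base + 150 if gate == "short_length" else base + LTR_LEN
            truth.decoys.append(
                {"key": key, "gate": gate, "chrom": cfg.chrom, "start": base, "end": end, "strand": "+"}
            )
            slot += 1

    elements.sort(key=lambda e: e.interval.start)
    genes.sort(key=lambda g: g.interval.start)
    return elements, genes, truth


def truth_to_loci(truth: TruthSet) -> list[HervLocus]:
    """Materialize planted loci as HervLocus records (for downstream sims)."""
    out = []
    for rec in truth.loci:
        out.append(
            HervLocus(
                locus_id=rec["key"],
                exons=(GenomicInterval(rec["chrom"], rec["start"], rec["end"], rec["strand"]),),
                strand=rec["strand"],
                supporting_samples=frozenset({"truth"}),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Transcript alignments
# ---------------------------------------------------------------------------


def simulate_transcripts(
    cfg: SimConfig,
    truth: TruthSet,
    sample_ids: Sequence[str] | None = None,
) -> dict[str, list[TranscriptAlignment]]:
    """Per-sample assembled-transcript alignments for planted loci and decoys.

    Planted loci appear in every sample with passing support and identity.
    Each decoy violates exactly its planted gate and passes every other one.
    """
    if sample_ids is None:
        sample_ids = [f"S{i + 1:02d}" for i in range(cfg.n_samples)]
    n = len(sample_ids)
    per_sample: dict[str, list[TranscriptAlignment]] = {s: [] for s in sample_ids}

    def chain(rec: dict) -> tuple[GenomicInterval, ...]:
        return (GenomicInterval(rec["chrom"], rec["start"], rec["end"], rec["strand"]),)

    for rec in truth.loci:
        hit = TranscriptHit(exons=chain(rec), identity=cfg.identity, score=100.0)
        for s in sample_ids:
            per_sample[s].append(
                TranscriptAlignment(
                    transcript_id=f"{rec['key']}|{s}",
                    sample_id=s,
                    support_count=cfg.support_count,
                    hits=(hit,),
                )
            )

    low_recurrence_n = math.ceil(0.5 * n) - 1
    for rec in truth.decoys:
        gate = rec["gate"]
        identity = 0.95 if gate == "low_identity" else cfg.identity
        support = 5 if gate == "low_count" else cfg.support_count
        samples = sample_ids[:low_recurrence_n] if gate == "low_recurrence" else sample_ids
        hits = [TranscriptHit(exons=chain(rec), identity=identity, score=100.0)]
        if gate == "multi_hit":
            alt = dict(rec)
            alt["start"], alt["end"] = rec["start"] + 20_000, rec["end"] + 20_000
            hits.append(TranscriptHit(exons=chain(alt), identity=cfg.identity - 0.005, score=95.0))
        for s in samples:
            per_sample[s].append(
                TranscriptAlignment(
                    transcript_id=f"{rec['key']}|{s}",
                    sample_id=s,
                    support_count=support,
                    hits=tuple(hits),
                )
            )
    return per_sample


# ---------------------------------------------------------------------------
# Sample metadata and counts
# ---------------------------------------------------------------------------


def make_meta(cfg: SimConfig) -> list[SampleMeta]:
    """One sample per (body site, individual); individuals recur across
    sites so the mixed model has repeated measures."""
    sites = [f"site{chr(65 + i)}" for i in range(cfg.n_sites)]
    meta = []
    for j in range(cfg.n_samples):
        ind = f"IND{j + 1:03d}"
        sex = "male" if j % 2 == 0 else "female"
        ethnicity = "EA" if (j // 2) % 2 == 0 else "AA"
        age = 20.0 + 50.0 * j / max(cfg.n_samples - 1, 1)
        for site in sites:
            meta.append(
                SampleMeta(
                    sample_id=f"{site}.{ind}",
                    individual_id=ind,
                    body_site=site,
                    sex=sex,
                    ethnicity=ethnicity,
                    age=age,
                )
            )
    return meta


def assign_expression_effects(cfg: SimConfig, locus_keys: Sequence[str]) -> dict[str, dict]:
    """Deterministically assign planted expression effects to loci."""
    effects: dict[str, dict] = {}
    keys = list(locus_keys)
    i = 0
    for _ in range(cfg.n_site_specific):
        if i < len(keys):
            effects[keys[i]] = {"type": "site_specific", "site": "siteA"}
            i += 1
    for _ in range(cfg.n_sex_biased):
        if i < len(keys):
            effects[keys[i]] = {"type": "sex", "delta": cfg.sex_delta}
            i += 1
    for _ in range(cfg.n_age_assoc):
        if i < len(keys):
            effects[keys[i]] = {"type": "age", "slope": cfg.age_slope}
            i += 1
    return effects


def simulate_counts(
    cfg: SimConfig,
    locus_keys: Sequence[str],
    meta: Sequence[SampleMeta],
    effects: Mapping[str, dict] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial counts with planted site/sex/age effects on the
    log2-mean scale. Returns (counts, effective lengths)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    effects = effects or {}
    sample_ids = [m.sample_id for m in meta]
    counts = np.zeros((len(locus_keys), len(meta)), dtype=int)
    mean_age = float(np.mean([m.age for m in meta]))
    for i, key in enumerate(locus_keys):
        eff = effects.get(key)
        for j, m in enumerate(meta):
            log_mu = math.log2(cfg.base_mean)
            if eff is not None:
                if eff["type"] == "site_specific" and m.body_site != eff["site"]:
                    log_mu = -6.0  # effectively silent
                elif eff["type"] == "sex" and m.sex == "male":
                    log_mu += eff["delta"]
                elif eff["type"] == "age":
                    log_mu += eff["slope"] * (m.age - mean_age)
            mu = 2.0**log_mu
            size = 1.0 / cfg.dispersion
            p = size / (size + mu)
            counts[i, j] = rng.negative_binomial(size, p)
    lengths = pd.Series(
        [500 + 100 * (i % 10) for i in range(len(locus_keys))], index=list(locus_keys), dtype=float
    )
    return pd.DataFrame(counts, index=list(locus_keys), columns=sample_ids), lengths


# ---------------------------------------------------------------------------
# Genotypes / QTL study
# ---------------------------------------------------------------------------


def simulate_qtl_study(
    n_individuals: int = 100,
    n_planted: int = 50,
    n_null: int = 500,
    n_cis: int = 50,
    beta: float = 1.0,
    planted_maf: float = 0.3,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, tuple[str, int]], GenotypeStudy, list[dict]]:
    """Expression + genotypes with planted additive cis effects.

    Each locus lives on its own toy chromosome with ``n_cis`` Hardy-Weinberg
    variants in its window; planted loci get y = beta * dosage + noise at
    one randomly chosen variant. Returns (expression, tss map, genotypes,
    planted-truth records).
    """
    rng = np.random.default_rng(seed)
    individuals = [f"IND{i + 1:04d}" for i in range(n_individuals)]
    n_loci = n_planted + n_null
    locus_keys = [f"Q{i + 1:04d}" for i in range(n_loci)]
    expr = np.zeros((n_loci, n_individuals))
    tss_map = {}
    var_rows = []
    dosage_rows = []
    planted = []
    for i, key in enumerate(locus_keys):
        chrom = f"c{key}"
        tss = 500_000
        tss_map[key] = (chrom, tss)
        mafs = rng.uniform(0.05, 0.5, size=n_cis)
        is_planted = i < n_planted
        planted_j = int(rng.integers(0, n_cis)) if is_planted else -1
        if is_planted:
            mafs[planted_j] = planted_maf
        dosages = rng.binomial(2, mafs[:, None], size=(n_cis, n_individuals)).astype(float)
        positions = np.linspace(tss - 900_000, tss + 900_000, n_cis).astype(int)
        for j in range(n_cis):
            var_rows.append(
                {
                    "variant_id": f"v_{key}_{j + 1}",
                    "chrom": chrom,
                    "pos": int(positions[j]),
                    "ref": "A",
                    "alt": "G",
                }
            )
            dosage_rows.append(dosages[j])
        y = rng.normal(0.0, noise_sd, size=n_individuals)
        if is_planted:
            y = y + beta * dosages[planted_j]
            planted.append({"locus_id": key, "variant_id": f"v_{key}_{planted_j + 1}", "beta": beta})
        expr[i] = y
    g = GenotypeStudy(
        dosage=np.vstack(dosage_rows),
        variants=pd.DataFrame(var_rows),
        individuals=individuals,
    )
    expr_df = pd.DataFrame(expr, index=locus_keys, columns=individuals)
    return expr_df, tss_map, g, planted


def simulate_genotypes(
    cfg: SimConfig,
    loci: Sequence[HervLocus],
    n_individuals: int,
    n_cis: int = 20,
    seed: int | None = None,
) -> tuple[GenotypeStudy, list[dict]]:
    """Hardy-Weinberg biallelic genotypes around each locus TSS with one
    planted additive effect per locus (effect size cfg.qtl_beta)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    individuals = [f"IND{j + 1:03d}" for j in range(n_individuals)]
    var_rows, dosage_rows, planted = [], [], []
    for locus in loci:
        tss = locus.tss
        mafs = rng.uniform(cfg.maf_low, cfg.maf_high, size=n_cis)
        planted_j = int(rng.integers(0, n_cis))
        positions = np.linspace(max(tss - 50_000, 1), tss + 50_000, n_cis).astype(int)
        for j in range(n_cis):
            vid = f"v_{locus.locus_id}_{j + 1}"
            var_rows.append(
                {"variant_id": vid, "chrom": locus.chrom, "pos": int(positions[j]), "ref": "A", "alt": "G"}
            )
            dosage_rows.append(rng.binomial(2, mafs[j], size=n_individuals).astype(float))
            if j == planted_j:
                planted.append(
                    {"locus_id": locus.locus_id, "variant_id": vid, "beta": cfg.qtl_beta}
                )
    g = GenotypeStudy(
        dosage=np.vstack(dosage_rows) if dosage_rows else np.empty((0, n_individuals)),
        variants=pd.DataFrame(var_rows, columns=["variant_id", "chrom", "pos", "ref", "alt"]),
        individuals=individuals,
    )
    return g, planted


def simulate_presence(
    locus_keys: Sequence[str],
    individuals: Sequence[str],
    absent_fraction: float = 0.1,
    seed: int = 0,
) -> dict[tuple[str, str], list[bool]]:
    """Contig-hit map: most pairs get one uniquely mapping contig, a random
    fraction only multi-mapping contigs (-> absent)."""
    rng = np.random.default_rng(seed)
    hits = {}
    for locus in locus_keys:
        for ind in individuals:
            if rng.random() < absent_fraction:
                hits[(locus, ind)] = [False, False]
            else:
                hits[(locus, ind)] = [True]
    return hits


# ---------------------------------------------------------------------------
# Epigenome
# ---------------------------------------------------------------------------


def simulate_epigenome(
    cfg: SimConfig,
    loci: Sequence[HervLocus],
    high_expression: Mapping[str, bool],
    marks: Sequence[str] = ("H3K27ac", "H3K9me3"),
    body_site: str = "siteA",
    individual: str = "IND001",
    seed: int | None = None,
) -> tuple[list[PeakSet], MethylationTrack]:
    """Peaks placed near the TSS of high-expression loci with probability
    ``peak_p_active`` (first mark) and ``peak_p_background`` otherwise;
    CpG betas differ between expressed and silent loci by construction."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    peak_sets = []
    for mi, mark in enumerate(marks):
        peaks = []
        for locus in loci:
            active = bool(high_expression.get(locus.locus_id, False)) and mi == 0
            p = cfg.peak_p_active if active else cfg.peak_p_background
            if rng.random() < p:
                center = locus.tss
                peaks.append(GenomicInterval(locus.chrom, max(0, center - 300), center + 300))
        peak_sets.append(
            PeakSet(mark=mark, body_site=body_site, individual=individual, peaks=tuple(peaks))
        )
    rows = []
    for locus in loci:
        expressed = bool(high_expression.get(locus.locus_id, False))
        mean_beta = cfg.meth_expressed if expressed else cfg.meth_silent
        for k in range(20):
            pos = locus.tss - 4000 + k * 400
            if pos < 0:
                continue
            beta = float(np.clip(rng.normal(mean_beta, 0.05), 0.0, 1.0))
            rows.append(
                {"chrom": locus.chrom, "pos": pos, "beta": beta, "coverage": int(rng.integers(10, 50))}
            )
    track = MethylationTrack(records=pd.DataFrame(rows, columns=["chrom", "pos", "beta", "coverage"]))
    return peak_sets, track
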