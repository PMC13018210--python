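"""Domain-hit calling, the three-domain architecture filter, and summaries.

The screen's specificity comes from requiring all three superfold domains
(FN-plug, NHL, YD-shell) to co-occur adjacently, in N-to-C order, on the
same reading frame — in this implementation, within one stop-free peptide
segment, since an in-frame stop between two domains would break the open
reading frame.  Per-domain hits are shortlisted at E <= 1e-10 with at least
30% of the model's match states covered; both thresholds are configurable
but default to the screen's published operating point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import seqio
from .profile_hmm import (
    HMMLibrary,
    ProfileHMMError,
    evalue,
    score_viterbi,
    score_viterbi_only,
)
from .seqio import GenomeRecord, TranslatedFrame, map_to_genome, reverse_complement

DEFAULT_E_MAX = 1e-10
DEFAULT_MIN_MODEL_COV = 0.30
DEFAULT_MAX_GAP = 300  # aa between consecutive domain envelopes
DEFAULT_MAX_OVERLAP_FRAC = 0.5


@dataclass(frozen=True)
class DomainHit:
    """A shortlisted local match of one domain model on one peptide segment."""

    model_name: str
    genome_id: str
    frame: int
    segment_index: int
    pep_start: int  # envelope, 0-based half-open, segment-local
    pep_end: int
    genomic_start: int  # 0-based half-open, forward strand
    genomic_end: int
    strand: str
    score: float  # bits
    evalue: float
    model_coverage: float


@dataclass
class TLPLocus:
    """An in-order, same-frame FN-plug + NHL + YD-shell hit triple."""

    genome_id: str
    hits: tuple[DomainHit, DomainHit, DomainHit]
    strand: str
    genomic_start: int
    genomic_end: int
    score: float  # summed bits
    copy_index: int = 0

    @property
    def frame(self) -> int:
        return self.hits[0].frame


def scan_frames(
    lib: HMMLibrary,
    frames: list[TranslatedFrame],
    E_max: float = DEFAULT_E_MAX,
    min_model_cov: float = DEFAULT_MIN_MODEL_COV,
    max_hits_per_segment: int = 8,
) -> list[DomainHit]:
    """Score every peptide segment against every model in the library.

    Hits are retained iff ``E <= E_max`` and the model span covers at least
    ``min_model_cov`` of the match states.  The E-value search-space factor
    is the total number of segments scanned in this call.  Within a segment
    a model may hit more than once (tandem copies): after each accepted hit
    the envelope is masked and the segment rescored, up to
    ``max_hits_per_segment`` times.
    """
    for model in lib:
        if model.calibration is None:
            raise ProfileHMMError(f"model {model.name!r} is not calibrated")
    n_targets = sum(len(fr.segments) for fr in frames)
    hits: list[DomainHit] = []
    for fr in frames:
        for seg_idx, seg in enumerate(fr.segments):
            for model in lib:
                peptide = seg.peptide
                for _ in range(max_hits_per_segment):
                    # cheap score-only screen; envelopes only for passing hits
                    if evalue(model, score_viterbi_only(model, peptide), n_targets) > E_max:
                        break
                    vh = score_viterbi(model, peptide)
                    E = evalue(model, vh.score, n_targets)
                    cov = (vh.k_end - vh.k_start) / model.M
                    if E > E_max:
                        break
                    if cov >= min_model_cov:
                        gs, ge, strand = map_to_genome(fr, seg, vh.pep_start, vh.pep_end)
                        hits.append(
                            DomainHit(
                                model_name=model.name,
                                genome_id=fr.genome_id,
                                frame=fr.frame,
                                segment_index=seg_idx,
                                pep_start=vh.pep_start,
                                pep_end=vh.pep_end,
                                genomic_start=gs,
                                genomic_end=ge,
                                strand=strand,
                                score=vh.score,
                                evalue=E,
                                model_coverage=cov,
                            )
                        )
                    # mask the envelope so further copies can surface
                    peptide = (
                        peptide[: vh.pep_start]
                        + "X" * (vh.pep_end - vh.pep_start)
                        + peptide[vh.pep_end :]
                    )
    hits.sort(key=lambda h: (h.genome_id, h.genomic_start, h.genomic_end, h.model_name))
    return hits


def call_architecture(
    hits: list[DomainHit],
    expected_order: tuple[str, ...] | None = None,
    max_gap: int = DEFAULT_MAX_GAP,
    max_overlap_frac: float = DEFAULT_MAX_OVERLAP_FRAC,
) -> list[TLPLocus]:
    """Assemble hit triples satisfying the architecture rule into loci.

    Within each (genome, frame, segment), candidate triples must follow
    ``expected_order`` N-to-C, with inter-envelope gaps <= ``max_gap`` aa and
    envelope overlaps of at most ``max_overlap_frac`` of the shorter
    envelope.  Overlapping candidates are resolved greedily by highest
    summed bit score (ties: leftmost genomic start); surviving loci are
    numbered per genome by genomic start.
    """
    if expected_order is None:
        expected_order = ("FN-plug", "NHL", "YD-shell")
    by_segment: dict[tuple, dict[str, list[DomainHit]]] = {}
    for h in hits:
        key = (h.genome_id, h.frame, h.segment_index)
        by_segment.setdefault(key, {}).setdefault(h.model_name, []).append(h)

    def compatible(a: DomainHit, b: DomainHit) -> bool:
        """b follows a in translated (N->C) order, adjacently."""
        if b.pep_start < a.pep_start:
            return False
        gap = b.pep_start - a.pep_end
        if gap > max_gap:
            return False
        overlap = max(0, a.pep_end - b.pep_start)
        shorter = min(a.pep_end - a.pep_start, b.pep_end - b.pep_start)
        return overlap <= max_overlap_frac * shorter

    candidates: list[TLPLocus] = []
    for (genome_id, _, _), by_model in by_segment.items():
        slots = [sorted(by_model.get(name, []), key=lambda h: h.pep_start) for name in expected_order]
        for h1 in slots[0]:
            for h2 in slots[1]:
                if not compatible(h1, h2):
                    continue
                for h3 in slots[2]:
                    if not compatible(h2, h3):
                        continue
                    triple = (h1, h2, h3)
                    candidates.append(
                        TLPLocus(
                            genome_id=genome_id,
                            hits=triple,
                            strand=h1.strand,
                            genomic_start=min(h.genomic_start for h in triple),
                            genomic_end=max(h.genomic_end for h in triple),
                            score=sum(h.score for h in triple),
                        )
                    )

    candidates.sort(key=lambda c: (-c.score, c.genome_id, c.genomic_start))
    accepted: list[TLPLocus] = []
    used: set[tuple] = set()
    for cand in candidates:
        ids = {(id(h)) for h in cand.hits}
        clash = any(
            a.genome_id == cand.genome_id
            and not (cand.genomic_end <= a.genomic_start or a.genomic_end <= cand.genomic_start)
            for a in accepted
        )
        if clash or ids & used:
            continue
        accepted.append(cand)
        used |= ids
    accepted.sort(key=lambda c: (c.genome_id, c.genomic_start, c.genomic_end))
    copy_counter: dict[str, int] = {}
    loci = []
    for c in accepted:
        copy_counter[c.genome_id] = copy_counter.get(c.genome_id, 0) + 1
        loci.append(replace_copy(c, copy_counter[c.genome_id]))
    return loci


def replace_copy(locus: TLPLocus, copy_index: int) -> TLPLocus:
    locus.copy_index = copy_index
    return locus


def find_downstream_orf(
    locus: TLPLocus,
    genome: GenomeRecord,
    window: int = 5000,
    min_orf: int = 150,
    table: str | int = "Standard",
) -> list[tuple[int, int, str, int]]:
    """Naive ORFs immediately downstream of the locus, same strand.

    Scans 5'->3' from the locus 3' end for ATG..stop open reading frames
    whose start lies within ``window`` nt and whose length (ATG through stop
    codon) is >= ``min_orf`` nt.  Returns (genomic_start, genomic_end,
    strand, length) tuples on the forward strand, sorted by proximity.
    These downstream neighbours are candidate immunity genes.
    """
    from Bio.Data import CodonTable

    table_id = seqio.GENETIC_CODES.get(table)
    stops = set(CodonTable.unambiguous_dna_by_id[table_id].stop_codons)
    n = len(genome.sequence)
    if locus.strand == "+":
        seq = genome.sequence
        origin = locus.genomic_end  # 3' end on the coding strand
    else:
        seq = reverse_complement(genome.sequence)
        origin = n - locus.genomic_start
    orfs = []
    limit = min(n, origin + window)
    for s in range(origin, limit):
        if seq[s : s + 3] != "ATG":
            continue
        for t in range(s + 3, n - 2, 3):
            codon = seq[t : t + 3]
            if codon in stops:
                length = t + 3 - s
                if length >= min_orf:
                    orfs.append((s, t + 3))
                break
    out = []
    for s, e in orfs:
        if locus.strand == "+":
            out.append((s, e, "+", e - s))
        else:
            out.append((n - e, n - s, "-", e - s))
    return out


@dataclass
class PrevalenceSummary:
    """Per-taxon screening tallies plus the per-genome locus table."""

    per_group: pd.DataFrame  # taxon_group, genomes_screened, genomes_positive, percent
    copy_histogram: dict[int, int]  # copies -> number of genomes with that many
    per_genome: pd.DataFrame  # genome_id, species, taxon_group, n_loci
    multi_copy_genomes: list[str] = field(default_factory=list)


def summarize_prevalence(loci: list[TLPLocus], metadata: pd.DataFrame) -> PrevalenceSummary:
    """Tally locus prevalence and copy number by taxon group."""
    counts = pd.Series([l.genome_id for l in loci]).value_counts() if loci else pd.Series(dtype=int)
    per_genome = metadata.copy()
    per_genome["n_loci"] = per_genome["genome_id"].map(counts).fillna(0).astype(int)
    rows = []
    for group, sub in per_genome.groupby("taxon_group", sort=True):
        screened = len(sub)
        positive = int((sub["n_loci"] > 0).sum())
        rows.append(
            {
                "taxon_group": group,
                "genomes_screened": screened,
                "genomes_positive": positive,
                "percent": 100.0 * positive / screened if screened else 0.0,
            }
        )
    hist_src = per_genome.loc[per_genome["n_loci"] > 0, "n_loci"]
    histogram = {int(k): int(v) for k, v in hist_src.value_counts().sort_index().items()}
    multi = sorted(per_genome.loc[per_genome["n_loci"] > 1, "genome_id"].tolist())
    return PrevalenceSummary(
        per_group=pd.DataFrame(rows, columns=["taxon_group", "genomes_screened", "genomes_positive", "percent"]),
        copy_histogram=histogram,
        per_genome=per_genome,
        multi_copy_genomes=multi,
    )


# --- tabular / GFF3 output --------------------------------------------------

HIT_COLUMNS = [
    "model_name", "genome_id", "frame", "segment_index", "pep_start", "pep_end",
    "genomic_start", "genomic_end", "strand", "score", "evalue", "model_coverage",
]


def hits_to_dataframe(hits: list[DomainHit]) -> pd.DataFrame:
    return pd.DataFrame([h.__dict__ for h in hits], columns=HIT_COLUMNS)


def write_hits_tsv(hits: list[DomainHit], path: str | Path) -> None:
    df = hits_to_dataframe(hits)
    df["score"] = df["score"].map(lambda v: f"{v:.4f}")
    df["evalue"] = df["evalue"].map(lambda v: f"{v:.6e}")
    df["model_coverage"] = df["model_coverage"].map(lambda v: f"{v:.4f}")
    df.to_csv(path, sep="\t", index=False)


def loci_to_gff3(loci: list[TLPLocus]) -> str:
    """GFF3 (1-based inclusive) with one protein_match row per locus and domain."""
    lines = ["##gff-version 3"]
    for locus in loci:
        lid = f"TLP_{locus.genome_id}_{locus.copy_index}"
        attrs = f"ID={lid};copy_index={locus.copy_index};frame={locus.frame}"
        lines.append(
            "\t".join(
                [
                    locus.genome_id, "tlpscan", "protein_match",
                    str(locus.genomic_start + 1), str(locus.genomic_end),
                    f"{locus.score:.4f}", locus.strand, ".", attrs,
                ]
            )
        )
        for h in locus.hits:
            lines.append(
                "\t".join(
                    [
                        locus.genome_id, "tlpscan", "protein_match",
                        str(h.genomic_start + 1), str(h.genomic_end),
                        f"{h.score:.4f}", h.strand, ".",
                        f"ID={lid}.{h.model_name};Parent={lid};model={h.model_name}"
                        f";model_coverage={h.model_coverage:.4f};evalue={h.evalue:.6e}",
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def write_loci_gff3(loci: list[TLPLocus], path: str | Path) -> None:
    Path(path).write_text(loci_to_gff3(loci))


def prevalence_to_json(summary: PrevalenceSummary) -> str:
    payload = {
        "per_group": summary.per_group.to_dict(orient="records"),
        "copy_histogram": {str(k): v for k, v in summary.copy_histogram.items()},
        "multi_copy_genomes": summary.multi_copy_genomes,
    }
    return json.dumps(payload, indent=2, sort_keys=True)
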