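"""Synthetic genomes, alignments and truth tables for the TLP screen.

The generator stands in for a genome-database screen: it plants
reverse-translated three-domain cassettes (FN-plug + linker + NHL + linker +
YD-shell, sampled from the very HMMs used for scanning) on either strand of
i.i.d. background DNA, together with decoys exercising each failure mode the
architecture rule must reject — shuffled domain order, domains split across
strands, and partial cassettes — and, optionally, a small immunity-like ORF
immediately downstream of each cassette on the same strand.  Every planted
element is recorded in a truth table so sensitivity and specificity are
measurable exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from . import seqio
from .profile_hmm import (
    AMINO_ACIDS,
    Alignment,
    HMMLibrary,
    ProfileHMM,
    build_hmm,
    calibrate,
    slice_alignment_by_reference,
)
from .seqio import GenomeRecord, reverse_complement

#: reference-residue boundaries of the three superfold domains
DOMAIN_BOUNDARIES = {
    "FN-plug": (673, 928),
    "NHL": (929, 1255),
    "YD-shell": (1256, 2139),
}


class GeneratorError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Benchmark layout; the defaults are the fixed acceptance benchmark."""

    n_genomes: int = 20
    genome_length: int = 200_000
    gc_content: float = 0.5
    n_cassettes: int = 30
    n_decoy_order: int = 10
    n_decoy_strand_split: int = 10
    n_decoy_partial: int = 10
    linker_len: tuple[int, int] = (5, 30)  # aa, uniform inclusive bounds
    codon_mode: str = "uniform"  # or "gc_biased"
    genetic_code: str | int = "Standard"
    plant_immunity_orf: bool = True
    immunity_distance: tuple[int, int] = (50, 400)  # nt downstream of cassette
    immunity_len: tuple[int, int] = (60, 150)  # codons between ATG and stop
    taxon_groups: tuple[str, ...] = ("taxon_A", "taxon_B", "taxon_C", "taxon_D")
    positive_rates: dict[str, float] | None = None  # rate-driven mode
    seed: int = 1337

    def __post_init__(self) -> None:
        if min(
            self.n_genomes, self.genome_length, self.n_cassettes,
            self.n_decoy_order, self.n_decoy_strand_split, self.n_decoy_partial,
        ) < 0:
            raise GeneratorError("counts and sizes must be non-negative")
        if not 0.0 <= self.gc_content <= 1.0:
            raise GeneratorError("gc_content must lie in [0, 1]")


@dataclass
class TruthRecord:
    genome_id: str
    kind: str  # cassette | decoy_order | decoy_strand_split | decoy_partial | immunity_orf
    start: int  # 0-based half-open genomic interval of the planted element
    end: int
    strand: str
    domains: tuple[tuple[str, int, int, str], ...] = ()  # (model, start, end, strand)


def truth_to_dataframe(truth: list[TruthRecord]) -> pd.DataFrame:
    rows = []
    for t in truth:
        rows.append(
            {
                "genome_id": t.genome_id,
                "kind": t.kind,
                "start": t.start,
                "end": t.end,
                "strand": t.strand,
                "domains": ";".join(f"{n}:{s}-{e}:{st}" for n, s, e, st in t.domains),
            }
        )
    return pd.DataFrame(rows, columns=["genome_id", "kind", "start", "end", "strand", "domains"])


def write_truth(truth: list[TruthRecord], tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    truth_to_dataframe(truth).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = [t.__dict__ for t in truth]
        Path(json_path).write_text(json.dumps(payload, indent=2, default=list))


# --- superfold-like alignment fixture ---------------------------------------

def generate_superfold_alignment(
    n_rows: int = 8,
    ref_len: int = 2139,
    reference_id: str = "ref_superfold",
    sub_rate: float = 0.25,
    del_rate: float = 0.02,
    seed: int = 20339,
) -> Alignment:
    """A family of related superfold-like sequences, aligned.

    The (ungapped) reference spans ``ref_len`` residues so the standard
    domain boundaries (FN-plug 673-928, NHL 929-1255, YD-shell 1256-2139)
    can be sliced from it.  Non-reference rows substitute residues at
    ``sub_rate`` and carry deletions at ``del_rate``; there are no
    insertions relative to the reference, so the reference row is gap-free.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    ancestor = rng.integers(0, 20, size=ref_len)
    rows = [(reference_id, "".join(aa[ancestor]))]
    for r in range(1, n_rows):
        seq = []
        for i in range(ref_len):
            u = rng.random()
            if u < del_rate:
                seq.append("-")
            elif u < del_rate + sub_rate:
                seq.append(aa[rng.integers(0, 20)])
            else:
                seq.append(aa[ancestor[i]])
        rows.append((f"homolog_{r:02d}", "".join(seq)))
    return Alignment(rows=rows, reference_id=reference_id)


def build_superfold_library(
    aln: Alignment,
    boundaries: dict[str, tuple[int, int]] | None = None,
    calibration_seed: int = 4242,
    n_cal: int = 200,
    len_cal: int = 400,
) -> HMMLibrary:
    """Split the alignment at the domain boundaries and build+calibrate models."""
    if boundaries is None:
        boundaries = DOMAIN_BOUNDARIES
    models = []
    for i, (name, (start, end)) in enumerate(boundaries.items()):
        sub = slice_alignment_by_reference(aln, start, end)
        hmm = build_hmm(sub, name=name)
        calibrate(hmm, n_cal=n_cal, len_cal=len_cal, seed=calibration_seed + i)
        models.append(hmm)
    return HMMLibrary(models=models, architecture=tuple(boundaries))


# --- sequence-level emitters -------------------------------------------------

def emit_from_hmm(hmm: ProfileHMM, seed: int | np.random.Generator) -> str:
    """Sample one peptide from the model's match/insert/delete process.

    Starts at the first match state and runs the transition-governed walk to
    the last state; deterministic for an integer seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    M = hmm.M
    out: list[str] = []
    k, state = 0, "M"
    while True:
        if state == "M":
            out.append(AMINO_ACIDS[rng.choice(20, p=hmm.match_emissions[k])])
            if k == M - 1:
                break
            j = rng.choice(3, p=hmm.transitions[k, 0:3])
            state = ("M", "I", "D")[j]
            if state != "I":
                k += 1
        elif state == "I":
            out.append(AMINO_ACIDS[rng.choice(20, p=hmm.insert_emissions)])
            j = rng.choice(2, p=hmm.transitions[k, 3:5])
            if j == 0:
                state = "M"
                k += 1
        else:  # delete: silent
            if k == M - 1:
                break
            j = rng.choice(2, p=hmm.transitions[k, 5:7])
            state = "M" if j == 0 else "D"
            k += 1
    return "".join(out)


def _codon_choices(table: str | int) -> dict[str, list[str]]:
    table_id = seqio.GENETIC_CODES[table]
    fwd = CodonTable.unambiguous_dna_by_id[table_id].forward_table
    choices: dict[str, list[str]] = {}
    for codon, aa in sorted(fwd.items()):
        choices.setdefault(aa, []).append(codon)
    return choices


def reverse_translate(
    peptide: str,
    table: str | int = "Standard",
    codon_mode: str = "uniform",
    seed: int | np.random.Generator = 0,
) -> str:
    """Map each residue to a synonymous codon; never emits stop codons.

    ``codon_mode="gc_biased"`` weights synonymous codons by 2**(GC count),
    emulating a high-GC genome's codon usage.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    choices = _codon_choices(table)
    codons = []
    for aa in peptide:
        opts = choices.get(aa)
        if not opts:
            raise GeneratorError(f"residue {aa!r} has no codon in table {table!r}")
        if codon_mode == "uniform":
            codons.append(opts[rng.integers(len(opts))])
        elif codon_mode == "gc_biased":
            w = np.array([2.0 ** sum(c in "GC" for c in codon) for codon in opts])
            codons.append(opts[rng.choice(len(opts), p=w / w.sum())])
        else:
            raise GeneratorError(f"unknown codon_mode {codon_mode!r}")
    return "".join(codons)


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def _background_dna(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)]


# --- benchmark assembly -------------------------------------------------------

def _build_cassette(
    lib: HMMLibrary,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    order: tuple[str, ...],
    subset: tuple[str, ...] | None = None,
):
    """DNA for a (possibly shuffled or partial) cassette plus its aa layout."""
    names = [n for n in order if subset is None or n in subset]
    parts: list[tuple[str | None, str]] = []  # (model name or None for linker, peptide)
    lo, hi = cfg.linker_len
    for i, name in enumerate(names):
        if i > 0:
            parts.append((None, _random_peptide(rng, int(rng.integers(lo, hi + 1)))))
        parts.append((name, emit_from_hmm(lib[name], rng)))
    full = "".join(p for _, p in parts)
    layout = []
    off = 0
    for name, pep in parts:
        if name is not None:
            layout.append((name, off, off + len(pep)))
        off += len(pep)
    dna = reverse_translate(full, cfg.genetic_code, cfg.codon_mode, rng)
    return dna, layout


def _place(
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    genome_length: int,
    elem_len: int,
    margin: int = 30,
    max_tries: int = 200,
) -> int:
    hi = genome_length - elem_len
    if hi < 0:
        raise GeneratorError("cassettes don't fit genome length")
    for _ in range(max_tries):
        pos = int(rng.integers(0, hi + 1))
        if all(pos + elem_len + margin <= s or e + margin <= pos for s, e in occupied):
            occupied.append((pos, pos + elem_len))
            return pos
    raise GeneratorError("cassettes don't fit genome length")


def generate_benchmark(
    cfg: GeneratorConfig,
    lib: HMMLibrary,
) -> tuple[list[GenomeRecord], pd.DataFrame, list[TruthRecord]]:
    """Generate genomes + metadata + truth table for a full screen benchmark.

    In the default count-driven mode, ``n_cassettes`` true cassettes and the
    configured decoys are scattered over genomes uniformly at random.  If
    ``cfg.positive_rates`` maps taxon groups to rates, each genome instead
    carries one cassette with its group's probability (decoy counts still
    apply), which gives direct control over per-group prevalence.
    """
    rng = np.random.default_rng(cfg.seed)
    order = tuple(lib.architecture)
    genome_ids = [f"g{i + 1:03d}" for i in range(cfg.n_genomes)]
    groups = [cfg.taxon_groups[i % len(cfg.taxon_groups)] for i in range(cfg.n_genomes)]
    seqs = {gid: _background_dna(rng, cfg.genome_length, cfg.gc_content) for gid in genome_ids}
    occupied: dict[str, list[tuple[int, int]]] = {gid: [] for gid in genome_ids}
    truth: list[TruthRecord] = []

    def overwrite(gid: str, pos: int, dna: str) -> None:
        seqs[gid][pos : pos + len(dna)] = list(dna)

    def plant_immunity(gid: str, cstart: int, cend: int, strand: str) -> None:
        ncod = int(rng.integers(cfg.immunity_len[0], cfg.immunity_len[1] + 1))
        body = reverse_translate(_random_peptide(rng, ncod), cfg.genetic_code, cfg.codon_mode, rng)
        orf = "ATG" + body + "TAA"
        dist = int(rng.integers(cfg.immunity_distance[0], cfg.immunity_distance[1] + 1))
        L = len(orf)
        if strand == "+":
            pos = cend + dist
            if pos + L > cfg.genome_length:
                return  # no room downstream; the cassette stays valid without one
            ins = orf
        else:
            pos = cstart - dist - L
            if pos < 0:
                return
            ins = reverse_complement(orf)
        if not all(pos + L + 10 <= s or e + 10 <= pos for s, e in occupied[gid]):
            return
        occupied[gid].append((pos, pos + L))
        overwrite(gid, pos, ins)
        truth.append(TruthRecord(genome_id=gid, kind="immunity_orf", start=pos, end=pos + L, strand=strand))

    def plant_element(gid: str, kind: str, subset=None, shuffle=False) -> None:
        elem_order = order
        if shuffle:
            wrong = [p for p in permutations(order) if p != order]
            elem_order = wrong[rng.integers(len(wrong))]
        dna, layout = _build_cassette(lib, cfg, rng, elem_order, subset)
        strand = "+" if rng.random() < 0.5 else "-"
        pos = _place(rng, occupied[gid], cfg.genome_length, len(dna))
        overwrite(gid, pos, dna if strand == "+" else reverse_complement(dna))
        L = len(dna)
        domains = []
        for name, a0, a1 in layout:
            if strand == "+":
                s, e = pos + 3 * a0, pos + 3 * a1
            else:
                s, e = pos + L - 3 * a1, pos + L - 3 * a0
            domains.append((name, s, e, strand))
        truth.append(
            TruthRecord(
                genome_id=gid, kind=kind, start=pos, end=pos + L,
                strand=strand, domains=tuple(domains),
            )
        )
        if kind == "cassette" and cfg.plant_immunity_orf:
            plant_immunity(gid, pos, pos + L, strand)

    def plant_strand_split(gid: str) -> None:
        dna_a, layout_a = _build_cassette(lib, cfg, rng, order, subset=order[:2])
        dna_b, layout_b = _build_cassette(lib, cfg, rng, order, subset=order[2:])
        strand = "+" if rng.random() < 0.5 else "-"
        anti = "-" if strand == "+" else "+"
        gap = int(rng.integers(10, 60))
        total = len(dna_a) + gap + len(dna_b)
        pos = _place(rng, occupied[gid], cfg.genome_length, total)
        overwrite(gid, pos, dna_a if strand == "+" else reverse_complement(dna_a))
        pos_b = pos + len(dna_a) + gap
        overwrite(gid, pos_b, dna_b if anti == "+" else reverse_complement(dna_b))
        domains = []
        for name, a0, a1 in layout_a:
            if strand == "+":
                s, e = pos + 3 * a0, pos + 3 * a1
            else:
                s, e = pos + len(dna_a) - 3 * a1, pos + len(dna_a) - 3 * a0
            domains.append((name, s, e, strand))
        for name, a0, a1 in layout_b:
            if anti == "+":
                s, e = pos_b + 3 * a0, pos_b + 3 * a1
            else:
                s, e = pos_b + len(dna_b) - 3 * a1, pos_b + len(dna_b) - 3 * a0
            domains.append((name, s, e, anti))
        truth.append(
            TruthRecord(
                genome_id=gid, kind="decoy_strand_split", start=pos,
                end=pos_b + len(dna_b), strand=strand, domains=tuple(domains),
            )
        )

    if cfg.positive_rates is not None:
        for gid, group in zip(genome_ids, groups):
            if rng.random() < cfg.positive_rates.get(group, 0.0):
                plant_element(gid, "cassette")
    else:
        for _ in range(cfg.n_cassettes):
            plant_element(genome_ids[rng.integers(cfg.n_genomes)], "cassette")
    for _ in range(cfg.n_decoy_order):
        plant_element(genome_ids[rng.integers(cfg.n_genomes)], "decoy_order", shuffle=True)
    for _ in range(cfg.n_decoy_strand_split):
        plant_strand_split(genome_ids[rng.integers(cfg.n_genomes)])
    for _ in range(cfg.n_decoy_partial):
        k = 1 + int(rng.integers(2))  # one or two domains, correct order
        start = int(rng.integers(len(order) - k + 1))
        plant_element(
            genome_ids[rng.integers(cfg.n_genomes)], "decoy_partial",
            subset=order[start : start + k],
        )

    genomes = [
        GenomeRecord(
            id=gid,
            sequence="".join(seqs[gid].tolist()),
            species=f"Synthetica exempli {i + 1}",
            taxon_group=groups[i],
        )
        for i, gid in enumerate(genome_ids)
    ]
    metadata = pd.DataFrame(
        {
            "genome_id": genome_ids,
            "species": [g.species for g in genomes],
            "taxon_group": groups,
        }
    )
    truth.sort(key=lambda t: (t.genome_id, t.start))
    return genomes, metadata, truth


def evaluate_recovery(loci, truth: list[TruthRecord], min_jaccard: float = 0.8) -> dict:
    """Match called loci against planted cassettes.

    A cassette counts as recovered when a locus in the same genome, on the
    same strand, overlaps it with Jaccard index >= ``min_jaccard``.  Loci
    matching no cassette are counted as false loci (decoy or background).
    """
    cassettes = [t for t in truth if t.kind == "cassette"]
    matched_truth: set[int] = set()
    matched_loci: set[int] = set()
    for li, locus in enumerate(loci):
        for ti, t in enumerate(cassettes):
            if locus.genome_id != t.genome_id or locus.strand != t.strand:
                continue
            inter = max(0, min(locus.genomic_end, t.end) - max(locus.genomic_start, t.start))
            union = (locus.genomic_end - locus.genomic_start) + (t.end - t.start) - inter
            if union > 0 and inter / union >= min_jaccard:
                matched_truth.add(ti)
                matched_loci.add(li)
    n_true = len(cassettes)
    return {
        "n_cassettes": n_true,
        "n_recovered": len(matched_truth),
        "sensitivity": len(matched_truth) / n_true if n_true else float("nan"),
        "n_loci": len(loci),
        "n_false_loci": len(loci) - len(matched_loci),
    }
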