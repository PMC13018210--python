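"""Hit calling, the three-domain architecture filter, neighbours, summaries."""

import re

import numpy as np
import pandas as pd
import pytest

from tlpscan import archscan, seqio, synthetic_data
from tlpscan.archscan import (
    DEFAULT_E_MAX,
    DEFAULT_MIN_MODEL_COV,
    DomainHit,
    TLPLocus,
    call_architecture,
    find_downstream_orf,
    loci_to_gff3,
    scan_frames,
    summarize_prevalence,
)
from tlpscan.profile_hmm import HMMLibrary, ProfileHMMError
from tlpscan.seqio import GenomeRecord, reverse_complement
from tests.conftest import make_toy_hmm

ORDER = ("FN-plug", "NHL", "YD-shell")


def consensus_cassette_dna(lib, linker="GSGSGSGSGS", order=None, seed=0):
    """Reverse-translated consensus cassette; returns (dna, aa layout)."""
    order = order or tuple(lib.architecture)
    parts = []
    layout = []
    off = 0
    for i, name in enumerate(order):
        if i > 0:
            parts.append(linker)
            off += len(linker)
        pep = lib[name].consensus()
        layout.append((name, off, off + len(pep)))
        parts.append(pep)
        off += len(pep)
    dna = synthetic_data.reverse_translate("".join(parts), seed=seed)
    return dna, layout


def plant(background_seed, length, inserts):
    """Random genome with (pos, dna) inserts overwritten in place."""
    rng = np.random.default_rng(background_seed)
    seq = synthetic_data._background_dna(rng, length, 0.5)
    for pos, dna in inserts:
        seq[pos : pos + len(dna)] = list(dna)
    return GenomeRecord(id="g", sequence="".join(seq.tolist()))


def make_hit(model="FN-plug", frame=1, seg=0, ps=0, pe=50, score=100.0, gid="g", strand="+"):
    return DomainHit(
        model_name=model, genome_id=gid, frame=frame, segment_index=seg,
        pep_start=ps, pep_end=pe, genomic_start=3 * ps, genomic_end=3 * pe,
        strand=strand, score=score, evalue=1e-30, model_coverage=0.9,
    )


class TestScanFrames:
    def test_published_default_thresholds(self):
        assert DEFAULT_E_MAX == 1e-10
        assert DEFAULT_MIN_MODEL_COV == 0.30

    def test_uncalibrated_library_rejected(self):
        lib = HMMLibrary(models=[make_toy_hmm(name="FN-plug")], architecture=("FN-plug",))
        with pytest.raises(ProfileHMMError, match="not calibrated"):
            scan_frames(lib, [])

    def test_planted_consensus_domain_is_retained(self, mini_library):
        pep = mini_library["FN-plug"].consensus()
        dna = synthetic_data.reverse_translate(pep, seed=3)
        genome = plant(1, 4000, [(900, dna)])
        frames = [fr for fr in seqio.six_frame_translate(genome)]
        hits = scan_frames(mini_library, frames)
        fn = [h for h in hits if h.model_name == "FN-plug"]
        assert len(fn) == 1
        assert fn[0].model_coverage >= 0.30
        assert fn[0].evalue <= 1e-10

    def test_evalue_threshold_boundary_excludes_hits(self, mini_library):
        """A hit with E just above the cutoff must be dropped."""
        pep = mini_library["FN-plug"].consensus()
        dna = synthetic_data.reverse_translate(pep, seed=3)
        genome = plant(1, 4000, [(900, dna)])
        frames = [fr for fr in seqio.six_frame_translate(genome)]
        hits = scan_frames(mini_library, frames)
        E_obs = min(h.evalue for h in hits if h.model_name == "FN-plug")
        tighter = scan_frames(mini_library, frames, E_max=E_obs / 10.0)
        assert not [h for h in tighter if h.model_name == "FN-plug"]

    def test_coverage_threshold_excludes_partial_match(self, mini_library):
        """Planting 20% of a domain cannot satisfy 30% model coverage."""
        pep = mini_library["YD-shell"].consensus()
        frag = pep[: len(pep) // 5]
        genome = plant(2, 4000, [(900, synthetic_data.reverse_translate(frag, seed=5))])
        frames = [fr for fr in seqio.six_frame_translate(genome)]
        hits = scan_frames(mini_library, frames, min_model_cov=0.30)
        assert not [h for h in hits if h.model_name == "YD-shell"]

    def test_genomic_interval_is_three_times_envelope(self, mini_library):
        pep = mini_library["NHL"].consensus()
        genome = plant(3, 4000, [(903, synthetic_data.reverse_translate(pep, seed=7))])
        frames = [fr for fr in seqio.six_frame_translate(genome)]
        for h in scan_frames(mini_library, frames):
            assert h.genomic_end - h.genomic_start == 3 * (h.pep_end - h.pep_start)


class TestCallArchitecture:
    def test_single_in_order_triple_forms_one_locus(self):
        hits = [
            make_hit("FN-plug", ps=0, pe=50),
            make_hit("NHL", ps=60, pe=130),
            make_hit("YD-shell", ps=140, pe=230),
        ]
        loci = call_architecture(hits, expected_order=ORDER)
        assert len(loci) == 1
        assert loci[0].copy_index == 1
        assert loci[0].score == pytest.approx(300.0)

    def test_wrong_order_never_assembles(self):
        hits = [
            make_hit("YD-shell", ps=0, pe=90),
            make_hit("NHL", ps=100, pe=170),
            make_hit("FN-plug", ps=180, pe=230),
        ]
        assert call_architecture(hits, expected_order=ORDER) == []

    def test_cross_frame_hits_never_assemble(self):
        hits = [
            make_hit("FN-plug", frame=1, ps=0, pe=50),
            make_hit("NHL", frame=1, ps=60, pe=130),
            make_hit("YD-shell", frame=-2, ps=140, pe=230),
        ]
        assert call_architecture(hits, expected_order=ORDER) == []

    def test_gap_beyond_maximum_rejected(self):
        hits = [
            make_hit("FN-plug", ps=0, pe=50),
            make_hit("NHL", ps=60, pe=130),
            make_hit("YD-shell", ps=131 + 300, pe=600),
        ]
        assert call_architecture(hits, expected_order=ORDER, max_gap=300) == []
        hits[2] = make_hit("YD-shell", ps=130 + 300, pe=600)
        assert len(call_architecture(hits, expected_order=ORDER, max_gap=300)) == 1

    def test_heavily_overlapping_envelopes_rejected(self):
        hits = [
            make_hit("FN-plug", ps=0, pe=50),
            make_hit("NHL", ps=10, pe=60),  # 40/50 overlap > 50%
            make_hit("YD-shell", ps=70, pe=160),
        ]
        assert call_architecture(hits, expected_order=ORDER) == []

    def test_empty_input_gives_empty_output(self):
        assert call_architecture([], expected_order=ORDER) == []

    def test_two_opposite_strand_cassettes_match_truth_within_3nt(self, mini_library):
        """Consensus cassettes on both strands are located near-exactly."""
        dna, layout = consensus_cassette_dna(mini_library)
        pos_f, pos_r = 1000, 6000
        genome = plant(4, 10000, [(pos_f, dna), (pos_r, reverse_complement(dna))])
        frames = [fr for fr in seqio.six_frame_translate(genome)]
        hits = scan_frames(mini_library, frames)
        loci = call_architecture(hits, expected_order=ORDER)
        assert len(loci) == 2
        spans = {(l.genomic_start, l.genomic_end, l.strand) for l in loci}
        expected = {
            (pos_f, pos_f + len(dna), "+"),
            (pos_r, pos_r + len(dna), "-"),
        }
        for (gs, ge, strand) in spans:
            match = [e for e in expected if e[2] == strand]
            assert match, f"unexpected strand {strand}"
            es, ee, _ = match[0]
            assert abs(gs - es) <= 3 and abs(ge - ee) <= 3

    def test_greedy_resolution_prefers_higher_combined_score(self):
        shared_yd = make_hit("YD-shell", ps=140, pe=230, score=50.0)
        hits = [
            make_hit("FN-plug", ps=0, pe=50, score=200.0),
            make_hit("FN-plug", ps=5, pe=55, score=10.0),
            make_hit("NHL", ps=60, pe=130, score=100.0),
            shared_yd,
        ]
        loci = call_architecture(hits, expected_order=ORDER)
        assert len(loci) == 1
        assert loci[0].hits[0].score == 200.0


class TestStrandMirror:
    def test_loci_identical_after_coordinate_mirroring(self, mini_library):
        """Screening g and rc(g) gives the same loci under x -> n - x."""
        dna, _ = consensus_cassette_dna(mini_library)
        genome = plant(6, 9000, [(1500, dna), (5500, reverse_complement(dna))])
        n = len(genome.sequence)
        rc = GenomeRecord(id="g", sequence=reverse_complement(genome.sequence))
        results = {}
        for label, g in (("fwd", genome), ("rev", rc)):
            frames = [fr for fr in seqio.six_frame_translate(g)]
            loci = call_architecture(
                scan_frames(mini_library, frames), expected_order=ORDER
            )
            results[label] = {
                (l.genomic_start, l.genomic_end, l.strand, round(l.score, 6)) for l in loci
            }
        mirrored = {
            (n - ge, n - gs, "-" if s == "+" else "+", sc)
            for gs, ge, s, sc in results["rev"]
        }
        assert results["fwd"] == mirrored


class TestFindDownstreamOrf:
    def locus(self, gs, ge, strand):
        h = make_hit(strand=strand)
        return TLPLocus(
            genome_id="g", hits=(h, h, h), strand=strand,
            genomic_start=gs, genomic_end=ge, score=1.0, copy_index=1,
        )

    def test_planted_orf_reported_first(self):
        rng = np.random.default_rng(63)
        orf = "ATG" + synthetic_data.reverse_translate(
            synthetic_data._random_peptide(rng, 90), seed=8
        ) + "TAA"
        # ATG-free background so the planted ORF is the only candidate
        base = GenomeRecord(id="g", sequence="C" * 6000)
        seq = list(base.sequence)
        seq[2200 : 2200 + len(orf)] = list(orf)
        genome = GenomeRecord(id="g", sequence="".join(seq))
        loci = self.locus(500, 2000, "+")
        found = find_downstream_orf(loci, genome, window=5000, min_orf=150)
        assert found, "planted ORF not found"
        s, e, strand, length = found[0]
        assert (s, strand) == (2200, "+")
        assert length == len(orf)

    def test_minus_strand_orf_upstream_in_forward_coordinates(self):
        rng = np.random.default_rng(64)
        orf = "ATG" + synthetic_data.reverse_translate(
            synthetic_data._random_peptide(rng, 90), seed=9
        ) + "TAA"
        genome = plant(8, 6000, [(1000, reverse_complement(orf))])
        loci = self.locus(3000, 5000, "-")
        found = find_downstream_orf(loci, genome, window=5000, min_orf=150)
        hits = [(s, e) for s, e, strand, _ in found if strand == "-"]
        assert (1000, 1000 + len(orf)) in hits

    def test_empty_when_no_orf_in_window(self):
        # genome without ATG at all downstream of the locus
        genome = GenomeRecord(id="g", sequence="C" * 4000)
        assert find_downstream_orf(self.locus(100, 500, "+"), genome) == []

    def test_agreement_with_regex_oracle(self):
        """Naive ORF calls equal an in-frame regex scan on random genomes."""
        rng = np.random.default_rng(65)
        for rep in range(50):
            n = 3000
            genome = GenomeRecord(
                id="g", sequence="".join(rng.choice(list("ACGT"), size=n))
            )
            locus = self.locus(0, 60, "+")
            got = {(s, e) for s, e, _, _ in find_downstream_orf(locus, genome, window=n, min_orf=30)}
            expected = set()
            seq = genome.sequence
            for m in re.finditer(r"(?=ATG)", seq):
                s = m.start()
                if s < 60:
                    continue
                for t in range(s + 3, n - 2, 3):
                    if seq[t : t + 3] in ("TAA", "TAG", "TGA"):
                        if t + 3 - s >= 30:
                            expected.add((s, t + 3))
                        break
            assert got == expected


class TestSummaries:
    def metadata(self):
        return pd.DataFrame(
            {
                "genome_id": [f"g{i}" for i in range(10)],
                "species": [f"sp{i}" for i in range(10)],
                "taxon_group": ["X"] * 10,
            }
        )

    def make_locus(self, gid):
        h = make_hit(gid=gid)
        return TLPLocus(genome_id=gid, hits=(h, h, h), strand="+",
                        genomic_start=0, genomic_end=100, score=1.0, copy_index=1)

    def test_two_of_ten_positive_is_twenty_percent(self):
        loci = [self.make_locus("g0"), self.make_locus("g3")]
        summary = summarize_prevalence(loci, self.metadata())
        row = summary.per_group.iloc[0]
        assert row["genomes_screened"] == 10
        assert row["genomes_positive"] == 2
        assert row["percent"] == pytest.approx(20.0)

    def test_empty_loci_give_zero_percent(self):
        summary = summarize_prevalence([], self.metadata())
        assert (summary.per_group["percent"] == 0).all()
        assert summary.copy_histogram == {}

    def test_histogram_counts_sum_to_positive_genomes(self):
        loci = [self.make_locus("g0"), self.make_locus("g0"), self.make_locus("g1")]
        summary = summarize_prevalence(loci, self.metadata())
        assert summary.copy_histogram == {1: 1, 2: 1}
        assert sum(summary.copy_histogram.values()) == 2
        assert summary.multi_copy_genomes == ["g0"]

    def test_gff3_output_is_one_based(self):
        locus = self.make_locus("g0")
        text = loci_to_gff3([locus])
        line = text.splitlines()[1].split("\t")
        assert line[0] == "g0"
        assert (line[3], line[4]) == ("1", "100")
        assert line[2] == "protein_match"


class TestMonotonicity:
    def test_tightening_thresholds_never_adds_loci(self, mini_library):
        dna, _ = consensus_cassette_dna(mini_library)
        genome = plant(9, 8000, [(1200, dna)])
        frames = [fr for fr in seqio.six_frame_translate(genome)]
        base = len(call_architecture(scan_frames(mini_library, frames), expected_order=ORDER))
        for e_max, cov in [(1e-20, 0.30), (1e-10, 0.50), (1e-30, 0.90)]:
            n = len(
                call_architecture(
                    scan_frames(mini_library, frames, E_max=e_max, min_model_cov=cov),
                    expected_order=ORDER,
                )
            )
            assert n <= base
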