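"""RHS cleavage-motif detection and C-terminal domain (CTD) annotation.

Bacterial TLPs carry the conserved RHS core cleavage site near the end of
the YD-shell: a simple ``PxxxxDPxG`` signature and, more informatively, a
bipartite aspartyl-protease motif ``DPx[GLR]-X18-DPxG`` whose two aspartates
are the catalytic residues.  Autoproteolysis liberates everything downstream
of the second ``DPxG`` tetrad; with the second aspartate at 1-based position
``d2``, the cleaved CTD starts at ``d2 + 5`` (cleavage after the tetrad's
glycine).  The CTD is the hypervariable, encapsulated putative toxin;
annotation here covers its sequence, average molecular mass, Kyte-Doolittle
hydropathy profile and hydrophobic (candidate transmembrane) segments.

All reported positions are 1-based inclusive, matching residue numbering
conventions in the structural literature.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils import molecular_weight
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

WATER_DA = 18.015


class MotifError(ValueError):
    pass


@dataclass
class MotifHit:
    """One occurrence of an RHS cleavage-site motif."""

    pattern_id: str  # "simple_PxxxxDPxG" or "bipartite"
    start: int  # 1-based position of the first motif residue
    end: int  # 1-based position of the last motif residue (inclusive)
    first_motif_variant: str | None = None  # residue at the first tetrad's 4th slot
    d1_pos: int | None = None  # 1-based catalytic aspartates (bipartite only)
    d2_pos: int | None = None


@dataclass
class CTDRecord:
    """Sequence downstream of the RHS cleavage site, with annotations."""

    parent_id: str
    ctd_start: int  # 1-based residue index in the parent
    sequence: str
    mass_kDa: float
    hydropathy: np.ndarray
    tm_segments: list[tuple[int, int]]  # 1-based inclusive, CTD-local
    annotations: dict = field(default_factory=dict)


def scan_simple_motif(seq: str) -> list[MotifHit]:
    """All (possibly overlapping) matches of P-x4-D-P-x-G, 1-based."""
    hits = []
    for m in re.finditer(r"(?=(P....DP.G))", seq):
        hits.append(
            MotifHit(pattern_id="simple_PxxxxDPxG", start=m.start() + 1, end=m.start() + 9)
        )
    return hits


def scan_bipartite_motif(
    seq: str,
    spacer: int = 18,
    first_terminal_variants: str = "GLR",
) -> list[MotifHit]:
    """All matches of the bipartite motif D-P-x-[GLR] - X{spacer} - D-P-x-G.

    Records the 1-based positions of the two catalytic aspartates and the
    residue observed at the first tetrad's terminal slot (G in canonical RHS
    proteins; L or R in some TLP families).
    """
    pat = re.compile(
        rf"(?=(DP.[{re.escape(first_terminal_variants)}].{{{spacer}}}DP.G))"
    )
    hits = []
    for m in pat.finditer(seq):
        d1 = m.start() + 1
        d2 = d1 + 4 + spacer
        hits.append(
            MotifHit(
                pattern_id="bipartite",
                start=d1,
                end=d2 + 3,
                first_motif_variant=seq[d1 + 2],  # 0-based d1+2 == 1-based d1+3
                d1_pos=d1,
                d2_pos=d2,
            )
        )
    return hits


def hydropathy_tm(
    seq: str,
    window: int = 19,
    threshold: float = 1.6,
    merge_gap: int = 3,
    min_run: int = 15,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Centered sliding-window Kyte-Doolittle profile and hydrophobic runs.

    The profile has one value per residue; residues whose centered window
    would overhang the sequence get NaN.  Runs of window centres above
    ``threshold`` are merged when separated by <= ``merge_gap`` residues and
    reported (1-based inclusive) when at least ``min_run`` long.
    """
    n = len(seq)
    values = np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in seq])
    half = window // 2
    profile = np.full(n, np.nan)
    if n >= window:
        kernel = np.ones(window) / window
        profile[half : n - half] = np.convolve(values, kernel, mode="valid")
    above = np.zeros(n, dtype=bool)
    above[~np.isnan(profile)] = profile[~np.isnan(profile)] > threshold
    # maximal runs, merged across short dips
    runs: list[list[int]] = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if runs and i - runs[-1][1] - 1 <= merge_gap:
                runs[-1][1] = j
            else:
                runs.append([i, j])
            i = j + 1
        else:
            i += 1
    segments = [(a + 1, b + 1) for a, b in runs if b - a + 1 >= min_run]
    return profile, segments


def molecular_mass(seq: str) -> float:
    """Average-isotope protein mass in kDa (peptide bonds release one water)."""
    if not seq:
        raise MotifError("empty sequence has no mass")
    return molecular_weight(seq, seq_type="protein") / 1000.0


def extract_ctd(
    seq: str,
    hit: MotifHit,
    parent_id: str = "",
    annotations: dict | None = None,
) -> CTDRecord:
    """Cleave at the bipartite RHS site and annotate the liberated CTD.

    ``ctd_start = d2_pos + 5``: the scissile bond follows the glycine of the
    second DPxG tetrad, so with the second catalytic aspartate at 2140 the
    CTD begins at residue 2145.
    """
    if hit.pattern_id != "bipartite" or hit.d2_pos is None:
        raise MotifError("extract_ctd requires a bipartite motif hit")
    if seq[hit.d2_pos - 1] != "D":
        raise MotifError(f"no aspartate at reported d2 position {hit.d2_pos}")
    ctd_start = hit.d2_pos + 5
    if ctd_start > len(seq):
        raise MotifError("motif at sequence end: CTD would be empty")
    ctd_seq = seq[ctd_start - 1 :]
    profile, segments = hydropathy_tm(ctd_seq)
    return CTDRecord(
        parent_id=parent_id,
        ctd_start=ctd_start,
        sequence=ctd_seq,
        mass_kDa=molecular_mass(ctd_seq),
        hydropathy=profile,
        tm_segments=segments,
        annotations=dict(annotations or {}),
    )
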