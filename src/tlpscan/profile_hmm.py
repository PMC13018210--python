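"""Per-domain profile HMMs: building, local scoring, and E-value calibration.

A model is built from one sub-alignment of the superfold multiple sequence
alignment (FN-plug, NHL or YD-shell).  Alignment columns with gap fraction
below ``match_gap_frac`` become match states; emissions and transitions are
count estimates smoothed with a background-mix pseudocount of weight ``A``.
Scoring is local (Smith-Waterman-style): entry at any match state with
uniform weight, exit from any match state at no cost, flanking residues and
insert-state residues emitted by the background.  Significance uses an
explicit Gumbel null fitted by maximum likelihood to Viterbi scores of
simulated background peptides; the calibration (mu, lambda, sizes, seed) is
stored on the model so every E-value is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import AlignIO
from scipy import stats

from ._kernels import (
    NEG_INF,
    forward_kernel,
    viterbi_kernel,
    viterbi_score_kernel,
    viterbi_scores_batch,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_UNKNOWN = 20  # X and other ambiguity codes: background emission, 0-bit odds

#: default superfold architecture, N-terminal to C-terminal
SUPERFOLD_ORDER = ("FN-plug", "NHL", "YD-shell")


class ProfileHMMError(ValueError):
    pass


#: pseudocount prior over transition targets, scaled by the pseudocount
#: weight A.  Match states strongly favour M->M, as in standard profile-HMM
#: construction; an uninformative prior would impute implausibly high indel
#: rates from small alignments.
TRANSITION_PRIOR = {
    "M": (0.90, 0.05, 0.05),  # M->M, M->I, M->D
    "I": (0.50, 0.50),  # I->M, I->I
    "D": (0.50, 0.50),  # D->M, D->D
}


def encode_peptide(peptide: str) -> np.ndarray:
    """Map residues to 0..19 (alphabetical) with ambiguity codes -> 20."""
    return np.array([AA_INDEX.get(aa, _UNKNOWN) for aa in peptide], dtype=np.int64)


@dataclass
class Alignment:
    """A protein multiple sequence alignment with a named reference row."""

    rows: list[tuple[str, str]]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise ProfileHMMError("alignment has no rows")
        width = len(self.rows[0][1])
        if any(len(s) != width for _, s in self.rows):
            raise ProfileHMMError("alignment rows differ in length")
        if self.reference_id not in {rid for rid, _ in self.rows}:
            raise ProfileHMMError(f"reference {self.reference_id!r} not in alignment")

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def reference_row(self) -> str:
        return next(s for rid, s in self.rows if rid == self.reference_id)


def read_alignment(path: str | Path, reference_id: str, fmt: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Stockholm file into an :class:`Alignment`."""
    msa = AlignIO.read(str(path), fmt)
    rows = [(rec.id, str(rec.seq).upper().replace(".", "-")) for rec in msa]
    return Alignment(rows=rows, reference_id=reference_id)


def slice_alignment_by_reference(aln: Alignment, start_res: int, end_res: int) -> Alignment:
    """Columns spanning reference residues ``start_res..end_res`` (1-based incl.).

    Columns where the reference carries a gap between the boundary residues
    are retained, so the slice is contiguous in alignment coordinates.
    """
    if start_res < 1 or start_res > end_res:
        raise ProfileHMMError(f"bad residue range {start_res}..{end_res}")
    ref = aln.reference_row
    res_cols = [c for c, ch in enumerate(ref) if ch != "-"]
    if end_res > len(res_cols):
        raise ProfileHMMError(
            f"reference has {len(res_cols)} residues, cannot slice to {end_res}"
        )
    c0, c1 = res_cols[start_res - 1], res_cols[end_res - 1]
    return Alignment(
        rows=[(rid, s[c0 : c1 + 1]) for rid, s in aln.rows],
        reference_id=aln.reference_id,
    )


@dataclass
class Calibration:
    mu: float
    lam: float
    n_cal: int
    len_cal: int
    seed: int


@dataclass
class ProfileHMM:
    """A local-mode profile HMM for one protein domain.

    Transition columns (per 0-based source state k): MM, MI, MD, IM, II,
    DM, DD.  The last match state exits only, so its MM/MI/MD are zero.
    """

    name: str
    match_emissions: np.ndarray  # (M, 20)
    insert_emissions: np.ndarray  # (20,) == background by construction
    transitions: np.ndarray  # (M, 7)
    background: np.ndarray  # (20,)
    calibration: Calibration | None = None
    _llr: np.ndarray | None = field(default=None, repr=False, compare=False)
    _log_trans: tuple[np.ndarray, ...] | None = field(default=None, repr=False, compare=False)

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def entry_bits(self) -> float:
        return -math.log2(self.M)

    def _tables(self):
        """Per-residue log-odds (21, M) and log2 transition vectors, cached."""
        if self._llr is None:
            llr = np.zeros((21, self.M))
            llr[:20] = np.log2(self.match_emissions.T / self.background[:, None])
            self._llr = llr
            with np.errstate(divide="ignore"):
                lt = np.where(self.transitions > 0.0, np.log2(self.transitions), NEG_INF)
            self._log_trans = tuple(np.ascontiguousarray(lt[:, j]) for j in range(7))
        return self._llr, self._log_trans

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in np.argmax(self.match_emissions, axis=1))

    def validate(self) -> None:
        if self.M < 1:
            raise ProfileHMMError("model has no match states")
        for label, table in (
            ("match emissions", self.match_emissions),
            ("insert emissions", self.insert_emissions[None, :]),
            ("background", self.background[None, :]),
        ):
            if np.any(table <= 0):
                raise ProfileHMMError(f"{label} contain non-positive probabilities")
            if np.max(np.abs(table.sum(axis=1) - 1.0)) > 1e-9:
                raise ProfileHMMError(f"{label} rows do not sum to 1")
        t = self.transitions
        groups = [(slice(0, 3), t[:-1]), (slice(3, 5), t[:-1]), (slice(5, 7), t[:-1])]
        for cols, rows in groups:
            if rows.shape[0] and np.max(np.abs(rows[:, cols].sum(axis=1) - 1.0)) > 1e-9:
                raise ProfileHMMError("transition rows do not sum to 1")


def build_hmm(
    aln: Alignment,
    name: str,
    match_gap_frac: float = 0.5,
    pseudocount_weight: float = 5.0,
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Estimate a profile HMM from an alignment.

    Columns with gap fraction < ``match_gap_frac`` become match states.
    Match emissions are ``(c + A*b) / (C + A)`` with observed counts ``c``,
    column total ``C``, background ``b`` and pseudocount weight ``A``.
    Transitions are counted from each row's implied state path and smoothed
    with the same weight ``A`` spread over the targets according to
    :data:`TRANSITION_PRIOR`.
    """
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    background = np.asarray(background, dtype=float)
    n_rows = len(aln.rows)
    cols = np.array([[s[c] for _, s in aln.rows] for c in range(aln.width)])
    gap_frac = (cols == "-").mean(axis=1)
    match_cols = np.flatnonzero(gap_frac < match_gap_frac)
    M = len(match_cols)
    if M == 0:
        raise ProfileHMMError("alignment yields zero match columns")
    A = pseudocount_weight

    emis = np.zeros((M, 20))
    for m, c in enumerate(match_cols):
        counts = np.zeros(20)
        for ch in cols[c]:
            i = AA_INDEX.get(ch)
            if i is not None:
                counts[i] += 1
        emis[m] = (counts + A * background) / (counts.sum() + A)

    # state path per row: M/D at match columns, I for residues between them
    STATES = ("MM", "MI", "MD", "IM", "II", "DM", "DD")
    tcounts = np.zeros((M, 7))
    match_set = {int(c): m for m, c in enumerate(match_cols)}
    for _, row in aln.rows:
        path: list[tuple[str, int]] = []  # (state, state index k)
        k_last = -1  # inserts between match states k and k+1 carry index k
        for c, ch in enumerate(row):
            m = match_set.get(c)
            if m is not None:
                path.append(("M" if ch != "-" else "D", m))
                k_last = m
            elif ch != "-":
                path.append(("I", k_last))
        # collapse leading/trailing flank inserts: local model ignores them
        while path and path[0][0] == "I":
            path.pop(0)
        while path and path[-1][0] == "I":
            path.pop()
        for (s1, k1), (s2, _) in zip(path, path[1:]):
            key = s1 + s2
            if key in ("MM", "MI", "MD", "IM", "II", "DM", "DD"):
                tcounts[k1, STATES.index(key)] += 1

    trans = np.zeros((M, 7))
    for cols_, prior in (
        (slice(0, 3), TRANSITION_PRIOR["M"]),
        (slice(3, 5), TRANSITION_PRIOR["I"]),
        (slice(5, 7), TRANSITION_PRIOR["D"]),
    ):
        c = tcounts[:, cols_]
        trans[:, cols_] = (c + A * np.asarray(prior)) / (c.sum(axis=1, keepdims=True) + A)
    trans[M - 1, 0:3] = 0.0  # last match state exits only

    hmm = ProfileHMM(
        name=name,
        match_emissions=emis,
        insert_emissions=background.copy(),
        transitions=trans,
        background=background,
    )
    hmm.validate()
    return hmm


def score_forward(hmm: ProfileHMM, peptide: str) -> float:
    """Log2 likelihood ratio of the local forward sum vs the background null."""
    if not peptide:
        raise ProfileHMMError("empty peptide")
    llr, lt = hmm._tables()
    mat = np.ascontiguousarray(llr[encode_peptide(peptide)])
    return forward_kernel(mat, *lt, hmm.entry_bits)


@dataclass
class ViterbiHit:
    score: float  # bits
    pep_start: int  # 0-based half-open envelope on the peptide
    pep_end: int
    k_start: int  # 0-based half-open span on the model's match states
    k_end: int


def score_viterbi(hmm: ProfileHMM, peptide: str) -> ViterbiHit:
    """Best single local path: bit score plus peptide envelope and model span."""
    if not peptide:
        raise ProfileHMMError("empty peptide")
    llr, lt = hmm._tables()
    mat = np.ascontiguousarray(llr[encode_peptide(peptide)])
    score, p0, p1, k0, k1 = viterbi_kernel(mat, *lt, hmm.entry_bits)
    return ViterbiHit(score=score, pep_start=p0, pep_end=p1, k_start=k0, k_end=k1)


def score_viterbi_only(hmm: ProfileHMM, peptide: str) -> float:
    """Viterbi bit score without envelope bookkeeping (faster; used in scans)."""
    if not peptide:
        raise ProfileHMMError("empty peptide")
    llr, lt = hmm._tables()
    mat = np.ascontiguousarray(llr[encode_peptide(peptide)])
    return viterbi_score_kernel(mat, *lt, hmm.entry_bits)


def sample_background_peptides(
    background: np.ndarray, n: int, length: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, length) int-encoded i.i.d. background peptides."""
    return rng.choice(20, size=(n, length), p=background)


def _batch_viterbi(hmm: ProfileHMM, encoded: np.ndarray) -> np.ndarray:
    llr, lt = hmm._tables()
    n, L = encoded.shape
    flat = np.ascontiguousarray(llr[encoded.reshape(-1)])
    lengths = np.full(n, L, dtype=np.int64)
    return viterbi_scores_batch(flat, lengths, *lt, hmm.entry_bits)


def calibrate(
    hmm: ProfileHMM, n_cal: int = 200, len_cal: int = 400, seed: int = 0
) -> ProfileHMM:
    """Fit the Gumbel null (mu, lambda) to background Viterbi scores in place.

    Deterministic given ``seed``; the calibration block (including the seed)
    is serialized with the model.
    """
    if n_cal < 50:
        raise ProfileHMMError("n_cal must be >= 50 for a stable Gumbel fit")
    rng = np.random.default_rng(seed)
    peptides = sample_background_peptides(hmm.background, n_cal, len_cal, rng)
    scores = _batch_viterbi(hmm, peptides)
    mu, beta = stats.gumbel_r.fit(scores)
    if beta <= 0:
        raise ProfileHMMError("degenerate Gumbel fit (lambda <= 0)")
    hmm.calibration = Calibration(mu=float(mu), lam=1.0 / float(beta), n_cal=n_cal, len_cal=len_cal, seed=seed)
    return hmm


def evalue(hmm: ProfileHMM, score: float, n_targets: int = 1) -> float:
    """Expected count of background scores >= ``score`` among ``n_targets``."""
    cal = hmm.calibration
    if cal is None:
        raise ProfileHMMError(f"model {hmm.name!r} is not calibrated")
    x = math.exp(-cal.lam * (score - cal.mu)) if cal.lam * (score - cal.mu) < 700 else math.inf
    return n_targets * float(-math.expm1(-x))


@dataclass
class HMMLibrary:
    """An ordered set of domain models plus the expected architecture order."""

    models: list[ProfileHMM]
    architecture: tuple[str, ...] = SUPERFOLD_ORDER

    def __post_init__(self) -> None:
        names = [m.name for m in self.models]
        if len(set(names)) != len(names):
            raise ProfileHMMError("duplicate model names in library")

    def __iter__(self):
        return iter(self.models)

    def __len__(self) -> int:
        return len(self.models)

    def __getitem__(self, name: str) -> ProfileHMM:
        for m in self.models:
            if m.name == name:
                return m
        raise KeyError(name)


# --- plain-text serialization (bit-exact via float hex) ---------------------

def _fmt_row(values: Iterable[float]) -> str:
    return " ".join(float(v).hex() for v in values)


def _parse_row(line: str) -> np.ndarray:
    return np.array([float.fromhex(tok) for tok in line.split()])


def write_hmm(hmm: ProfileHMM, fh) -> None:
    fh.write("PROFILE-HMM v1\n")
    fh.write(f"NAME {hmm.name}\n")
    fh.write(f"M {hmm.M}\n")
    fh.write(f"ALPHABET {AMINO_ACIDS}\n")
    fh.write("BACKGROUND " + _fmt_row(hmm.background) + "\n")
    fh.write("INSERT " + _fmt_row(hmm.insert_emissions) + "\n")
    fh.write("MATCH\n")
    for row in hmm.match_emissions:
        fh.write(_fmt_row(row) + "\n")
    fh.write("TRANSITIONS\n")
    for row in hmm.transitions:
        fh.write(_fmt_row(row) + "\n")
    if hmm.calibration is not None:
        c = hmm.calibration
        fh.write(
            f"CALIBRATION {float(c.mu).hex()} {float(c.lam).hex()} "
            f"{c.n_cal} {c.len_cal} {c.seed}\n"
        )
    fh.write("END\n")


def read_hmm(fh) -> ProfileHMM:
    header = fh.readline().strip()
    if header != "PROFILE-HMM v1":
        raise ProfileHMMError(f"bad model header {header!r}")
    name = fh.readline().split(maxsplit=1)[1].strip()
    M = int(fh.readline().split()[1])
    fh.readline()  # alphabet
    background = _parse_row(fh.readline().split(" ", 1)[1])
    insert = _parse_row(fh.readline().split(" ", 1)[1])
    assert fh.readline().strip() == "MATCH"
    match = np.vstack([_parse_row(fh.readline()) for _ in range(M)])
    assert fh.readline().strip() == "TRANSITIONS"
    trans = np.vstack([_parse_row(fh.readline()) for _ in range(M)])
    calibration = None
    line = fh.readline().strip()
    if line.startswith("CALIBRATION"):
        toks = line.split()
        calibration = Calibration(
            mu=float.fromhex(toks[1]),
            lam=float.fromhex(toks[2]),
            n_cal=int(toks[3]),
            len_cal=int(toks[4]),
            seed=int(toks[5]),
        )
        line = fh.readline().strip()
    if line != "END":
        raise ProfileHMMError("model file missing END")
    return ProfileHMM(
        name=name,
        match_emissions=match,
        insert_emissions=insert,
        transitions=trans,
        background=background,
        calibration=calibration,
    )


def write_library(lib: HMMLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("HMM-LIBRARY v1\n")
        fh.write("ARCHITECTURE " + " ".join(lib.architecture) + "\n")
        fh.write(f"NMODELS {len(lib.models)}\n")
        for m in lib.models:
            write_hmm(m, fh)


def read_library(path: str | Path) -> HMMLibrary:
    with open(path) as fh:
        if fh.readline().strip() != "HMM-LIBRARY v1":
            raise ProfileHMMError("not an HMM library file")
        architecture = tuple(fh.readline().split()[1:])
        n = int(fh.readline().split()[1])
        models = [read_hmm(fh) for _ in range(n)]
    return HMMLibrary(models=models, architecture=architecture)
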