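"""Shared fixtures: toy models, a mini domain library, and the benchmark run.

Expensive artefacts (calibrated libraries, the full planted-genome
benchmark) are session-scoped so every test file shares one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from tlpscan import archscan, seqio, synthetic_data
from tlpscan.profile_hmm import ProfileHMM, calibrate

#: small domain layout used by unit tests (fast to scan); the full-size
#: superfold fixture lives in the acceptance tests
MINI_BOUNDARIES = {"FN-plug": (1, 60), "NHL": (61, 140), "YD-shell": (141, 240)}


def make_toy_hmm(
    M: int = 3,
    seed: int = 0,
    name: str = "toy",
    peaked: float | None = None,
    calibrated: bool = False,
) -> ProfileHMM:
    """A small random (optionally emission-peaked) model for oracle tests."""
    rng = np.random.default_rng(seed)
    if peaked is None:
        emis = rng.dirichlet(np.full(20, 0.5), size=M)
    else:
        emis = np.full((M, 20), (1.0 - peaked) / 19.0)
        for k in range(M):
            emis[k, rng.integers(20)] = peaked
    trans = np.zeros((M, 7))
    trans[:, 0:3] = rng.dirichlet((8.0, 1.0, 1.0), size=M)
    trans[:, 3:5] = rng.dirichlet((1.0, 1.0), size=M)
    trans[:, 5:7] = rng.dirichlet((1.0, 1.0), size=M)
    trans[M - 1, 0:3] = 0.0
    hmm = ProfileHMM(
        name=name,
        match_emissions=emis,
        insert_emissions=np.full(20, 0.05),
        transitions=trans,
        background=np.full(20, 0.05),
    )
    if calibrated:
        calibrate(hmm, seed=seed + 1)
    return hmm


@pytest.fixture(scope="session")
def mini_alignment():
    return synthetic_data.generate_superfold_alignment(ref_len=240, seed=91)


@pytest.fixture(scope="session")
def mini_library(mini_alignment):
    return synthetic_data.build_superfold_library(mini_alignment, boundaries=MINI_BOUNDARIES)


@pytest.fixture(scope="session")
def superfold_alignment():
    """Full-size superfold-like alignment (reference spans 2139 residues)."""
    return synthetic_data.generate_superfold_alignment()


@pytest.fixture(scope="session")
def superfold_library(superfold_alignment):
    return synthetic_data.build_superfold_library(superfold_alignment)


@pytest.fixture(scope="session")
def benchmark_run(superfold_library):
    """The fixed planted-genome benchmark, screened once per session."""
    cfg = synthetic_data.GeneratorConfig()
    genomes, metadata, truth = synthetic_data.generate_benchmark(cfg, superfold_library)
    frames = [fr for g in genomes for fr in seqio.six_frame_translate(g)]
    hits = archscan.scan_frames(superfold_library, frames)
    loci = archscan.call_architecture(hits, expected_order=tuple(superfold_library.architecture))
    return {
        "config": cfg,
        "genomes": genomes,
        "metadata": metadata,
        "truth": truth,
        "frames": frames,
        "hits": hits,
        "loci": loci,
    }
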