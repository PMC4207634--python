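"""Jones-Taylor-Thornton (1992) amino acid replacement model.

Loads the published exchangeability matrix and equilibrium frequencies
from the bundled data file and exposes the rate matrix (scaled to one
expected substitution per site) plus its spectral decomposition for
fast transition-probability evaluation.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np

from ._seq import AMINO_ACIDS


@lru_cache(maxsize=1)
def _load() -> tuple[np.ndarray, np.ndarray]:
    text = (
        resources.files("lephox").joinpath("data/jtt.txt").read_text()
    )
    lines = [l for l in text.splitlines() if l and not l.startswith("#")]
    assert lines[0] == "exchangeabilities"
    tri = []
    i = 1
    while lines[i] != "frequencies":
        tri.append([float(x) for x in lines[i].split()])
        i += 1
    freqs = np.array([float(x) for x in lines[i + 1].split()])
    S = np.zeros((20, 20))
    for r, row in enumerate(tri, start=1):
        for c, val in enumerate(row):
            S[r, c] = S[c, r] = val
    freqs = freqs / freqs.sum()
    return S, freqs


def jtt_frequencies() -> np.ndarray:
    """Equilibrium amino-acid frequencies, order ARNDCQEGHILKMFPSTWYV."""
    return _load()[1].copy()


@lru_cache(maxsize=1)
def jtt_rate_matrix() -> np.ndarray:
    """Reversible rate matrix Q = S * diag(pi), scaled to 1 sub/site."""
    S, pi = _load()
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(pi * np.diag(Q)).sum()
    return Q / scale


@lru_cache(maxsize=1)
def _spectral():
    Q = jtt_rate_matrix()
    _, pi = _load()
    sq = np.sqrt(pi)
    B = (Q * sq[:, None]) / sq[None, :]
    B = 0.5 * (B + B.T)  # symmetrize against roundoff
    lam, U = np.linalg.eigh(B)
    left = U / sq[:, None]   # maps to P = D^{-1/2} U e^{lam t} U' D^{1/2}
    right = U * sq[:, None]
    return lam, left, right


def jtt_transition_matrix(t: float) -> np.ndarray:
    """P(t) = exp(Q t) under the JTT model."""
    lam, left, right = _spectral()
    P = (left * np.exp(lam * t)) @ right.T
    return np.clip(P, 0.0, None)


def aa_to_index(seq: str) -> np.ndarray:
    """Map residues to 0-19; gaps/ambiguity to -1."""
    lut = np.full(128, -1, dtype=np.int8)
    for i, a in enumerate(AMINO_ACIDS):
        lut[ord(a)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
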