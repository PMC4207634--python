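"""In silico evolution of homeodomain DNA binding sites.

Starting from each of the four homopolymer cores (poly-A/C/G/T), the
engine runs cycles of single-base mutation and greedy selection against
a pluggable protein-DNA energy model (lower energy = more stable),
keeping every evaluated (sequence, energy) pair in an archive. The
mutable core is 11 positions with elevated proposal weight on the inner
9; consensus base-probability matrices are built from the pooled
lowest-energy archive entries across the four starts, and a one-pass
substitution scan provides a control free of any starting-point bias.

The built-in :class:`ContactPotentialModel` is a coarse additive
residue-base contact potential patterned on the helix-3 and N-terminal
arm DNA contacts of the Antp homeodomain-DNA co-crystal geometry.
Atomic scoring backends (e.g. wrappers around structure-based energy
functions) can be plugged in through :class:`ExternalEnergyModel` or
any object satisfying the ``score(protein, dna) -> float`` contract.
"""

from __future__ import annotations

import hashlib
import math
import shlex
import subprocess
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from ._seq import AA_INDEX, BASES

# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DnaCore:
    """Mutable DNA core of a protein-DNA complex.

    ``inner window`` is the centered span of ``core_length - 2``
    positions (9 of 11 by default) that receives elevated mutation
    sampling.
    """

    sequence: str
    core_length: int = 11

    def __post_init__(self) -> None:
        if len(self.sequence) != self.core_length:
            raise ValueError("sequence length must equal core_length")
        if set(self.sequence) - set(BASES):
            raise ValueError("sequence must be over ACGT")

    @property
    def inner_window(self) -> range:
        return range(1, self.core_length - 1)


@runtime_checkable
class EnergyModel(Protocol):
    descriptor: str

    def score(self, protein_hd: str, dna: DnaCore) -> float: ...


# residue-base compatibility scores in [0, 1]; higher = more favourable.
# Coarse preferences: Asn/Gln major-groove H-bonds to adenine, Arg/Lys to
# guanine, hydrophobics to the thymine methyl, Ser/Thr/Cys weakly to
# guanine/cytosine; all else background 0.25.
_COMPAT_PREFS = {
    "N": {"A": 1.0, "T": 0.45},
    "Q": {"A": 0.9, "T": 0.5},
    "R": {"G": 1.0, "A": 0.4},
    "K": {"G": 0.9, "T": 0.35},
    "S": {"G": 0.6, "C": 0.5},
    "T": {"G": 0.55, "C": 0.5},
    "C": {"G": 0.5},
    "H": {"G": 0.7, "A": 0.45},
    "W": {"T": 0.6},
    "F": {"T": 0.55},
    "Y": {"T": 0.6, "C": 0.4},
    "I": {"T": 0.7},
    "L": {"T": 0.65},
    "V": {"T": 0.65},
    "M": {"T": 0.7},
    "A": {"T": 0.4},
    "E": {"C": 0.45},
    "D": {"C": 0.4},
    "G": {},
    "P": {},
}


def _compat_table() -> np.ndarray:
    table = np.full((20, 4), 0.25)
    for aa, prefs in _COMPAT_PREFS.items():
        for base, v in prefs.items():
            table[AA_INDEX[aa], BASES.index(base)] = v
    return table


# (homeodomain position 1-60, core position 1-11, weight): N-terminal arm
# residues 2-8 reach the minor groove at the core edges; recognition
# helix 3 residues 47-55 read the central major groove.
_DEFAULT_CONTACTS = [
    (2, 1, 0.5), (3, 2, 1.0), (5, 3, 1.0), (7, 2, 0.5), (8, 4, 0.5),
    (47, 5, 1.0), (50, 6, 1.0), (51, 7, 1.0), (54, 8, 1.0), (55, 9, 0.5),
    (53, 10, 0.5), (57, 11, 0.5),
]


class ContactPotentialModel:
    """Additive residue-base contact potential.

    energy = -sum over contacts of weight * compat[residue, base].
    Deterministic and strictly additive over core positions, so the
    position-wise substitution scan is exact for it.
    """

    def __init__(self, contacts=None, compat: np.ndarray | None = None):
        self.contacts = list(contacts) if contacts is not None else list(_DEFAULT_CONTACTS)
        self.compat = compat if compat is not None else _compat_table()

    @property
    def descriptor(self) -> str:
        h = hashlib.sha1(
            (str(self.contacts) + str(self.compat.round(6).tolist())).encode()
        ).hexdigest()[:10]
        return f"contact-potential({h})"

    def score(self, protein_hd: str, dna: DnaCore) -> float:
        total = 0.0
        for hd_pos, core_pos, weight in self.contacts:
            if hd_pos > len(protein_hd) or core_pos > dna.core_length:
                continue
            aa = protein_hd[hd_pos - 1]
            j = AA_INDEX.get(aa)
            if j is None:
                continue
            b = BASES.index(dna.sequence[core_pos - 1])
            total -= weight * self.compat[j, b]
        return total


class ExternalEnergyModel:
    """Subprocess adapter for atomic scoring backends.

    Runs ``command protein dna_sequence`` and parses a single float from
    stdout, allowing structure-based scorers to satisfy the energy
    contract without linking into this package.
    """

    def __init__(self, command: str, timeout: float = 600.0):
        self.command = command
        self.timeout = timeout

    @property
    def descriptor(self) -> str:
        return f"external({self.command})"

    def score(self, protein_hd: str, dna: DnaCore) -> float:
        out = subprocess.run(
            shlex.split(self.command) + [protein_hd, dna.sequence],
            capture_output=True, text=True, timeout=self.timeout, check=True,
        )
        return float(out.stdout.strip().split()[-1])


@dataclass
class EvolutionConfig:
    cycles: int = 1000
    inner_weight: float = 3.0
    archive_top_n: int = 50
    core_length: int = 11
    temperature: float = 0.0  # 0 = greedy accept-if-not-worse
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.inner_weight < 1:
            raise ValueError("inner_weight must be >= 1")


@dataclass
class EvolutionTrace:
    start: str  # homopolymer base
    records: list[tuple[int, str, float, bool]]  # cycle, proposal, energy, accepted
    best_energy_path: list[float]
    archive: dict[str, float]  # sequence -> best energy seen
    final_sequence: str
    final_energy: float


def mutate(dna: DnaCore, config: EvolutionConfig, rng: np.random.Generator) -> DnaCore:
    """Change exactly one core position to a different base.

    The position is drawn with weight ``inner_weight`` for the inner
    window and 1.0 for the two flanks; the new base is uniform over the
    three alternatives.
    """
    L = dna.core_length
    weights = np.ones(L)
    weights[1 : L - 1] = config.inner_weight
    pos = rng.choice(L, p=weights / weights.sum())
    alternatives = [b for b in BASES if b != dna.sequence[pos]]
    new_base = alternatives[rng.integers(3)]
    seq = dna.sequence[:pos] + new_base + dna.sequence[pos + 1 :]
    return DnaCore(sequence=seq, core_length=L)


def _check_energy(e: float, model) -> float:
    if not math.isfinite(e):
        raise RuntimeError(
            f"non-finite energy from model {model.descriptor!r}"
        )
    return e


def evolve(
    protein_hd: str, model, config: EvolutionConfig
) -> list[EvolutionTrace]:
    """Run one mutation/selection trajectory per homopolymer start.

    Each cycle proposes a single mutant of the current template,
    rescores the full complex, and accepts it if the energy is not
    worse (greedy; ties accepted). With ``temperature > 0`` worse
    proposals are instead accepted with Metropolis probability
    exp(-delta/T). Every evaluated (sequence, energy) pair is archived.
    Per-start RNG seeds derive deterministically from ``config.seed``.
    """
    traces = []
    for idx, base in enumerate(BASES):
        rng = np.random.default_rng(config.seed + idx)
        current = DnaCore(base * config.core_length, config.core_length)
        e_cur = _check_energy(model.score(protein_hd, current), model)
        archive = {current.sequence: e_cur}
        records = []
        best_path = []
        best = e_cur
        for cycle in range(1, config.cycles + 1):
            proposal = mutate(current, config, rng)
            e_new = _check_energy(model.score(protein_hd, proposal), model)
            prev = archive.get(proposal.sequence)
            if prev is None or e_new < prev:
                archive[proposal.sequence] = e_new
            if e_new <= e_cur:
                accept = True
            elif config.temperature > 0:
                accept = rng.random() < math.exp(
                    -(e_new - e_cur) / config.temperature
                )
            else:
                accept = False
            if accept:
                current, e_cur = proposal, e_new
            best = min(best, e_cur)
            records.append((cycle, proposal.sequence, e_new, accept))
            best_path.append(best)
        traces.append(
            EvolutionTrace(
                start=base, records=records, best_energy_path=best_path,
                archive=archive, final_sequence=current.sequence,
                final_energy=e_cur,
            )
        )
    return traces


@dataclass
class ConsensusMatrix:
    probabilities: np.ndarray  # core_length x 4, rows sum to 1
    information_content: np.ndarray  # bits per position
    source_count: int

    @property
    def core_length(self) -> int:
        return self.probabilities.shape[0]

    def argmax_sequence(self) -> str:
        return "".join(BASES[j] for j in self.probabilities.argmax(axis=1))


def consensus_from_archives(
    traces: list[EvolutionTrace], top_n: int = 50
) -> ConsensusMatrix:
    """Consensus matrix from the pooled lowest-energy archive entries.

    Archives from all starts are pooled, deduplicated by sequence
    keeping each sequence's best energy, and the ``top_n`` lowest-energy
    sequences vote per position. Information content is
    2 + sum p log2 p bits. Fewer than ``top_n`` distinct sequences
    triggers a warning and uses all of them.
    """
    pooled: dict[str, float] = {}
    for tr in traces:
        for seq, e in tr.archive.items():
            if seq not in pooled or e < pooled[seq]:
                pooled[seq] = e
    if not pooled:
        raise ValueError("empty archives")
    ordered = sorted(pooled.items(), key=lambda kv: (kv[1], kv[0]))
    if len(ordered) < top_n:
        import warnings

        warnings.warn(
            f"only {len(ordered)} distinct sequences in archives; using all"
        )
    chosen = [seq for seq, _ in ordered[:top_n]]
    L = len(chosen[0])
    counts = np.zeros((L, 4))
    for seq in chosen:
        for i, b in enumerate(seq):
            counts[i, BASES.index(b)] += 1
    probs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    return ConsensusMatrix(
        probabilities=probs, information_content=ic, source_count=len(chosen)
    )


def substitution_scan(
    protein_hd: str, model, start: DnaCore
) -> tuple[np.ndarray, str]:
    """Score all single-base substitutions of the start sequence.

    Returns the (core_length x 4) energy matrix (current base included)
    and the position-wise argmin sequence (ties to the alphabetically
    first base). For strictly additive models the argmin sequence is
    the global optimum; in general it is a starting-bias control for
    the evolutionary runs.
    """
    L = start.core_length
    matrix = np.zeros((L, 4))
    for pos in range(L):
        for j, b in enumerate(BASES):
            seq = start.sequence[:pos] + b + start.sequence[pos + 1 :]
            matrix[pos, j] = _check_energy(
                model.score(protein_hd, DnaCore(seq, L)), model
            )
    argmin = "".join(BASES[int(row.argmin())] for row in matrix)
    return matrix, argmin


# ---------------------------------------------------------------------------
# logo / matrix export
# ---------------------------------------------------------------------------


def logo_export(matrix: ConsensusMatrix, path, name: str = "consensus") -> None:
    """Write a MEME-style minimal motif file plus IC comment lines."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {matrix.core_length} "
            f"nsites= {matrix.source_count} E= 0\n"
        )
        for row in matrix.probabilities:
            fh.write(" ".join(f"{p:.12e}" for p in row) + "\n")
        fh.write("\n# information content (bits)\n")
        for i, ic in enumerate(matrix.information_content, start=1):
            fh.write(f"# pos {i}: {ic:.6f}\n")


def read_meme_matrix(path) -> ConsensusMatrix:
    """Read back a matrix written by :func:`logo_export`."""
    probs = []
    nsites = 0
    with open(path) as fh:
        in_matrix = False
        for line in fh:
            if line.startswith("letter-probability matrix:"):
                in_matrix = True
                for tok, nxt in zip(line.split(), line.split()[1:]):
                    if tok == "nsites=":
                        nsites = int(nxt)
                continue
            if in_matrix:
                parts = line.split()
                if len(parts) == 4:
                    probs.append([float(x) for x in parts])
                else:
                    in_matrix = False
    p = np.array(probs)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return ConsensusMatrix(
        probabilities=p, information_content=2.0 + plogp.sum(axis=1),
        source_count=nsites,
    )
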