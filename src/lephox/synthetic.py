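"""Ground-truthed synthetic inputs for every pipeline stage.

Each generator returns both the data and a machine-readable truth record
so downstream estimators can be scored against known parameters: shotgun
read sets from genomes with planted homeobox genes, codon alignments
evolved at chosen dN/dS, protein-DNA energy landscapes with a planted
optimal site, and multi-species protein alignments with planted
conserved motifs.
"""

from __future__ import annotations

import io
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Phylo
from scipy.linalg import expm

from ._seq import (
    AMINO_ACIDS,
    BASES,
    CODON_TO_AA,
    SENSE_CODONS,
    SYNONYMOUS,
    decode,
    encode,
    is_transition,
    revcomp,
)

# ---------------------------------------------------------------------------
# genomes and reads
# ---------------------------------------------------------------------------


@dataclass
class SyntheticGenomeSpec:
    """A random genome with optional planted protein-coding segments.

    ``planted_genes`` is a list of ``(name, protein, position, strand)``:
    the protein is reverse-translated (uniform synonymous codon choice)
    and spliced into the background sequence at the given 0-based
    nucleotide position, on the forward (+) or reverse (-) strand.
    """

    length: int
    gc_fraction: float = 0.40
    planted_genes: list[tuple[str, str, int, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        intervals = []
        for name, protein, pos, strand in self.planted_genes:
            if strand not in "+-":
                raise ValueError(f"gene {name}: strand must be '+' or '-'")
            end = pos + 3 * len(protein)
            if pos < 0 or end > self.length:
                raise ValueError(f"gene {name}: [{pos}, {end}) outside genome")
            intervals.append((pos, end, name))
        intervals.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(intervals, intervals[1:]):
            if s2 < e1:
                raise ValueError(
                    f"planted genes {n1} and {n2} overlap: "
                    f"[{s1},{e1}) vs [{s2},{e2})"
                )


@dataclass
class ReadSimSpec:
    """Paired-end shotgun read simulation parameters."""

    read_length: int = 101
    coverage: float = 15.0
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Reverse-translate with uniform random synonymous codon choice."""
    codons = []
    for aa in protein:
        if aa not in SYNONYMOUS:
            raise ValueError(f"cannot back-translate residue {aa!r}")
        options = SYNONYMOUS[aa]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def gen_genome(spec: SyntheticGenomeSpec) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate the genome and a truth table of planted-gene coordinates.

    Returns ``({contig_id: sequence}, truth)`` where ``truth`` has
    columns name/start/end/strand/protein/cds with 0-based half-open
    nucleotide coordinates on the forward strand.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=spec.length, p=probs).astype(np.uint8)
    seq = list(decode(codes))
    rows = []
    for name, protein, pos, strand in spec.planted_genes:
        cds = back_translate(protein, rng)
        insert = cds if strand == "+" else revcomp(cds)
        end = pos + len(cds)
        seq[pos:end] = insert
        rows.append(
            {"name": name, "start": pos, "end": end, "strand": strand,
             "protein": protein, "cds": cds}
        )
    truth = pd.DataFrame(
        rows, columns=["name", "start", "end", "strand", "protein", "cds"]
    )
    return {"synthetic_contig_1": "".join(seq)}, truth


@dataclass
class ReadSet:
    """Paired reads held as 2-bit code matrices (n_pairs x read_length)."""

    r1: np.ndarray
    r2: np.ndarray
    true_total_bases: int

    @property
    def n_pairs(self) -> int:
        return self.r1.shape[0]

    def sequences(self):
        for row in self.r1:
            yield decode(row)
        for row in self.r2:
            yield decode(row)

    def write_fastq(self, path1, path2) -> None:
        qual = "I" * self.r1.shape[1]
        for path, mat, tag in ((path1, self.r1, "/1"), (path2, self.r2, "/2")):
            with open(path, "w") as fh:
                for i in range(mat.shape[0]):
                    fh.write(f"@pair{i}{tag}\n{decode(mat[i])}\n+\n{qual}\n")


def simulate_reads(genome: str, spec: ReadSimSpec) -> ReadSet:
    """Simulate error-prone paired-end reads at the requested coverage.

    The number of pairs is ``round(coverage * G / (2 * L))``; inserts are
    Normal(insert_mean, insert_sd) clipped to [read_length, G]; R2 is the
    reverse complement of the fragment tail. Substitution errors only.
    """
    G = len(genome)
    L = spec.read_length
    if G <= spec.insert_mean:
        raise ValueError("genome shorter than mean insert size")
    rng = np.random.default_rng(spec.seed)
    n_pairs = round(spec.coverage * G / (2 * L))
    frags = np.clip(
        np.rint(rng.normal(spec.insert_mean, spec.insert_sd, n_pairs)).astype(int),
        L, G,
    )
    starts = np.floor(rng.random(n_pairs) * (G - frags + 1)).astype(np.int64)
    gcodes = encode(genome)
    offs = np.arange(L)
    r1 = gcodes[starts[:, None] + offs]
    r2 = 3 - gcodes[(starts + frags)[:, None] - 1 - offs]  # revcomp of tail
    if spec.error_rate > 0:
        for mat in (r1, r2):
            mask = rng.random(mat.shape) < spec.error_rate
            shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
            mat[mask] = (mat[mask] + shift) % 4
    return ReadSet(r1=r1, r2=r2, true_total_bases=n_pairs * 2 * L)


# ---------------------------------------------------------------------------
# codon alignments under a GY94-style model
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCodonSpec:
    """Codon alignment evolved on a tree with branch-specific dN/dS.

    ``tree`` is a rooted newick string with branch lengths in expected
    substitutions per codon; ``omega_by_branch`` maps the *child* clade
    name of a branch to its dN/dS, with key ``"*"`` as the default.
    """

    tree: str
    omega_by_branch: dict[str, float]
    codon_count: int
    kappa: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.codon_count <= 0:
            raise ValueError("codon_count must be positive")
        for name, om in self.omega_by_branch.items():
            if om < 0:
                raise ValueError(f"omega for branch {name!r} must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


def gy94_rate_matrix(omega: float, kappa: float) -> np.ndarray:
    """61x61 GY94 rate matrix (uniform codon frequencies), scaled so the
    expected substitution rate is 1 per codon."""
    n = len(SENSE_CODONS)
    Q = np.zeros((n, n))
    pi = 1.0 / n
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            rate = kappa if is_transition(*diffs[0]) else 1.0
            if CODON_TO_AA[ci] != CODON_TO_AA[cj]:
                rate *= omega
            Q[i, j] = rate * pi
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -pi * np.trace(Q)
    if scale > 0:
        Q /= scale
    return Q


def _branch_omega(spec: SyntheticCodonSpec, clade_name: str | None) -> float:
    if clade_name is not None and clade_name in spec.omega_by_branch:
        return spec.omega_by_branch[clade_name]
    if "*" in spec.omega_by_branch:
        return spec.omega_by_branch["*"]
    raise KeyError(
        f"no omega for branch {clade_name!r} and no '*' default given"
    )


def gen_codon_alignment(
    spec: SyntheticCodonSpec,
) -> tuple[dict[str, str], dict[str, float]]:
    """Simulate a stop-free in-frame alignment along the tree.

    Returns ``({leaf: dna}, {branch_child_name: omega_used})``.
    """
    tree = Phylo.read(io.StringIO(spec.tree), "newick")
    rng = np.random.default_rng(spec.seed)
    n_codons = spec.codon_count
    root_state = rng.integers(0, len(SENSE_CODONS), size=n_codons)

    leaves: dict[str, np.ndarray] = {}
    used: dict[str, float] = {}
    pmat_cache: dict[tuple[float, float], np.ndarray] = {}

    def descend(clade, state):
        for child in clade.clades:
            t = child.branch_length or 0.0
            omega = _branch_omega(spec, child.name)
            if child.name is not None:
                used[child.name] = omega
            if t > 0:
                key = (omega, round(t, 12))
                if key not in pmat_cache:
                    pmat_cache[key] = expm(gy94_rate_matrix(omega, spec.kappa) * t)
                P = pmat_cache[key]
                new = np.empty_like(state)
                for s in np.unique(state):
                    idx = np.nonzero(state == s)[0]
                    new[idx] = rng.choice(len(SENSE_CODONS), size=idx.size, p=P[s])
            else:
                new = state.copy()
            if child.is_terminal():
                leaves[child.name] = new
            else:
                descend(child, new)

    descend(tree.root, root_state)
    aln = {
        name: "".join(SENSE_CODONS[s] for s in states)
        for name, states in leaves.items()
    }
    return aln, used


# ---------------------------------------------------------------------------
# planted protein-DNA energy landscape
# ---------------------------------------------------------------------------


@dataclass
class PlantedSiteSpec:
    """Additive mismatch landscape with a unique planted optimum."""

    target_site: str
    mismatch_penalty: float = 1.0
    noise_sd: float = 0.0
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if not self.target_site or set(self.target_site) - set(BASES):
            raise ValueError("target_site must be a non-empty ACGT string")
        if self.mismatch_penalty <= 0:
            raise ValueError("mismatch_penalty must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


class PlantedOptimumModel:
    """Energy model scoring mismatch-count x penalty (+ optional noise).

    Noise is drawn deterministically per DNA sequence (seeded from a
    CRC of the sequence) so the model is a pure function, as the energy
    contract requires.
    """

    def __init__(self, spec: PlantedSiteSpec):
        self.spec = spec

    @property
    def descriptor(self) -> str:
        s = self.spec
        return (
            f"planted-optimum(target={s.target_site},penalty={s.mismatch_penalty},"
            f"noise_sd={s.noise_sd})"
        )

    def score(self, protein_hd: str, dna) -> float:
        seq = getattr(dna, "sequence", dna)
        if len(seq) != len(self.spec.target_site):
            raise ValueError("DNA length does not match planted target")
        mm = sum(a != b for a, b in zip(seq, self.spec.target_site))
        energy = mm * self.spec.mismatch_penalty
        if self.spec.noise_sd > 0:
            key = zlib.crc32(seq.encode()) ^ (self.spec.noise_seed & 0xFFFFFFFF)
            noise_rng = np.random.default_rng(key)
            energy += noise_rng.normal(0.0, self.spec.noise_sd)
        return float(energy)


def gen_planted_energy_model(spec: PlantedSiteSpec) -> PlantedOptimumModel:
    return PlantedOptimumModel(spec)


# ---------------------------------------------------------------------------
# protein MSAs with planted conserved motifs
# ---------------------------------------------------------------------------


@dataclass
class PlantedMotifSpec:
    """Multi-species protein MSA with planted lineage-spanning motifs.

    ``motifs`` is a list of ``(start_column, residues, carrier_species)``.
    Motifs whose carrier set covers at least half the species and both
    lineage groups enter the truth table; others are still planted but
    excluded from truth (they must not be called conserved).
    """

    species: list[str]
    lineage_partition: tuple[frozenset, frozenset]
    n_columns: int
    motifs: list[tuple[int, str, frozenset]] = field(default_factory=list)
    background_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        g1, g2 = (frozenset(g) for g in self.lineage_partition)
        self.lineage_partition = (g1, g2)
        if g1 & g2:
            raise ValueError("lineage groups must be disjoint")
        if not g1 or not g2:
            raise ValueError("both lineage groups must be non-empty")
        if not (g1 | g2) <= set(self.species):
            raise ValueError("lineage partition names unknown species")
        occupied: list[tuple[int, int]] = []
        for start, residues, carriers in self.motifs:
            if len(residues) < 3:
                raise ValueError("planted motifs must be >= 3 residues")
            if start < 0 or start + len(residues) > self.n_columns:
                raise ValueError("motif outside alignment")
            if not frozenset(carriers) <= set(self.species):
                raise ValueError("motif carriers include unknown species")
            occupied.append((start, start + len(residues)))
        occupied.sort()
        for (s1, e1), (s2, e2) in zip(occupied, occupied[1:]):
            if s2 <= e1:  # adjacency would merge detected runs
                raise ValueError("planted motifs must be separated by >= 1 column")


def motif_in_truth(spec: PlantedMotifSpec, carriers: frozenset) -> bool:
    """Conservation rule for a planted motif: carried by at least half
    the species and by at least one member of each lineage group."""
    g1, g2 = spec.lineage_partition
    half = math.ceil(len(spec.species) / 2)
    return len(carriers) >= half and bool(carriers & g1) and bool(carriers & g2)


def _column_qualifies(
    residues: dict[str, str], species: list[str],
    g1: frozenset, g2: frozenset,
) -> bool:
    """True if some residue state is carried by >= half the species with
    at least one carrier on each side of the lineage partition."""
    half = math.ceil(len(species) / 2)
    counts: dict[str, list[str]] = {}
    for sp in species:
        counts.setdefault(residues[sp], []).append(sp)
    for state, carriers in counts.items():
        cs = set(carriers)
        if len(cs) >= half and cs & g1 and cs & g2:
            return True
    return False


def gen_msa_with_motifs(spec: PlantedMotifSpec):
    """Generate the MSA and a truth table of rule-passing planted motifs.

    Background cells are i.i.d. residues per species; columns outside
    truth motifs are redrawn until they fail the conservation rule, so
    the planted truth is exactly the set of detectable motifs.
    Returns ``(MsaBlock, truth DataFrame)``.
    """
    from .conservation import MsaBlock

    rng = np.random.default_rng(spec.seed)
    g1, g2 = spec.lineage_partition
    n = spec.n_columns
    cols: list[dict[str, str]] = [
        {sp: AMINO_ACIDS[rng.integers(20)] for sp in spec.species} for _ in range(n)
    ]

    truth_rows = []
    truth_cols: set[int] = set()
    for start, residues, carriers in spec.motifs:
        carriers = frozenset(carriers)
        in_truth = motif_in_truth(spec, carriers)
        for k, res in enumerate(residues):
            col = cols[start + k]
            for sp in carriers:
                col[sp] = res
                if spec.background_rate > 0 and rng.random() < spec.background_rate:
                    col[sp] = AMINO_ACIDS[rng.integers(20)]
        if in_truth:
            truth_cols.update(range(start, start + len(residues)))
            truth_rows.append(
                {"start": start, "length": len(residues), "residues": residues,
                 "carriers": ",".join(sorted(carriers))}
            )

    # guarantee non-truth columns do not qualify under the column rule
    for j in range(n):
        if j in truth_cols:
            continue
        fixed = {
            sp for start, residues, carriers in spec.motifs
            if start <= j < start + len(residues)
            for sp in carriers
        }
        for _ in range(1000):
            if not _column_qualifies(cols[j], spec.species, g1, g2):
                break
            for sp in spec.species:
                if sp not in fixed:
                    cols[j][sp] = AMINO_ACIDS[rng.integers(20)]
        else:  # pragma: no cover - essentially unreachable
            raise RuntimeError(f"could not de-conserve background column {j}")

    rows = ["".join(cols[j][sp] for j in range(n)) for sp in spec.species]
    msa = MsaBlock(
        species=list(spec.species), rows=rows,
        lineage_partition=(set(g1), set(g2)),
    )
    truth = pd.DataFrame(truth_rows, columns=["start", "length", "residues", "carriers"])
    return msa, truth


# ---------------------------------------------------------------------------
# synthetic homeodomain reference panel
# ---------------------------------------------------------------------------

# Drosophila Antp homeodomain, the canonical 60-residue reference fold.
ANTP_HOMEODOMAIN = "RKRGRQTYTRYQTLELEKEFHFNRYLTRRRRIEIAHALCLTERQIKIWFQNRRMKWKKEN"

HOX_CLASSES = (
    "lab", "pb", "zen/Shx", "Dfd", "Scr", "ftz", "Antp", "Ubx", "abdA", "AbdB",
)


def gen_reference_panel(
    n_per_class: int = 3, divergence: float = 0.30, seed: int = 0
) -> list[tuple[str, str, str]]:
    """Synthetic labelled homeodomain reference panel for classification.

    Ten class archetypes are derived from the Antp homeodomain scaffold
    by seeded substitution at ``divergence`` of positions, then each
    class is populated with ``n_per_class`` members differing at a few
    further sites. Position 10 carries the Hox3 diagnostic: serine in
    the zen/Shx class and a non-serine residue in every other class.
    Returns a list of ``(id, class, 60-aa sequence)``.
    """
    rng = np.random.default_rng(seed)
    scaffold = ANTP_HOMEODOMAIN[:60]
    n_mut = round(divergence * 60)
    panel = []
    for cls in HOX_CLASSES:
        arche = list(scaffold)
        positions = rng.choice(60, size=n_mut, replace=False)
        for p in positions:
            choices = [a for a in AMINO_ACIDS if a != arche[p]]
            arche[p] = choices[rng.integers(len(choices))]
        if cls == "zen/Shx":
            arche[9] = "S"
        elif arche[9] == "S":
            arche[9] = "T"
        for m in range(n_per_class):
            member = list(arche)
            for p in rng.choice(60, size=3, replace=False):
                if p == 9:
                    continue
                choices = [a for a in AMINO_ACIDS if a != member[p]]
                member[p] = choices[rng.integers(len(choices))]
            panel.append((f"{cls.replace('/', '_')}_{m}", cls, "".join(member)))
    return panel
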