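"""Alignment post-processing, conserved-motif calls and divergence.

A conserved motif is a run of three or more consecutive alignment
columns in each of which some residue state is carried by at least half
the species examined and by at least one species on each side of a
two-group lineage partition (deeply diverging lineages, e.g. basal
moths vs butterflies). Columns with more than 50% missing data are
removed before analysis. Invariant-site percentages and pairwise
divergence matrices (p, Poisson, JTT maximum likelihood) summarise
per-gene-family constraint.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from ._jtt import aa_to_index, jtt_frequencies, jtt_transition_matrix

MISSING = set("-X")


@dataclass
class MsaBlock:
    """Aligned protein block with species labels and lineage partition."""

    species: list[str]
    rows: list[str]
    lineage_partition: tuple[set, set] | None = None

    def __post_init__(self) -> None:
        if len(self.species) != len(self.rows):
            raise ValueError("species and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows must have equal aligned length")
        if self.lineage_partition is not None:
            g1, g2 = (set(g) for g in self.lineage_partition)
            if g1 & g2:
                raise ValueError("lineage groups must be disjoint")
            if not (g1 | g2) <= set(self.species):
                raise ValueError("lineage partition names unknown species")
            self.lineage_partition = (g1, g2)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> dict[str, str]:
        return {sp: row[j] for sp, row in zip(self.species, self.rows)}


@dataclass
class ConservedMotif:
    start_column: int
    length: int
    consensus: str
    support: list[int]  # per-column carrier counts


@dataclass
class InvariantReport:
    gene_group: str
    n_columns: int
    n_invariant: int
    percent_invariant: int  # rounded to nearest integer for reporting


def filter_columns(
    msa: MsaBlock, max_missing_fraction: float = 0.5
) -> tuple[MsaBlock, list[int]]:
    """Drop columns whose missing-data fraction exceeds the threshold.

    Missing means gap '-' or unknown 'X'. A column with a fraction
    exactly at the threshold is kept (the rule is strictly greater
    than). Returns the filtered block and the kept-column index map.
    """
    n = len(msa.species)
    keep = []
    for j in range(msa.n_columns):
        missing = sum(row[j] in MISSING for row in msa.rows)
        if missing / n <= max_missing_fraction:
            keep.append(j)
    if not keep:
        warnings.warn("all columns exceeded the missing-data threshold")
    rows = ["".join(row[j] for j in keep) for row in msa.rows]
    return (
        MsaBlock(species=list(msa.species), rows=rows,
                 lineage_partition=msa.lineage_partition),
        keep,
    )


def column_conserved_state(
    col: dict[str, str], g1: set, g2: set
) -> str | None:
    """The qualifying residue state of a column, or None.

    A state qualifies when carried by >= ceil(n/2) of the species in
    the column's denominator (all species; gaps stay in the denominator
    but never carry) and by >= 1 species of each lineage group. If
    several states qualify the most frequent (then alphabetically
    first) is returned.
    """
    half = math.ceil(len(col) / 2)
    carriers: dict[str, set] = {}
    for sp, aa in col.items():
        if aa in MISSING:
            continue
        carriers.setdefault(aa, set()).add(sp)
    best = None
    for state in sorted(carriers):
        cs = carriers[state]
        if len(cs) >= half and cs & g1 and cs & g2:
            if best is None or len(cs) > len(carriers[best]):
                best = state
    return best


def find_conserved_motifs(msa: MsaBlock) -> list[ConservedMotif]:
    """Report maximal runs of >= 3 qualifying columns as motifs."""
    if msa.lineage_partition is None:
        raise ValueError("lineage partition required for motif detection")
    g1, g2 = msa.lineage_partition
    if not g1 or not g2:
        raise ValueError("both lineage groups must be non-empty")
    states = [
        column_conserved_state(msa.column(j), g1, g2) for j in range(msa.n_columns)
    ]
    motifs: list[ConservedMotif] = []
    j = 0
    n = msa.n_columns
    while j < n:
        if states[j] is None:
            j += 1
            continue
        k = j
        while k < n and states[k] is not None:
            k += 1
        if k - j >= 3:
            consensus = "".join(states[x] for x in range(j, k))
            support = [
                sum(row[x] == states[x] for row in msa.rows) for x in range(j, k)
            ]
            motifs.append(
                ConservedMotif(start_column=j, length=k - j,
                               consensus=consensus, support=support)
            )
        j = k
    return motifs


def invariant_fraction(msa: MsaBlock, gene_group: str = "") -> InvariantReport:
    """Percentage of columns with a single residue state.

    Intended for gapless blocks such as the 60-column homeodomain; the
    reported percentage is rounded to the nearest integer.
    """
    if len(msa.rows) < 2:
        raise ValueError("invariant fraction needs >= 2 sequences")
    n_cols = msa.n_columns
    n_inv = sum(
        len({row[j] for row in msa.rows}) == 1 for j in range(n_cols)
    )
    percent = round(100 * n_inv / n_cols) if n_cols else 0
    return InvariantReport(
        gene_group=gene_group, n_columns=n_cols,
        n_invariant=n_inv, percent_invariant=percent,
    )


@dataclass
class DivergenceMatrix:
    taxa: list[str]
    values: np.ndarray
    model: str
    saturated: list[tuple[str, str]] = field(default_factory=list)


def _pair_sites(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    ia, ib = aa_to_index(a), aa_to_index(b)
    ok = (ia >= 0) & (ib >= 0)  # pairwise deletion of gap/ambiguous sites
    return ia[ok], ib[ok]


def jtt_ml_distance(a: str, b: str, t_max: float = 50.0, tol: float = 1e-6) -> float:
    """Maximum-likelihood distance under the JTT model.

    Optimizes the single time parameter of log L(t) = sum over sites of
    ln(pi_x P_xy(t)) by bounded 1-D search.
    """
    ia, ib = _pair_sites(a, b)
    if ia.size == 0:
        return math.nan
    if np.all(ia == ib):
        return 0.0
    pi = jtt_frequencies()
    counts = np.zeros((20, 20))
    np.add.at(counts, (ia, ib), 1.0)

    def neg_ll(t):
        P = jtt_transition_matrix(t)
        with np.errstate(divide="ignore"):
            ll = counts * np.log(np.clip(pi[:, None] * P, 1e-300, None))
        return -ll.sum()

    res = minimize_scalar(neg_ll, bounds=(1e-8, t_max), method="bounded",
                          options={"xatol": tol})
    return float(res.x)


def pairwise_distance_matrix(
    seqs: dict[str, str], model: str = "p"
) -> DivergenceMatrix:
    """Pairwise divergence under 'p', 'poisson' or 'jtt_ml'.

    p is the mismatch fraction over pairwise-complete sites; poisson is
    -ln(1 - p) (infinite, with a saturation flag, at p = 1); jtt_ml is
    the ML time under the empirical JTT matrix.
    """
    if model not in ("p", "poisson", "jtt_ml"):
        raise ValueError(f"unknown distance model {model!r}")
    taxa = list(seqs)
    n = len(taxa)
    if len({len(s) for s in seqs.values()}) > 1:
        raise ValueError("sequences must be aligned to equal length")
    vals = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[taxa[i]], seqs[taxa[j]]
            if model == "jtt_ml":
                d = jtt_ml_distance(a, b)
            else:
                ia, ib = _pair_sites(a, b)
                p = float(np.mean(ia != ib)) if ia.size else math.nan
                if model == "p":
                    d = p
                else:
                    if p >= 1.0:
                        d = math.inf
                        saturated.append((taxa[i], taxa[j]))
                    else:
                        d = -math.log(1.0 - p)
            vals[i, j] = vals[j, i] = d
    return DivergenceMatrix(taxa=taxa, values=vals, model=model,
                            saturated=saturated)
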